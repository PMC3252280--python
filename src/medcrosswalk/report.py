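"""Match statistics and ground-truth scoring.

Two views are produced.  :func:`compute_match_stats` tabulates, per matching
method, the percentage of left-catalog items with at least one surviving
(MATCH) record — over the complete reference catalog and over the subset of
items actually in use — with the mismatch rate reported separately.  Items
matched more than once count once: the statistic is "% of items matched",
not pairs.  :func:`score_against_truth` replaces expert review on synthetic
data: precision and recall of a crosswalk's matched pairs against the
generator's item-to-drug identity map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .catalog_model import CatalogEntry, CatalogSnapshot
from .crosswalk import MatchMethod, MatchRecord, MatchStatus
from .synthgen import GroundTruth

__all__ = [
    "MatchStats",
    "MethodScore",
    "compute_match_stats",
    "score_against_truth",
    "stats_frame",
    "render_markdown",
    "method_attribute_filter",
]


@dataclass(frozen=True)
class MatchStats:
    """One row of a method-comparison table."""

    label: str
    n_reference: int
    n_reference_matched: int
    n_reference_mismatch: int
    n_in_use: int
    n_in_use_matched: int
    n_in_use_mismatch: int

    def __post_init__(self) -> None:
        for num, den in (
            (self.n_reference_matched, self.n_reference),
            (self.n_reference_mismatch, self.n_reference),
            (self.n_in_use_matched, self.n_in_use),
            (self.n_in_use_mismatch, self.n_in_use),
        ):
            if not 0 <= num <= max(den, num):
                raise ValueError("negative count")

    @staticmethod
    def _pct(num: int, den: int) -> Optional[float]:
        # zero denominators are flagged (None), never divided
        if den == 0:
            return None
        return round(100.0 * num / den, 2)

    @property
    def pct_reference(self) -> Optional[float]:
        return self._pct(self.n_reference_matched, self.n_reference)

    @property
    def pct_reference_mismatch(self) -> Optional[float]:
        return self._pct(self.n_reference_mismatch, self.n_reference)

    @property
    def pct_in_use(self) -> Optional[float]:
        return self._pct(self.n_in_use_matched, self.n_in_use)

    @property
    def pct_in_use_mismatch(self) -> Optional[float]:
        return self._pct(self.n_in_use_mismatch, self.n_in_use)


def compute_match_stats(
    left_snapshot: CatalogSnapshot,
    crosswalks: Mapping[str, Sequence[MatchRecord]],
) -> list[MatchStats]:
    """Tabulate per-method match percentages for one left catalog.

    *crosswalks* maps a method label to its records; only records whose left
    side belongs to *left_snapshot* are counted.  The in-use denominator is
    the snapshot's ``in_use_item_ids``.
    """
    reference_ids = left_snapshot.item_ids
    in_use_ids = left_snapshot.in_use_item_ids
    out = []
    for label, records in crosswalks.items():
        matched: set[str] = set()
        mismatched: set[str] = set()
        for rec in records:
            if rec.left.system_id != left_snapshot.system_id:
                continue
            if rec.left.local_item_id not in reference_ids:
                continue
            if rec.status is MatchStatus.MATCH:
                matched.add(rec.left.local_item_id)
            else:
                mismatched.add(rec.left.local_item_id)
        # a left item whose whole group was demoted counts only as mismatch
        matched -= mismatched
        out.append(
            MatchStats(
                label=label,
                n_reference=len(reference_ids),
                n_reference_matched=len(matched),
                n_reference_mismatch=len(mismatched),
                n_in_use=len(in_use_ids),
                n_in_use_matched=len(matched & in_use_ids),
                n_in_use_mismatch=len(mismatched & in_use_ids),
            )
        )
    return out


def stats_frame(stats: Sequence[MatchStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": s.label,
                "n_reference": s.n_reference,
                "pct_reference": s.pct_reference,
                "pct_reference_mismatch": s.pct_reference_mismatch,
                "n_in_use": s.n_in_use,
                "pct_in_use": s.pct_in_use,
                "pct_in_use_mismatch": s.pct_in_use_mismatch,
            }
            for s in stats
        ]
    )


def _fmt(pct: Optional[float]) -> str:
    return "n/a" if pct is None else f"{pct:.2f}%"


def render_markdown(stats: Sequence[MatchStats]) -> str:
    lines = [
        "| Method | Reference N | Matched (reference) | Mismatch (reference) "
        "| In-use N | Matched (in use) | Mismatch (in use) |",
        "|---|---|---|---|---|---|---|",
    ]
    for s in stats:
        lines.append(
            f"| {s.label} | {s.n_reference} | {_fmt(s.pct_reference)} "
            f"| {_fmt(s.pct_reference_mismatch)} | {s.n_in_use} "
            f"| {_fmt(s.pct_in_use)} | {_fmt(s.pct_in_use_mismatch)} |"
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# ground-truth scoring


@dataclass(frozen=True)
class MethodScore:
    n_matched_pairs: int
    n_correct_pairs: int
    n_true_pairs: int

    @property
    def precision(self) -> Optional[float]:
        """Correct matched pairs / matched pairs; None (undefined) when the
        crosswalk is empty."""
        if self.n_matched_pairs == 0:
            return None
        return self.n_correct_pairs / self.n_matched_pairs

    @property
    def recall(self) -> Optional[float]:
        """Correct matched pairs / true pairs both systems contain; None
        when there are no true pairs to find."""
        if self.n_true_pairs == 0:
            return None
        return self.n_correct_pairs / self.n_true_pairs


def method_attribute_filter(method: MatchMethod):
    """Predicate selecting entries that carry the attribute a method needs."""
    attr = {
        MatchMethod.CHARGE_CODE: "charge_code",
        MatchMethod.DISPENSE_CODE: "dispense_code",
        MatchMethod.PRIMARY_NDC: "primary_ndc",
        MatchMethod.RELATED_NDC: "primary_ndc",
    }.get(method)

    def keep(entry: CatalogEntry) -> bool:
        return attr is None or entry.attribute(attr) is not None

    return keep


def score_against_truth(
    records: Sequence[MatchRecord],
    truth: GroundTruth,
    left: CatalogSnapshot,
    right: CatalogSnapshot,
    restrict=None,
) -> MethodScore:
    """Precision/recall of a crosswalk against the generator's identity map.

    *restrict*, when given, is a predicate on :class:`CatalogEntry` applied
    to both sides of the true-pair universe (e.g. from
    :func:`method_attribute_filter`, so items lacking a method's attribute
    do not count against its recall).
    """
    keep = restrict or (lambda e: True)
    left_items = {e.local_item_id for e in left.entries if keep(e)}
    right_items = {e.local_item_id for e in right.entries if keep(e)}
    true_pairs = {
        (a, b)
        for a, b in truth.true_pairs(left.system_id, right.system_id)
        if a in left_items and b in right_items
    }
    matched: set[tuple[str, str]] = set()
    for rec in records:
        if rec.status is not MatchStatus.MATCH:
            continue
        if (
            rec.left.system_id == left.system_id
            and rec.right.system_id == right.system_id
        ):
            matched.add((rec.left.local_item_id, rec.right.local_item_id))
    id_map = truth.item_to_drug
    correct = {
        (a, b)
        for a, b in matched
        if id_map.get((left.system_id, a)) == id_map.get((right.system_id, b))
        and id_map.get((left.system_id, a)) is not None
    }
    return MethodScore(len(matched), len(correct), len(true_pairs))
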