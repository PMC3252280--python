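"""Vocabulary concept tables and cross-vocabulary links.

The semantic layer consists of per-vocabulary concepts (a Multum MMDC, an
RxNorm clinical drug, a MediSpan GPI ...), the NDC sets that belong to each
concept, and links between concepts of different vocabularies annotated with
the basis of the link (generic name GN, brand name BN, semantic clinical
drug SCD, clinical drug CD).  Three queries drive all vocabulary-based
matching and enrichment:

* which concepts of a vocabulary contain a given NDC;
* the related-NDC closure of an NDC through a vocabulary's concepts; and
* one-hop cross-vocabulary concept mapping restricted to a basis set.

Links are traversed in both directions.  Multi-hop chains are composed
explicitly by the caller so that provenance stays single-concept.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import (
    ConceptNotFoundError,
    ConfigurationError,
    FormatError,
    IntegrityError,
)
from .ndc import is_normalized_ndc

__all__ = [
    "TermType",
    "LinkBasis",
    "VocabularyConcept",
    "CrossVocabLink",
    "VocabGraph",
    "concept_for_ndc",
    "related_ndcs",
    "map_concept",
    "read_concept_table",
    "read_link_table",
    "write_concept_table",
    "write_link_table",
]


class TermType(str, enum.Enum):
    CD = "CD"  # clinical drug
    GN = "GN"  # generic name
    SCD = "SCD"  # semantic clinical drug
    BN = "BN"  # brand name
    MMDC = "MMDC"  # main Multum drug code
    DRUGCODE = "DRUGCODE"  # Multum drug code (dNNNNN)
    GPI = "GPI"  # MediSpan generic product identifier


class LinkBasis(str, enum.Enum):
    GN = "GN"
    BN = "BN"
    SCD = "SCD"
    CD = "CD"


ConceptKey = tuple[str, str]  # (vocabulary_id, concept_id)


@dataclass(frozen=True)
class VocabularyConcept:
    vocabulary_id: str
    concept_id: str
    term_type: TermType
    ndcs: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "term_type", TermType(self.term_type))
        object.__setattr__(self, "ndcs", frozenset(self.ndcs))
        for ndc in self.ndcs:
            if not is_normalized_ndc(ndc):
                raise IntegrityError(
                    f"concept {self.vocabulary_id}:{self.concept_id} carries "
                    f"non-normalized NDC {ndc!r}"
                )

    @property
    def key(self) -> ConceptKey:
        return (self.vocabulary_id, self.concept_id)


@dataclass(frozen=True)
class CrossVocabLink:
    source: ConceptKey
    target: ConceptKey
    basis: LinkBasis

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", tuple(self.source))
        object.__setattr__(self, "target", tuple(self.target))
        object.__setattr__(self, "basis", LinkBasis(self.basis))
        if self.source[0] == self.target[0]:
            raise IntegrityError(
                f"link {self.source} -> {self.target} stays within one vocabulary"
            )


class VocabGraph:
    """Indexed store of vocabulary concepts and cross-vocabulary links."""

    def __init__(
        self,
        concepts: Iterable[VocabularyConcept],
        links: Iterable[CrossVocabLink] = (),
    ) -> None:
        self._concepts: dict[ConceptKey, VocabularyConcept] = {}
        for c in concepts:
            if c.key in self._concepts:
                raise IntegrityError(f"duplicate concept {c.key}")
            self._concepts[c.key] = c
        self._links: tuple[CrossVocabLink, ...] = tuple(links)
        for lk in self._links:
            for endpoint in (lk.source, lk.target):
                if endpoint not in self._concepts:
                    raise IntegrityError(f"link endpoint {endpoint} has no concept")
        # ndc -> vocabulary -> set of concept ids
        self._ndc_index: dict[str, dict[str, set[str]]] = {}
        for c in self._concepts.values():
            for ndc in c.ndcs:
                self._ndc_index.setdefault(ndc, {}).setdefault(
                    c.vocabulary_id, set()
                ).add(c.concept_id)
        # adjacency for bidirectional one-hop mapping
        self._adjacency: dict[ConceptKey, list[tuple[ConceptKey, LinkBasis]]] = {}
        for lk in self._links:
            self._adjacency.setdefault(lk.source, []).append((lk.target, lk.basis))
            self._adjacency.setdefault(lk.target, []).append((lk.source, lk.basis))

    # -- introspection ------------------------------------------------------

    @property
    def vocabularies(self) -> frozenset[str]:
        return frozenset(c.vocabulary_id for c in self._concepts.values())

    @property
    def concepts(self) -> tuple[VocabularyConcept, ...]:
        return tuple(self._concepts.values())

    @property
    def links(self) -> tuple[CrossVocabLink, ...]:
        return self._links

    @property
    def ndc_index(self) -> Mapping[str, Mapping[str, frozenset[str]]]:
        return {
            ndc: {v: frozenset(ids) for v, ids in per_vocab.items()}
            for ndc, per_vocab in self._ndc_index.items()
        }

    def concept(self, key: ConceptKey) -> VocabularyConcept:
        try:
            return self._concepts[tuple(key)]
        except KeyError:
            raise ConceptNotFoundError(tuple(key)) from None

    def __contains__(self, key: ConceptKey) -> bool:
        return tuple(key) in self._concepts

    def _require_vocabulary(self, vocabulary: str) -> None:
        if vocabulary not in self.vocabularies:
            raise ConfigurationError(
                f"unknown vocabulary {vocabulary!r}; graph has "
                f"{sorted(self.vocabularies)}"
            )

    # -- queries ------------------------------------------------------------

    def concept_for_ndc(self, ndc: str, vocabulary: str) -> frozenset[str]:
        """All concept ids of *vocabulary* whose NDC set contains *ndc*.

        Empty when the NDC is unknown to the vocabulary (an "obsolete" NDC).
        """
        self._require_vocabulary(vocabulary)
        return frozenset(self._ndc_index.get(ndc, {}).get(vocabulary, ()))

    def related_ndcs(self, ndc: str, vocabulary: str) -> frozenset[str]:
        """The related-NDC closure of *ndc* through *vocabulary*:
        ``{ndc}`` united with the NDC sets of every concept containing it.

        Always contains the input, even when the NDC is unknown to the
        vocabulary, so primary-NDC matches are a subset of related-NDC
        matches by construction.
        """
        out = {ndc}
        for cid in self.concept_for_ndc(ndc, vocabulary):
            out |= self._concepts[(vocabulary, cid)].ndcs
        return frozenset(out)

    def map_concept(
        self,
        source: ConceptKey,
        target_vocabulary: str,
        bases: Iterable[LinkBasis | str],
    ) -> frozenset[str]:
        """Concept ids of *target_vocabulary* reachable from *source* by one
        cross-vocabulary link whose basis is in *bases* (either direction)."""
        source = tuple(source)
        if source not in self._concepts:
            raise ConceptNotFoundError(source)
        basis_set = {LinkBasis(b) for b in bases}
        return frozenset(
            key[1]
            for key, basis in self._adjacency.get(source, ())
            if key[0] == target_vocabulary and basis in basis_set
        )


# module-level aliases matching the operation names used throughout the docs


def concept_for_ndc(graph: VocabGraph, ndc: str, vocabulary: str) -> frozenset[str]:
    return graph.concept_for_ndc(ndc, vocabulary)


def related_ndcs(graph: VocabGraph, ndc: str, vocabulary: str) -> frozenset[str]:
    return graph.related_ndcs(ndc, vocabulary)


def map_concept(
    graph: VocabGraph,
    source: ConceptKey,
    target_vocabulary: str,
    bases: Iterable[LinkBasis | str],
) -> frozenset[str]:
    return graph.map_concept(source, target_vocabulary, bases)


# ---------------------------------------------------------------------------
# pipe-delimited I/O (RRF-like: one NDC per concept row)

_CONCEPT_COLUMNS = ["vocabulary", "concept_id", "term_type", "ndc"]
_LINK_COLUMNS = ["src_vocab", "src_id", "dst_vocab", "dst_id", "basis"]


def read_concept_table(path: Path | str) -> list[VocabularyConcept]:
    """Read a pipe-delimited concept table (vocabulary|concept_id|term_type|ndc,
    one NDC per row, empty ndc cell for NDC-less concepts)."""
    try:
        df = pd.read_csv(path, sep="|", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header row") from exc
    missing = [c for c in _CONCEPT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    grouped: dict[ConceptKey, tuple[str, set[str]]] = {}
    for r in df.itertuples(index=False):
        key = (r.vocabulary, r.concept_id)
        tt, ndcs = grouped.setdefault(key, (r.term_type, set()))
        if tt != r.term_type:
            raise IntegrityError(f"{path}: conflicting term types for {key}")
        if r.ndc.strip():
            ndcs.add(r.ndc.strip())
    return [
        VocabularyConcept(v, cid, TermType(tt), frozenset(ndcs))
        for (v, cid), (tt, ndcs) in grouped.items()
    ]


def write_concept_table(
    concepts: Iterable[VocabularyConcept], path: Path | str
) -> None:
    rows = []
    for c in sorted(concepts, key=lambda c: c.key):
        ndcs = sorted(c.ndcs) or [""]
        for ndc in ndcs:
            rows.append(
                {
                    "vocabulary": c.vocabulary_id,
                    "concept_id": c.concept_id,
                    "term_type": c.term_type.value,
                    "ndc": ndc,
                }
            )
    pd.DataFrame(rows, columns=_CONCEPT_COLUMNS).to_csv(path, sep="|", index=False)


def read_link_table(path: Path | str) -> list[CrossVocabLink]:
    try:
        df = pd.read_csv(path, sep="|", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header row") from exc
    missing = [c for c in _LINK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return [
        CrossVocabLink((r.src_vocab, r.src_id), (r.dst_vocab, r.dst_id), LinkBasis(r.basis))
        for r in df.itertuples(index=False)
    ]


def write_link_table(links: Iterable[CrossVocabLink], path: Path | str) -> None:
    rows = [
        {
            "src_vocab": lk.source[0],
            "src_id": lk.source[1],
            "dst_vocab": lk.target[0],
            "dst_id": lk.target[1],
            "basis": lk.basis.value,
        }
        for lk in sorted(links, key=lambda l: (l.source, l.target, l.basis.value))
    ]
    pd.DataFrame(rows, columns=_LINK_COLUMNS).to_csv(path, sep="|", index=False)
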