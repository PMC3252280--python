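"""Independent brute-force oracles used to validate the optimized paths.

Everything here is deliberately naive — nested loops and full scans over
the raw tables — and shares no code with the package's indexed
implementations.
"""

from __future__ import annotations


def norm(code: str) -> str:
    return code.strip().casefold()


def metadata_pairs(left_snapshot, right_snapshot, attr: str) -> set[tuple[str, str]]:
    """O(n*m) nested-loop equality scan on one metadata attribute."""
    pairs = set()
    for a in left_snapshot.entries:
        va = getattr(a, attr)
        if va is None:
            continue
        for b in right_snapshot.entries:
            vb = getattr(b, attr)
            if vb is not None and norm(va) == norm(vb):
                pairs.add((a.local_item_id, b.local_item_id))
    return pairs


def primary_ndc_pairs(left_snapshot, right_snapshot) -> set[tuple[str, str]]:
    pairs = set()
    for a in left_snapshot.entries:
        if a.primary_ndc is None:
            continue
        for b in right_snapshot.entries:
            if b.primary_ndc == a.primary_ndc:
                pairs.add((a.local_item_id, b.local_item_id))
    return pairs


def concepts_containing(graph, ndc: str, vocabulary: str) -> set[str]:
    """Full scan of every concept's NDC set."""
    return {
        c.concept_id
        for c in graph.concepts
        if c.vocabulary_id == vocabulary and ndc in c.ndcs
    }


def two_hop_closure(graph, ndc: str, vocabulary: str) -> set[str]:
    """Explicit NDC -> concept -> NDC enumeration, plus the input."""
    out = {ndc}
    for c in graph.concepts:
        if c.vocabulary_id == vocabulary and ndc in c.ndcs:
            out |= set(c.ndcs)
    return out


def related_ndc_pairs(
    left_snapshot, right_snapshot, graph, vocabulary: str
) -> set[tuple[str, str]]:
    """Nested loop over the two-hop closure of each left primary NDC."""
    pairs = set()
    for a in left_snapshot.entries:
        if a.primary_ndc is None:
            continue
        expanded = two_hop_closure(graph, a.primary_ndc, vocabulary)
        for b in right_snapshot.entries:
            raw = set(b.additional_ndcs)
            if b.primary_ndc is not None:
                raw.add(b.primary_ndc)
            if expanded & raw:
                pairs.add((a.local_item_id, b.local_item_id))
    return pairs


def link_filter(graph, source, target_vocabulary: str, bases) -> set[str]:
    """Filter over the full link table, both directions."""
    bases = {getattr(b, "value", b) for b in bases}
    out = set()
    for lk in graph.links:
        if lk.basis.value not in bases:
            continue
        if lk.source == tuple(source) and lk.target[0] == target_vocabulary:
            out.add(lk.target[1])
        if lk.target == tuple(source) and lk.source[0] == target_vocabulary:
            out.add(lk.source[1])
    return out


def in_use_scan(snapshot, orders, transactions, year: int) -> set[str]:
    """Independent full scan for the in-use item set."""
    used = set()
    for e in snapshot.entries:
        for o in orders:
            if (
                o.system_id == snapshot.system_id
                and o.local_item_id == e.local_item_id
                and o.order_date.year == year
            ):
                used.add(e.local_item_id)
        if e.charge_code is not None:
            for t in transactions:
                if t.post_date.year == year and norm(t.charge_code) == norm(e.charge_code):
                    used.add(e.local_item_id)
    return used


def pairs_of(records) -> set[tuple[str, str]]:
    return {(r.left.local_item_id, r.right.local_item_id) for r in records}
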