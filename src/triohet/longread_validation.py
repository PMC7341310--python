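"""Verification of called splicing events against long-read alignments.

A differential event claims that two isoforms — the inclusion and exclusion
forms — are both expressed. Long reads can vouch for that claim: a read
*matches* a chain when its intron junctions, restricted to the event's
span, coincide with the chain's junctions within a boundary tolerance
(long reads carry alignment noise at splice sites). A gene is *covered*
when any read overlaps any of its called events, and *verified* (default
criterion) when at least one called event has both chains each supported by
at least one read; the laxer "any_isoform" criterion accepts a single
matching chain.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from triohet.io_formats import Interval, LongReadAlignment, SpliceEvent
from triohet.modes import round_half_away

DEFAULT_TOLERANCE = 10


def event_span(event: SpliceEvent) -> Interval:
    """[min start, max end) over both chains' blocks."""
    blocks = list(event.inclusion_chain) + list(event.exclusion_chain)
    return min(s for s, _ in blocks), max(e for _, e in blocks)


def _junctions(blocks: Sequence[Interval]) -> list[Interval]:
    """Intron junctions: (donor end, acceptor start) between consecutive blocks."""
    return [(e0, s1) for (_, e0), (s1, _) in zip(blocks, blocks[1:])]


def chain_matches(
    read: LongReadAlignment,
    chain: Sequence[Interval],
    span: Interval,
    tolerance: int = DEFAULT_TOLERANCE,
) -> bool:
    """Does the read's junction structure inside ``span`` reproduce the chain's?

    Junction lists must agree in number and each donor/acceptor boundary
    within ±``tolerance`` bases. A chain with no junctions (e.g. the
    retained-intron inclusion form) matches iff one read block covers the
    whole span — which, blocks being disjoint, also means no junction
    interrupts it.
    """
    lo, hi = span
    read_juncs = [
        (a, b) for a, b in _junctions(read.blocks) if a >= lo - tolerance and b <= hi + tolerance
    ]
    chain_juncs = _junctions(chain)
    if not chain_juncs:
        return any(s <= lo + tolerance and e >= hi - tolerance for s, e in read.blocks)
    if len(read_juncs) != len(chain_juncs):
        return False
    return all(
        abs(ra - ca) <= tolerance and abs(rb - cb) <= tolerance
        for (ra, rb), (ca, cb) in zip(read_juncs, chain_juncs)
    )


def _overlaps(read: LongReadAlignment, span: Interval) -> bool:
    lo, hi = span
    return read.blocks[0][0] < hi and read.blocks[-1][1] > lo


@dataclass(frozen=True)
class ValidationReport:
    """Gene-level rollup of long-read support for called events."""

    n_das_genes: int
    covered: int
    verified: int
    detail: pd.DataFrame  # gene_id, covered, verified, supporting_reads

    @property
    def pct_verified_of_covered(self) -> float | None:
        """Integer percent verified/covered; None (undefined) when nothing is covered."""
        return verification_percentage(self.covered, self.verified)


def verification_percentage(covered: int, verified: int) -> float | None:
    """round(100·verified/covered), half away from zero; None if covered == 0."""
    if covered == 0:
        return None
    return round_half_away(100.0 * verified / covered)


def validate(
    called_events: Iterable[SpliceEvent],
    reads: Sequence[LongReadAlignment],
    mode: str = "both_isoforms",
    tolerance: int = DEFAULT_TOLERANCE,
) -> ValidationReport:
    """Roll called events up to genes and score long-read coverage/verification.

    ``mode`` is "both_isoforms" (an event verifies its gene only when each
    chain has ≥1 matching read) or "any_isoform" (either chain suffices).
    """
    if mode not in ("both_isoforms", "any_isoform"):
        raise ValueError(f"unknown validation mode {mode!r}")
    events = list(called_events)
    by_chrom_strand: dict[tuple[str, str], list[LongReadAlignment]] = defaultdict(list)
    for r in reads:
        by_chrom_strand[(r.chrom, r.strand)].append(r)

    gene_covered: dict[str, bool] = {}
    gene_verified: dict[str, bool] = {}
    gene_support: dict[str, set[str]] = defaultdict(set)
    for ev in events:
        gene_covered.setdefault(ev.gene_id, False)
        gene_verified.setdefault(ev.gene_id, False)
        span = event_span(ev)
        candidates = by_chrom_strand.get((ev.chrom, ev.strand), [])
        inc_hit = exc_hit = False
        for r in candidates:
            if not _overlaps(r, span):
                continue
            gene_covered[ev.gene_id] = True
            matched = False
            if chain_matches(r, ev.inclusion_chain, span, tolerance):
                inc_hit = True
                matched = True
            if chain_matches(r, ev.exclusion_chain, span, tolerance):
                exc_hit = True
                matched = True
            if matched:
                gene_support[ev.gene_id].add(r.read_id)
        event_ok = (inc_hit and exc_hit) if mode == "both_isoforms" else (inc_hit or exc_hit)
        if event_ok:
            gene_verified[ev.gene_id] = True

    detail = pd.DataFrame(
        {
            "gene_id": list(gene_covered),
            "covered": [gene_covered[g] for g in gene_covered],
            "verified": [gene_verified[g] for g in gene_covered],
            "supporting_reads": [",".join(sorted(gene_support[g])) for g in gene_covered],
        }
    )
    covered = int(detail["covered"].sum()) if not detail.empty else 0
    verified = int(detail["verified"].sum()) if not detail.empty else 0
    assert verified <= covered <= len(gene_covered)
    return ValidationReport(
        n_das_genes=len(gene_covered), covered=covered, verified=verified, detail=detail
    )
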