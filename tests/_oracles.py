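"""Independent brute-force oracles for cross-checking the library.

Each function is a deliberately naive re-computation (full scans, per-base
loops) that shares no code with the implementation it checks.
"""
from __future__ import annotations

import numpy as np


def brute_in_island(chrom: str, pos: int, islands) -> bool:
    """Full scan over every island interval (half-open)."""
    return any(i.chrom == chrom and i.start <= pos < i.end for i in islands)


def brute_nearest_tss(chrom: str, pos: int, genes):
    """Exhaustive nearest-TSS search with the documented tie-breaks.

    Returns (gene_id, signed_distance) or None when the chromosome carries
    no genes.  Sign: negative when the site is upstream in the gene's
    reading direction.  Ties: upstream gene first, then gene_id.
    """
    cands = [g for g in genes if g.chrom == chrom]
    if not cands:
        return None
    best = min(abs(pos - g.tss) for g in cands)
    tied = [g for g in cands if abs(pos - g.tss) == best]

    def signed(g):
        return pos - g.tss if g.strand == "+" else g.tss - pos

    tied.sort(key=lambda g: (signed(g) >= 0, g.gene_id))
    return tied[0].gene_id, signed(tied[0])


def brute_promoter_members(window, positions) -> list[int]:
    """Per-base scan: which positions fall inside the window interval."""
    members = []
    covered = set(range(window.start, window.end))
    for p in positions:
        if p in covered:
            members.append(p)
    return members


def brute_coverage_filter(rows, min_reads: int):
    """Row scan of (site_id, reads_control, reads_hypoxic) tuples."""
    kept = []
    for site_id, rc, rh in rows:
        if rc >= min_reads and rh >= min_reads:
            kept.append(site_id)
    return kept


def brute_direction_counts(deltas):
    """Recount hyper/hypo/none from a plain list of delta values."""
    hyper = sum(1 for d in deltas if d > 0)
    hypo = sum(1 for d in deltas if d < 0)
    none = sum(1 for d in deltas if d == 0)
    return hyper, hypo, none


def brute_classify(direction: str, pct_hyper: float, threshold: float = 90.0) -> str:
    """Literal restatement of the concordance rules."""
    lo, hi = 100.0 - threshold, threshold
    if direction == "up" and pct_hyper <= lo:
        return "concordant_up"
    if direction == "down" and pct_hyper >= hi:
        return "concordant_down"
    if direction == "up" and pct_hyper >= hi:
        return "discordant_up"
    if direction == "down" and pct_hyper <= lo:
        return "discordant_down"
    return "unclassified"
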