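"""Integration of promoter methylation change with differential expression.

For each DE gene, the sites falling in its promoter window (1500 bp
upstream to 500 bp downstream of the TSS) are profiled for direction of
methylation change; genes with fewer than two measured promoter sites are
excluded as too noisy.  The per-promoter hypermethylated-site percentage,

    pct_hyper = 100 * n_hyper / n_sites,

is combined with the expression direction into a concordance class using a
90% threshold: an up-regulated gene with a >=90% hypomethylated promoter
(pct_hyper <= 10) is ``concordant_up``; a down-regulated gene with a >=90%
hypermethylated promoter (pct_hyper >= 90) is ``concordant_down``; the
opposite pairings are discordant; everything in between is unclassified.
Concordant genes follow the canonical promoter-methylation paradigm
(hypomethylation with activation, hypermethylation with repression).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord, GenomeAnnotation
from .de import FC_MIN

MIN_PROMOTER_SITES = 2
CONCORDANCE_THRESHOLD = 90.0

CLASSES = (
    "concordant_up",
    "concordant_down",
    "discordant_up",
    "discordant_down",
    "unclassified",
)


@dataclass(frozen=True)
class PromoterProfile:
    """Direction tallies over the measured sites of one gene's promoter."""

    gene_id: str
    n_sites: int
    n_hyper: int
    n_hypo: int
    n_none: int
    pct_hyper: float


def promoter_profile(
    gene: GeneRecord,
    deltas: pd.DataFrame,
    ann: GenomeAnnotation,
    min_sites: int = MIN_PROMOTER_SITES,
    site_change_cutoff: float = 0.0,
) -> Optional[PromoterProfile]:
    """Profile the measured sites inside one gene's promoter window.

    Returns ``None`` (gene rejected) when fewer than ``min_sites`` sites were
    measured.  ``site_change_cutoff`` > 0 demotes small changes to "none";
    by default any nonzero delta counts toward a direction.  Zero-change
    sites stay in the denominator of ``pct_hyper``.
    """
    w = ann.promoter_window(gene)
    sel = deltas[
        (deltas["chrom"] == w.chrom)
        & (deltas["pos"] >= w.start)
        & (deltas["pos"] < w.end)
    ]
    n = len(sel)
    if n < min_sites:
        return None
    d = sel["delta"].to_numpy()
    big = np.abs(d) >= site_change_cutoff if site_change_cutoff > 0 else d != 0
    n_hyper = int(((d > 0) & big).sum())
    n_hypo = int(((d < 0) & big).sum())
    return PromoterProfile(
        gene_id=gene.gene_id,
        n_sites=n,
        n_hyper=n_hyper,
        n_hypo=n_hypo,
        n_none=n - n_hyper - n_hypo,
        pct_hyper=100.0 * n_hyper / n,
    )


def classify_concordance(
    direction: str, pct_hyper: float, threshold: float = CONCORDANCE_THRESHOLD
) -> str:
    """Concordance class from expression direction and promoter pct_hyper.

    Bounds are inclusive: pct_hyper <= 100 - threshold counts as a
    hypomethylated promoter, >= threshold as hypermethylated.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    hypo = pct_hyper <= 100.0 - threshold
    hyper = pct_hyper >= threshold
    if direction == "up":
        if hypo:
            return "concordant_up"
        if hyper:
            return "discordant_up"
    else:
        if hyper:
            return "concordant_down"
        if hypo:
            return "discordant_down"
    return "unclassified"


def integrate(
    de_filtered: pd.DataFrame,
    deltas: pd.DataFrame,
    ann: GenomeAnnotation,
    min_promoter_sites: int = MIN_PROMOTER_SITES,
    threshold: float = CONCORDANCE_THRESHOLD,
    site_change_cutoff: float = 0.0,
) -> pd.DataFrame:
    """Concordance records for every DE gene passing the promoter-site filter.

    ``de_filtered`` is the output of :func:`mscc.de.filter_de` (must carry a
    ``direction`` column).  Genes absent from the annotation or with fewer
    than ``min_promoter_sites`` measured promoter sites are skipped.
    """
    genes = {g.gene_id: g for g in ann.genes}
    rows = []
    for r in de_filtered.itertuples(index=False):
        gene = genes.get(r.gene_id)
        if gene is None:
            continue
        prof = promoter_profile(
            gene, deltas, ann, min_promoter_sites, site_change_cutoff
        )
        if prof is None:
            continue
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "fold_change": r.fold_change,
                "direction": r.direction,
                "n_sites": prof.n_sites,
                "pct_hyper": round(prof.pct_hyper, 4),
                "class": classify_concordance(r.direction, prof.pct_hyper, threshold),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "fold_change", "direction",
            "n_sites", "pct_hyper", "class",
        ],
    )


def classify_table(
    table: pd.DataFrame,
    fc_min: float = FC_MIN,
    threshold: float = CONCORDANCE_THRESHOLD,
) -> pd.DataFrame:
    """Classify rows already in per-promoter summary form.

    Expects columns fold_change and pct_hyper (plus anything else, passed
    through); direction is derived from the fold change.  This is the entry
    point for replaying a published gene table through the classifier.
    """
    out = table.copy()
    fc = out["fold_change"].to_numpy(dtype=float)
    out["direction"] = np.where(fc > fc_min, "up", "down")
    out["class"] = [
        classify_concordance(d, p, threshold)
        for d, p in zip(out["direction"], out["pct_hyper"])
    ]
    return out


def concordance_report(
    records: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-class counts plus a publication-style table sorted by fold change.

    The table runs from the strongest down-regulation to the strongest
    up-regulation with columns chrom, gene, fold_change, n_sites,
    pct_hyper (4 decimals), class.
    """
    counts = pd.Series(0, index=list(CLASSES), dtype=int, name="n_genes")
    if len(records):
        observed = records["class"].value_counts()
        counts.update(observed)
        counts = counts.astype(int)
    name_col = "gene_id" if "gene_id" in records.columns else "gene"
    cols = ["chrom", name_col, "fold_change", "n_sites", "pct_hyper", "class"]
    cols = [c for c in cols if c in records.columns]
    sort_keys = [c for c in ("fold_change", name_col) if c in records.columns]
    table = records.sort_values(sort_keys, kind="mergesort").reset_index(drop=True)[cols]
    if "pct_hyper" in table.columns:
        table["pct_hyper"] = table["pct_hyper"].round(4)
    return counts, table


def write_concordance_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_class_counts_tsv(counts: pd.Series, path) -> None:
    counts.rename_axis("class").reset_index().to_csv(path, sep="\t", index=False)
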