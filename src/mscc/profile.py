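"""Methylome-wide change profile: per-site deltas, direction calls and
region-stratified hyper/hypo summaries.

delta = m_hypoxic - m_control on the absolute fraction scale; a site is
"substantial" when |delta| >= change_cutoff (0.20 by default, i.e. a 20
percentage-point methylation change).  Summaries are tallied genome-wide and
within promoters, CpG islands, and island sites within 1500 bp of a TSS, at
coverage thresholds 30/60/100 combined tags per condition.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import CcggSite, GenomeAnnotation, annotate_sites
from .quant import CONTROL, TREATED

CHANGE_CUTOFF = 0.20
STRATA = ("genome", "promoter", "island", "island_near_tss")
NEAR_TSS_BP = 1500


@dataclass(frozen=True)
class RegionSummary:
    """Hyper/hypo site tallies for one stratum at given thresholds."""

    stratum: str
    n_total: int
    n_hyper: int
    n_hypo: int
    coverage_threshold: int
    change_cutoff: float


def site_deltas(
    meth: pd.DataFrame,
    sites: Sequence[CcggSite],
    ann: GenomeAnnotation,
    change_cutoff: float = CHANGE_CUTOFF,
    conditions: Sequence[str] = (CONTROL, TREATED),
) -> pd.DataFrame:
    """Per-site methylation change with direction and annotation context.

    ``meth`` is the coverage-filtered wide table from
    :func:`mscc.quant.methylation_table`.  Sites present in ``meth`` but not
    in ``sites`` raise; sites on chromosomes outside the annotation are kept
    (genome stratum) but flagged with missing gene context.
    """
    ctl, trt = conditions
    site_df = annotate_sites(sites, ann)
    df = meth.merge(site_df, on="site_id", how="left", validate="one_to_one")
    if df["pos"].isna().any():
        missing = df.loc[df["pos"].isna(), "site_id"].head(3).tolist()
        raise ValueError(f"sites absent from annotation input: {missing}")
    delta = df[f"m_{trt}"].to_numpy() - df[f"m_{ctl}"].to_numpy()
    df["delta"] = delta
    df["direction"] = np.select(
        [delta > 0, delta < 0], ["hyper", "hypo"], default="none"
    )
    df["substantial"] = np.abs(delta) >= change_cutoff
    df = df.rename(
        columns={"in_promoter_of": "promoter_gene", "signed_distance": "tss_distance"}
    )
    df["pos"] = df["pos"].astype(int)
    cols = [
        "site_id", "chrom", "pos",
        f"m_{ctl}", f"m_{trt}", f"reads_{ctl}", f"reads_{trt}",
        "delta", "direction", "substantial",
        "in_island", "promoter_gene", "nearest_gene", "tss_distance",
    ]
    return df[cols]


def _stratum_mask(deltas: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum == "genome":
        return np.ones(len(deltas), dtype=bool)
    if stratum == "promoter":
        return deltas["promoter_gene"].notna().to_numpy()
    if stratum == "island":
        return deltas["in_island"].to_numpy(dtype=bool)
    if stratum == "island_near_tss":
        near = (
            deltas["tss_distance"].abs().to_numpy() <= NEAR_TSS_BP
        ) & deltas["tss_distance"].notna().to_numpy()
        return deltas["in_island"].to_numpy(dtype=bool) & near
    raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")


def summarize_region(
    deltas: pd.DataFrame,
    stratum: str,
    coverage_threshold: int = 30,
    change_cutoff: float = 0.0,
    conditions: Sequence[str] = (CONTROL, TREATED),
) -> RegionSummary:
    """Count hyper-/hypo-methylated sites within one stratum.

    Only sites with at least ``coverage_threshold`` combined tags in each
    condition are counted; with ``change_cutoff`` > 0, sites changing less
    than the cutoff are excluded from both direction tallies (they still
    count in ``n_total``).
    """
    # note: no in-place ops — _stratum_mask may hand back a column view
    mask = _stratum_mask(deltas, stratum)
    for cond in conditions:
        mask = mask & (deltas[f"reads_{cond}"].to_numpy() >= coverage_threshold)
    d = deltas.loc[mask, "delta"].to_numpy()
    big = np.abs(d) >= change_cutoff
    return RegionSummary(
        stratum=stratum,
        n_total=int(mask.sum()),
        n_hyper=int(((d > 0) & big).sum()),
        n_hypo=int(((d < 0) & big).sum()),
        coverage_threshold=coverage_threshold,
        change_cutoff=change_cutoff,
    )


def summarize_all(
    deltas: pd.DataFrame,
    coverage_thresholds: Sequence[int] = (30, 60, 100),
    change_cutoffs: Sequence[float] = (0.0, CHANGE_CUTOFF),
    conditions: Sequence[str] = (CONTROL, TREATED),
) -> pd.DataFrame:
    """All strata x thresholds x cutoffs as one tidy summary table."""
    rows = [
        summarize_region(deltas, s, t, c, conditions)
        for s in STRATA
        for t in coverage_thresholds
        for c in change_cutoffs
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def tss_profile(deltas: pd.DataFrame) -> pd.DataFrame:
    """Signed distance-to-nearest-TSS profile, one row per resolvable site.

    Sites whose chromosome carries no gene (missing nearest TSS) are
    excluded.  ``in_promoter`` marks sites assigned to some gene's promoter.
    """
    ok = deltas["tss_distance"].notna()
    out = deltas.loc[
        ok, ["site_id", "tss_distance", "delta", "in_island", "promoter_gene"]
    ].copy()
    out["tss_distance"] = out["tss_distance"].astype(int)
    out["in_promoter"] = out.pop("promoter_gene").notna()
    return out.reset_index(drop=True)


# ---------------------------------------------------------------- plotting

def plot_methylation_scatter(
    deltas: pd.DataFrame,
    path,
    stratum: str = "genome",
    conditions: Sequence[str] = (CONTROL, TREATED),
) -> None:
    """Optional control-vs-treated methylation scatter for one stratum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ctl, trt = conditions
    sub = deltas[_stratum_mask(deltas, stratum)]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(sub[f"m_{ctl}"], sub[f"m_{trt}"], s=4, alpha=0.3, linewidths=0)
    ax.plot([0, 1], [0, 1], color="grey", lw=0.8)
    ax.set_xlabel(f"methylation, {ctl}")
    ax.set_ylabel(f"methylation, {trt}")
    ax.set_title(stratum)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tss_profile(profile: pd.DataFrame, path, max_bp: int = 10000) -> None:
    """Optional methylation-change vs signed TSS-distance scatter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = profile[profile["tss_distance"].abs() <= max_bp]
    fig, ax = plt.subplots(figsize=(6, 4))
    grey = sub[~(sub["in_island"] & sub["in_promoter"])]
    green = sub[sub["in_island"] & sub["in_promoter"]]
    ax.scatter(grey["tss_distance"], grey["delta"], s=4, alpha=0.3, linewidths=0)
    ax.scatter(
        green["tss_distance"], green["delta"], s=4, alpha=0.5,
        linewidths=0, color="green",
    )
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("distance to nearest TSS (bp; negative = upstream)")
    ax.set_ylabel("methylation change")
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------- I/O

def write_deltas_tsv(deltas: pd.DataFrame, path) -> None:
    deltas.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_summaries_tsv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, sep="\t", index=False, float_format="%.2f")
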