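"""Per-site methylation quantification from two-library MSCC tag counts.

MSCC sequences two tag libraries per sample: a methylation-sensitive library
(HpaII; tags come from unmethylated CCGG molecules, count U) and an inverse
methylation-insensitive library (MspI; tags from methylated molecules,
count M).  The per-site methylation fraction is estimated as the
library-size-normalized share of methylated-library signal,

    m_hat = (M / N_M) / (M / N_M + U / N_U),

which reduces to M / (M + U) for equal library totals and is correctable by
the four internal spike-in standards (0%, 33%, 67%, 100% methylated).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
TREATED = "hypoxic"

#: Default minimum combined tag count (U + M) per condition for a site to
#: be considered measured.
MIN_READS = 30

#: Spike-in standards: reserved contig, site ids and their true fractions.
SPIKEIN_CHROM = "spikein"
SPIKEIN_FRACTIONS: dict[str, float] = {
    "spikein_0": 0.0,
    "spikein_33": 1.0 / 3.0,
    "spikein_67": 2.0 / 3.0,
    "spikein_100": 1.0,
}


class QuantError(ValueError):
    pass


@dataclass(frozen=True)
class LibraryInfo:
    """Total mapped tags per library for one condition (the normalizers)."""

    condition: str
    sensitive_total: int
    insensitive_total: int

    def __post_init__(self) -> None:
        if self.sensitive_total <= 0 or self.insensitive_total <= 0:
            raise QuantError(
                f"library totals for {self.condition} must be positive"
            )


@dataclass(frozen=True)
class CalibrationFit:
    """Linear map from raw m_hat to calibrated fraction, fit on the four
    spike-in standards; ``residuals`` are true - fitted at the standards."""

    slope: float
    intercept: float
    residuals: tuple[float, ...]


def estimate_methylation(
    sensitive_count, insensitive_count, sensitive_total, insensitive_total
):
    """Raw methylation fraction estimate; NaN where U + M = 0 (undefined site).

    Vectorized over array inputs.  Invariant to scaling both libraries'
    counts and totals by a common constant.
    """
    u = np.asarray(sensitive_count, dtype=float)
    m = np.asarray(insensitive_count, dtype=float)
    if np.any(u < 0) or np.any(m < 0):
        raise QuantError("negative tag counts")
    rate_u = u / float(sensitive_total)
    rate_m = m / float(insensitive_total)
    denom = rate_u + rate_m
    with np.errstate(invalid="ignore", divide="ignore"):
        m_hat = np.where(denom > 0, rate_m / np.where(denom > 0, denom, 1.0), np.nan)
    if m_hat.ndim == 0:
        return float(m_hat)
    return m_hat


def default_library_info(counts: pd.DataFrame) -> dict[str, LibraryInfo]:
    """Library totals as column sums of the counts table (spike-ins included),
    used when no explicit LibraryInfo is supplied."""
    info = {}
    for cond, grp in counts.groupby("condition", sort=True):
        info[cond] = LibraryInfo(
            cond,
            int(grp["sensitive_count"].sum()),
            int(grp["insensitive_count"].sum()),
        )
    return info


def is_spikein(site_ids) -> np.ndarray:
    return pd.Series(site_ids, dtype=str).str.startswith("spikein").to_numpy()


def methylation_table(
    counts: pd.DataFrame,
    library_info: Optional[Mapping[str, LibraryInfo]] = None,
    conditions: Sequence[str] = (CONTROL, TREATED),
    calibration: Optional[CalibrationFit] = None,
    drop_spikeins: bool = True,
) -> pd.DataFrame:
    """Wide per-site methylation table from a long counts table.

    ``counts`` columns: site_id, condition, sensitive_count, insensitive_count.
    Output columns: site_id, m_<cond>, reads_<cond> for each condition.
    Sites with U + M = 0 in a condition get NaN there (undefined, excluded
    by the coverage filter).  Spike-in rows contribute to default library
    totals but are dropped from the output unless ``drop_spikeins=False``.
    """
    required = {"site_id", "condition", "sensitive_count", "insensitive_count"}
    missing = required - set(counts.columns)
    if missing:
        raise QuantError(f"counts table missing columns: {sorted(missing)}")
    present = set(counts["condition"].unique())
    absent = set(conditions) - present
    if absent:
        raise QuantError(f"conditions absent from counts table: {sorted(absent)}")
    if library_info is None:
        library_info = default_library_info(counts)

    out: Optional[pd.DataFrame] = None
    for cond in conditions:
        lib = library_info[cond]
        grp = counts[counts["condition"] == cond]
        m_hat = estimate_methylation(
            grp["sensitive_count"].to_numpy(),
            grp["insensitive_count"].to_numpy(),
            lib.sensitive_total,
            lib.insensitive_total,
        )
        if calibration is not None:
            m_hat = apply_calibration(m_hat, calibration)
        part = pd.DataFrame(
            {
                "site_id": grp["site_id"].to_numpy(),
                f"m_{cond}": m_hat,
                f"reads_{cond}": (
                    grp["sensitive_count"].to_numpy()
                    + grp["insensitive_count"].to_numpy()
                ),
            }
        )
        out = part if out is None else out.merge(part, on="site_id", how="outer")
    assert out is not None
    for cond in conditions:
        out[f"reads_{cond}"] = out[f"reads_{cond}"].fillna(0).astype(int)
    if drop_spikeins:
        out = out[~is_spikein(out["site_id"])].reset_index(drop=True)
    return out


def filter_coverage(
    meth: pd.DataFrame,
    min_reads: int = MIN_READS,
    conditions: Sequence[str] = (CONTROL, TREATED),
) -> pd.DataFrame:
    """Keep sites with at least ``min_reads`` combined tags in EACH condition.

    Sites undefined (NaN estimate) in any condition are dropped as well.
    Monotone: raising ``min_reads`` never adds sites.
    """
    keep = np.ones(len(meth), dtype=bool)
    for cond in conditions:
        keep &= meth[f"reads_{cond}"].to_numpy() >= min_reads
        keep &= meth[f"m_{cond}"].notna().to_numpy()
    return meth[keep].reset_index(drop=True)


def fit_calibration(
    raw_m_hat: Sequence[float],
    true_fractions: Sequence[float] = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0),
) -> CalibrationFit:
    """Least-squares line mapping raw estimates at the four internal
    standards to their known fractions."""
    raw = np.asarray(raw_m_hat, dtype=float)
    true = np.asarray(true_fractions, dtype=float)
    if raw.shape != (4,) or true.shape != (4,):
        raise QuantError("calibration requires exactly the four standards")
    if np.any(~np.isfinite(raw)):
        raise QuantError("calibration standards with undefined estimates")
    slope, intercept = np.polyfit(raw, true, 1)
    fitted = slope * raw + intercept
    return CalibrationFit(float(slope), float(intercept), tuple(true - fitted))


def apply_calibration(values, fit: CalibrationFit):
    """Apply a calibration line and clamp into [0, 1]."""
    v = np.asarray(values, dtype=float)
    out = np.clip(fit.slope * v + fit.intercept, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def spikein_calibration(
    counts: pd.DataFrame,
    library_info: Optional[Mapping[str, LibraryInfo]] = None,
    conditions: Sequence[str] = (CONTROL, TREATED),
) -> Optional[CalibrationFit]:
    """Fit one calibration line from the spike-in rows of a counts table.

    Raw estimates at each standard are averaged across conditions so a single
    line applies identically to both samples.  Returns ``None`` (caller logs
    a warning and uses raw values) when any standard is missing.
    """
    meth = methylation_table(
        counts, library_info=library_info, conditions=conditions, drop_spikeins=False
    )
    meth = meth[is_spikein(meth["site_id"])].set_index("site_id")
    raws, trues = [], []
    for sid, frac in SPIKEIN_FRACTIONS.items():
        if sid not in meth.index:
            return None
        vals = [meth.loc[sid, f"m_{c}"] for c in conditions]
        if any(not np.isfinite(v) for v in vals):
            return None
        raws.append(float(np.mean(vals)))
        trues.append(frac)
    return fit_calibration(raws, trues)


# ---------------------------------------------------------------------- I/O

def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"site_id": str})


def read_library_info_tsv(path) -> dict[str, LibraryInfo]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        r.condition: LibraryInfo(
            r.condition, int(r.sensitive_total), int(r.insensitive_total)
        )
        for r in df.itertuples(index=False)
    }


def write_methylation_tsv(meth: pd.DataFrame, path) -> None:
    meth.to_csv(path, sep="\t", index=False, float_format="%.6f")
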