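"""Differential-expression table filtering and fold-change binning.

The pipeline takes a DE results table (gene_id, fold_change, p_value) as
input — differential testing itself is done upstream by dedicated tools —
and applies the significance and effect-size filters: p < 0.05 and fold
change > 1.5 or < 1/1.5 (the "absolute fold change greater than 1.5" rule
read symmetrically on the ratio scale).  No multiple-testing correction is
applied; the filter mirrors the raw-p convention of the upstream analysis.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

P_MAX = 0.05
FC_MIN = 1.5


class DEError(ValueError):
    pass


@dataclass(frozen=True)
class DEGene:
    """One filtered DE gene with its direction call."""

    gene_id: str
    fold_change: float
    p_value: float
    direction: str  # "up" | "down"


def filter_de(
    table: pd.DataFrame, p_max: float = P_MAX, fc_min: float = FC_MIN
) -> pd.DataFrame:
    """Keep genes with p_value < p_max and fold change beyond fc_min in
    either direction; adds a ``direction`` column (up/down).

    Both inequalities are strict, so a gene at exactly fold change 1.5 is
    dropped.  Extra columns pass through untouched.
    """
    for col in ("gene_id", "fold_change", "p_value"):
        if col not in table.columns:
            raise DEError(f"DE table missing column {col!r}")
    fc = table["fold_change"].to_numpy(dtype=float)
    bad = ~(fc > 0)
    if bad.any():
        row = table.index[bad][0]
        raise DEError(
            f"non-positive fold change for gene "
            f"{table.loc[row, 'gene_id']!r} (row {row})"
        )
    p = table["p_value"].to_numpy(dtype=float)
    up = fc > fc_min
    down = fc < 1.0 / fc_min
    keep = (p < p_max) & (up | down)
    out = table.loc[keep].copy()
    out["direction"] = np.where(up[keep], "up", "down")
    return out.reset_index(drop=True)


def fc_histogram(kept: pd.DataFrame, bin_edges: Sequence[float]) -> pd.DataFrame:
    """Tabulate filtered genes into fold-change bins, up and down separately.

    Bins are half-open [edge_i, edge_{i+1}) and must be sorted ascending.
    The binning is exhaustive over genes within [edges[0], edges[-1]);
    genes outside the edge range are counted into the flanking bins is NOT
    done — edges are expected to cover the data.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise DEError("bin_edges must be a sorted 1-D sequence of >= 2 values")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        fc = kept["fold_change"].to_numpy(dtype=float)
        in_bin = (fc >= lo) & (fc < hi)
        dirs = kept["direction"].to_numpy()
        rows.append(
            {
                "bin_left": lo,
                "bin_right": hi,
                "n_up": int((in_bin & (dirs == "up")).sum()),
                "n_down": int((in_bin & (dirs == "down")).sum()),
                "n_total": int(in_bin.sum()),
            }
        )
    return pd.DataFrame(rows)


def read_de_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})


def write_de_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
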