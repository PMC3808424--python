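"""Synthetic MSCC study generator.

Emulates the statistical structure the analysis assumes, with known truth:

* a genome of chromosomes carrying genes (TSS + strand), CpG islands
  preferentially overlapping promoters, and CCGG sites denser inside
  islands;
* a true methylome where island sites are hypomethylated and non-island
  sites methylated at typical somatic levels, and where a configurable
  fraction of genes have every promoter site shifted in the treated
  condition (condition-dependent promoter hypomethylation when the shift is
  negative);
* two-library tag counts per site and condition — sensitive-library tags
  from unmethylated molecules, inverse insensitive-library tags from
  methylated molecules — drawn as independent Poissons, plus the four
  internal calibration standards at 0%, 33%, 67% and 100% methylation on a
  reserved "spikein" contig;
* a differential-expression table with truth labels, standing in for the
  upstream expression analysis.

Everything is reproducible from ``SimulationConfig.seed`` alone.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import (
    CcggSite,
    GeneRecord,
    GenomeAnnotation,
    IslandRecord,
    promoter_window,
)
from .quant import CONTROL, TREATED, LibraryInfo, SPIKEIN_FRACTIONS, SPIKEIN_CHROM


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate the study conditions.

    ``mean_site_depth`` is the expected tag count per site per library;
    ``depth_ratio`` multiplies the insensitive library's depth so the two
    libraries can be sequenced unevenly (exactly what library-size
    normalization must correct).  ``fraction_of_promoters_shifted`` and
    ``shift_size`` define the treated-condition promoter effect;
    ``de_fraction`` and ``lfc_scale`` shape the DE truth.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    n_islands: int = 150
    n_sites: int = 8000
    mean_site_depth: float = 50.0
    depth_ratio: float = 1.0
    spikein_depth: float = 1000.0
    island_meth_mean: float = 0.10
    nonisland_meth_mean: float = 0.75
    meth_concentration: float = 10.0
    fraction_of_promoters_shifted: float = 0.10
    shift_size: float = -0.40
    noise_sd: float = 0.02
    de_fraction: float = 0.02
    up_fraction_of_de: float = 0.61
    lfc_scale: float = 0.5
    island_site_density_ratio: float = 5.0
    island_promoter_overlap_prob: float = 0.6
    island_min_len: int = 500
    island_max_len: int = 2000
    promoter_site_boost: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_of_promoters_shifted",
            "de_fraction",
            "up_fraction_of_de",
            "island_promoter_overlap_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chrom", "n_genes", "n_sites"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_islands < 0:
            raise ConfigError("n_islands must be >= 0")
        for name in ("mean_site_depth", "spikein_depth", "depth_ratio",
                     "lfc_scale", "island_site_density_ratio"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 < self.island_meth_mean < 1 or not 0 < self.nonisland_meth_mean < 1:
            raise ConfigError("baseline methylation means must be in (0, 1)")
        total_bp = self.n_chrom * self.chrom_length
        if self.n_sites + self.n_genes * max(self.promoter_site_boost, 0) > total_bp:
            raise ConfigError("more sites requested than base pairs available")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class TrueMethylome:
    """Ground-truth per-site fractions and per-gene labels.

    ``sites`` columns: site_id, chrom, pos, in_island, shifted, m_control,
    m_treated.  ``genes`` columns: gene_id, de_status (up/down/null),
    promoter_shifted.
    """

    sites: pd.DataFrame
    genes: pd.DataFrame


@dataclass(frozen=True)
class SpikeInStandard:
    """One internal calibration standard with its simulated counts."""

    standard_id: str
    true_fraction: float
    counts: pd.DataFrame  # rows: condition, sensitive_count, insensitive_count


@dataclass
class SimulatedDataset:
    """Everything one simulated study produces."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    sites: list[CcggSite]
    truth: TrueMethylome
    counts: pd.DataFrame
    library_info: dict[str, LibraryInfo]
    standards: list[SpikeInStandard]
    de_table: pd.DataFrame


# ------------------------------------------------------------------ helpers

def _sample_unique_ints(rng: np.random.Generator, low: int, high: int, n: int) -> list[int]:
    if n > high - low:
        raise ConfigError(f"cannot place {n} unique positions in [{low}, {high})")
    chosen: set[int] = set()
    while len(chosen) < n:
        draw = rng.integers(low, high, size=n - len(chosen))
        chosen.update(int(x) for x in draw)
    return sorted(chosen)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ----------------------------------------------------------------- genome

def simulate_genome(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GenomeAnnotation, list[CcggSite]]:
    """Chromosomes, genes, islands and CCGG sites.

    Genes get collision-free TSS positions; each island overlaps a random
    promoter with probability ``island_promoter_overlap_prob`` (centred on
    the TSS) and sits uniformly otherwise; site density inside islands is
    ``island_site_density_ratio`` times the outside density.  With
    ``promoter_site_boost`` > 0, that many guaranteed sites are added inside
    every promoter window on top of the background placement.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = cfg.chrom_length
    chroms = {f"chr{i + 1}": L for i in range(cfg.n_chrom)}
    chrom_names = list(chroms)

    # genes: spread across chromosomes, unique TSS well inside the chromosome
    per_chrom = [cfg.n_genes // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_genes % cfg.n_chrom):
        per_chrom[i] += 1
    genes: list[GeneRecord] = []
    pad = 2000
    gid = 0
    for chrom, n in zip(chrom_names, per_chrom):
        if n == 0:
            continue
        tss = _sample_unique_ints(rng, pad, L - pad, n)
        strands = rng.choice(["+", "-"], size=n)
        for t, s in zip(tss, strands):
            gid += 1
            genes.append(GeneRecord(f"g{gid:05d}", chrom, str(s), int(t)))

    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    # islands: optionally centred on a promoter's TSS
    islands: list[IslandRecord] = []
    for _ in range(cfg.n_islands):
        chrom = str(rng.choice(chrom_names))
        length = int(rng.integers(cfg.island_min_len, cfg.island_max_len + 1))
        cands = genes_by_chrom.get(chrom, [])
        if cands and rng.random() < cfg.island_promoter_overlap_prob:
            g = cands[int(rng.integers(len(cands)))]
            start = g.tss - length // 2
        else:
            start = int(rng.integers(0, L - length))
        start = min(max(start, 0), L - length)
        islands.append(IslandRecord(chrom, start, start + length))

    ann = GenomeAnnotation(chroms, genes, islands)

    # sites: elevated density inside the island union
    union = {
        c: _merge_intervals([(i.start, i.end) for i in islands if i.chrom == c])
        for c in chrom_names
    }
    island_bp = {c: sum(e - s for s, e in union[c]) for c in chrom_names}
    b_in = sum(island_bp.values())
    b_out = cfg.n_chrom * L - b_in
    r = cfg.island_site_density_ratio
    p_in = (r * b_in) / (r * b_in + b_out) if b_in else 0.0
    n_in = int(rng.binomial(cfg.n_sites, p_in))
    n_out = cfg.n_sites - n_in

    positions: set[tuple[str, int]] = set()

    def in_union(chrom: str, pos: int) -> bool:
        for s, e in union[chrom]:
            if s <= pos < e:
                return True
            if s > pos:
                break
        return False

    # inside-island placements: pick a segment weighted by length
    segments = [(c, s, e) for c in chrom_names for s, e in union[c]]
    if segments and n_in:
        weights = np.array([e - s for _, s, e in segments], dtype=float)
        weights /= weights.sum()
        while len(positions) < n_in:
            need = n_in - len(positions)
            picks = rng.choice(len(segments), size=need, p=weights)
            for k in picks:
                c, s, e = segments[k]
                positions.add((c, int(rng.integers(s, e))))
    n_placed_in = len(positions)
    # outside placements: rejection sampling against the island union
    while len(positions) < n_placed_in + n_out:
        need = n_placed_in + n_out - len(positions)
        cs = rng.choice(cfg.n_chrom, size=need)
        ps = rng.integers(0, L, size=need)
        for ci, p in zip(cs, ps):
            chrom = chrom_names[int(ci)]
            if not in_union(chrom, int(p)):
                positions.add((chrom, int(p)))
            if len(positions) >= n_placed_in + n_out:
                break

    # guaranteed promoter sites
    if cfg.promoter_site_boost > 0:
        for g in genes:
            w = ann.promoter_window(g)
            have = sum(
                1 for (c, p) in positions if c == w.chrom and w.start <= p < w.end
            )
            need = cfg.promoter_site_boost - have
            guard = 0
            while need > 0:
                p = int(rng.integers(w.start, w.end))
                if (w.chrom, p) not in positions:
                    positions.add((w.chrom, p))
                    need -= 1
                guard += 1
                if guard > 100 * cfg.promoter_site_boost:
                    raise ConfigError(
                        f"cannot fit {cfg.promoter_site_boost} sites in promoter "
                        f"of {g.gene_id}"
                    )

    order = {c: i for i, c in enumerate(chrom_names)}
    placed = sorted(positions, key=lambda cp: (order[cp[0]], cp[1]))
    sites = [
        CcggSite(f"site_{i:06d}", c, p) for i, (c, p) in enumerate(placed, start=1)
    ]
    return ann, sites


# --------------------------------------------------------------- methylome

def simulate_methylome(
    ann: GenomeAnnotation,
    sites: Sequence[CcggSite],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> TrueMethylome:
    """True per-site fractions and per-gene truth labels.

    Control fractions are Beta-distributed around a low island mean and a
    high non-island mean.  Genes flagged ``promoter_shifted`` have every
    site in their promoter window moved by ``shift_size`` in the treated
    condition (clamped to [0, 1]); all other sites get clipped Gaussian
    noise of sd ``noise_sd``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    k = cfg.meth_concentration

    in_island = np.array([ann.site_in_island(s) for s in sites], dtype=bool)
    n = len(sites)
    mean = np.where(in_island, cfg.island_meth_mean, cfg.nonisland_meth_mean)
    m_control = rng.beta(mean * k, (1.0 - mean) * k, size=n)

    gene_ids = [g.gene_id for g in ann.genes]
    n_genes = len(gene_ids)
    is_de = rng.random(n_genes) < cfg.de_fraction
    is_up = rng.random(n_genes) < cfg.up_fraction_of_de
    de_status = np.where(is_de, np.where(is_up, "up", "down"), "null")
    shifted_gene = rng.random(n_genes) < cfg.fraction_of_promoters_shifted

    shifted_windows = []
    for g, s in zip(ann.genes, shifted_gene):
        if s:
            shifted_windows.append(ann.promoter_window(g))
    site_shifted = np.zeros(n, dtype=bool)
    by_chrom: dict[str, list] = {}
    for w in shifted_windows:
        by_chrom.setdefault(w.chrom, []).append((w.start, w.end))
    for i, s in enumerate(sites):
        for lo, hi in by_chrom.get(s.chrom, ()):
            if lo <= s.pos < hi:
                site_shifted[i] = True
                break

    noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    m_treated = np.where(
        site_shifted,
        np.clip(m_control + cfg.shift_size, 0.0, 1.0),
        np.clip(m_control + noise, 0.0, 1.0),
    )

    site_df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "in_island": in_island,
            "shifted": site_shifted,
            "m_control": m_control,
            "m_treated": m_treated,
        }
    )
    gene_df = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "de_status": de_status,
            "promoter_shifted": shifted_gene,
        }
    )
    return TrueMethylome(site_df, gene_df)


# ------------------------------------------------------------------ counts

def _poisson_counts(
    rng: np.random.Generator, m: np.ndarray, depth_u: float, depth_m: float
) -> tuple[np.ndarray, np.ndarray]:
    u = rng.poisson(depth_u * (1.0 - m))
    mm = rng.poisson(depth_m * m)
    return u, mm


def simulate_site_counts(
    truth: TrueMethylome,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict[str, LibraryInfo], list[SpikeInStandard]]:
    """Two-library Poisson tag counts per site and condition plus spike-ins.

    Sensitive tags U ~ Poisson(d_U * (1 - m)), insensitive tags
    M ~ Poisson(d_M * m) with d_U = mean_site_depth and
    d_M = mean_site_depth * depth_ratio.  The four standards are generated
    the same way at depth ``spikein_depth`` on the reserved contig and
    emitted as ordinary counts rows.  Library totals are the column sums
    including spike-ins.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    d_u = cfg.mean_site_depth
    d_m = cfg.mean_site_depth * cfg.depth_ratio
    frames = []
    spike_rows: dict[str, list] = {sid: [] for sid in SPIKEIN_FRACTIONS}
    for cond, col in ((CONTROL, "m_control"), (TREATED, "m_treated")):
        m = truth.sites[col].to_numpy()
        u, mm = _poisson_counts(rng, m, d_u, d_m)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": truth.sites["site_id"],
                    "condition": cond,
                    "sensitive_count": u,
                    "insensitive_count": mm,
                }
            )
        )
        for sid, frac in SPIKEIN_FRACTIONS.items():
            su, sm = _poisson_counts(
                rng, np.array([frac]), cfg.spikein_depth, cfg.spikein_depth * cfg.depth_ratio
            )
            spike_rows[sid].append(
                {
                    "site_id": sid,
                    "condition": cond,
                    "sensitive_count": int(su[0]),
                    "insensitive_count": int(sm[0]),
                }
            )
    spike_df = pd.DataFrame([row for sid in SPIKEIN_FRACTIONS for row in spike_rows[sid]])
    counts = pd.concat(frames + [spike_df], ignore_index=True)
    # Library totals reflect the per-library sequencing capacity (tags the
    # library would yield were every molecule cut), so N_U/N_M equals the
    # true depth ratio d_U/d_M and normalization corrects it exactly.  This
    # mirrors the real assay, where both libraries are sequenced to a fixed
    # throughput regardless of methylation content, and keeps the invariant
    # totals >= per-site sums.
    n = len(truth.sites)
    cap_u = int(round(d_u * n + 4 * cfg.spikein_depth))
    cap_m = int(round(d_m * n + 4 * cfg.spikein_depth * cfg.depth_ratio))
    library_info = {
        cond: LibraryInfo(cond, cap_u, cap_m) for cond in (CONTROL, TREATED)
    }
    standards = [
        SpikeInStandard(sid, frac, pd.DataFrame(spike_rows[sid]))
        for sid, frac in SPIKEIN_FRACTIONS.items()
    ]
    return counts, library_info, standards


def simulate_spikein_counts(
    rng: np.random.Generator, depth: float, depth_ratio: float = 1.0
) -> pd.DataFrame:
    """One replicate of the four internal standards under the two-library
    Poisson model: U ~ Poisson(d_U·(1-f)), M ~ Poisson(d_M·f).

    Returns rows (standard_id, true_fraction, sensitive_count,
    insensitive_count).  Used for calibration-recovery experiments without
    simulating a whole study.
    """
    rows = []
    for sid, f in SPIKEIN_FRACTIONS.items():
        u, m = _poisson_counts(rng, np.array([f]), depth, depth * depth_ratio)
        rows.append(
            {
                "standard_id": sid,
                "true_fraction": f,
                "sensitive_count": int(u[0]),
                "insensitive_count": int(m[0]),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- DE

def simulate_de_table(
    truth: TrueMethylome,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """DE results with known truth: up genes get fold change
    1.5 * 1.5**|N(0, lfc_scale)| and p ~ U(0, 0.05); down genes the
    reciprocal; null genes fold change near 1 and p ~ U(0, 1)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ln15 = math.log(1.5)
    rows = []
    for r in truth.genes.itertuples(index=False):
        if r.de_status == "up":
            fc = math.exp((abs(rng.normal(0.0, cfg.lfc_scale)) + 1.0) * ln15)
            p = rng.uniform(0.0, 0.05)
        elif r.de_status == "down":
            fc = math.exp(-(abs(rng.normal(0.0, cfg.lfc_scale)) + 1.0) * ln15)
            p = rng.uniform(0.0, 0.05)
        else:
            fc = math.exp(rng.normal(0.0, 0.1 * ln15))
            p = rng.uniform(0.0, 1.0)
        rows.append({"gene_id": r.gene_id, "fold_change": fc, "p_value": p})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ driver

def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator from one seed: genome, methylome, counts, DE."""
    rng = np.random.default_rng(cfg.seed)
    ann, sites = simulate_genome(cfg, rng)
    truth = simulate_methylome(ann, sites, cfg, rng)
    counts, library_info, standards = simulate_site_counts(truth, cfg, rng)
    de_table = simulate_de_table(truth, cfg, rng)
    return SimulatedDataset(
        cfg, ann, sites, truth, counts, library_info, standards, de_table
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write every artifact as deterministic TSV/BED under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "chrom_sizes": out / "chrom_sizes.tsv",
        "genes": out / "genes.tsv",
        "islands": out / "islands.bed",
        "sites": out / "sites.bed",
        "counts": out / "counts.tsv",
        "library_info": out / "library_info.tsv",
        "truth_sites": out / "truth_sites.tsv",
        "truth_genes": out / "truth_genes.tsv",
        "de": out / "de.tsv",
        "config": out / "config.yaml",
    }
    pd.DataFrame(
        {"chrom": list(ds.annotation.chromosomes),
         "length": list(ds.annotation.chromosomes.values())}
    ).to_csv(paths["chrom_sizes"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand, "tss": g.tss}
            for g in ds.annotation.genes
        ]
    ).to_csv(paths["genes"], sep="\t", index=False)
    with open(paths["islands"], "w") as fh:
        for isl in ds.annotation.islands:
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\n")
    with open(paths["sites"], "w") as fh:
        for s in ds.sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 4}\t{s.site_id}\n")
    ds.counts.to_csv(paths["counts"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "condition": li.condition,
                "sensitive_total": li.sensitive_total,
                "insensitive_total": li.insensitive_total,
            }
            for li in ds.library_info.values()
        ]
    ).to_csv(paths["library_info"], sep="\t", index=False)
    ds.truth.sites.to_csv(
        paths["truth_sites"], sep="\t", index=False, float_format="%.6f"
    )
    ds.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    ds.de_table.to_csv(paths["de"], sep="\t", index=False, float_format="%.9g")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(ds.config), fh, sort_keys=True)
    return paths
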