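"""End-to-end pipeline orchestration and the packaged published gene table.

``run_pipeline`` chains the analysis stages — quantify (counts to per-site
methylation), profile (deltas and region summaries), de-filter and
integrate (concordance classes) — over TSV interchange files, records a
manifest with input/output checksums and every threshold, and is
byte-deterministic: re-running on identical inputs reproduces identical
files.  The 59-gene published concordance table ships as a TSV fixture and
is the worked example the classifier can be replayed on.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    GenomeAnnotation,
    read_chrom_sizes,
    read_genes_gtf,
    read_genes_tsv,
    read_islands_bed,
    read_sites_bed,
    read_sites_tsv,
)
from .de import filter_de, read_de_tsv, write_de_tsv
from .integrate import (
    concordance_report,
    integrate,
    write_class_counts_tsv,
    write_concordance_tsv,
)
from .profile import (
    site_deltas,
    summarize_all,
    tss_profile,
    write_deltas_tsv,
    write_summaries_tsv,
)
from .quant import (
    filter_coverage,
    methylation_table,
    read_counts_tsv,
    read_library_info_tsv,
    spikein_calibration,
    write_methylation_tsv,
)

logger = logging.getLogger("mscc")

#: sha256 of the packaged published gene table (59 rows).
TABLE1_SHA256 = "f5e8864ce3f580234bd333b4ac31f1fc21224a7f7ac93bc7251fc48e37dcad24"


class PipelineError(RuntimeError):
    pass


class FixtureError(RuntimeError):
    pass


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 59-row published concordance gene table.

    Columns: chrom, gene, fold_change, n_sites, pct_hyper (the percentage of
    measured promoter sites that were hypermethylated).  The file's sha256
    is verified against a frozen constant to guard the packaging.
    """
    ref = resources.files("mscc").joinpath("data/table1.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise FixtureError(
            f"packaged gene table checksum mismatch: {digest} != {TABLE1_SHA256}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t", dtype={"gene": str})


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run (analysis stages are
    seed-free; only simulation consumes randomness)."""

    counts: Path
    genes: Path
    islands: Path
    sites: Path
    de: Path
    outdir: Path
    chrom_sizes: Optional[Path] = None
    library_info: Optional[Path] = None
    min_reads: int = 30
    change_cutoff: float = 0.20
    coverage_thresholds: Sequence[int] = (30, 60, 100)
    p_max: float = 0.05
    fc_min: float = 1.5
    min_promoter_sites: int = 2
    concordance_threshold: float = 90.0
    site_change_cutoff: float = 0.0
    calibrate: bool = False

    def __post_init__(self) -> None:
        for name in ("counts", "genes", "islands", "sites", "de"):
            setattr(self, name, Path(getattr(self, name)))
        self.outdir = Path(self.outdir)
        if self.chrom_sizes is not None:
            self.chrom_sizes = Path(self.chrom_sizes)
        if self.library_info is not None:
            self.library_info = Path(self.library_info)
        if not 0 < self.p_max <= 1:
            raise PipelineError("p_max must be in (0, 1]")
        if self.fc_min < 1:
            raise PipelineError("fc_min must be >= 1")
        if not 50 <= self.concordance_threshold <= 100:
            raise PipelineError("concordance_threshold must be in [50, 100]")
        if self.min_reads < 0 or self.min_promoter_sites < 0:
            raise PipelineError("count thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_annotation(cfg: PipelineConfig) -> tuple[GenomeAnnotation, list]:
    if cfg.genes.suffix.lower() in (".gtf", ".gff"):
        genes = read_genes_gtf(cfg.genes)
    else:
        genes = read_genes_tsv(cfg.genes)
    islands = read_islands_bed(cfg.islands)
    if cfg.sites.suffix.lower() == ".bed":
        sites = read_sites_bed(cfg.sites)
    else:
        sites = read_sites_tsv(cfg.sites)
    if cfg.chrom_sizes is not None:
        chroms = read_chrom_sizes(cfg.chrom_sizes)
    else:
        # infer: everything needs to fit, pad past the largest coordinate
        chroms: dict[str, int] = {}
        for g in genes:
            chroms[g.chrom] = max(chroms.get(g.chrom, 0), g.tss + 2001)
        for isl in islands:
            chroms[isl.chrom] = max(chroms.get(isl.chrom, 0), isl.end + 1)
        for s in sites:
            chroms[s.chrom] = max(chroms.get(s.chrom, 0), s.pos + 5)
    ann = GenomeAnnotation(chroms, genes, islands)
    return ann, sites


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute quantify -> profile -> de-filter -> integrate; return the manifest.

    Aborts before any stage runs if an input path is missing, naming it.
    """
    inputs = {
        "counts": cfg.counts,
        "genes": cfg.genes,
        "islands": cfg.islands,
        "sites": cfg.sites,
        "de": cfg.de,
    }
    if cfg.chrom_sizes is not None:
        inputs["chrom_sizes"] = cfg.chrom_sizes
    if cfg.library_info is not None:
        inputs["library_info"] = cfg.library_info
    for name, path in inputs.items():
        if not Path(path).is_file():
            raise PipelineError(f"input file for {name!r} not found: {path}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)

    stage = "quantify"
    try:
        counts = read_counts_tsv(cfg.counts)
        library_info = (
            read_library_info_tsv(cfg.library_info)
            if cfg.library_info is not None
            else None
        )
        calibration = None
        if cfg.calibrate:
            calibration = spikein_calibration(counts, library_info)
            if calibration is None:
                logger.warning(
                    "[quantify] spike-in standards incomplete; using raw estimates"
                )
        meth = methylation_table(counts, library_info, calibration=calibration)
        meth = filter_coverage(meth, cfg.min_reads)
        meth_path = cfg.outdir / "methylation.tsv"
        write_methylation_tsv(meth, meth_path)
        logger.info("[quantify] %d sites pass the %d-read filter", len(meth), cfg.min_reads)

        stage = "profile"
        ann, sites = _load_annotation(cfg)
        site_ids = {s.site_id for s in sites}
        meth = meth[meth["site_id"].isin(site_ids)].reset_index(drop=True)
        deltas = site_deltas(meth, sites, ann, cfg.change_cutoff)
        deltas_path = cfg.outdir / "site_profile.tsv"
        write_deltas_tsv(deltas, deltas_path)
        summaries = summarize_all(
            deltas,
            coverage_thresholds=cfg.coverage_thresholds,
            change_cutoffs=(0.0, cfg.change_cutoff),
        )
        summaries_path = cfg.outdir / "region_summaries.tsv"
        write_summaries_tsv(summaries, summaries_path)
        profile_path = cfg.outdir / "tss_profile.tsv"
        tss_profile(deltas).to_csv(
            profile_path, sep="\t", index=False, float_format="%.6f"
        )
        logger.info("[profile] %d sites profiled", len(deltas))

        stage = "de-filter"
        de_table = read_de_tsv(cfg.de)
        de_kept = filter_de(de_table, cfg.p_max, cfg.fc_min)
        de_path = cfg.outdir / "de_filtered.tsv"
        write_de_tsv(de_kept, de_path)
        logger.info("[de-filter] %d genes pass", len(de_kept))

        stage = "integrate"
        records = integrate(
            de_kept,
            deltas,
            ann,
            cfg.min_promoter_sites,
            cfg.concordance_threshold,
            cfg.site_change_cutoff,
        )
        counts_by_class, table = concordance_report(records)
        concordance_path = cfg.outdir / "concordance.tsv"
        write_concordance_tsv(table, concordance_path)
        class_counts_path = cfg.outdir / "class_counts.tsv"
        write_class_counts_tsv(counts_by_class, class_counts_path)
        logger.info("[integrate] class counts: %s", counts_by_class.to_dict())
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    outputs = {
        "methylation": meth_path,
        "site_profile": deltas_path,
        "region_summaries": summaries_path,
        "tss_profile": profile_path,
        "de_filtered": de_path,
        "concordance": concordance_path,
        "class_counts": class_counts_path,
    }
    manifest = {
        "version": __version__,
        "thresholds": {
            "min_reads": cfg.min_reads,
            "change_cutoff": cfg.change_cutoff,
            "coverage_thresholds": list(cfg.coverage_thresholds),
            "p_max": cfg.p_max,
            "fc_min": cfg.fc_min,
            "min_promoter_sites": cfg.min_promoter_sites,
            "concordance_threshold": cfg.concordance_threshold,
            "site_change_cutoff": cfg.site_change_cutoff,
            "calibrate": cfg.calibrate,
        },
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "outputs": {
            k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()
        },
        "class_counts": counts_by_class.to_dict(),
    }
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
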