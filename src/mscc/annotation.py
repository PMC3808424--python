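"""Genome annotation model for MSCC analysis.

Holds the coordinate frame everything else hangs off: chromosomes, gene
transcription start sites (TSS), CpG islands and the measurable CCGG sites
(the HpaII/MspI recognition motif).  Provides promoter windowing, island
membership and signed nearest-TSS distances.

Coordinate convention: 0-based, half-open everywhere.  BED input is native;
GTF-dialect input (1-based, closed intervals) is converted on read.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: Promoter window extent relative to the TSS, in the gene's reading
#: direction: 1500 bp upstream to 500 bp downstream.
PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500


class AnnotationError(ValueError):
    """Raised for inconsistent annotation (unknown chromosome, bad interval)."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to the attributes the analysis needs: one TSS per gene."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise AnnotationError(f"gene {self.gene_id}: tss must be >= 0")


@dataclass(frozen=True)
class IslandRecord:
    """A CpG island interval, half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"island {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )


@dataclass(frozen=True)
class CcggSite:
    """A measurable CCGG site; ``pos`` is the first C on the forward strand."""

    site_id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise AnnotationError(f"site {self.site_id}: pos must be >= 0")


@dataclass(frozen=True)
class PromoterWindow:
    """Half-open promoter interval of one gene (width 2000 bp unless clipped)."""

    gene_id: str
    chrom: str
    start: int
    end: int


def signed_tss_distance(pos: int, gene: GeneRecord) -> int:
    """Signed distance from ``pos`` to the gene's TSS in reading direction.

    Negative means the position is upstream of the TSS (for a minus-strand
    gene, positions with ``pos > tss`` are upstream).
    """
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def promoter_window(
    gene: GeneRecord,
    chrom_length: Optional[int] = None,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> PromoterWindow:
    """Strand-aware promoter window: [tss-upstream, tss+downstream) in the
    gene's reading direction, clipped to the chromosome."""
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return PromoterWindow(gene.gene_id, gene.chrom, start, end)


def _tie_break_key(pos: int):
    """Sort key for equidistant genes: upstream first, then gene_id."""

    def key(gene: GeneRecord):
        return (signed_tss_distance(pos, gene) >= 0, gene.gene_id)

    return key


@dataclass
class GenomeAnnotation:
    """Chromosomes, genes and CpG islands with cached interval indexes.

    ``chromosomes`` maps chromosome name to length in bp.  Validates that
    names are unique, gene ids are unique and every feature lies within its
    chromosome.
    """

    chromosomes: dict[str, int]
    genes: list[GeneRecord]
    islands: list[IslandRecord]
    _island_trees: dict[str, IntervalTree] = field(init=False, repr=False)
    _promoter_trees: dict[str, IntervalTree] = field(init=False, repr=False)
    _tss_index: dict[str, tuple[np.ndarray, list[GeneRecord]]] = field(
        init=False, repr=False
    )
    promoter_upstream: int = PROMOTER_UPSTREAM
    promoter_downstream: int = PROMOTER_DOWNSTREAM

    def __post_init__(self) -> None:
        self.chromosomes = dict(self.chromosomes)
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise AnnotationError(f"chromosome {name}: non-positive length")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate gene ids: {dup[:5]}")
        for g in self.genes:
            length = self._chrom_length(g.chrom, f"gene {g.gene_id}")
            if g.tss >= length:
                raise AnnotationError(
                    f"gene {g.gene_id}: tss {g.tss} outside {g.chrom} [0, {length})"
                )
        for isl in self.islands:
            length = self._chrom_length(isl.chrom, f"island {isl.start}-{isl.end}")
            if isl.end > length:
                raise AnnotationError(
                    f"island {isl.chrom}:{isl.start}-{isl.end} outside [0, {length})"
                )
        self._build_indexes()

    def _chrom_length(self, chrom: str, what: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise AnnotationError(f"{what}: unknown chromosome {chrom!r}") from None

    def _build_indexes(self) -> None:
        self._island_trees = {}
        for isl in self.islands:
            self._island_trees.setdefault(isl.chrom, IntervalTree()).addi(
                isl.start, isl.end, isl
            )
        self._promoter_trees = {}
        self._tss_index = {}
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
            w = self.promoter_window(g)
            if w.end > w.start:
                self._promoter_trees.setdefault(g.chrom, IntervalTree()).addi(
                    w.start, w.end, g
                )
        for chrom, genes in by_chrom.items():
            genes = sorted(genes, key=lambda g: (g.tss, g.gene_id))
            self._tss_index[chrom] = (
                np.array([g.tss for g in genes], dtype=np.int64),
                genes,
            )

    # ------------------------------------------------------------------ queries

    def promoter_window(self, gene: GeneRecord) -> PromoterWindow:
        """Promoter window of ``gene``, clipped to its chromosome."""
        length = self._chrom_length(gene.chrom, f"gene {gene.gene_id}")
        return promoter_window(
            gene, length, self.promoter_upstream, self.promoter_downstream
        )

    def site_in_island(self, site: CcggSite) -> bool:
        """True iff the site position falls inside any CpG island (union test)."""
        self._chrom_length(site.chrom, f"site {site.site_id}")
        tree = self._island_trees.get(site.chrom)
        return bool(tree is not None and tree.overlaps_point(site.pos))

    def nearest_tss_distance(self, site: CcggSite) -> Optional[tuple[str, int]]:
        """Nearest gene by |pos - tss| and the signed, strand-aware distance.

        Ties between equidistant genes break toward the gene the site is
        upstream of, then lexicographically by gene id.  Returns ``None``
        when the chromosome carries no genes (flagged-missing; such sites
        are excluded from TSS profiles).
        """
        idx = self._tss_index.get(site.chrom)
        if idx is None:
            return None
        tss, genes = idx
        dist = np.abs(tss - site.pos)
        best = int(dist.min())
        cands = [genes[i] for i in np.flatnonzero(dist == best)]
        g = min(cands, key=_tie_break_key(site.pos))
        return g.gene_id, signed_tss_distance(site.pos, g)

    def promoter_gene(self, site: CcggSite) -> Optional[str]:
        """Gene whose promoter window contains the site, or ``None``.

        When overlapping windows both contain the site, the gene with the
        nearest TSS wins (same tie-break as :meth:`nearest_tss_distance`),
        so downstream strata stay disjoint.
        """
        tree = self._promoter_trees.get(site.chrom)
        if tree is None:
            return None
        hits = [iv.data for iv in tree[site.pos]]
        if not hits:
            return None
        best = min(abs(signed_tss_distance(site.pos, g)) for g in hits)
        cands = [g for g in hits if abs(signed_tss_distance(site.pos, g)) == best]
        return min(cands, key=_tie_break_key(site.pos)).gene_id


def annotate_sites(
    sites: Sequence[CcggSite], ann: GenomeAnnotation
) -> pd.DataFrame:
    """Per-site annotation table.

    Columns: site_id, chrom, pos, in_island, in_promoter_of, nearest_gene,
    signed_distance.  Sites on chromosomes absent from the annotation get
    in_island=False and missing gene fields (they stay in genome-wide
    tallies but drop out of region strata).
    """
    rows = []
    known = ann.chromosomes
    for s in sites:
        if s.chrom in known:
            in_island = ann.site_in_island(s)
            prom = ann.promoter_gene(s)
            near = ann.nearest_tss_distance(s)
        else:
            in_island, prom, near = False, None, None
        rows.append(
            {
                "site_id": s.site_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "in_island": in_island,
                "in_promoter_of": prom,
                "nearest_gene": near[0] if near else None,
                "signed_distance": near[1] if near else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "chrom",
            "pos",
            "in_island",
            "in_promoter_of",
            "nearest_gene",
            "signed_distance",
        ],
    )


# ---------------------------------------------------------------------- I/O

_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["chrom"], df["length"].astype(int)))


def read_genes_tsv(path) -> list[GeneRecord]:
    """Genes from TSV with columns gene_id, chrom, strand, tss (0-based)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    return [
        GeneRecord(r.gene_id, r.chrom, r.strand, int(r.tss))
        for r in df.itertuples(index=False)
    ]


def read_genes_gtf(path) -> list[GeneRecord]:
    """Genes from a GTF-dialect file (1-based, closed intervals).

    Uses 'gene' feature rows (falling back to 'transcript' if none); the TSS
    is the 5' end in reading direction, converted to 0-based.
    """
    feats: dict[str, list] = {"gene": [], "transcript": []}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in feats:
                continue
            m = _GTF_GENE_ID.search(parts[8])
            if not m:
                raise AnnotationError(f"GTF row without gene_id attribute: {line!r}")
            chrom, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
            tss = start - 1 if strand == "+" else end - 1
            feats[parts[2]].append(GeneRecord(m.group(1), chrom, strand, tss))
    rows = feats["gene"] or feats["transcript"]
    seen: dict[str, GeneRecord] = {}
    for g in rows:
        seen.setdefault(g.gene_id, g)
    return list(seen.values())


def read_islands_bed(path) -> list[IslandRecord]:
    """CpG islands from BED3 (0-based half-open, native convention)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    return [
        IslandRecord(r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def read_sites_bed(path) -> list[CcggSite]:
    """CCGG sites from BED4 (name column = site_id; start = site position)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 3],
        names=["chrom", "pos", "site_id"], dtype={"site_id": str},
    )
    return [
        CcggSite(r.site_id, r.chrom, int(r.pos)) for r in df.itertuples(index=False)
    ]


def read_sites_tsv(path) -> list[CcggSite]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"site_id": str})
    return [
        CcggSite(r.site_id, r.chrom, int(r.pos)) for r in df.itertuples(index=False)
    ]


def write_site_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.0f")
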