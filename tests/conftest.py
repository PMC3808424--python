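import numpy as np
import pytest
from hypothesis import settings

from mscc.annotation import CcggSite, GeneRecord, GenomeAnnotation, IslandRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """A two-chromosome toy genome with genes on both strands and islands."""
    genes = [
        GeneRecord("gA", "chr1", "+", 10_000),
        GeneRecord("gB", "chr1", "-", 30_000),
        GeneRecord("gC", "chr2", "+", 5_000),
    ]
    islands = [
        IslandRecord("chr1", 50, 200),
        IslandRecord("chr1", 9_000, 11_000),
        IslandRecord("chr2", 4_000, 6_000),
    ]
    return GenomeAnnotation({"chr1": 100_000, "chr2": 50_000}, genes, islands)


def random_genome(rng: np.random.Generator, n_genes=30, n_islands=15, n_sites=400,
                  length=100_000, n_chrom=2):
    """Small random genome for oracle-equivalence checks."""
    chroms = {f"chr{i + 1}": length for i in range(n_chrom)}
    names = list(chroms)
    genes = []
    used = set()
    while len(genes) < n_genes:
        c = names[int(rng.integers(n_chrom))]
        t = int(rng.integers(0, length))
        if (c, t) in used:
            continue
        used.add((c, t))
        genes.append(
            GeneRecord(f"g{len(genes):04d}", c, str(rng.choice(["+", "-"])), t)
        )
    islands = []
    for _ in range(n_islands):
        c = names[int(rng.integers(n_chrom))]
        s = int(rng.integers(0, length - 500))
        islands.append(IslandRecord(c, s, s + int(rng.integers(100, 500))))
    seen = set()
    sites = []
    while len(sites) < n_sites:
        c = names[int(rng.integers(n_chrom))]
        p = int(rng.integers(0, length))
        if (c, p) in seen:
            continue
        seen.add((c, p))
        sites.append(CcggSite(f"s{len(sites):05d}", c, p))
    return GenomeAnnotation(chroms, genes, islands), sites
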