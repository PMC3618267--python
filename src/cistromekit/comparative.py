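"""Peak-set comparison: overlap partitioning, coverage by other factors,
paired testing, subpopulation motif enrichment, and chromosome correlation.

Overlap between two region sets is counted directionally: ``n_A_and_B`` is
the number of A regions overlapping at least one B region (>= 1 shared bp by
default), which in general differs from ``n_B_and_A``. This matches how a
Venn-style comparison of two ChIP-seq factors counts "regions of factor B
also targeted by factor A".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import GeneModel, GenomicRegion, PSFM
from .motifscan import EnrichmentResult, enrichment_stats, scan_regions

__all__ = [
    "OverlapPartition",
    "overlap_partition",
    "covered_percentage",
    "paired_difference_test",
    "subpopulation_motif_enrichment",
    "chromosome_correlation",
]


@dataclass
class OverlapPartition:
    """Directional overlap partition of two region sets."""

    a_specific: list[GenomicRegion]
    a_shared: list[GenomicRegion]
    b_specific: list[GenomicRegion]
    b_shared: list[GenomicRegion]

    @property
    def n_a(self) -> int:
        return len(self.a_specific) + len(self.a_shared)

    @property
    def n_b(self) -> int:
        return len(self.b_specific) + len(self.b_shared)

    @property
    def n_a_and_b(self) -> int:
        return len(self.a_shared)

    @property
    def n_b_and_a(self) -> int:
        return len(self.b_shared)

    @property
    def n_a_specific(self) -> int:
        return len(self.a_specific)

    @property
    def n_b_specific(self) -> int:
        return len(self.b_specific)


def _build_trees(regions: list[GenomicRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def _overlaps(region: GenomicRegion, trees, min_overlap: int) -> bool:
    tree = trees.get(region.chrom)
    if tree is None:
        return False
    for iv in tree.overlap(region.start, region.end):
        shared = min(region.end, iv.end) - max(region.start, iv.begin)
        if shared >= min_overlap:
            return True
    return False


def overlap_partition(
    set_a: list[GenomicRegion],
    set_b: list[GenomicRegion],
    min_overlap: int = 1,
) -> OverlapPartition:
    """Split each set into regions overlapping the other set vs specific ones."""
    if not set_a or not set_b:
        warnings.warn("overlap_partition called with an empty set", stacklevel=2)
    trees_a = _build_trees(set_a)
    trees_b = _build_trees(set_b)
    a_spec, a_shared, b_spec, b_shared = [], [], [], []
    for r in set_a:
        (a_shared if _overlaps(r, trees_b, min_overlap) else a_spec).append(r)
    for r in set_b:
        (b_shared if _overlaps(r, trees_a, min_overlap) else b_spec).append(r)
    return OverlapPartition(a_spec, a_shared, b_spec, b_shared)


def covered_percentage(
    target_regions: list[GenomicRegion],
    factor_sets: dict[str, list[GenomicRegion]],
    min_overlap: int = 1,
) -> dict[str, float]:
    """Fraction of target regions overlapped by each named factor set."""
    if not target_regions:
        raise ValueError("empty target set")
    if not factor_sets:
        raise ValueError("need at least one factor set")
    report = {}
    for name, regions in factor_sets.items():
        trees = _build_trees(regions)
        covered = sum(_overlaps(r, trees, min_overlap) for r in target_regions)
        report[name] = covered / len(target_regions)
    return report


def paired_difference_test(x, y):
    """Paired t-test on matched per-factor fractions.

    Returns (mean difference, t statistic, two-sided p). With zero variance
    of the differences: p = 1 when the mean difference is 0, else the p-value
    is reported as the smallest positive float (below machine precision).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean_d = float(d.mean())
    if float(d.std(ddof=1)) == 0.0:
        if mean_d == 0.0:
            return 0.0, 0.0, 1.0
        t = float("inf") if mean_d > 0 else float("-inf")
        return mean_d, t, float(np.finfo(float).tiny)
    t, p = stats.ttest_rel(x, y)
    return mean_d, float(t), float(p)


def subpopulation_motif_enrichment(
    partition: OverlapPartition,
    psfm: PSFM,
    genome: dict[str, str],
    background: list[GenomicRegion],
    threshold: float = 0.9,
    both_strands: bool = True,
) -> dict[str, EnrichmentResult]:
    """Motif enrichment in the three overlap subpopulations (A-specific,
    shared, B-specific) against one common background region set."""
    _, n_bg, l_bg = scan_regions(psfm, background, genome, threshold, both_strands)
    results = {}
    subpops = {
        "A_specific": partition.a_specific,
        "A_and_B": partition.a_shared,
        "B_specific": partition.b_specific,
    }
    for name, regions in subpops.items():
        if not regions:
            warnings.warn(f"subpopulation {name} is empty: skipped", stacklevel=2)
            continue
        _, n_s, l_s = scan_regions(psfm, regions, genome, threshold, both_strands)
        results[name] = enrichment_stats(n_s, l_s, n_bg, l_bg, motif=psfm.name)
    return results


def chromosome_correlation(
    peaks: list[GenomicRegion],
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
):
    """Squared Pearson correlation of per-chromosome peak counts against gene
    counts (distinct gene names) and against nucleotide counts.

    Returns (r2_gene, r2_nucleotide, per-chromosome table as a dict of lists).
    Chromosomes are those listed in ``chrom_sizes``.
    """
    chroms = list(chrom_sizes)
    if len(chroms) < 3:
        raise ValueError("need at least 3 chromosomes")
    peak_counts = np.array([sum(p.chrom == c for p in peaks) for c in chroms], dtype=float)
    gene_counts = np.array(
        [len({g.name for g in genes if g.chrom == c}) for c in chroms], dtype=float
    )
    nt_counts = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    if peak_counts.std() == 0:
        raise ValueError("degenerate: peak counts have zero variance across chromosomes")
    r_gene = stats.pearsonr(peak_counts, gene_counts).statistic
    r_nt = stats.pearsonr(peak_counts, nt_counts).statistic
    table = {
        "chrom": chroms,
        "n_peaks": peak_counts.astype(int).tolist(),
        "n_genes": gene_counts.astype(int).tolist(),
        "n_nucleotides": nt_counts.astype(int).tolist(),
    }
    return float(r_gene**2), float(r_nt**2), table
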