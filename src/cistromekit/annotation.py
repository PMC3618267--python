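"""Priority-based genomic annotation of ChIP-seq peaks against gene models.

Each peak is anchored at its summit (midpoint fallback) and assigned exactly
one category relative to nearby genes, in gene-oriented coordinates:

    promoter             TSS - 2 kb .. TSS + 1 kb          (closed both ends)
    gene_body            (TSS + 1 kb, TES]
    upstream_enhancer    [TSS - 50 kb, TSS - 2 kb)
    downstream_enhancer  (TES, TES + 50 kb]
    distal_intergenic    > 50 kb from every gene

"Upstream"/"downstream" follow the gene's strand. When several genes place
the anchor in different categories, the highest-priority category wins
(promoter > gene body > upstream enhancer > downstream enhancer); ties within
a category go to the smallest |distance to TSS|, then lexicographic gene name,
so the assignment is deterministic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from .io_formats import GeneModel, GenomicRegion

__all__ = [
    "CATEGORIES",
    "PeakAnnotation",
    "GeneIndex",
    "classify_peak",
    "annotate_peaks",
    "gene_target_summary",
]

CATEGORIES = (
    "promoter",
    "gene_body",
    "upstream_enhancer",
    "downstream_enhancer",
    "distal_intergenic",
)
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}

PROMOTER_UP = 2_000
PROMOTER_DOWN = 1_000
ENHANCER_RANGE = 50_000


@dataclass
class PeakAnnotation:
    """One peak, its unique category, linked gene and gene-oriented TSS distance.

    ``gene`` and ``distance_to_tss`` are absent exactly when the category is
    distal_intergenic. Distance is signed in the gene's reading direction:
    negative upstream of the TSS, positive downstream.
    """

    peak: GenomicRegion
    category: str
    gene: GeneModel | None = None
    distance_to_tss: int | None = None


class GeneIndex:
    """Per-chromosome gene lookup for anchors within the 50 kb search range."""

    def __init__(self, genes: list[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.tx_start)

    def near(self, chrom: str, pos: int, margin: int = ENHANCER_RANGE):
        for g in self._by_chrom.get(chrom, []):
            if g.tx_start - margin <= pos < g.tx_end + margin:
                yield g

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())


def _categorize_for_gene(anchor: int, gene: GeneModel) -> tuple[str, int] | None:
    """Category of an anchor relative to one gene, with the oriented TSS
    distance, or None when the anchor is outside the gene's 50 kb windows."""
    # oriented offset from the TSS: 0 at TSS, increases in reading direction
    if gene.strand == "+":
        d = anchor - gene.tss
    else:
        d = gene.tss - anchor
    d_tes = gene.tx_end - gene.tx_start - 1  # oriented position of the TES
    if -PROMOTER_UP <= d <= PROMOTER_DOWN:
        return "promoter", d
    if PROMOTER_DOWN < d <= d_tes:
        return "gene_body", d
    if -ENHANCER_RANGE <= d < -PROMOTER_UP:
        return "upstream_enhancer", d
    if 0 < d - d_tes <= ENHANCER_RANGE:
        return "downstream_enhancer", d
    return None


def classify_peak(peak: GenomicRegion, genes: GeneIndex) -> PeakAnnotation:
    """Assign the unique category of one peak (anchored at its summit)."""
    anchor = peak.anchor
    best: tuple[int, int, str, str, GeneModel, int] | None = None
    for gene in genes.near(peak.chrom, anchor):
        res = _categorize_for_gene(anchor, gene)
        if res is None:
            continue
        cat, d = res
        key = (_PRIORITY[cat], abs(d), gene.name)
        if best is None or key < best[:3]:
            best = (*key, cat, gene, d)
    if best is None:
        return PeakAnnotation(peak, "distal_intergenic")
    _, _, _, cat, gene, d = best
    return PeakAnnotation(peak, cat, gene, d)


def annotate_peaks(peaks: list[GenomicRegion], genes: list[GeneModel] | GeneIndex):
    """Annotate every peak; returns (annotations, category distribution).

    The distribution maps each category to ``(count, percentage)``; counts
    sum to the number of peaks and percentages to 100.
    """
    if not peaks:
        raise ValueError("empty peak list")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    if len(index) == 0:
        warnings.warn("empty gene set: all peaks are distal_intergenic", stacklevel=2)
    annotations = [classify_peak(p, index) for p in peaks]
    counts = Counter(a.category for a in annotations)
    n = len(peaks)
    distribution = {
        cat: (counts.get(cat, 0), 100.0 * counts.get(cat, 0) / n) for cat in CATEGORIES
    }
    return annotations, distribution


@dataclass
class GeneTargetSummary:
    """Per-gene proximal/distal targeting counts across a peak set."""

    n_targeted: int
    n_proximal_only: int
    n_distal_only: int
    n_both: int
    flags: dict[str, dict[str, bool]]  # gene name -> {has_proximal, has_distal}


def gene_target_summary(annotations: list[PeakAnnotation]) -> GeneTargetSummary:
    """Summarize which genes are targeted proximally (promoter peaks) and/or
    distally (gene body or enhancer peaks linked to the gene)."""
    flags: dict[str, dict[str, bool]] = {}
    for a in annotations:
        if a.gene is None:
            continue
        entry = flags.setdefault(a.gene.name, {"has_proximal": False, "has_distal": False})
        if a.category == "promoter":
            entry["has_proximal"] = True
        else:
            entry["has_distal"] = True
    n_both = sum(1 for f in flags.values() if f["has_proximal"] and f["has_distal"])
    n_prox = sum(1 for f in flags.values() if f["has_proximal"] and not f["has_distal"])
    n_dist = sum(1 for f in flags.values() if f["has_distal"] and not f["has_proximal"])
    return GeneTargetSummary(len(flags), n_prox, n_dist, n_both, flags)
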