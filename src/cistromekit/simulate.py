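"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generators emulate the data a ChIP-seq cistrome study consumes — a
repeat-masked genome, gene models, peaks with summits carrying planted motif
instances, a conservation-like score track with a bump at each summit, a
co-bound second factor's peak set with a controlled overlap fraction, and
read (tag) positions concentrated at summits — so that every downstream
computation can be checked against construction-time truth without any
external data.

Every generator is a pure function of its ``seed`` (all randomness flows
through one ``numpy.random.Generator``); the recorded truth round-trips
through JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .annotation import CATEGORIES, GeneIndex, classify_peak
from .io_formats import ALPHABET, PSFM, GeneModel, GenomicRegion, ScoreTrack
from .motifscan import scan_regions

__all__ = [
    "SimulationTruth",
    "generate_genome",
    "generate_gene_models",
    "generate_peaks_with_motifs",
    "plant_motif_instances",
    "generate_score_track",
    "generate_cobound_set",
    "generate_tags",
]


@dataclass
class SimulationTruth:
    """Construction-time ground truth of one generator call.

    ``payload`` holds generator-specific records (planted instances, per-peak
    categories, designed fractions...); the whole object serializes to JSON
    and reloads identically.
    """

    generator: str
    seed: int
    payload: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["generator"], d["seed"], d["payload"])


def _sample_bases(rng: np.random.Generator, n: int, gc_fraction: float) -> np.ndarray:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=[at, gc, gc, at])


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------

def generate_genome(
    n_chroms: int = 2,
    chrom_length: int | list[int] = 300_000,
    gc_fraction: float = 0.41,
    masked_fraction: float = 0.10,
    seed: int = 0,
    mask_run_length: int = 150,
):
    """Random genome with i.i.d. bases at the stated GC content and a
    ``masked_fraction`` of bases lowercased in contiguous runs (soft-masked
    repeats). ``chrom_length`` is one length for all chromosomes or a list of
    per-chromosome lengths. Returns ``({chrom: sequence}, truth)``."""
    if not (0 <= gc_fraction < 1) or not (0 <= masked_fraction < 1):
        raise ValueError("fractions must lie in [0, 1)")
    lengths = ([int(chrom_length)] * n_chroms if np.isscalar(chrom_length)
               else [int(x) for x in chrom_length])
    if len(lengths) != n_chroms:
        raise ValueError("need one length per chromosome")
    if min(lengths) < 10_000:
        raise ValueError("chromosomes must be at least 10 kb")
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    mask_runs: dict[str, list[list[int]]] = {}
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        chrom_len = lengths[c]
        bases = _sample_bases(rng, chrom_len, gc_fraction)
        masked = np.zeros(chrom_len, dtype=bool)
        target = int(round(masked_fraction * chrom_len))
        runs = []
        covered = 0
        guard = 0
        while covered < target and guard < 100_000:
            guard += 1
            start = int(rng.integers(0, chrom_len - mask_run_length))
            end = min(start + mask_run_length, chrom_len)
            if masked[start:end].any():
                continue
            masked[start:end] = True
            covered += end - start
            runs.append([start, end])
        seq = bases.copy()
        seq[masked] += 32  # ASCII lowercase
        genome[chrom] = seq.tobytes().decode("ascii")
        mask_runs[chrom] = sorted(runs)
    truth = SimulationTruth(
        "generate_genome",
        seed,
        {
            "gc_fraction": gc_fraction,
            "masked_fraction": masked_fraction,
            "chrom_sizes": {c: len(s) for c, s in genome.items()},
            "mask_runs": mask_runs,
        },
    )
    return genome, truth


def generate_gene_models(
    genome: dict[str, str],
    n_genes: int = 20,
    seed: int = 0,
    length_range: tuple[int, int] = (5_000, 20_000),
    spacing: int = 5_000,
):
    """Non-overlapping genes with mixed strands, keeping 50 kb flanks at the
    chromosome ends where the chromosome allows."""
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    sizes = {c: len(genome[c]) for c in chroms}
    genes: list[GeneModel] = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for i in range(n_genes):
        name = f"gene{i + 1:03d}"
        for _attempt in range(5_000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = sizes[chrom]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            flank = 50_000 if size > 2 * 50_000 + length else 1_000
            if size - flank - length <= flank:
                continue
            start = int(rng.integers(flank, size - flank - length))
            end = start + length
            if any(start - spacing < e and s < end + spacing for s, e in placed[chrom]):
                continue
            # alternate strands so both are always represented
            strand = "+" if i % 2 == 0 else "-"
            genes.append(GeneModel(name, chrom, strand, start, end))
            placed[chrom].append((start, end))
            break
        else:
            raise ValueError("genome too small to place the requested genes")
    truth = SimulationTruth(
        "generate_gene_models",
        seed,
        {
            "genes": [
                {"name": g.name, "chrom": g.chrom, "strand": g.strand,
                 "tx_start": g.tx_start, "tx_end": g.tx_end,
                 "tss": g.tss, "tes": g.tes}
                for g in genes
            ]
        },
    )
    return genes, truth


# ---------------------------------------------------------------------------
# Peaks with planted motifs
# ---------------------------------------------------------------------------

def _allocate(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items to the mix's classes."""
    keys = list(mix)
    raw = np.array([mix[k] for k in keys], dtype=float)
    if not np.isclose(raw.sum(), 1.0, atol=1e-9):
        raise ValueError("mix fractions must sum to 1")
    exact = raw * n
    counts = np.floor(exact).astype(int)
    for idx in np.argsort(-(exact - counts)):
        if counts.sum() >= n:
            break
        counts[idx] += 1
    return dict(zip(keys, counts.tolist()))


def _sample_instance(rng: np.random.Generator, psfm: PSFM, exact: bool) -> str:
    if exact:
        return psfm.consensus
    letters = [
        ALPHABET[int(rng.choice(4, p=psfm.freq[j]))] for j in range(psfm.length)
    ]
    return "".join(letters)


def _category_anchor(rng, gene: GeneModel, category: str) -> int | None:
    """Random anchor whose oriented TSS offset lies in the category's range."""
    d_tes = gene.tx_end - gene.tx_start - 1
    ranges = {
        "promoter": (-2_000, 1_000),
        "gene_body": (1_001, d_tes),
        "upstream_enhancer": (-50_000, -2_001),
        "downstream_enhancer": (d_tes + 1, d_tes + 50_000),
    }
    lo, hi = ranges[category]
    if hi < lo:
        return None
    d = int(rng.integers(lo, hi + 1))
    return gene.tss + d if gene.strand == "+" else gene.tss - d


def generate_peaks_with_motifs(
    genome: dict[str, str],
    genes: list[GeneModel],
    n_peaks: int = 100,
    category_mix: dict[str, float] | None = None,
    plant_mix: dict[str, float] | None = None,
    psfm_long: PSFM | None = None,
    psfm_short: PSFM | None = None,
    seed: int = 0,
    peak_width: int = 400,
    thr_long: float = 0.8,
    thr_short: float = 0.9,
    exact_consensus: bool = True,
    ensure_clean: bool = True,
):
    """Peaks whose summits fall in demanded annotation categories, carrying
    long / short-only / no planted motif instances per ``plant_mix``.

    Peak sequence is freshly drawn unmasked background (peaks model mappable,
    open regions) with the instance written at the summit. With
    ``ensure_clean`` each peak is re-drawn until its motif content matches its
    class exactly at the stated thresholds (no chance hits), so downstream
    composition recovery is exact by construction. Returns
    ``(peaks, modified_genome, truth)``.
    """
    if category_mix is None:
        category_mix = {"promoter": 0.14, "gene_body": 0.42, "upstream_enhancer": 0.15,
                        "downstream_enhancer": 0.09, "distal_intergenic": 0.20}
    if plant_mix is None:
        plant_mix = {"long": 0.4, "short_only": 0.3, "neither": 0.3}
    unknown = set(category_mix) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {unknown}")
    needs_genes = any(c != "distal_intergenic" and f > 0 for c, f in category_mix.items())
    if needs_genes and not genes:
        raise ValueError("category mix demands gene-linked peaks but no genes given")

    rng = np.random.default_rng(seed)
    index = GeneIndex(genes)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    sizes = {c: len(s) for c, s in seqs.items()}
    half = peak_width // 2
    occupied: dict[str, IntervalTree] = {c: IntervalTree() for c in seqs}

    cat_counts = _allocate(n_peaks, category_mix)
    plant_counts = _allocate(n_peaks, plant_mix)
    cat_list = [c for c, k in cat_counts.items() for _ in range(k)]
    plant_list = [c for c, k in plant_counts.items() for _ in range(k)]
    rng.shuffle(cat_list)
    rng.shuffle(plant_list)

    peaks: list[GenomicRegion] = []
    records = []
    for i, (category, plant_class) in enumerate(zip(cat_list, plant_list)):
        placed = False
        for _attempt in range(5_000):
            if category == "distal_intergenic":
                chrom = list(seqs)[int(rng.integers(len(seqs)))]
                anchor = int(rng.integers(half, sizes[chrom] - half))
            else:
                if not genes:
                    raise ValueError(f"no genes available for category {category}")
                gene = genes[int(rng.integers(len(genes)))]
                chrom = gene.chrom
                anchor = _category_anchor(rng, gene, category)
                if anchor is None:
                    continue
            start, end = anchor - half, anchor + half
            if start < 0 or end > sizes[chrom]:
                continue
            if occupied[chrom].overlap(start, end):
                continue
            peak = GenomicRegion(chrom, start, end, summit=anchor, name=f"peak{i + 1:04d}")
            if classify_peak(peak, index).category != category:
                continue
            instance = _write_peak_sequence(
                rng, seqs, genome, peak, plant_class, psfm_long, psfm_short,
                thr_long, thr_short, exact_consensus, ensure_clean,
            )
            if instance is _DIRTY:
                continue
            occupied[chrom].addi(start, end)
            peaks.append(peak)
            rec = {"name": peak.name, "chrom": chrom, "start": start, "end": end,
                   "summit": anchor, "category": category, "plant_class": plant_class}
            if instance is not None:
                rec["instance"] = instance
            records.append(rec)
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place a {category} peak (genome too crowded?)")

    modified = {c: b.decode("ascii") for c, b in seqs.items()}
    truth = SimulationTruth(
        "generate_peaks_with_motifs",
        seed,
        {
            "category_mix": {c: cat_counts.get(c, 0) for c in CATEGORIES},
            "plant_mix": plant_counts,
            "peaks": records,
            "thr_long": thr_long,
            "thr_short": thr_short,
        },
    )
    return peaks, modified, truth


_DIRTY = object()  # sentinel: peak sequence failed the cleanliness check


def _write_peak_sequence(
    rng, seqs, genome, peak, plant_class, psfm_long, psfm_short,
    thr_long, thr_short, exact_consensus, ensure_clean, max_redraw: int = 20,
):
    """Fill the peak with fresh unmasked background, plant the class's
    instance at the summit, and verify the motif content matches the class."""
    chrom = peak.chrom
    width = peak.end - peak.start
    original = seqs[chrom][peak.start : peak.end]
    gc = 0.41
    for _redraw in range(max_redraw):
        background = _sample_bases(rng, width, gc)
        seqs[chrom][peak.start : peak.end] = background.tobytes()
        instance = None
        psfm = {"long": psfm_long, "short_only": psfm_short}.get(plant_class)
        if psfm is not None:
            instance = _sample_instance(rng, psfm, exact_consensus)
            pos = peak.summit - psfm.length // 2
            seqs[chrom][pos : pos + psfm.length] = instance.encode("ascii")
        if not ensure_clean:
            return {"sequence": instance} if instance else None
        view = {chrom: seqs[chrom].decode("ascii")}
        ok = True
        if psfm_long is not None:
            _, n_long, _ = scan_regions(psfm_long, [peak], view, thr_long)
            want_long = plant_class == "long"
            ok &= (n_long > 0) == want_long if want_long else n_long == 0
        if ok and psfm_short is not None:
            _, n_short, _ = scan_regions(psfm_short, [peak], view, thr_short)
            if plant_class == "short_only":
                ok &= n_short > 0
            elif plant_class == "neither":
                ok &= n_short == 0
        if ok:
            if instance is not None:
                return {"sequence": instance, "position": peak.summit - psfm.length // 2}
            return None
    seqs[chrom][peak.start : peak.end] = original
    return _DIRTY


def plant_motif_instances(
    genome: dict[str, str],
    regions: list[GenomicRegion],
    psfm: PSFM,
    rate_per_kb: float,
    seed: int = 0,
    exact_consensus: bool = True,
):
    """Plant Poisson(rate_per_kb * width/1000) motif instances at random,
    non-overlapping positions within each region. Returns
    ``(modified_genome, truth)``; used for density-controlled enrichment
    recovery where the composition machinery's class logic is not needed."""
    rng = np.random.default_rng(seed)
    seqs = {c: bytearray(s, "ascii") for c, s in genome.items()}
    l = psfm.length
    instances = []
    for r in regions:
        n = int(rng.poisson(rate_per_kb * r.width / 1000.0))
        taken: list[tuple[int, int]] = []
        for _ in range(n):
            for _attempt in range(200):
                pos = int(rng.integers(r.start, r.end - l + 1))
                if any(pos < e and s < pos + l for s, e in taken):
                    continue
                inst = _sample_instance(rng, psfm, exact_consensus)
                seqs[r.chrom][pos : pos + l] = inst.encode("ascii")
                taken.append((pos, pos + l))
                instances.append({"chrom": r.chrom, "position": pos, "sequence": inst})
                break
    truth = SimulationTruth(
        "plant_motif_instances", seed,
        {"rate_per_kb": rate_per_kb, "motif": psfm.name, "instances": instances},
    )
    return {c: b.decode("ascii") for c, b in seqs.items()}, truth


# ---------------------------------------------------------------------------
# Score tracks, co-bound sets, tags
# ---------------------------------------------------------------------------

def generate_score_track(
    anchors,
    chrom_sizes: dict[str, int],
    height: float = 0.9,
    width: int = 1_000,
    baseline: float = 0.1,
    seed: int = 0,
):
    """Baseline score everywhere with a symmetric triangular bump of the given
    height added at each anchor summit; overlapping bumps merge by max."""
    if width >= 2 * 3_000 * 2:
        raise ValueError("bump width unreasonably large")
    track = ScoreTrack()
    half = width // 2
    offsets = np.arange(-half, half + 1)
    bump = height * (1.0 - np.abs(offsets) / half) if half > 0 else np.array([height])
    for chrom, size in chrom_sizes.items():
        arr = np.full(size, baseline)
        for a in anchors:
            if a.chrom != chrom:
                continue
            lo = max(a.summit - half, 0)
            hi = min(a.summit + half + 1, size)
            seg = bump[lo - (a.summit - half) : len(offsets) - ((a.summit + half + 1) - hi)]
            arr[lo:hi] = np.maximum(arr[lo:hi], baseline + seg)
        track.set_array(chrom, arr)
    truth = SimulationTruth(
        "generate_score_track", seed,
        {"height": height, "width": width, "baseline": baseline,
         "n_anchors": len(list(anchors))},
    )
    return track, truth


def generate_cobound_set(
    base_peaks: list[GenomicRegion],
    overlap_fraction: float,
    jitter: int = 100,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
    width: int = 400,
    n_regions: int | None = None,
):
    """Second-factor peak set in which exactly ``floor(overlap_fraction * n)``
    regions overlap (>= 1 bp) a distinct base peak and the rest overlap none.

    ``n_regions`` defaults to the base set size. Returns ``(regions, truth)``.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_regions if n_regions is not None else len(base_peaks)
    k = int(np.floor(overlap_fraction * n))
    if chrom_sizes is None:
        chrom_sizes = {}
        for p in base_peaks:
            chrom_sizes[p.chrom] = max(chrom_sizes.get(p.chrom, 0), p.end + 100_000)
    base_trees: dict[str, IntervalTree] = {}
    for p in base_peaks:
        base_trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)

    chosen = rng.choice(len(base_peaks), size=k, replace=False)
    regions: list[GenomicRegion] = []
    half = width // 2
    for j, bi in enumerate(chosen):
        base = base_peaks[int(bi)]
        center = base.anchor + int(rng.integers(-jitter, jitter + 1))
        start = max(center - half, 0)
        end = start + width
        # clamp so at least 1 bp overlaps the chosen base peak
        if start >= base.end:
            start, end = base.end - 1, base.end - 1 + width
        if end <= base.start:
            start, end = base.start + 1 - width, base.start + 1
            start = max(start, 0)
            end = start + width
        regions.append(GenomicRegion(base.chrom, start, end,
                                     summit=(start + end) // 2, name=f"cb{j + 1:04d}"))
    chroms = list(chrom_sizes)
    for j in range(n - k):
        for _attempt in range(20_000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, chrom_sizes[chrom] - width))
            end = start + width
            tree = base_trees.get(chrom)
            if tree is not None and tree.overlap(start, end):
                continue
            regions.append(GenomicRegion(chrom, start, end,
                                         summit=(start + end) // 2,
                                         name=f"cb{k + j + 1:04d}"))
            break
        else:
            raise ValueError("genome too crowded to place disjoint regions")
    truth = SimulationTruth(
        "generate_cobound_set", seed,
        {"overlap_fraction": overlap_fraction, "n_regions": n,
         "n_overlapping": k, "base_indices": [int(x) for x in chosen]},
    )
    return regions, truth


def generate_tags(
    peaks: list[GenomicRegion],
    tags_per_peak: int = 50,
    background_tags: int = 0,
    spread: float = 100.0,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
):
    """Tag (read 5' end) positions: ``tags_per_peak`` normal draws around each
    summit with the given spread, plus uniform background tags. Returns
    ``({chrom: sorted positions}, truth)``."""
    if spread <= 0:
        raise ValueError("spread must be positive")
    rng = np.random.default_rng(seed)
    if chrom_sizes is None:
        chrom_sizes = {}
        for p in peaks:
            chrom_sizes[p.chrom] = max(chrom_sizes.get(p.chrom, 0), p.end + 10_000)
    positions: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    for p in peaks:
        draws = rng.normal(p.anchor, spread, size=tags_per_peak)
        draws = np.clip(np.rint(draws), 0, chrom_sizes[p.chrom] - 1).astype(int)
        positions[p.chrom].extend(draws.tolist())
    if background_tags:
        total = sum(chrom_sizes.values())
        for chrom, size in chrom_sizes.items():
            n = int(round(background_tags * size / total))
            positions[chrom].extend(rng.integers(0, size, size=n).tolist())
    tags = {c: np.sort(np.array(v, dtype=int)) for c, v in positions.items()}
    truth = SimulationTruth(
        "generate_tags", seed,
        {"tags_per_peak": tags_per_peak, "background_tags": background_tags,
         "spread": spread,
         "n_tags": {c: int(len(v)) for c, v in tags.items()}},
    )
    return tags, truth
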