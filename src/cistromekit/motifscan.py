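"""MotifScan: PSFM similarity scoring, window scanning, and enrichment stats.

The similarity between a motif of length *l* and an equal-length sequence is
the information-weighted, consensus-normalized score

    S = sum_j I_j (2 P_{i(j),j} - 1)  /  sum_j I_j (2 P_j^max - 1)

where I_j is the information content of column j, P_{i(j),j} the frequency of
the observed letter, and P_j^max the column maximum. S = 1 exactly when the
sequence matches a maximum-frequency letter at every informative column; S can
be negative for anti-consensus sequences. The ratio is invariant to the
logarithm base used inside I_j (the base is a common factor of numerator and
denominator); we report I_j in bits.

Enrichment of matched windows in a sample region set against a background set
uses a binomial model approximated by a normal: with N_c matches in background
length L_c and sample effective length L_s, the expected sample count is
E = N_c * L_s / L_c, fold enrichment F = N_s / E, and Z = (N_s - E) / sqrt(E)
(variance taken as E because the per-base match probability is small).
Effective length counts unmasked bases only: lowercase (soft-masked repeat)
and N (hard-masked) bases are excluded, and any window touching one is
unscorable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import ALPHABET, PSFM, GenomicRegion

__all__ = [
    "MotifHit",
    "EnrichmentResult",
    "MotifComposition",
    "PositionHistogram",
    "column_information",
    "similarity_score",
    "scan_regions",
    "enrichment_stats",
    "motif_composition",
    "hit_position_distribution",
    "consensus_psfm",
    "builtin_psfm",
]

# degenerate-window sentinel: anything but uppercase A/C/G/T
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map uppercase A/C/G/T to 0..3 and every masked/other base to 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class MotifHit:
    """One matched window: best strand and similarity at one position."""

    region_index: int
    chrom: str
    start: int  # absolute 0-based window start
    strand: str
    similarity: float
    length: int


@dataclass
class EnrichmentResult:
    """Binomial-approximation enrichment of one motif in a sample vs background.

    ``low_expected`` flags E < 10, where the normal approximation is dubious;
    ``undefined`` flags N_c = 0, where F and Z cannot be formed (they are NaN,
    never infinities).
    """

    n_sample: int
    len_sample: int
    n_background: int
    len_background: int
    expected: float
    fold_enrichment: float
    z_score: float
    low_expected: bool = False
    undefined: bool = False
    motif: str | None = None

    def to_dict(self) -> dict:
        return {
            "motif": self.motif,
            "n_sample": self.n_sample,
            "len_sample": self.len_sample,
            "n_background": self.n_background,
            "len_background": self.len_background,
            "expected": self.expected,
            "fold_enrichment": self.fold_enrichment,
            "z_score": self.z_score,
            "low_expected": self.low_expected,
            "undefined": self.undefined,
        }


@dataclass
class MotifComposition:
    """Partition of a peak set into long / short-only / neither classes."""

    n_total: int
    n_long: int
    n_short_only: int
    n_neither: int

    @property
    def pct_long(self) -> float:
        return 100.0 * self.n_long / self.n_total

    @property
    def pct_short_only(self) -> float:
        return 100.0 * self.n_short_only / self.n_total

    @property
    def pct_neither(self) -> float:
        return 100.0 * self.n_neither / self.n_total


@dataclass
class PositionHistogram:
    """Histogram of motif-hit offsets relative to peak summits."""

    edges: np.ndarray
    counts: np.ndarray
    n_midpoint_fallback: int = 0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def column_information(psfm: PSFM, base: float = 2.0) -> np.ndarray:
    """Per-column information content I_j = sum_i P_ij log(P_ij / Q_i).

    Zero frequencies contribute 0 (the 0*log0 = 0 convention). With a uniform
    background every I_j is nonnegative; reported in bits by default.
    """
    if np.any(psfm.background <= 0):
        raise ValueError("background frequencies must be strictly positive")
    P = psfm.freq
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = P * (np.log(P / psfm.background[None, :]) / np.log(base))
    terms[P == 0] = 0.0
    return terms.sum(axis=1)


def _score_weights(psfm: PSFM) -> tuple[np.ndarray, float]:
    """Numerator weights W[j, i] = I_j (2 P_ij - 1) and the consensus
    denominator sum_j I_j (2 P_j^max - 1)."""
    I = column_information(psfm)
    W = I[:, None] * (2.0 * psfm.freq - 1.0)
    denom = float((I * (2.0 * psfm.freq.max(axis=1) - 1.0)).sum())
    if denom == 0.0:
        raise ValueError("uninformative PSFM: every column is uniform")
    # pad a 5th letter column (masked bases); value irrelevant, windows
    # containing them are excluded before scoring
    W5 = np.zeros((psfm.length, 5))
    W5[:, :4] = W
    return W5, denom


def similarity_score(psfm: PSFM, sequence: str) -> float:
    """Similarity S between the PSFM and one equal-length sequence."""
    if len(sequence) != psfm.length:
        raise ValueError(
            f"sequence length {len(sequence)} != motif length {psfm.length}"
        )
    codes = encode_sequence(sequence.upper())
    if np.any(codes > 3):
        raise ValueError(f"letters outside ACGT in {sequence!r}")
    W, denom = _score_weights(psfm)
    return float(W[np.arange(psfm.length), codes].sum() / denom)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan_regions(
    psfm: PSFM,
    regions: list[GenomicRegion],
    genome: dict[str, str],
    threshold: float,
    both_strands: bool = True,
):
    """Slide the motif (step 1 bp) over each region and collect matches.

    A window is scorable only if all its bases are unmasked (uppercase
    A/C/G/T). A scorable window matches when S >= threshold on the forward
    strand or — with ``both_strands`` — on either strand; it is counted once,
    and the hit records the better strand. Returns ``(hits, n_matched,
    effective_length)`` where ``effective_length`` is the total number of
    unmasked bases across the regions (the denominator of match density).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    l = psfm.length
    W_fwd, denom = _score_weights(psfm)
    if both_strands:
        W_rev, _ = _score_weights(psfm.reverse_complement())
    jdx = np.arange(l)

    hits: list[MotifHit] = []
    n_matched = 0
    l_eff = 0
    for ridx, region in enumerate(regions):
        seq = genome[region.chrom][region.start : region.end]
        codes = encode_sequence(seq)
        l_eff += int(np.count_nonzero(codes < 4))
        if len(codes) < l:
            continue
        win = sliding_window_view(codes, l)
        valid = (win < 4).all(axis=1)
        if not valid.any():
            continue
        gathered = win[valid]
        s_fwd = W_fwd[jdx, gathered].sum(axis=1) / denom
        if both_strands:
            s_rev = W_rev[jdx, gathered].sum(axis=1) / denom
            best = np.maximum(s_fwd, s_rev)
            strands = np.where(s_fwd >= s_rev, "+", "-")
        else:
            best = s_fwd
            strands = np.full(len(s_fwd), "+")
        matched = best >= threshold
        n_matched += int(matched.sum())
        offsets = np.where(valid)[0][matched]
        for off, s, strand in zip(offsets, best[matched], strands[matched]):
            hits.append(
                MotifHit(ridx, region.chrom, region.start + int(off), str(strand), float(s), l)
            )
    return hits, n_matched, l_eff


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def enrichment_stats(
    n_sample: int,
    len_sample: int,
    n_background: int,
    len_background: int,
    motif: str | None = None,
) -> EnrichmentResult:
    """E = N_c L_s / L_c, F = N_s / E, Z = (N_s - E) / sqrt(E)."""
    if min(n_sample, n_background) < 0 or min(len_sample, len_background) <= 0:
        raise ValueError("counts must be nonnegative and lengths positive")
    expected = n_background * len_sample / len_background
    if n_background == 0:
        return EnrichmentResult(
            n_sample, len_sample, n_background, len_background,
            0.0, float("nan"), float("nan"), low_expected=True, undefined=True,
            motif=motif,
        )
    fold = n_sample / expected
    z = (n_sample - expected) / np.sqrt(expected)
    low = expected < 10
    if low:
        warnings.warn(
            f"expected count E={expected:.3g} < 10: normal approximation to the "
            "binomial is dubious",
            stacklevel=2,
        )
    return EnrichmentResult(
        n_sample, len_sample, n_background, len_background,
        float(expected), float(fold), float(z), low_expected=low, motif=motif,
    )


# ---------------------------------------------------------------------------
# Motif composition of peaks
# ---------------------------------------------------------------------------

def motif_composition(
    peaks: list[GenomicRegion],
    genome: dict[str, str],
    psfm_long: PSFM,
    psfm_short: PSFM,
    thr_long: float = 0.8,
    thr_short: float = 0.9,
    both_strands: bool = True,
) -> MotifComposition:
    """Classify peaks as long / short-only / neither motif carriers.

    A peak carrying at least one long-motif match (at ``thr_long``) is "long"
    regardless of short matches — the short element is nearly contained in the
    long one, so long-carrying peaks are excluded before short-only counting.
    """
    if not peaks:
        raise ValueError("empty peak list")
    long_hits, _, _ = scan_regions(psfm_long, peaks, genome, thr_long, both_strands)
    short_hits, _, _ = scan_regions(psfm_short, peaks, genome, thr_short, both_strands)
    has_long = {h.region_index for h in long_hits}
    has_short = {h.region_index for h in short_hits}
    n_total = len(peaks)
    n_long = len(has_long)
    n_short_only = len(has_short - has_long)
    return MotifComposition(n_total, n_long, n_short_only, n_total - n_long - n_short_only)


def hit_position_distribution(
    hits: list[MotifHit],
    peaks: list[GenomicRegion],
    half_range: int = 1000,
    bin_size: int = 50,
) -> PositionHistogram:
    """Histogram of hit-center offsets relative to the summit of each hit's peak.

    The hit center is ``window_start + floor(l / 2)``. Peaks without a summit
    fall back to their midpoint; the count of such fallbacks is reported.
    """
    edges = np.arange(-half_range, half_range + bin_size, bin_size)
    offsets = []
    n_fallback = 0
    for h in hits:
        peak = peaks[h.region_index]
        if peak.summit is None:
            n_fallback += 1
        offsets.append(h.start + h.length // 2 - peak.anchor)
    counts, edges = np.histogram(offsets, bins=edges)
    return PositionHistogram(edges, counts, n_fallback)


# ---------------------------------------------------------------------------
# Built-in consensus-derived matrices
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: IUPAC consensus strings of the bundled motifs. These matrices are
#: synthetic reconstructions built from the published consensus sequences
#: (the numeric matrices behind them are not public); use real matrices
#: where available.
BUILTIN_CONSENSUS = {
    "PU1_long": "RAAAGRGGAAGTG",   # extended PU.1 element, (A/G)AAAG(A/G)GGAAGTG
    "PU1_short": "AGRGGAAG",       # canonical PU.1 element, AG(A/G)GGAAG
    "RAREh": "AGGTCA",             # retinoic acid response element half site
}


def consensus_psfm(name: str, consensus: str, minor: float = 0.04) -> PSFM:
    """Build a PSFM from an IUPAC consensus.

    Each letter outside the column's allowed set gets frequency ``minor``;
    the remainder splits evenly over allowed letters. This is a labeled
    reconstruction, not a measured matrix.
    """
    freq = np.zeros((len(consensus), 4))
    for j, sym in enumerate(consensus.upper()):
        allowed = _IUPAC.get(sym)
        if allowed is None:
            raise ValueError(f"unknown IUPAC symbol {sym!r}")
        k = len(allowed)
        for i, letter in enumerate(ALPHABET):
            if letter in allowed:
                freq[j, i] = (1.0 - minor * (4 - k)) / k
            else:
                freq[j, i] = minor
    return PSFM(name, freq)


def builtin_psfm(name: str) -> PSFM:
    """One of the bundled consensus-derived matrices (see BUILTIN_CONSENSUS)."""
    return consensus_psfm(name, BUILTIN_CONSENSUS[name])
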