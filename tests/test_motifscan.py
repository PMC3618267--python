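"""MotifScan: similarity scoring vs an independent oracle, scanning,
enrichment statistics, and motif composition of peaks."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cistromekit as ck
from cistromekit.motifscan import encode_sequence

# ---------------------------------------------------------------------------
# Independent brute-force oracle for the similarity formula
# ---------------------------------------------------------------------------

LETTERS = "ACGT"


def oracle_information(freq_col, background=(0.25,) * 4, base=2.0):
    total = 0.0
    for p, q in zip(freq_col, background):
        if p > 0:
            total += p * math.log(p / q, base)
    return total


def oracle_similarity(freq, sequence, base=2.0):
    """Direct evaluation of S = sum I_j (2 P_ij - 1) / sum I_j (2 Pmax_j - 1)."""
    num = den = 0.0
    for j, letter in enumerate(sequence):
        ij = oracle_information(freq[j], base=base)
        num += ij * (2.0 * freq[j][LETTERS.index(letter)] - 1.0)
        den += ij * (2.0 * max(freq[j]) - 1.0)
    return num / den


def random_psfm(rng, length):
    freq = rng.dirichlet(np.full(4, 0.5), size=length)
    return ck.PSFM(f"rand{length}", freq)


# ---------------------------------------------------------------------------
# Information content
# ---------------------------------------------------------------------------

def test_column_information_reference_values():
    uniform = ck.PSFM("u", [[0.25] * 4])
    assert ck.column_information(uniform)[0] == pytest.approx(0.0, abs=1e-12)
    deterministic = ck.PSFM("d", [[1, 0, 0, 0]])
    assert ck.column_information(deterministic)[0] == pytest.approx(2.0)  # log2(4)
    skewed = ck.PSFM("s", [[0.7, 0.1, 0.1, 0.1]])
    expected = 0.7 * math.log2(2.8) + 3 * 0.1 * math.log2(0.4)
    assert ck.column_information(skewed)[0] == pytest.approx(expected)
    assert expected == pytest.approx(0.6432, abs=5e-5)


def test_zero_background_rejected():
    m = ck.PSFM("b", [[0.7, 0.1, 0.1, 0.1]], background=[0.5, 0.5, 0.0, 0.0])
    with pytest.raises(ValueError, match="background"):
        ck.column_information(m)


# ---------------------------------------------------------------------------
# Similarity score
# ---------------------------------------------------------------------------

def two_column_psfm():
    return ck.PSFM("two", [[0.7, 0.1, 0.1, 0.1], [0, 0, 1, 0]])


def test_similarity_consensus_is_one():
    assert ck.similarity_score(two_column_psfm(), "AG") == pytest.approx(1.0)


def test_similarity_hand_value():
    # (0.6432*(2*0.1-1) + 2*1) / (0.6432*(2*0.7-1) + 2*1)
    i1 = 0.7 * math.log2(2.8) + 0.3 * math.log2(0.4)
    expected = (i1 * -0.8 + 2.0) / (i1 * 0.4 + 2.0)
    assert ck.similarity_score(two_column_psfm(), "CG") == pytest.approx(expected)
    assert expected == pytest.approx(0.658, abs=5e-4)


def test_uniform_column_contributes_nothing():
    m = ck.PSFM("u1", [[0.25] * 4, [0, 0, 1, 0]])
    scores = {ck.similarity_score(m, x + "G") for x in LETTERS}
    assert len({round(s, 12) for s in scores}) == 1


def test_all_uniform_psfm_rejected():
    m = ck.PSFM("flat", [[0.25] * 4, [0.25] * 4])
    with pytest.raises(ValueError, match="uninformative"):
        ck.similarity_score(m, "AC")


def test_similarity_matches_oracle_over_all_sequences():
    rng = np.random.default_rng(7)
    for _ in range(5):
        length = int(rng.integers(2, 6))
        m = random_psfm(rng, length)
        for seq in map("".join, itertools.product(LETTERS, repeat=length)):
            assert ck.similarity_score(m, seq) == pytest.approx(
                oracle_similarity(m.freq, seq), abs=1e-9
            )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 8))
def test_similarity_at_most_one_and_base_invariant(seed, length):
    rng = np.random.default_rng(seed)
    m = random_psfm(rng, length)
    seq = "".join(rng.choice(list(LETTERS), size=length))
    s = ck.similarity_score(m, seq)
    assert s <= 1 + 1e-12
    assert ck.similarity_score(m, m.consensus) == pytest.approx(1.0)
    # the log base inside I_j cancels in the ratio
    assert oracle_similarity(m.freq, seq, base=2.0) == pytest.approx(
        oracle_similarity(m.freq, seq, base=math.e), abs=1e-9
    )


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def consensus_only_psfm(consensus):
    return ck.consensus_psfm("scan", consensus, minor=0.0)


def test_region_shorter_than_motif_contributes_nothing():
    genome = {"chr1": "AAAA"}
    m = consensus_only_psfm("GGAAGG")
    hits, n, l_eff = ck.scan_regions(m, [ck.GenomicRegion("chr1", 0, 4)], genome, 0.8)
    assert (hits, n, l_eff) == ([], 0, 4)


def test_planted_consensus_found_at_exact_offset():
    m = consensus_only_psfm("GGAA")
    genome = {"chr1": "T" * 10 + "GGAA" + "T" * 10}
    hits, n, _ = ck.scan_regions(
        m, [ck.GenomicRegion("chr1", 0, 24)], genome, 1.0, both_strands=False
    )
    assert n == 1
    assert (hits[0].start, hits[0].strand) == (10, "+")
    assert hits[0].similarity == pytest.approx(1.0)


def test_reverse_complement_found_on_minus_strand():
    m = consensus_only_psfm("GGAA")
    genome = {"chr1": "C" * 8 + "TTCC" + "C" * 8}  # revcomp of GGAA
    hits, n, _ = ck.scan_regions(m, [ck.GenomicRegion("chr1", 0, 20)], genome, 1.0)
    assert n == 1 and hits[0].strand == "-"
    assert hits[0].similarity == pytest.approx(1.0)
    _, n_single, _ = ck.scan_regions(
        m, [ck.GenomicRegion("chr1", 0, 20)], genome, 1.0, both_strands=False
    )
    assert n_single == 0


def test_masked_bases_excluded_from_windows_and_effective_length():
    m = consensus_only_psfm("GGAA")
    # lowercase (soft-masked) consensus must not match; N is hard-masked
    genome = {"chr1": "ggaaGGAANACGT"}
    region = ck.GenomicRegion("chr1", 0, 13)
    hits, n, l_eff = ck.scan_regions(m, [region], genome, 0.9)
    assert n == 1 and hits[0].start == 4
    assert l_eff == 8  # 13 bases minus 4 lowercase minus 1 N


def test_scan_counts_match_oracle_threshold_crossings():
    rng = np.random.default_rng(21)
    genome = {"chr1": "".join(rng.choice(list(LETTERS), size=400))}
    region = [ck.GenomicRegion("chr1", 0, 400)]
    for _ in range(3):
        m = random_psfm(rng, 4)
        for thr in (0.5, 0.8, 0.95):
            _, n, _ = ck.scan_regions(m, region, genome, thr, both_strands=False)
            expected = sum(
                oracle_similarity(m.freq, genome["chr1"][i : i + 4]) >= thr
                for i in range(400 - 3)
            )
            assert n == expected


def test_reverse_complement_scanning_symmetry():
    """Scanning a sequence equals scanning its revcomp with the revcomp PSFM,
    with mirrored window starts."""
    comp = str.maketrans("ACGT", "TGCA")
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list(LETTERS), size=200))
    rc = seq.translate(comp)[::-1]
    m = random_psfm(rng, 5)
    hits_f, n_f, _ = ck.scan_regions(
        m, [ck.GenomicRegion("chr1", 0, 200)], {"chr1": seq}, 0.7
    )
    hits_r, n_r, _ = ck.scan_regions(
        m.reverse_complement(), [ck.GenomicRegion("chr1", 0, 200)], {"chr1": rc}, 0.7
    )
    assert n_f == n_r
    assert sorted(200 - 5 - h.start for h in hits_r) == sorted(h.start for h in hits_f)


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def test_enrichment_direct_arithmetic():
    with pytest.warns(UserWarning, match="normal approximation"):
        res = ck.enrichment_stats(9, 10_000, 100, 1_000_000)
    assert res.expected == pytest.approx(1.0)
    assert res.fold_enrichment == pytest.approx(9.0)
    assert res.z_score == pytest.approx(8.0)
    assert res.low_expected


def test_enrichment_null_identity():
    res = ck.enrichment_stats(100, 10_000, 1000, 100_000)
    assert res.expected == pytest.approx(100.0)
    assert res.fold_enrichment == pytest.approx(1.0)
    assert res.z_score == pytest.approx(0.0)
    assert not res.low_expected


def test_enrichment_zero_background_marked_undefined():
    res = ck.enrichment_stats(5, 1000, 0, 100_000)
    assert res.undefined
    assert math.isnan(res.fold_enrichment) and math.isnan(res.z_score)


def test_enrichment_rejects_bad_inputs():
    with pytest.raises(ValueError):
        ck.enrichment_stats(-1, 10, 1, 10)
    with pytest.raises(ValueError):
        ck.enrichment_stats(1, 0, 1, 10)


def test_z_null_calibration_monte_carlo():
    """Z under the stated binomial model is ~N(0,1): seeded replicates."""
    rng = np.random.default_rng(42)
    l_s, p = 100_000, 1e-3  # E = 100
    n_c, l_c = 10_000, 10_000_000  # N_c*L_s/L_c = 100 exactly
    draws = rng.binomial(l_s, p, size=1000)
    z = np.array([ck.enrichment_stats(int(x), l_s, n_c, l_c).z_score for x in draws])
    assert -0.1 <= z.mean() <= 0.1
    assert 0.85 <= z.var() <= 1.15


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def test_all_long_consensus_gives_100_percent(long_motif, short_motif):
    genome = {"chr1": ("T" * 50 + long_motif.consensus + "T" * 50) * 3}
    w = 100 + len(long_motif.consensus)
    peaks = [ck.GenomicRegion("chr1", i * w, (i + 1) * w) for i in range(3)]
    comp = ck.motif_composition(peaks, genome, long_motif, short_motif)
    assert (comp.pct_long, comp.pct_short_only, comp.pct_neither) == (100.0, 0.0, 0.0)


def test_peak_with_both_motifs_counts_as_long_only(long_motif, short_motif):
    seq = "T" * 30 + long_motif.consensus + "T" * 10 + short_motif.consensus + "T" * 30
    genome = {"chr1": seq}
    peaks = [ck.GenomicRegion("chr1", 0, len(seq))]
    comp = ck.motif_composition(peaks, genome, long_motif, short_motif)
    assert (comp.n_long, comp.n_short_only) == (1, 0)


def test_composition_partitions_and_percentages_sum(planted, long_motif, short_motif):
    peaks, genome, truth = planted
    comp = ck.motif_composition(peaks, genome, long_motif, short_motif)
    assert comp.n_long + comp.n_short_only + comp.n_neither == comp.n_total
    assert comp.pct_long + comp.pct_short_only + comp.pct_neither == pytest.approx(100.0)
    # generator ground truth: 40 long / 30 short-only / 30 neither
    assert comp.n_long == truth.payload["plant_mix"]["long"]
    assert comp.n_short_only == truth.payload["plant_mix"]["short_only"]


def test_empty_peak_list_rejected(long_motif, short_motif):
    with pytest.raises(ValueError, match="empty"):
        ck.motif_composition([], {}, long_motif, short_motif)


# ---------------------------------------------------------------------------
# Hit position distribution
# ---------------------------------------------------------------------------

def test_hits_at_summits_land_in_central_bin():
    m = consensus_only_psfm("GGAA")
    peaks, hits = [], []
    for i in range(10):
        peaks.append(ck.GenomicRegion("chr1", i * 1000, i * 1000 + 400, summit=i * 1000 + 200))
        hits.append(ck.MotifHit(i, "chr1", i * 1000 + 200 - 2, "+", 1.0, 4))
    hist = ck.hit_position_distribution(hits, peaks, half_range=500, bin_size=50)
    central = np.searchsorted(hist.edges, 0, side="right") - 1
    assert hist.counts[central] == 10 and hist.counts.sum() == 10


def test_uniform_hits_give_flat_histogram():
    from scipy import stats

    rng = np.random.default_rng(3)
    peak = ck.GenomicRegion("chr1", 0, 1001, summit=500)
    offsets = rng.integers(-500, 500, size=10_000)
    hits = [ck.MotifHit(0, "chr1", 500 + o, "+", 1.0, 0) for o in offsets]
    hist = ck.hit_position_distribution([h for h in hits], [peak], half_range=500, bin_size=50)
    chi2 = stats.chisquare(hist.counts)
    assert chi2.pvalue > 0.01


def test_empty_hits_give_zero_histogram():
    hist = ck.hit_position_distribution([], [], half_range=500, bin_size=50)
    assert hist.counts.sum() == 0


def test_missing_summit_uses_midpoint_and_is_flagged():
    peak = ck.GenomicRegion("chr1", 0, 400)
    hit = ck.MotifHit(0, "chr1", 198, "+", 1.0, 4)
    hist = ck.hit_position_distribution([hit], [peak], half_range=100, bin_size=10)
    assert hist.n_midpoint_fallback == 1
    assert hist.counts.sum() == 1


def test_encode_sequence_maps_masked_to_sentinel():
    codes = encode_sequence("ACGTacgtN")
    assert codes.tolist() == [0, 1, 2, 3, 4, 4, 4, 4, 4]
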