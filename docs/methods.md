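# Methods

## Motif model and similarity score

A motif is a position-specific frequency matrix (PSFM) over {A, C, G, T}
with background letter frequencies `Q_i` (uniform 0.25 unless supplied).
Column information content is

    I_j = Σ_i P_ij · log2(P_ij / Q_i),

with the `0·log 0 = 0` convention, so a uniform column carries zero weight.
The similarity between the motif and an equal-length sequence is

    S = Σ_j I_j (2 P_{i(j),j} − 1) / Σ_j I_j (2 P_j^max − 1),

where `i(j)` is the letter observed at position j. S equals 1 exactly when
every informative column sees a maximum-frequency letter, and can go
negative for anti-consensus sequences. The logarithm base inside `I_j`
cancels between numerator and denominator, so S is base-invariant; we report
`I_j` in bits. A PSFM whose columns are all uniform has no consensus
direction and is rejected as uninformative.

Counts read from matrix files are normalized per column with no pseudocount
by default (`pseudocount` is available on `read_psfm`); zero frequencies are
legal in S through the `0·log 0` convention.

## Scanning and masking

Windows slide 1 bp at a time over each region and are scored on both strands
by default; a window matching on either strand (S ≥ threshold) is counted
once, recording the better strand. `S ≥ threshold` (rather than strict `>`)
is used so that a threshold of 1.0 selects exact consensus matches.

Masking: lowercase bases are soft-masked repeats and `N` is hard-masked. Any
window containing such a base is unscorable and excluded from match counts;
the *effective length* `L` of a region set is its count of unmasked bases,
which is the denominator of match density. Base counting (rather than window
counting) keeps `L` independent of motif length.

## Enrichment statistics

The number of matched windows in a region set of effective length `L` is
modeled as Binomial(n ≈ L, p) with small p, approximated by a normal with
mean and variance both equal to the expectation. With `N_c` matches in a
background set of effective length `L_c` and a sample of effective length
`L_s`:

    E = N_c · L_s / L_c,   F = N_s / E,   Z = (N_s − E) / √E.

When `E < 10` the result carries a `low_expected` flag — the normal
approximation is then dubious — but is still returned. When `N_c = 0`, F and
Z are undefined and reported as NaN with an `undefined` flag, never as
infinities. The background region set is always an explicit input; there is
no implicit genome-wide default.

## Motif composition of a peak set

A peak "contains" a motif if at least one of its windows matches at the
motif's threshold (defaults: 0.8 for the long element, 0.9 for the short
element and RAREh — the shorter, lower-information matrices need the
stricter threshold for specificity). Because the short PU.1 element is
nearly contained within the long one, peaks containing the long element are
excluded before counting short-only peaks; the classes long / short-only /
neither therefore partition the peak set and their percentages sum to 100.

## Peak annotation

Each peak is anchored at its summit (midpoint when no summit is recorded —
a point anchor guarantees a unique, reproducible class where partial-overlap
rules would not). In gene-oriented coordinates the categories are:

| category            | range (oriented offset d from TSS)         |
|---------------------|---------------------------------------------|
| promoter            | −2,000 ≤ d ≤ +1,000 (closed both ends)      |
| gene_body           | +1,000 < d ≤ d(TES)                         |
| upstream_enhancer   | −50,000 ≤ d < −2,000                        |
| downstream_enhancer | 0 < d − d(TES) ≤ +50,000                    |
| distal_intergenic   | beyond 50 kb from every gene                |

Shared edges are assigned to the higher-priority side (the promoter is
closed on both ends; adjacent classes open at the shared edge); each edge
has an explicit unit test. When several genes yield categories for one
anchor, the winner is chosen by category priority (promoter > gene body >
upstream enhancer > downstream enhancer), then smallest |distance to TSS|,
then lexicographic gene name — the last two tie-breaks make the assignment
deterministic where the priority rule alone is ambiguous. Each transcript
record is treated as a gene model; no isoform collapsing is performed.

The per-gene summary marks a gene proximally targeted when a promoter peak
links to it and distally targeted when any gene-body or enhancer peak does.

## Summit-aligned profiles

Peaks are aligned at summits and oriented 5′→3′ by the linked gene's strand;
distal intergenic peaks default to +. Profiles span ±W bp (default W =
3,000) with 2W+1 positions including the summit at 0. Missing track values
(phastCons-like tracks have gaps) are excluded from the per-position mean —
the profile is coverage-weighted — rather than imputed as zero, which would
bias the curve downward in gappy regions; `missing_as_zero=True` gives the
alternative convention. Anchors near a chromosome edge contribute only
in-bounds positions.

Tag density uses 500 bp windows stepped every 10 bp (window size follows the
field's convention; the step is a resolution choice and configurable). A
window at offset x counts tags within `window//2` bp of the center on both
sides — 501 positions for a 500 bp window — which makes the profile an exact
mirror under orientation reversal; density is tags per bp per anchor.

## Peak-set comparison

Overlap is ≥ 1 shared bp on half-open intervals (configurable
`min_overlap`), and partitions are directional: `n_A_and_B` counts A regions
overlapping any B region, which need not equal `n_B_and_A`. Covered
percentage of a target set by a factor set is the fraction of target regions
with ≥ 1 bp overlap; matched covered-percentage vectors for two target sets
are compared with a paired t-test (zero-variance differences are handled
explicitly: p = 1 when the mean difference is zero, otherwise the p-value is
reported as the smallest positive float). Subpopulation enrichment runs the
motif scan on each overlap subpopulation against one shared background.
Chromosome correlation reports squared Pearson correlations of
per-chromosome peak counts against distinct-gene counts and against
chromosome lengths (from a chrom.sizes file, not ungapped length).

## Synthetic data generator

The generators emulate the structure of a TF ChIP-seq study at desk scale:

- **Genome** — i.i.d. bases at 41 % GC (a mammalian-like default), 10 % of
  bases soft-masked in 150 bp runs; chromosomes of 300 kb by default
  (hundreds of kb keep full scans and placement comfortably fast while
  leaving room for 50 kb annotation windows).
- **Genes** — 5–20 kb transcripts, non-overlapping with 5 kb spacing,
  alternating strands, placed away from chromosome ends.
- **Peaks** — 400 bp with a central summit; summits are placed by rejection
  sampling so that the annotation stage recovers the demanded category mix
  *exactly* (default mix 14/42/15/9/20 % across
  promoter/body/upstream/downstream/distal, a promoter-minority pattern
  typical of this factor class). Peak sequence is freshly drawn unmasked
  background — peaks model mappable, open chromatin — with the planted
  instance written at the summit. Default plant mix: 40 % long motif, 30 %
  short-only, 30 % neither. Exact-consensus planting is the default (it
  removes threshold sensitivity so composition recovery is exact);
  PSFM-sampled instances are available for enrichment tests. With
  `ensure_clean` each peak is re-drawn until its motif content matches its
  class at the stated thresholds, so chance background hits cannot blur the
  designed composition.
- **Density planting** (`plant_motif_instances`) — Poisson-distributed
  instances per region at a stated rate per kb, for fold-enrichment recovery
  designs where foreground/background density ratio is the ground truth.
- **Score track** — baseline 0.1 with a triangular bump (height 0.9, width
  1 kb) at each summit, merged by max; the profile stage must find its peak
  at position 0 with value baseline + height.
- **Co-bound set** — exactly ⌊f·n⌋ regions overlap ≥ 1 bp with distinct base
  peaks (jittered around their summits, clamped to preserve overlap); the
  rest are rejection-placed disjoint from all base peaks, so the designed
  overlap count is recovered exactly.
- **Tags** — normal draws around summits (spread 100 bp, mimicking fragment
  ends clustering at the binding site) plus uniform background.

All randomness flows through one `numpy.random.Generator` per call; outputs
are byte-identical across runs with the same seed.

What the generator does *not* emulate: real base composition and repeat
structure, read-level artifacts (duplicates, mappability), overlapping gene
models, and correlated conservation beyond the planted bump. Passing the
closed-loop tests therefore demonstrates correctness of the computations
under known ground truth, not robustness to every property of real genomes.

## Numerical and design choices

- Internal coordinates are 0-based half-open everywhere; only readers and
  writers convert (BED is native; MACS-style peak tables are 1-based
  inclusive with summit as offset-from-start).
- Enrichment warnings (`E < 10`) are warnings, not errors.
- The bundled PU.1-long, PU.1-short and RAREh matrices are reconstructions
  from published consensus strings (degenerate positions split the dominant
  mass; off-consensus letters get 0.04) and are labeled as such; measured
  matrices should be supplied for real data.
- The acceptance script's problem sizes (3 chromosomes of 250–350 kb, 200
  peaks, 100 + 600 enrichment regions, 1,000 null replicates) were chosen as
  the smallest sizes at which the stochastic recoveries sit well inside
  their statistical tolerances.

## Known limitations

- Whole-genome-scale claims (e.g. percentages over tens of thousands of
  real peaks) require real genome, annotation and track inputs; the package
  reads them, but validation here is against synthetic truth.
- Overlapping matched windows are counted individually in N (window
  counting), which can count one long homotypic run as several matches.
- Gene-model handling treats every transcript as a gene; studies that
  collapse isoforms should de-duplicate before annotation.
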