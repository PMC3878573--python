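# Methods

This note records the models, conventions, and numerical choices behind
each stage of the pipeline, and what the synthetic ground truth does and
does not emulate.

## Coordinates, matching windows, and binding profiles

All genomic intervals are 0-based half-open (BED convention); peak summits
are absolute positions. Two peaks from different experiments mark the same
bound region when their summits lie within **70 bp** (inclusive); a region
is *stringently not bound* in an experiment when no peak of that
experiment comes within **1 kb** of the anchor, measured anchor-to-nearest
peak edge, so a peak overlapping the window in any base blocks the call.
Both windows are read as inclusive — the stringency-conservative choice;
distances in between give an *ambiguous* status that excludes the region
from profile assignment. Summit matching is greedy nearest-first per
chromosome with distance ties broken toward the earlier-sorted peak;
anchors for profile assignment come from pooling all summits per
chromosome and grouping greedily within the matching window (the group's
first summit is the anchor). The seven profile letters a–g enumerate the
non-empty values of the bound triple (GATA2@MP, GATA2@E, GATA1@E):
a=(B,N,N), b=(N,N,B), c=(B,B,B), d=(B,B,N), e=(N,B,N), f=(B,N,B),
g=(N,B,B). Letters are fixed identifiers; observed frequencies are
reported but never used for labeling. GATA1 binding in MPCs exists in the
data but is not part of the letter definition.

When a permissive (non-filtered) peak list is available it is used for the
not-bound test; otherwise the stringent list stands in and a warning is
logged.

Peak-to-gene assignment takes the gene whose TSS minimizes |summit − TSS|,
ties broken toward the lexicographically smaller gene id. The dynamic
binding complexity score is a documented surrogate: the number of distinct
(region, experiment) bound events over a gene's assigned regions.

## Motif scanning and enrichment

Patterns are IUPAC strings; composite kinds (direct repeats, palindromes,
gapped composites) expand to one concrete string per spacer length, with
spacers as N runs. Matching semantics: a sequence character matches a
pattern character when its base set is contained in the pattern
character's IUPAC set — hence a sequence N matches only a pattern N, and a
pattern N matches anything. Lowercase letters in published motif names
(wGATAAsA) are matched by their plain uppercase IUPAC meaning, since no
quantitative weighting is given. All overlapping matches are counted;
minus-strand matches are matches of the reverse-complemented pattern
reported at the forward offset. Scanning is regex-based with lookahead for
overlaps and is verified in the test suite against a character-by-character
brute-force oracle.

Enrichment uses the region-level presence statistic (fraction of regions
with ≥ 1 match) because the comparisons of interest are between peak
classes; the count statistic is available from the count matrix. The null
resamples foreground-sized sets without replacement from foreground ∪
background (≥ 1000 permutations); z = (obs − null mean)/null sd; the
empirical two-sided p-value uses +1 smoothing; Benjamini–Hochberg controls
FDR across the lexicon at α = 0.05. A degenerate null (sd = 0) is reported
as non-significant with a note. The default background for class
comparisons is the complementary peak class.

## Expression linkage

Time courses are z-scored per gene before k-means (clusters capture shape,
not level; flat genes become all-zero profiles). The default is k = 30 per
lineage with k-means++ seeding and 25 restarts; centroids are member means
in z-space. Correspondence analysis is the SVD of the standardized
residual matrix S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}; principal coordinates
are reported for rows and columns, and total inertia equals both Σσ² and
χ²/N (an identity the tests verify to 1e-10). Association significance is
assessed by two-sided hypergeometric (Fisher exact) tests per cluster with
BH correction — CA itself is used for visualization and ranking. A
differential-expression call for peak-count analyses is |log2 FC| ≥ 1
between the compared timepoints, matching the 2-fold convention used for
concordance scoring (up: FC > 2, down: FC < 0.5). Fold changes apply a
pseudocount (1st percentile of positive values) only when nonpositive
values are present.

## Triad circuit model

Genes are indexed (Gata1, Gata2, Pu.1). Four edges are fixed by the
literature: positive autoregulation of GATA1 and PU.1 and their mutual
cross-inhibition. The five GATA2 edges — autoregulation plus both
directions with GATA1 and with PU.1 (a2..a6) — take unknown signs, giving
32 architectures, identified by a 5-bit id (a2 is the most significant
bit; bit 1 = activation).

Rate law (fractional-occupancy / Hill form, h = 2 by default):

    dx_i/dt = α_i (β_i + A_i(t)) / (1 + β_i + A_i(t) + R_i(t)) − γ_i x_i

with A_i/R_i summing a_ji(t)·x_j^h over activating/repressing inputs,
β = (X, 0, 0) a constant positive input to Gata1, and a_ji(t) =
a_ji(0)·exp(λ t/T), T = 168 h. Trends (sign of λ) are fixed from the
stage-resolved binding data: GATA1 edges strengthen (λ = ln 4), the GATA2
edges weaken (λ = −ln 4), PU.1 binding is constant; `derive_timeprofiles`
computes λ from MP/E strength ratios with thresholds 2× (up) and 0.5×
(down) and a cap of ln 8. The GATA1·PU.1 composite-repressor term
b(t)·x₁^h·x₃^h is implemented behind a flag; the default uses the two
separate inhibitory edges.

The reference integrator is adaptive (LSODA, rtol 1e-8); the fitting path
uses a fixed-step RK4 (3 h substeps) vectorized across parameter sets and,
for the 32-architecture scan, across architectures via a per-column sign
mask. At the ground-truth parameters the two agree to ~1e-4 in energy.

**Fitting.** Free parameters (19): α, γ per gene, the nine edge strengths,
X, and the initial state. Strengths, rates, and X are sampled
log-uniformly (α ∈ [0.02, 1] h⁻¹, γ ∈ [0.01, 0.5] h⁻¹, a(0) ∈ [0.01, 20],
X ∈ [0.01, 5]); the initial state is linear in [0, 1]. Starts are a Latin
hypercube; refinement is either Nelder–Mead on the best starts or (the
default for the architecture scan) a batched stochastic local search: a
broad phase over every start (σ decaying 0.25 → 0.03 in the unit cube)
followed by a deep polish of the kept best (σ 0.1 → 0.001, random
coordinate subsets), which costs the same per round for all kept fits
because it is vectorized. The energy compares **min–max-normalized**
simulated trajectories with min–max-normalized observations — both the
observed profiles and the model trajectories are treated as shapes, which
is also why the initial state must be fitted rather than pinned to the
normalized data.

**Consensus.** Architectures are ranked by their fit energies;
`rank_and_consensus` reports, per unknown edge, the sign distribution
among low-energy fits and flags a consensus only when a single sign holds
in a configured fraction (default 100%) of them. Low energy is either a
pooled quantile (default 0.25) or, in the sign-recovery protocol, every
fit within 1.5× of the global best energy — the factor form adapts to the
achieved fit quality, which a pooled quantile cannot, once all kept fits
are locally optimized.

**Knockdown.** A knockdown scales the target gene's production rate α and
its initial level by (1 − fraction), emulating shRNA depletion of existing
transcript plus new synthesis, and reports the change in the other genes'
mean expression over t ≥ 120 h.

## Synthetic ground truth: what it emulates, and its identifiability design

Peak sets place region anchors ≥ 2 kb + margin apart, draw profile letters
from configurable frequencies (defaults decrease a > b > … > g), jitter
co-bound summits with a truncated Gaussian (clipped at half the matching
window so planted pairs always match), and draw tag counts from a negative
binomial (mean 50, dispersion 5). Sequences are i.i.d. with specified GC
(no higher-order Markov background — motif-enrichment nulls on real
genomes are harsher than this), with planted non-overlapping motif
instances at class-specific Poisson rates and exact positional truth.
Expression is centroid + Gaussian noise with binding classes drawn at
cluster-dependent odds. None of this emulates read-level noise, copy
number, mappability, or chromatin domain structure, so passing tests
demonstrate correctness of the analysis logic, not robustness to genomic
artifacts.

The circuit ground truth was designed for sign identifiability, which is
not automatic in this model family: a trace explainable by PU.1's own
(fixed-positive, free-strength) self-activation plus the growing GATA1
antagonism identifies nothing about the GATA2 edge. The diagnostic shape
is a Pu.1 trace that **falls early and recovers late**: every input to
Pu.1 other than the GATA2 edge pushes monotonically over time (constant
self-activation, strengthening GATA1 inhibition), so a fall-then-rise
requires an exogenous drive that strengthens during differentiation. In
the repression world (the default truth, architecture 24) that
strengthening drive is derepression — GATA2 binding decays, releasing
Pu.1. In the activation control world the generator posits GATA2 binding
at the Pu.1 locus that grows during differentiation (increasing trend,
λ = ln 16) while GATA2 expression settles at a plateau, so the same shape
implicates a strengthening activation and the recovered consensus flips to
positive. Both worlds use noise sd 0.05 on the simulated scale, and both
truths span a wide dynamic range in every gene so that the noise stays
small relative to the normalized trajectories. The
GATA1→GATA2 and PU.1→GATA2 strengths are zero in both truths, making
GATA2 autonomous; this keeps the planted knockdown phenotypes clean
(*Gata2* knockdown derepresses *Pu.1*; *Pu.1* knockdown cannot touch
*Gata2*) and leaves those two edge signs deliberately unidentified — the
consensus machinery should and does report no consensus for them.

## Problem sizes and determinism

The replicated experiments use sizes chosen to characterize the methods at
desk scale: profile recovery on 10,000 regions; scanner validation on
1,000 random sequences over the full lexicon; calibration of each
enrichment test over 200 null replicates; sign recovery over 20 replicates
per direction at 200 starts per architecture with 60 kept solutions.
Every stage draws its randomness from an explicit seed (the pipeline
splits one root seed deterministically per stage), and regeneration with
the same seed is bit-identical; pipeline outputs are byte-identical across
runs with the same config.

## Known limitations

- The 32-architecture scan explores sign space only; edge strengths are
  nuisance parameters, and only edges whose dynamics leave a signature in
  the data (here GATA2→PU.1) reach consensus.
- The stochastic refiner finds the deep basin with high but not unit
  probability per restart; the multi-architecture scan is robust because
  several architectures share the identifiable structure, but single-
  architecture fits should use generous restarts.
- Timing classification assumes stage-ordered peak sets with consistent
  summit coordinates across stages; it does not model stage-specific
  summit drift.
- The motif engine matches consensus strings, not position weight
  matrices; graded affinity is out of scope.
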