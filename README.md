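# gatatriad

Analysis toolkit for dissecting how the hematopoietic transcription factors
GATA1, GATA2, and PU.1 redistribute across the genome and reshape gene
expression as multipotent progenitor cells (MPCs) commit to the erythroid or
neutrophil lineage. The package re-implements, as a tested pipeline with
fully synthetic ground-truth inputs, four analysis stages that together link
dynamic ChIP-seq binding to expression programs and to regulatory logic:

1. **Peak interplay** (`gatatriad.interplay`) — summit-based matching of
   peaks across experiments (two peaks mark the same bound region when
   their summits fall within 70 bp), stringent bound / not-bound calls
   (not bound = no peak within 1 kb), and classification of every region
   into one of the seven GATA binding profiles *a–g*: the non-empty
   combinations of the binary triple (GATA2 bound in MPC, GATA2 bound in
   erythroid, GATA1 bound in erythroid). Profile *f* is canonical GATA
   switching; profile *c* is GATA2-primed co-binding.
2. **Motif engine** (`gatatriad.motifs`) — IUPAC scanning of a GATA/ETS
   motif lexicon (WGATAR, WGATAAG, WGAT direct repeats and palindromes
   spaced 3–4 / 3–5 bp, GGAAGTG, TGASTCA, CWGCWGC, the composite
   CTG-N8-WGATAA, …) with permutation z-scores for region-level
   enrichment/depletion under Benjamini–Hochberg FDR control.
3. **Expression linkage** (`gatatriad.linkage`) — k-means clustering of
   per-gene z-scored expression time courses, correspondence analysis of
   bound-gene counts against clusters (total inertia = χ²/N; distance from
   the point of inertia measures association), hypergeometric cluster
   enrichment, centroid–reference correlation, and fold-change
   stratification by binding profile.
4. **Triad circuit inference** (`gatatriad.triad`) — the modeling core: a
   three-gene ODE circuit with Shea–Ackers/Hill rate laws and
   exponentially time-varying interaction strengths (trends fixed by the
   stage-resolved binding data). The five GATA2 edges of unknown
   regulatory sign define 2⁵ = 32 candidate architectures; each is fit to
   the observed three-gene time course by multi-start energy minimization
   (energy = Σ squared residuals of normalized trajectories), and the edge
   signs shared by all low-energy fits form the consensus regulatory
   logic — recovering GATA2 repression of *Pu.1* and predicting that
   *Gata2* knockdown derepresses *Pu.1* while *Pu.1* knockdown leaves
   *Gata2* untouched.

`gatatriad.synthetic` generates ground-truth inputs for every stage — peak
sets with planted profiles, sequences with planted motifs, clustered
expression with planted binding associations, and noisy circuit
trajectories from a known signed architecture — so the whole pipeline is
verifiable without any external download.

## Worked example

```python
from gatatriad import synthetic, triad

# simulate a noisy erythroid time course from the ground-truth circuit in
# which GATA2 represses Pu.1 (architecture id 24; signs a2..a6 = ++---)
arch, profiles, params, x0 = synthetic.triad_truth(gata2_pu1_sign=-1)
obs, truth = synthetic.simulate_noisy_timecourse(
    arch, params, noise_sd=0.05, seed=3, timeprofiles=profiles, x0=x0
)

# fit all 32 signed architectures (200 Latin-hypercube starts each,
# batched stochastic refinement) and extract the consensus signs
fits = triad.fit_all_architectures(obs, timeprofiles=profiles,
                                   n_starts=200, n_keep=60, seed=3)
consensus, summary = triad.rank_and_consensus(fits, energy_factor=1.5)
print(consensus.to_string(index=False))
```

prints

```
  edge  n_low_energy  frac_plus  frac_minus  consensus_sign
G2->G2             9   0.555556    0.444444               0
G2->G1             9   0.444444    0.555556               0
G1->G2             9   0.111111    0.888889               0
 G2->P             9   0.000000    1.000000              -1
 P->G2             9   0.333333    0.666667               0
```

Nine fits land within 1.5× of the best energy; every one of them carries a
negative GATA2→PU.1 edge, so repression of *Pu.1* by GATA2 is the consensus
(`consensus_sign = -1`), while the other four GATA2 edges remain undecided
(`0`) — exactly the planted logic. Re-simulating any of those fits with
*Gata2* production knocked down 70% raises late-time *Pu.1* expression.

A full run over generated files:

```bash
gatatriad simulate --seed 1 --out bundle/
gatatriad all --manifest bundle/manifest.json --out results/
```

writes per-stage tables (profile letters, motif enrichment, cluster
enrichment, CA coordinates, architecture energies) and a `summary.json`
containing the profile frequencies and the consensus sign table.

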