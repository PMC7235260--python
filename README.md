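# cisrange

Tools for quantifying **how far transcription factors act** along the genome:
regulatory-potential (RP) scoring of TF ChIP-seq peaks against gene TSSs,
inference of TF-specific regulatory decay distances from perturbation
experiments and expression cohorts, TAD chromatin-state classification, and
TAD-wise downstream analyses (target-TAD calling, pioneer-factor-like
testing, eQTL/Hi-C distance decay, trait–TF prioritization).  Everything is
exercisable end to end on synthetic data with planted ground truth.

## Who this is for

Regulatory genomicists who want a tested, reusable implementation of the
RP-based decay-distance framework — either to run the statistics on their own
peak/expression/TAD tables or to study the estimator's behavior under
controlled simulation.

## The model

The regulatory potential of TF *i* on gene *j* sums the TF's binding sites in
the gene's TAD, each weighted by an exponentially decaying function of the
peak–TSS distance *x*:

    R_ij(Δ) = Σ_k 2^(−x_ijk / Δ)

Δ is the **decay distance**: the separation at which a single site's modeled
effect is halved.  A power-law kernel Σ_k x^λ (λ < 0) is available for
comparison with Hi-C contact decay.  The TF-specific **regulatory decay
distance Δ\*** is the Δ on a 33-point geometric grid (100 bp – 4000 kb) that
best couples RP scores to an independent target-gene signal:

* **Perturbation route** — Δ\* maximizes the two-sample Kolmogorov–Smirnov
  separation of RP scores between differentially expressed genes
  (|log2FC| > 1, p < 0.01 after perturbing the TF) and all other genes.
* **Expression-cohort route** — per-gene correlations γ̂_ij between TF and
  gene expression (the MLE of the regulatory effect in a standardized linear
  model) are compared against R_i·(Δ); Δ\* maximizes |ρ| between the two
  vectors (equivalently ρ², the profile likelihood), or the distance
  correlation in the nonlinear variant.  Samples qualify when their
  concordance curve exceeds 0.1; qualified samples' curves are averaged.

TFs split into short-range (Δ\* ≤ 3 kb) and long-range (Δ\* > 3 kb) classes.
TAD context modulates the distances: A-type TADs (strong H3K27ac across
samples) versus B-type TADs (weak H3K27ac) are called from the extreme
clusters of a TAD × sample hierarchical biclustering, and class-restricted
estimation yields Δ^A and Δ^B.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data.  Simulate a cohort and infer the planted decay distance:

```bash
python analysis/01_simulate_cohort.py --seed 11
python analysis/02_infer_decay_distances.py
```

prints:

```
simulated 50 TADs (27 A-type, 23 B-type), 640 genes, 8 TF samples, 200 expression samples
planted decay distance 10 kb, calibrated beta 0.00881, 100 DE genes
inputs written to results/data/

planted decay distance: 10 kb
   expression-linear: delta* = 10.3 kb (long-range, max statistic 0.3957)
     expression-dcor: delta* = 10.3 kb (long-range, max statistic 0.3642)
     perturbation-ks: delta* = 7.4 kb (long-range, max statistic 0.6848)
```

All three routes land on the planted 10 kb (the grid is geometric, so
10.3 kb and 7.4 kb are the grid points bracketing 10 kb): the TF is
correctly classified long-range, and the expression-route concordance peaks
near the calibrated 0.4.  The remaining scripts classify TAD chromatin
states (`03`), call target TADs from occupancy z-scores (`04`), recover
class-specific decay distances, eQTL distance contrasts and Hi-C exponents
(`05`), prioritize TFs for a trait by cosine similarity with permutation
p-values (`06`), and run the pioneer-factor-like logistic test (`07`).
`cisrange.pipeline.run_pipeline` chains the stages from one config with
provenance stamping.

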