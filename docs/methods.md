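# Methods

## The problem and the model

`breedcomp` predicts each animal's **genomic breed composition (GBC)** — a
vector q = (q_1, …, q_K) of ancestry proportions over K reference purebreds,
with q_k ≥ 0 and Σ q_k = 1 — from SNP genotypes, and then calls the animal
**purebred** (of its top breed) when max_k q_k strictly exceeds a
determination threshold θ, and **hybrid** otherwise.

The distinguishing choice is the *multi-output regression framework*: the
training target for a purebred is its vertex of the simplex (e.g. a Duroc is
[0, 0, 1]), and for an F1 Yorkshire × Landrace it is [0.50, 0.50, 0.0]. The
model is trained to minimise the mean squared error between its predicted
composition and these target vectors, rather than cross-entropy against
class labels. The classification-framework baselines ("-CLA") share the same
feature pipeline and architectures but use one-hot class targets (the K
purebreds plus an explicit hybrid class) and cross-entropy-style losses.

Because the prior over training compositions is discrete (vertices plus the
F1 midpoint), a well-trained regression-framework model behaves like a
posterior-mean predictor: for a test F1 it outputs nearly exactly
[0.5, 0.5, 0], concentrating harder around the true composition than the
per-individual maximum-likelihood estimate can (the MLE's spread is bounded
below by the Fisher information of the marker panel). This is why the MLP's
F1 predictions cluster tightly in [0.45, 0.65] while the likelihood
baseline's do not, and it is the mechanism behind the regression framework's
advantage in hybrid identification.

## Pipeline

1. **Genotype I/O** — PLINK text (.ped/.map) and binary (.bed/.bim/.fam,
   SNP-major v1.00) filesets. Dosage counts copies of the A1 allele (first
   allele column of .bim/.map); `0 0` / code `01` become missing. For
   .ped/.map, which carry no allele columns, A1 is inferred as the lexically
   smaller observed allele (with a single observed allele treated as A2);
   the simulator writes A1='A', A2='G' so the convention is self-consistent.
2. **QC** — per-SNP filters on non-missing calls only: call rate ≥ 0.90,
   MAF ≥ 0.05, and a two-sided Hardy–Weinberg exact test (Wigginton-style,
   conditional on allele counts, computed in log space) with exclusion at
   P < 10⁻⁶ strictly. Samples are never filtered. A SNP failing several
   rules is attributed to the first failing rule (call rate → MAF → HWE) in
   the report; the surviving set is order-independent. Note that pooling
   diverged breeds induces a Wahlund heterozygote deficit, so at these
   sample sizes the HWE filter removes a visible fraction of SNPs
   (~15–20% of a simulated 1,000-SNP panel); this mirrors what the filter
   does on real multi-breed cohorts and leaves ample markers.
3. **Imputation** — missing calls are kept as NA through QC, then imputed
   per SNP from that SNP's observed calls (default: mode; `mean_rounded`
   available) because no model backend consumes NA.
4. **Encoding** — each dosage becomes a 3-column indicator block (one-hot),
   giving a 3M-column binary feature matrix shared by all backends.
   Targets are encoded per framework as above.
5. **Prediction and decision** — every backend returns one simplex-valid
   vector per sample; `call_breed` applies the strict-inequality threshold
   rule (boundary equality → hybrid) and reports the top-two breed pair for
   hybrids. Default θ = 0.75; the scan grid is {0.60, 0.65, …, 0.90}.

## Backends

**MLP (the primary method).** A feed-forward network with hidden layers
1024-512-256 (ReLU), softmax output (so predictions are structurally on the
simplex), MSE loss under the regression framework, trained by
backpropagation with Adam. Defaults: learning rate 1e-3, inverted dropout
0.4 on hidden activations (optional SNP-level input dropout, off by
default), L2 weight decay 1e-4, batch size 256, at most 100 epochs with
early stopping (patience 8, tolerance 1e-6) on a 10% held-out validation
split, best-validation weights restored; then a dropout-annealing phase of
up to 15 epochs without dropout, resumed from the best weights, whose
snapshot is kept under a one-standard-error rule on the validation loss.
All randomness (initialisation, batch order, dropout, validation split)
flows from `random_state`; a fit is bit-reproducible and serialised models
re-predict bitwise.

Three numerical points shaped these defaults. First, MSE-through-softmax
has vanishing gradients at simplex vertices: too large a learning rate
drives the softmax into saturation early and training stalls at a
degenerate solution (observed at lr 2e-3, and at lr 1e-3 with small batches
and no dropout); lr 1e-3 with dropout 0.4 and batch 256 is stable. Second,
generalisation quality — not training fit — controls how tightly hybrid
predictions concentrate around [0.5, 0.5, 0]; dropout is what buys that
concentration (validation MSE ~1e-5 versus ~2e-3 without it). Third, the
near-zero components (an F1's third-breed proportion) converge slowest —
their MSE gradients scale quadratically with the component — and plateau
around 0.01 under persistent dropout noise; the no-dropout annealing phase
tightens them toward zero without disturbing the learned representation,
and the one-SE acceptance rule recognises that validation differences
smaller than the loss estimate's standard error are noise.

**Random forest / SVR.** sklearn `RandomForestRegressor` (natively
multi-output; default 100 trees, sqrt features) and one `SVR` per breed
component (RBF kernel, C = 10, ε = 0.01). Neither structurally guarantees
the simplex, so raw outputs are clipped to [0, 1] and renormalised to sum
to 1 (an all-zero row raises rather than renormalising silently).
Classification variants use `RandomForestClassifier` / `SVC(probability=True)`
and return class probabilities.

**Supervised ancestry likelihood.** A supervised analogue of model-based
ancestry estimation: breed allele frequencies are taken from labelled
training purebreds (clamped to [1e-4, 1 − 1e-4]), and each sample's q
maximises the binomial admixture log-likelihood
Σ_j [g_j log(Σ_k q_k p_kj) + (2 − g_j) log(Σ_k q_k (1 − p_kj))] via EM
(allele-origin responsibilities), converging when the per-sample gain drops
below 1e-8 or after 2,000 iterations. The log-likelihood is asserted
non-decreasing every iteration; converged samples leave the active set,
which matters at 50K SNPs where near-vertex (purebred) samples converge
sublinearly. Re-implementing unsupervised block-relaxation ancestry
clustering is out of scope; the component-to-breed matching step it would
require is exactly what supervision removes.

## The synthetic study

No public genotypes exist for the motivating application, so the simulator
defines the study conditions. Breed allele frequencies follow the
Balding–Nichols model: ancestral frequency p₀ ~ U(0.05, 0.5) per SNP, breed
frequency ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F), so breed frequencies have mean
p₀ and variance F·p₀(1−p₀), and the realised pairwise Hudson FST recovers
the configured F. Within a breed, genotypes are Binomial(2, p) (HWE); an F1
draws one allele from each parental breed; a general admixed individual
draws each allele from breed k with probability q_k. Missing calls are
masked i.i.d. (default rate 0.01 — small but nonzero so the QC + imputation
path is always exercised).

The default design is three breeds (Yorkshire, Landrace, Duroc) at F = 0.15
over 1,000 SNPs: a training population of 300 purebreds per breed plus 150
Yorkshire × Landrace F1s, and an independent test population of 100 per
breed plus 100 F1s drawn from the *same* breed frequencies with a fresh
seed — emulating a second, genetically connected cohort. F = 0.15 makes the
breeds separable at ~1,000 markers, mimicking the regime where even a
~1.3K-SNP chip suffices; the density-robustness check runs the same design
at 1,337 and 50,000 SNPs (with the likelihood backend, which is tractable
at 150K one-hot features where the full-width MLP is not).

What the simulator does **not** emulate: linkage disequilibrium (SNPs are
independent), ascertainment bias of real chips, genotyping error beyond
missingness, pedigree structure beyond one generation of specified crosses,
backcrosses/rotational crosses in the default design, and selection or
mutation. Passing tests therefore demonstrate the correctness and internal
consistency of the method under idealised breed divergence, not field
performance on any real livestock cohort.

## Evaluation designs

Cross-validation is five replicates of stratified fivefold CV (stratified
by category so the hybrid class cannot vanish from a fold; replicate r
splits with seed base + r); every method in a run receives byte-identical
train/test matrices. Accuracy is the proportion of correctly called
individuals per true category (a hybrid called purebred is simply an error —
no partial credit), reported to 4 decimals; summaries average the 25
fold-runs unweighted, and the threshold scan's "overall" accuracy is the
unweighted mean over categories (sample-weighted available by flag).
Hyperparameter grid search minimises mean validation MSE over shared
fivefold splits, ties to the first config in grid order. Training-set
titration subsamples one category along a count ladder (nested, seeded)
against a fixed test set. Independent testing intersects-and-aligns the two
panels by SNP id (alleles must agree) before encoding.

## Known limitations

- The MLP is plain numpy on CPU; at 50K+ SNPs the one-hot width makes the
  default architecture expensive, which is why the density experiment uses
  the likelihood backend. Desk-scale problem sizes used throughout the
  test-suite runs (1,000-SNP default panel, ≤ 1,350 training samples) are
  the package's chosen study conditions.
- Threshold calling reports only the top-two breed pair for hybrids; no
  uncertainty intervals on GBC are calibrated.
- The ped/map dialect cannot represent allele roles for monomorphic SNPs;
  round trips are exact for the bed dialect and for polymorphic panels
  under the documented A1 convention.
- The classification-framework hybrid call is the argmax class; thresholded
  class probabilities are representable but not the default.
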