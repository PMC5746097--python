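# Methods

## Feature extraction

### Pseudo-amino-acid composition (PseAAC, type 1)

Each sequence contributes 20 residue frequencies plus λ tier-correlation
factors. The pairwise correlation Θ(R<sub>i</sub>, R<sub>j</sub>) is the
mean of the squared differences of three per-residue properties —
hydrophobicity, hydrophilicity and side-chain mass — each standardized to
zero mean and unit (population) standard deviation over the 20 amino acids.
The raw property table is bundled as `src/apoploc/data/aa_properties.tsv`
(the canonical values used by the widely deployed PseAAC web service:
Tanford-style hydrophobicity, Hopp–Woods hydrophilicity, side-chain masses)
and can be overridden with a user TSV of the same layout. Different
published property tables shift feature values in the third decimal; the
bundled table is pinned so results are reproducible.

Defaults: λ = 15, ω = 0.05. λ must be strictly smaller than the sequence
length, so the shortest admissible sequence (L = 50) caps λ at 49. Because
frequencies rather than raw counts are used, the composition block sums to
Σf = 1 and the whole vector sums to one by construction; this invariant is
property-tested.

### Pseudo-PSSM (PsePSSM)

The profile is sigmoid-normalized entrywise before any summarisation — the
sigmoid is applied to the raw integer log-odds, not to a rescaled version.
The descriptor concatenates the 20 column means with ξ tiers of 20 lagged
squared differences, tier-major (all 20 columns of lag 1, then lag 2, ...).
Default ξ = 10, giving 20 + 200 = 220 components; ξ = 0 degenerates to the
plain 20-dimensional profile composition. Each tier t ≤ ξ reuses the same
lagged-squared-difference form with lag t, which is what makes the
dimension come out at 20 + 20ξ.

Real profiles are parsed from the PSI-BLAST ASCII layout (one row per
position: index, residue, 20 log-odds integers, 20 percentage columns, two
floats; only the log-odds are kept). When no profile search is available,
`surrogate_pssm` fabricates one: row i is the BLOSUM62 substitution row of
residue i (in PSI-BLAST column order) plus rounded Gaussian noise with
standard deviation `noise_sd` (default 2.0, comparable to the score scale
of real profiles). Surrogates preserve residue identity — which is exactly
the property that lets the profile block carry class signal in synthetic
data — but have none of the position-specific conservation structure of a
real homology search, so results on surrogates say nothing about how
informative real evolutionary profiles would be.

## 2-D wavelet denoising

The n × d feature matrix is treated as one 2-D signal. Defaults follow the
pipeline's operating point: db8, 4 decomposition levels, soft thresholding,
a single global threshold. Supported families: db1/db4/db8, sym3/sym7,
coif2/coif4, bior1.1/bior2.4/bior3.3.

* **Boundary handling.** Symmetric (half-point) extension, with
  crop-on-reconstruct for non-dyadic sizes such as 317 × 255. Perfect
  reconstruction (≤ 1e−8 max-abs without thresholding) holds for every
  supported family at levels 3–5 and is asserted in the tests. Parseval
  energy equality is exact only for orthonormal filters under periodized
  boundaries, so the energy-conservation test uses
  `extension="periodization"` on dyadic input for the db/sym/coif families;
  it is not asserted for the biorthogonal ones.
* **Level bound.** A decomposition is refused when the level exceeds
  ⌊log₂ min(n, d)⌋ (subbands would degenerate). Levels beyond the usual
  filter-length-based recommendation are allowed deliberately — a 4-level
  db8 transform of a 317 × 255 matrix is the intended operating point —
  and reconstruct exactly.
* **Universal ("default") threshold.** thr = σ̂ √(2 ln n) with σ̂ =
  median(|d₁ᴰ|)/0.6745 (MAD of the finest diagonal subband) and n the
  element count of the matrix; a single global value applied to every
  detail subband. An all-zero diagonal subband yields thr = 0 with a
  warning.
* **Birgé–Massart thresholds.** Per level t (1 = finest) and direction,
  keep the ⌊M/(J+2−t)^α⌋ largest coefficients, M being the size of a
  finest-level subband; the threshold is the magnitude of the first
  discarded coefficient, 0 when the budget covers the whole subband.
  Default α = 1.5 (a denoising-oriented choice; compression uses larger α).
* **Quantization.** Soft sign(x)·max(|x|−thr, 0) by default, hard
  x·1[|x|>thr] as the alternative. Approximation coefficients are never
  thresholded.

**Leakage.** The faithful protocol denoises the full dataset matrix before
any train/test split, so under the jackknife each held-out row has
participated in the threshold estimate and the reconstruction of the rows
it is classified against. This replicates the whole-matrix protocol of the
method as published, and the reported jackknife numbers should be read with
that caveat. An alternative leak-free mode (`denoise_mode="leak_free"`)
refits the 2-D denoiser on the n−1 training rows of each fold and applies
the train-derived global threshold to the held-out row with the 1-D
per-row transform.

## Classification

One-vs-one SVM: k(k−1)/2 binary soft-margin machines (sklearn `SVC`
underneath), trained on each class pair, with explicit vote counting.
Per-class vote counts are also the ROC scores. Vote ties break by the
largest aggregate signed decision value over the tied classes, then
lexicographically with a warning — deterministic and auditable. Kernels:
linear (default), cubic polynomial, RBF, sigmoid. C defaults to 1 and γ to
1/d, the library defaults, because the source method reports neither; the
sweep tooling exposes both. Baselines use the stated settings — 3-NN with
Euclidean distance, random forest with 100 trees, Gaussian naive Bayes,
CART decision tree — with library defaults elsewhere.

## Evaluation

Jackknife = leave-one-out: n folds, fold i trains on the other n−1 rows.
Self-consistency = resubstitution. Metrics are computed on the one-vs-rest
collapse of each class: Sens = TP/(TP+FN), Spec = TN/(TN+FP), MCC by the
standard formula with 0/0 → 0 (warned). Overall accuracy is trace/n. A
single summary MCC is reported as the macro-average of the per-class
values, with the per-class values always emitted alongside. ROC is computed
one-vs-rest per class, interpolated onto a 101-point FPR grid, macro-
averaged, and integrated by the trapezoid rule; a class with constant
scores contributes the chance diagonal with a warning.

## Synthetic data

The generator emulates the structure of the curated apoptosis-protein
benchmarks — a few hundred sequences in 4–6 compartment classes, lengths
≥ 50 — without distributing any real sequences. One base residue
distribution is drawn from a flat Dirichlet (concentration 20 split over
the alphabet) and shared by all classes; class c then multiplies the
probabilities of its own disjoint residue triplet by e^separation and
renormalizes. Separation 0 therefore makes the classes exactly
exchangeable (no label signal at all), and separation 3 concentrates
roughly three quarters of the probability mass on the class triplet.
Sequence lengths are uniform on [50, 300]. Surrogate profiles inherit
residue identity, so both feature blocks carry the class signal. What
passing tests show is that the pipeline recovers planted compositional
structure and stays at chance when none is planted — not that it would
reach any particular accuracy on real proteins, whose class signal is
weaker, correlated and partly positional.

An independent-draw design (a separate Dirichlet per class) was rejected:
even with identical concentrations, each class would inherit its own
sampling quirks and carry label signal at "zero" separation, making a
chance-level null impossible to state.

`make_noise_fixture` builds the denoising testbed: a smooth low-rank matrix
(sum of `rank` outer products of sinusoids with random phases and
amplitudes) plus σ × standard-normal noise, default 317 × 255 to exercise
the exact non-dyadic benchmark geometry.

## Problem sizes and statistical checks

Jackknife experiments use 4 classes × 30 sequences (n = 120, d = 255), a
size at which leave-one-out with the OVO SVM completes in seconds while
leaving enough per-class samples for stable sensitivities. The chance-level
null uses 10 independent datasets of n = 60 (600 pooled predictions, so
3·SE ≈ 5 percentage points around 25%). Denoising efficacy uses 10 seeded
317 × 255 fixtures at σ = 0.5 against a rank-3 clean signal.

One protocol-level caveat is load-bearing: on signal-free balanced data,
leave-one-out with a margin classifier is biased *below* chance — removing
the test sample makes its class the training minority, and every pairwise
SVM then votes for the majority class, driving OA toward 0 rather than
1/k. This is a well-known property of the protocol, not of the generator.
The chance-level check therefore probes the null with the 3-NN baseline,
which has no such imbalance sensitivity; the SVM's behavior on the null is
documented here rather than asserted as "chance".

## Known limitations

* Surrogate profiles are compositional, not evolutionary; absolute
  accuracies on synthetic data do not transfer to real benchmarks.
* The faithful denoising protocol leaks test-row information into the
  threshold estimate (see above); the leak-free mode is slower and not the
  default.
* C and γ are library defaults, not tuned values.
* Wavelet-packet threshold selection and translation-invariant
  (cycle-spinning) denoising are out of scope.
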