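# Methods

## Phase lag index

For channels *a*, *b* with instantaneous phases φ_a(t_k), φ_b(t_k),

PLI = | (1/n) Σ_k sign( wrap(φ_a(t_k) − φ_b(t_k)) ) |,

with wrap(·) mapping to (−π, π] and sign(0) = 0.  Three conventions are
deliberate, because PLI is undefined without them:

* **Phase extraction** is the analytic-signal (Hilbert-transform) phase
  of the (optionally band-pass-filtered) channel — the standard choice
  for PLI on electrophysiology.  The Hilbert phase is only meaningful
  for roughly narrow-band signals, which is why `band_filter`
  (zero-phase 4th-order Butterworth, applied forward and backward)
  exists; no band is applied by default and any band is configurable,
  since the appropriate rhythm depends on the study.
* **Wrapping** to (−π, π] happens before the signum, so a lead of 3π/2
  counts as a lag of π/2.
* **sign(0) = 0** (mathematical signum): identical signals, and any
  pure zero-lag coupling, give PLI 0 — the "no consistent lag" reading
  that makes PLI insensitive to volume conduction.

One PLI value per pair is computed over the whole recording by default
(one network per subject); `epoch_samples` switches to averaging PLI
over fixed-length epochs.  The node count is data-driven — nothing
assumes a particular montage — and fixtures use 273 sensors.  The dense
weighted graph is passed downstream without thresholding; density is
handled by the walk transition law instead.

## Random walks and skip-gram

Walks are first-order: from node *X_i* the successor is sampled among
positive-weight neighbours with probability proportional to edge weight
(self-loops are ignored).  On a dense PLI graph uniform sampling would
ignore all structure, which is why weight-proportional sampling is the
default; uniform sampling and top-k edge sparsification are options.
Each of *I* iterations roots one walk of length *l* at every node, so
the corpus has I·|V| walks.  Second-order (return/in-out biased) walks
are out of scope.

Skip-gram treats walks as sentences: every node within *w* positions of
a focus node (clipped at walk ends) is a positive context.  The model
is the standard shared parameterization — one |V|×d input matrix and
one d×|V| output matrix; with one-hot inputs this is exactly a
per-node three-layer network whose hidden activation is the node's
embedding row.  Training is SGD on the full-softmax co-occurrence
likelihood: pairs are shuffled each epoch and processed in minibatches
whose gradients are **summed, not averaged**, so each pair contributes
a full step at the current learning rate (per-pair word2vec semantics,
up to within-batch parameter staleness).  Full softmax is exact and
cheap at |V| ≈ 273; negative sampling is available for large graphs.
The embedding is the trained input matrix Φ.

Unstated-by-design defaults, all configurable: I = 10 walks/node,
l = 40, window w = 5, 5 epochs, learning rate 0.025 with linear decay
to 10⁻⁴ — conventional DeepWalk/word2vec-scale settings for graphs of
a few hundred nodes.  The configuration rejects d ≥ |V| (the embedding
must be a genuine reduction).

## Graph to image

PCA (fit per graph, on the mean-centred embedding rows) orders features
by explained variance; d_PCA = 4 features are kept by default.  Each
component's loading vector is flipped so its largest-magnitude entry is
positive, removing the run-to-run sign ambiguity of eigenvectors —
without this, histogram channels would flip between runs.  Feature pair
c (features 2c−1, 2c) becomes channel c: each axis's min–max range is
divided into r = 10 equal-width bins (half-open, last bin closed, so
the maximum lands in the top bin and no node is dropped), and cell
(x, y) counts the nodes binned there; feature 2c−1 indexes rows.  A
zero-range feature maps all nodes to bin 0 with a logged warning.
Per-graph bin edges follow the per-subject construction of the
transform; dataset-global edges are available via the `edges` argument
when cross-subject pixel comparability matters.  Mass conservation —
every channel sums to |V| — is a structural invariant and the basis of
the acceptance check.

## CNN and cross-validation

Input r×r×(d_PCA/2) → conv 3×3 ×32 (ReLU) → conv 3×3 ×128 (ReLU) →
max-pool 2×2 → flatten → FC 32 (ReLU) → FC 16 (ReLU) → FC 2 (softmax).
Convolutions are unpadded ("valid"); for a 10×10 input the spatial
chain is 10 → 8 → 6 → 3 and the flatten width is 3·3·128 = 1,152.
Dropout 0.25 is applied after both convolutions and the first FC layer,
during training only; evaluation is deterministic.  The loss is
categorical cross-entropy plus an L2 penalty (coefficient 5·10⁻⁴) on
all weight matrices (not biases), optimised with Adam (lr 0.001,
β₁ = 0.9, β₂ = 0.999) for up to 1,000 epochs with early stopping on
validation loss (patience 50, min-delta 0) and restoration of the best
weights.  `count_parameters` reports 74,848 trainable weights and
75,058 parameters including biases for the default configuration.

Cross-validation draws, per iteration, a fresh random partition of the
subjects into k near-equal folds; each fold serves once as the test
group, a fresh model is initialised per fold from the seed stream, and
the held-out fold doubles as the early-stopping validation set (an
inner split would cost a third of a 40-subject cohort; with the
held-out fold also steering early stopping, reported fold accuracies
are mildly optimistic, which is acceptable for the synthetic recovery
check this package performs).  Images enter the CNN as raw counts by
default; `normalize_counts` divides each channel by its pixel sum.

Classes are one-hot encoded in the fixed order (control, case) =
(0, 1).

## Synthetic data

`simulate_coupled_signals` builds each channel as

cs · cos(2π f_b t + φ_b + lag_ch) + (1 − cs) · ε,

where block *b* has a common random initial phase φ_b and frequency
f_b, lag_ch is a per-channel phase lag, cs is the coupling strength and
ε is white Gaussian noise.  Two details are required for the generator
to carry a PLI-visible signal:

* **within a block, channels get distinct lags** (sorted draws from
  (0, π/2]) — with identical lags Δφ ≡ 0 and PLI is 0 by the sign(0)
  convention;
* **blocks get distinct frequencies**, spread evenly across
  ±`freq_jitter_hz` (default 1 Hz) around the base frequency (10 Hz)
  plus a small random component.  Random frequency draws alone can
  collide; two blocks at the same frequency hold a constant phase
  difference and show spuriously perfect PLI, blurring the class
  structure.  Even spacing guarantees pairwise drift, so between-block
  PLI averages out over a recording.

Class difference is encoded in coupling topology (2 vs 4 blocks by
default, coupling strength 0.85) and never in amplitude, because PLI is
amplitude-blind: the discriminative signal can only flow through the
intended path.  Cohorts are fully seed-reproducible, with one derived
stream per subject.

What the generator does **not** emulate: 1/f sensor noise spectra,
artifacts (cardiac, ocular, movement), volume conduction/field spread,
non-stationary coupling, or realistic head geometry.  Passing the
end-to-end test therefore shows that the pipeline recovers
phase-coupling class structure when it exists and is stationary; it
does not show that clinical recordings contain such structure or that
clinical accuracy would match.

## Problem sizes and numerical choices

Shape-contract tests use the 273-sensor montage; behavioural and
property tests use 6–40-node graphs and 8–40-subject cohorts
(recordings of 3,000 samples at 250 Hz), where every stage's statistics
are already stable.  The end-to-end cohort check runs 40 channels × 40
subjects through the full pipeline in about a minute on one CPU.
Ties in max-pooling break to the first element (deterministic);
histogram bin edges treat the max as belonging to the top bin;
`wrap_phase` folds exact −π onto +π so the wrapped interval is
(−π, π].  All randomness flows from named, independently derived
streams of a single master seed (`graphimg._rng`), so every stage is
reproducible in isolation and pipeline reruns are byte-identical.

## Known limitations

* The Hilbert phase of broadband signals is hard to interpret; band
  limits should be chosen per study (none are applied by default).
* Per-graph PCA and min–max binning make pixel positions comparable
  only statistically across subjects; the dataset-global options exist
  for studies that need strict comparability.
* Skip-gram embeddings are stochastic; only seeded runs are exactly
  reproducible, and embeddings of symmetric graphs are identifiable
  only up to rotation — downstream PCA re-aligns but cannot undo all
  of it.
* With ~75k parameters against tens of training images the CNN relies
  on dropout, weight decay and early stopping; reported accuracies on
  small cohorts have high fold-to-fold variance.
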