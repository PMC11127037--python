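# Methods

## The analysis model

The package implements decoding-based representational similarity analysis
for epoched EEG with single-case inference. The chain is:

1. **Preprocessing** (for continuous input): re-reference to a chosen
   electrode, zero-phase band-pass (default 0.01–80 Hz), cut epochs
   (default −200…1100 ms around onset), polyphase-downsample (default to
   256 Hz). Synthetic epochs are generated directly at the analysis rate
   and skip this stage.
2. **Pairwise decoding RDMs.** For each stimulus pair and timepoint, a
   Fisher linear discriminant w = Σ̂⁻¹(μ_b − μ_a) is trained on sensor
   topographies under stratified k-fold cross-validation (default 5 folds,
   5 repetitions); the cross-validated AUC of held-out decision values is
   the dissimilarity. Σ̂ is the class-demeaned pooled covariance shrunk
   toward (tr Σ̂ / C)·I. AUC is rank-based with half credit for ties.
3. **Temporal generalization.** TGM(s,t) = corr(RDM(s), RDM(t)) over the
   pair dimension, Pearson by default, Spearman as an option. Group TGMs
   average controls after Fisher z-transform (raw averaging available).
4. **Model comparison.** Model RDMs are aligned to the brain RDMs through
   a shared `PairIndex` object (misalignment is an error, never silent).
   Brain-model similarity per timepoint is Spearman correlation; the
   partial variant rank-transforms all three vectors (average ranks) and
   applies the first-order partial-correlation formula.
5. **Inference.** Patient-versus-controls contrasts use the
   Crawford-Howell modified t-test, df = n − 1, two-tailed, uncorrected at
   α = .05 by default (FDR is deliberately not applied by default to keep
   the map interpretation simple; the p-maps are saved so any correction
   can be applied post hoc). Within-group effects use sign-flip
   permutation tests, exhaustive when 2ⁿ fits in the permutation budget.

## Assumptions

* Trials are exchangeable within stimulus; one-back repetition trials are
  excluded from decoding by default (motor/adaptation confounds).
* The Crawford-Howell test assumes an approximately Gaussian control
  distribution; its Monte-Carlo calibration (false-positive rate at
  α = .05 with 18 controls) is checked in the test suite.
* Cross-validated AUC under the null is slightly *below* 0.5 (the familiar
  pessimistic bias of cross-validation: each fold's held-out sample is
  anti-correlated with its training sample). The null checks therefore
  test "chance within sampling error", not exact equality to 0.5.

## The synthetic generator

A participant is a `SimulationConfig`: a stimulus catalog, a geometry
schedule, trial/channel/rate counts and a seed. The geometry schedule is a
list of latency windows, each holding a latent pattern matrix
(stimuli × latent dims) and a gain. The noiseless topography of stimulus
*s* at time *t* is M · Σ_w env_w(t)·g_w·P_w[s], with M a seeded random
orthonormal channel-mixing matrix (orthonormality preserves pairwise
pattern geometry in sensor space — checked by a recovery test). Trial data
add i.i.d. Gaussian noise (optional AR(1)). Window envelopes rise/fall
linearly over a 20 ms cross-fade; with a nonzero persistence time constant
τ the gain instead decays as exp(−(t − t_end)/τ) after the window — the
patient abnormality that makes early geometry linger into late latencies.

The default cohort geometry (`make_synthetic_run`) uses two *contiguous*
windows: an early exemplar-like (low-abstraction) pattern at 60–160 ms and
a sustained category-clustered (high-abstraction) pattern at 160–480 ms,
both derived from the corresponding model feature banks by SVD projection
so the injected brain geometry matches the model RDMs it is later compared
with. Contiguity matters: with a silent gap between windows, controls have
no geometry in the gap and a persistence patient's excess generalization
spreads over the whole post-early map instead of concentrating in the
early × late region the persistence knob is meant to produce.

### Parameters that matter

| parameter | default | unit | why |
| --- | --- | --- | --- |
| catalog | 49 stimuli, 24 faces (8 identities × 3 expressions, 4 female), 8 animals / 8 objects / 9 scenes | — | the study's stimulus structure |
| trials per stimulus | 60 | count | ≈3,200 one-back trials / 49 stimuli over two sessions; a reconstruction, not a reported value |
| channels | 128 | count | high-density montage |
| sampling rate | 256 | Hz | analysis rate; one decoding bin per sample (≈3.9 ms ≈ "4 ms bins") |
| epoch window | −200…1100 | ms | trial epoch; decoding runs on −200…800 ms, contrasts on 0…800 ms |
| repeat probability | 0.1 | — | one-back repetition rate |
| window gain | 0.5 | latent-pattern SD units | in-window pairwise AUC ≈ 0.85 at test scale; the first draft (1.2) saturated AUC at exactly 1.0, which collapses RDM variance and is unrealistically decodable |
| noise sd | 1.0 | sensor units | reference noise level |
| persistence τ | 0 (controls) / 250 (patient demos) | ms | 0 reproduces the control regime; 250 ms leaves clear early-geometry traces across the late window |
| folds × repetitions | 5 × 5 | — | cross-validation scheme |
| shrinkage | Ledoit-Wolf analytic | — | 128 features vs. tens of trials makes the raw pooled covariance singular |

### What the generator does and does not emulate

It reproduces the *data structure* (trials × channels × time with a
stimulus catalog, one-back repeats, a patient + control cohort) and a
controllable representational geometry with known ground truth. It does
not attempt biophysical realism: no forward head model, no 1/f spectrum by
default (AR(1) optional), no artifacts, no inter-subject anatomical
variability (controls differ only by noise seed). Passing recovery tests
therefore demonstrates that the *analysis* recovers injected geometry,
persistence and model-preference effects at realistic SNR — not that it
would survive real-data artifacts those tests do not model.

## Numerical choices

* **Reproducibility.** All randomness flows from `numpy` `SeedSequence`s;
  decoding fold seeds derive from (master seed, unordered pair index,
  repetition), which makes decode(a, b) ≡ decode(b, a) exactly and results
  independent of pair evaluation order. Within a pair, trials are
  canonically ordered by a content hash before fold assignment, so results
  are invariant to the order trials arrive in. Class imbalance is resolved
  by seeded subsampling of the larger class.
* **Undefined values are NaN, never 0.** Constant RDM vectors (e.g. when
  AUC saturates at every pair) yield NaN TGM rows; zero-variance control
  cells (e.g. the unit TGM diagonal) yield NaN contrast cells; both are
  excluded from masks and counted, not silently dropped.
* **Partial correlation degeneracy.** When the control is rank-affine to
  either input, the partial-correlation numerator vanishes with the
  denominator (Cauchy-Schwarz); the implementation returns 0 ("nothing
  left to explain") and reserves NaN for numerically degenerate cells with
  a nonvanishing numerator.
* **Filtering.** The band-pass cascades a high-pass and a low-pass
  Butterworth half (2nd order each, forward-backward): with cutoffs four
  decades apart a single band-pass design is ill-conditioned. The
  high-pass uses Gustafsson initial conditions because at 0.01 Hz the
  impulse response is far longer than any practical padding.
* **Permutation ties.** Permuted statistics within 1e-9 (relative) of the
  observed one count as ties, so the identity permutation is always
  counted regardless of summation order.
* **Epoching convention.** Half-open [tmin, tmax) with the onset sample
  included: 1300 ms at 1024 Hz → 1331 samples.

## Design choices where the design was open

* TGM correlation type defaults to Pearson (the minimal reading of
  "cross-correlated"), with Spearman exposed; group TGMs Fisher-z average.
* Categorical RDM distance is Euclidean on concatenated binary codes,
  Hamming optional.
* The PCA face score standardizes both contrasts (correlation PCA) since
  accuracy and RT live on incommensurate scales, negates the RT contrast
  so both variables point "higher = better", and fixes the component sign
  to the accuracy contrast.
* The behavioral two-subgroup check uses the pooled-variance two-sample t.
* Partial-out scheme: visual-model timecourses partial out the semantic
  model; the semantic timecourse partials out the deepest visual model.

## Problem sizes used by tests and the acceptance script

Recovery and calibration runs use reduced scale: 8 stimuli (28 pairs),
6–10 controls, 20–40 trials per stimulus, 8–16 channels, 60 one-sample
bins at 80–100 Hz; calibration of the Crawford-Howell test uses 20,000
vectorized Gaussian replicates; the persistence signature pools 20 seeds
(12 in the acceptance script). These sizes give comfortable margins for
every qualitative signature while keeping a full run in minutes.

## Known limitations

* No classifier-based temporal generalization (train at t, test at t′);
  the TGM here correlates RDMs, which is symmetric by construction.
* No cluster-mass permutation correction for maps (uncorrected masks
  mirror the single-case literature's convention; FDR flag available for
  timecourses/maps post hoc).
* No noise-ceiling estimation and no variance partitioning beyond
  first-order partial correlation.
* The synthetic cohort has no age structure; the behavioral generator's
  subgroup labels exist only to exercise the subgroup statistics.
* Vendor EEG formats (BDF/EDF) are out of scope; continuous input enters
  through `ContinuousRecording` (array + events) or the HDF5 epoch
  container.
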