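# eegrsa

Time-resolved EEG representational similarity analysis (RSA) with
single-case statistics — the analysis chain used to characterize how a
brain-lesioned patient's stimulus representations unfold in time compared
with a neurotypical control group, exercised end to end on a synthetic-data
generator with programmable ground truth.

## Who this is for

Cognitive/computational neuroscientists running decoding-based RSA on
epoched M/EEG, in particular single-case (patient versus controls) designs
where group statistics are unavailable and every inference runs through a
case-versus-normative-sample test.

## What it computes

**Brain RDMs from decoding.** For every pair of stimuli *(i, j)* and every
timepoint *t*, a Fisher linear discriminant is trained on the sensor
topographies (all channels as features, pooled covariance shrunk toward a
scaled identity with an analytically chosen Ledoit-Wolf intensity) under
stratified 5-fold cross-validation repeated 5 times. The cross-validated
ROC area AUC(i, j, t) of the held-out decision values is the pairwise
dissimilarity; stacking all n(n−1)/2 pairs gives the time-resolved
representational dissimilarity matrix series (for the default 49-stimulus
catalog: 1176 pairs).

**Temporal generalization.** The time × time matrix
TGM(s, t) = corr(RDM(s), RDM(t)) asks how similar the representational
geometry at latency *s* is to the one at latency *t*; a geometry
"generalizes" when early rows stay correlated with late columns.

**Model comparison.** Model RDMs (network-layer feature banks via
1 − Pearson, embedding models via cosine distance, categorical one-hot /
multi-hot codes via binary-vector distance) are compared with the brain
RDM per timepoint through partial Spearman correlation,

ρ<sub>ab·c</sub> = (r<sub>ab</sub> − r<sub>ac</sub> r<sub>bc</sub>) / √((1 − r<sub>ac</sub>²)(1 − r<sub>bc</sub>²)),

computed on average-rank-transformed pair vectors, so a correlated control
model (e.g. a semantic embedding) can be partialled out of a visual-layer
comparison and vice versa.

**Single-case inference.** Every patient-versus-controls contrast — scalar
scores, ρ(t) curves, TGM cells — uses the Crawford-Howell modified t-test

t = (x<sub>case</sub> − x̄<sub>controls</sub>) / (s<sub>controls</sub> √((n+1)/n)),  df = n − 1,

with two-tailed p from Student's t. Within-group effects use exact or
sampled sign-flip permutation tests. A PCA-based face-specific behavioral
score collapses face-vs-nonface accuracy and RT contrasts
((face − nonface)/(face + nonface)) into one component.

**Synthetic ground truth.** `eegrsa.synth` generates epoched multichannel
EEG whose representational geometry follows a programmable schedule of
latency windows (latent pattern matrices mixed into sensors through a
seeded orthonormal matrix, plus Gaussian noise). A persistence time
constant lets early-window geometry decay slowly into late latencies — the
patient abnormality — and a gain knob can remove the late high-abstraction
signal. Behavioral tables and model feature banks with tunable category
abstraction complete the inputs, so every downstream stage is testable
without any recorded data.

## Worked example

```bash
python examples/04_case_statistics.py
```

```
first PC explains 66.0% of the variance across the accuracy and RT contrasts
face-specific score, patient vs controls: t(17) = -5.0303, p = 0.0001028 (below controls)
face-memory score, patient vs controls:   t(17) = -4.4766, p = 0.0003319
controls' nonface > face accuracy, exact sign-flip permutation p = 0.0038
```

A patient simulated with a −6 SD face-specific deficit against 18 controls:
the PCA score collapses the accuracy and RT contrasts into one variable,
and the Crawford-Howell test (df = 17 for 18 controls) flags the patient
far below the control distribution, while the face-memory score shows the
same deficit on an independent measure. The remaining examples walk
through decoding (`01`), temporal generalization with the persistence
signature (`02`), model comparison with partial Spearman (`03`) and the
end-to-end pipeline with byte-reproducible artifacts (`04`, `05`):

```bash
python examples/02_temporal_generalization.py
```

```
significant positive cells: 26; in the early x late region: 22 (85%, region covers 29% of the map)
-> the patient's early representations generalize abnormally far forward in time
```

The same end-to-end run is available from the shell:

```bash
eegrsa run-all --preset small --persistence 250 --face-deficit -6 --out report/
```

## Layout

| module | contents |
| --- | --- |
| `eegrsa.synth` | stimulus catalogs, geometry-scheduled epochs, model features, behavior |
| `eegrsa.preproc` | re-reference, band-pass, epoch, downsample |
| `eegrsa.rdm` | pairwise Fisher-LDA decoding, `PairIndex`, RDM series, pair subsets |
| `eegrsa.tgm` | temporal generalization matrices, group means, case contrasts |
| `eegrsa.models` | model RDMs, (partial) Spearman timecourses, case contrasts |
| `eegrsa.stats` | Crawford-Howell, p-from-t, face score, permutation tests |
| `eegrsa.pipeline` | end-to-end orchestration, artifacts, manifest; CLI in `eegrsa.cli` |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
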