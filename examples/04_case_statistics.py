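"""Single-case behavioral statistics: the PCA face score and Crawford-Howell.

Generates a one-back behavioral table for 18 controls plus a patient with a
severe face-specific deficit, collapses face-vs-nonface accuracy and RT
contrasts into one PCA score, and tests the patient against the control
distribution.  Also shows the exact sign-flip permutation test.
"""

import numpy as np

from eegrsa import crawford_howell, face_specific_score, gen_behavior, permutation_test

behavior = gen_behavior(n_controls=18, patient_face_deficit=-6.0, seed=3)
print(behavior.head(3).to_string(index=False))

score = face_specific_score(behavior.face_acc, behavior.nonface_acc,
                            behavior.face_rt, behavior.nonface_rt)
print(f"\nfirst PC explains {score.variance_explained:.1f}% of the variance "
      "across the accuracy and RT contrasts")

result = crawford_howell(score.pc_scores[0], score.pc_scores[1:])
print(f"face-specific score, patient vs controls: "
      f"t({result.df}) = {result.t:.4f}, p = {result.p:.4g} ({result.direction} controls)")

cfmt = crawford_howell(behavior.cfmt_score[0], behavior.cfmt_score[1:])
print(f"face-memory score, patient vs controls:   "
      f"t({cfmt.df}) = {cfmt.t:.4f}, p = {cfmt.p:.4g}")

# permutation test of a within-group effect (controls' face - nonface accuracy)
diffs = (behavior.face_acc - behavior.nonface_acc).to_numpy()[1:]
p_perm = permutation_test(-diffs, n_perm=100_000, scheme="sign_flip", seed=0)
print(f"controls' nonface > face accuracy, exact sign-flip permutation p = {p_perm:.4f}")
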