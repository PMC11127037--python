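"""Single-case and group inferential statistics.

The centerpiece is the Crawford-Howell modified t-test, the standard tool
for comparing one patient's score against a small normative control sample.
Unlike a z-score against the control mean, it treats the control statistics
as estimates from a finite sample, inflating the standard error by
sqrt((n+1)/n) and referring the statistic to Student's t with n-1 degrees
of freedom.  The module also provides the PCA-based face-specific behavioral
score, a pooled-variance two-sample t-test for control subgroup checks, and
nonparametric permutation tests for within-group effects.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CaseControlResult",
    "FaceScoreResult",
    "crawford_howell",
    "p_from_t",
    "face_specific_score",
    "two_sample_t",
    "permutation_test",
]


@dataclass(frozen=True)
class CaseControlResult:
    """Outcome of a single-case versus controls comparison.

    ``t`` carries the sign of ``case_value - control_mean``; ``p`` is the
    two-tailed Student-t tail probability with ``df = n_controls - 1``.
    """

    t: float
    df: int
    p: float
    case_value: float
    control_mean: float
    control_sd: float

    @property
    def direction(self) -> str:
        """'below' if the case scores under the control mean, else 'above'."""
        return "below" if self.t < 0 else "above"


@dataclass(frozen=True)
class FaceScoreResult:
    """Face-specific behavioral score extracted by PCA.

    ``contrast_scores`` holds the per-participant (face - nonface) /
    (face + nonface) contrasts for accuracy and RT (rows = participants,
    columns = [accuracy, rt]); ``pc_scores`` is the first principal
    component score per participant (zero mean across participants);
    ``variance_explained`` is the percentage of variance captured by that
    component.
    """

    contrast_scores: np.ndarray
    pc_scores: np.ndarray
    variance_explained: float
    loadings: np.ndarray


def p_from_t(t: float, df: int, tails: int = 2) -> float:
    """Tail probability of Student's t.

    Parameters
    ----------
    t : observed statistic (sign is ignored for the two-tailed case).
    df : degrees of freedom, must be >= 1.
    tails : 2 (default) for a two-tailed p, 1 for one-tailed on ``|t|``.
    """
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    return float(tails * sps.t.sf(abs(t), df))


def crawford_howell(
    case_value: float, control_values, tails: int = 2
) -> CaseControlResult:
    """Crawford-Howell modified t-test of one case against n controls.

    t = (case - mean) / (sd * sqrt((n + 1) / n)), with sd the unbiased
    (ddof=1) control standard deviation, referred to Student's t with
    df = n - 1.
    """
    controls = np.asarray(control_values, dtype=float).ravel()
    n = controls.size
    if n < 2:
        raise ValueError(f"need at least 2 controls, got {n}")
    mean = controls.mean()
    sd = controls.std(ddof=1)
    if sd == 0:
        raise ValueError("control sample has zero variance; test undefined")
    t = (case_value - mean) / (sd * np.sqrt((n + 1) / n))
    df = n - 1
    return CaseControlResult(
        t=float(t),
        df=df,
        p=p_from_t(t, df, tails=tails),
        case_value=float(case_value),
        control_mean=float(mean),
        control_sd=float(sd),
    )


def crawford_howell_map(case_values: np.ndarray, control_values: np.ndarray, tails: int = 2):
    """Vectorized Crawford-Howell over an arbitrary-shaped grid.

    ``control_values`` has the controls on its first axis and must match
    ``case_values`` in the remaining axes.  Cells where any input is NaN or
    where the control sd is zero yield NaN t and p.  Returns (t, p, df).
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    n = control_values.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 controls, got {n}")
    if control_values.shape[1:] != case_values.shape:
        raise ValueError(
            f"controls shape {control_values.shape[1:]} does not match case shape {case_values.shape}"
        )
    mean = control_values.mean(axis=0)
    sd = control_values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (case_values - mean) / (sd * np.sqrt((n + 1) / n))
    t = np.where(sd > 0, t, np.nan)
    df = n - 1
    p = np.full_like(t, np.nan)
    ok = np.isfinite(t)
    p[ok] = tails * sps.t.sf(np.abs(t[ok]), df)
    return t, p, df


def two_sample_t(group_a, group_b):
    """Pooled-variance two-sample t-test (two-tailed).

    Returns (t, df, p) with df = n_a + n_b - 2.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance; test undefined")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), a.size + b.size - 2, float(p)


def face_specific_score(
    face_acc,
    nonface_acc,
    face_rt,
    nonface_rt,
    participant_ids=None,
) -> FaceScoreResult:
    """Combine face/non-face accuracy and RT contrasts into a single score.

    Each participant's face-specific performance is summarized by the
    contrast (face - nonface) / (face + nonface), computed separately for
    accuracy and RT.  Because a *lower* RT means better performance, the RT
    contrast is negated so both variables point the same way.  The two
    standardized contrasts are then submitted to a PCA across participants;
    the first component score is the face-specific performance score.  The
    component sign is fixed so that a higher score means better face-specific
    accuracy.
    """
    arrays = [np.asarray(x, dtype=float).ravel() for x in (face_acc, nonface_acc, face_rt, nonface_rt)]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("all behavioral inputs must have the same length")
    if n < 3:
        raise ValueError(f"need at least 3 participants, got {n}")
    fa, na, fr, nr = arrays
    for name, s in (("accuracy", fa + na), ("rt", fr + nr)):
        bad = np.flatnonzero(s == 0)
        if bad.size:
            raise ValueError(f"zero {name} contrast denominator for participant(s) {bad.tolist()}")
    acc_contrast = (fa - na) / (fa + na)
    rt_contrast = (fr - nr) / (fr + nr)
    # negate RT before PCA: a *smaller* face RT means better face performance
    X = np.column_stack([acc_contrast, -rt_contrast])
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    # 2-variable PCA on the correlation matrix via SVD of standardized data
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / (n - 1)
    variance_explained = 100.0 * var[0] / var.sum()
    loading = Vt[0]
    if loading[0] < 0:  # anchor sign to the accuracy contrast
        loading = -loading
    pc_scores = Z @ loading
    return FaceScoreResult(
        contrast_scores=np.column_stack([acc_contrast, rt_contrast]),
        pc_scores=pc_scores,
        variance_explained=float(variance_explained),
        loadings=loading,
    )


def permutation_test(
    values,
    n_perm: int = 10000,
    scheme: str = "sign_flip",
    seed: int = 0,
    labels=None,
    alternative: str = "greater",
) -> float:
    """Nonparametric permutation p-value for a mean (or mean-difference).

    ``sign_flip`` tests the mean of per-subject statistics against zero by
    randomly flipping signs; when the 2**n exhaustive enumeration fits in
    ``n_perm`` draws it is used instead of sampling, making the p exact.
    ``label_shuffle`` tests a two-group mean difference by shuffling the
    binary ``labels`` vector.  Sampled p-values use the standard
    add-one correction p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; permutation p will be coarse", n_perm)
    rng = np.random.default_rng(seed)

    def _tail(null, obs):
        # tolerance so the identity permutation always counts as a tie even
        # when summation order makes it differ from obs in the last ulp
        eps = 1e-9 * max(1.0, abs(obs))
        if alternative == "greater":
            return null >= obs - eps
        if alternative == "less":
            return null <= obs + eps
        return np.abs(null) >= abs(obs) - eps

    if scheme == "sign_flip":
        obs = values.mean()
        if 2**n <= n_perm:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
            null = signs @ values / n
            return float(np.mean(_tail(null, obs)))
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        null = signs @ values / n
        return float((1 + _tail(null, obs).sum()) / (1 + n_perm))
    if scheme == "label_shuffle":
        if labels is None:
            raise ValueError("label_shuffle requires a labels vector")
        labels = np.asarray(labels).ravel().astype(bool)
        if labels.size != n or labels.all() or not labels.any():
            raise ValueError("labels must split subjects into two nonempty groups")
        obs = values[labels].mean() - values[~labels].mean()
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            stat = values[perm].mean() - values[~perm].mean()
            count += bool(_tail(stat, obs))
        return float((1 + count) / (1 + n_perm))
    raise ValueError(f"unknown permutation scheme {scheme!r}")
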