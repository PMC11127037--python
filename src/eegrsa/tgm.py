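"""Temporal generalization of representational geometries.

A time x time temporal generalization matrix (TGM) is built by correlating
a participant's time-resolved RDM vectors across all timepoint pairs: cell
(s, t) asks how similar the representational geometry at latency s is to
the one at latency t.  A geometry "generalizes" forward when early rows
stay correlated with late columns.  Patient-versus-controls contrasts are
computed cell-wise with the Crawford-Howell modified t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .rdm import RDMSeries
from .stats import crawford_howell_map

__all__ = ["TGM", "TGMContrast", "compute_tgm", "mean_tgm", "tgm_case_contrast"]


@dataclass
class TGM:
    """Time x time correlation matrix between time-resolved RDM vectors."""

    values: np.ndarray
    time_ms: np.ndarray
    metric: str = "pearson"
    pair_subset: str = "all"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        n = self.time_ms.size
        if self.values.shape != (n, n):
            raise ValueError(f"values must be ({n}, {n}), got {self.values.shape}")


@dataclass
class TGMContrast:
    """Cell-wise Crawford-Howell patient-vs-controls contrast of TGMs."""

    t_map: np.ndarray
    p_map: np.ndarray
    df: int
    alpha: float
    time_ms: np.ndarray

    @property
    def mask(self) -> np.ndarray:
        """Boolean significance map: p < alpha (NaN cells are False)."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.p_map, nan=1.0) < self.alpha

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.t_map).sum())


def compute_tgm(
    rdm: RDMSeries,
    metric: str = "pearson",
    time_range: tuple[float, float] | None = (0.0, 800.0),
) -> TGM:
    """Correlate the RDM pair-vectors across all timepoint pairs.

    ``metric`` is 'pearson' (default) or 'spearman' (Pearson on average
    ranks, hence invariant to monotone transforms of the dissimilarities).
    Timepoints whose pair-vector is constant have no defined correlation;
    their row and column are set to NaN rather than silently zeroed.
    """
    if metric not in ("pearson", "spearman"):
        raise ValueError(f"metric must be 'pearson' or 'spearman', got {metric!r}")
    if rdm.n_pairs < 3:
        raise ValueError("need at least 3 pairs for a meaningful correlation")
    if time_range is not None:
        keep = (rdm.time_ms >= time_range[0] - 1e-9) & (rdm.time_ms <= time_range[1] + 1e-9)
        values, time_ms = rdm.values[keep], rdm.time_ms[keep]
    else:
        values, time_ms = rdm.values, rdm.time_ms
    X = rankdata(values, axis=1) if metric == "spearman" else values
    sd = X.std(axis=1)
    tgm = np.full((X.shape[0], X.shape[0]), np.nan)
    ok = sd > 0
    if ok.any():
        tgm_ok = np.corrcoef(X[ok])
        tgm[np.ix_(ok, ok)] = tgm_ok
    return TGM(values=tgm, time_ms=time_ms, metric=metric, pair_subset=rdm.subset)


def mean_tgm(tgms: list[TGM], fisher_z: bool = True) -> TGM:
    """Average TGMs across participants (Fisher z by default).

    The z-transform stabilizes correlation variance before averaging; the
    result is transformed back with tanh.  NaN cells propagate.
    """
    if not tgms:
        raise ValueError("no TGMs to average")
    _check_axes(tgms)
    stack = np.stack([t.values for t in tgms])
    if fisher_z:
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    return TGM(values=mean, time_ms=tgms[0].time_ms, metric=tgms[0].metric,
               pair_subset=tgms[0].pair_subset)


def _check_axes(tgms):
    ref = tgms[0]
    for t in tgms[1:]:
        if t.values.shape != ref.values.shape or not np.allclose(t.time_ms, ref.time_ms):
            raise ValueError("TGM axes do not match")
        if t.metric != ref.metric or t.pair_subset != ref.pair_subset:
            raise ValueError("TGM metric/subset do not match")


def tgm_case_contrast(patient: TGM, controls: list[TGM], alpha: float = 0.05) -> TGMContrast:
    """Cell-wise Crawford-Howell t-map of a patient TGM against controls.

    Cells undefined in the patient or any control (NaN) are excluded from
    the contrast and stay NaN in the maps; p-values are two-tailed and
    uncorrected.
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 control TGMs")
    _check_axes([patient] + list(controls))
    control_stack = np.stack([c.values for c in controls])
    t_map, p_map, df = crawford_howell_map(patient.values, control_stack)
    return TGMContrast(t_map=t_map, p_map=p_map, df=df, alpha=alpha, time_ms=patient.time_ms)
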