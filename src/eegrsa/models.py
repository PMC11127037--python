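"""Model RDMs and brain-model comparison via (partial) Spearman correlation.

Model RDMs summarize a candidate representation — layer activations of a
visual network, sentence-embedding vectors of image captions, or binary
categorical codes — as a pairwise dissimilarity vector over the same
stimulus pairs as the brain RDMs.  Brain-model similarity is then the
Spearman rank correlation per timepoint; to separate correlated models
(e.g. a deep visual layer and a semantic embedding), the shared variance of
a control model can be partialled out in the rank domain (first-order
partial correlation on average-rank-transformed vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

from .rdm import PairIndex, RDMSeries
from .stats import crawford_howell_map
from .synth import StimulusCatalog

__all__ = [
    "ModelRDM",
    "TimecourseResult",
    "load_features_csv",
    "rdm_from_features",
    "categorical_rdm",
    "spearman_rdm",
    "partial_spearman_rdm",
    "model_timecourse",
    "timecourse_case_contrast",
]

METRICS = ("one_minus_pearson", "cosine_distance", "binary_vector_distance")


@dataclass
class ModelRDM:
    """Pair-vector of model dissimilarities aligned to a PairIndex."""

    values: np.ndarray
    pair_index: PairIndex
    metric: str
    name: str = "model"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.pair_index.n_pairs,):
            raise ValueError(
                f"values length {self.values.size} != n_pairs {self.pair_index.n_pairs}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("model RDM contains non-finite values")


@dataclass
class TimecourseResult:
    """Per-timepoint (partial) Spearman correlation of brain with one model."""

    rho: np.ndarray
    time_ms: np.ndarray
    model: str
    partialled_out: str | None = None
    subject: str | None = None


def load_features_csv(path, delimiter: str = ",") -> np.ndarray:
    """Read a (stimuli x features) matrix from CSV/TSV.

    Expects a header row of feature names and the stimulus id in the first
    column; rows are returned sorted by stimulus id so the matrix aligns
    with the catalog's PairIndex.
    """
    import pandas as pd

    frame = pd.read_csv(path, sep=delimiter)
    id_col = frame.columns[0]
    frame = frame.sort_values(id_col)
    ids = frame[id_col].to_numpy()
    if not np.array_equal(ids, np.arange(len(ids))):
        raise ValueError("first column must hold contiguous stimulus ids from 0")
    return frame.drop(columns=id_col).to_numpy(dtype=float)


def rdm_from_features(
    features: np.ndarray,
    metric: str = "one_minus_pearson",
    pair_index: PairIndex | None = None,
    name: str = "model",
) -> ModelRDM:
    """Pairwise dissimilarities of a (stimuli x features) activation matrix.

    'one_minus_pearson' is the convention for network-layer RDMs,
    'cosine_distance' for embedding-based semantic RDMs; both lie in [0, 2].
    """
    F = np.asarray(features, dtype=float)
    if F.ndim != 2 or F.shape[0] < 2:
        raise ValueError("features must be 2-D with at least 2 stimuli")
    if pair_index is None:
        pair_index = PairIndex.from_n(F.shape[0])
    elif pair_index.n_stimuli != F.shape[0]:
        raise ValueError("pair_index does not match the number of stimuli")
    if metric == "one_minus_pearson":
        constant = np.flatnonzero(F.std(axis=1) == 0)
        if constant.size:
            raise ValueError(
                f"constant feature row(s) {constant.tolist()}: Pearson undefined"
            )
        values = pdist(F, metric="correlation")
    elif metric == "cosine_distance":
        values = pdist(F, metric="cosine")
    elif metric == "binary_vector_distance":
        values = pdist(F, metric="euclidean")
    else:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    return ModelRDM(values=values, pair_index=pair_index, metric=metric, name=name)


def _encode_dimension(catalog: StimulusCatalog, dim: str) -> np.ndarray:
    table = catalog.table
    if dim == "animacy":
        levels = table["category"].map(lambda c: "animate" if c in ("face", "animal") else "inanimate")
    elif dim in table.columns:
        levels = table[dim]
    else:
        raise ValueError(f"unknown catalog dimension {dim!r}")
    filled = levels.astype(object).where(levels.notna(), "_none")
    uniq = sorted(set(filled))
    code = np.zeros((len(table), len(uniq)))
    for k, level in enumerate(uniq):
        code[:, k] = (filled == level).to_numpy()
    return code


def categorical_rdm(
    catalog: StimulusCatalog,
    dimensions: list[str],
    encoding: str = "multihot",
    distance: str = "euclidean",
    pair_index: PairIndex | None = None,
) -> ModelRDM:
    """Binary-code categorical model RDM over catalog dimensions.

    'onehot' encodes a single dimension as a one-of-k binary vector;
    'multihot' concatenates the codes of several dimensions (category,
    face_gender, face_expression, face_identity, animacy).  Dissimilarity
    is the Euclidean (or Hamming) distance between code vectors.
    """
    if encoding == "onehot" and len(dimensions) != 1:
        raise ValueError("onehot encoding takes exactly one dimension")
    if encoding not in ("onehot", "multihot"):
        raise ValueError(f"encoding must be 'onehot' or 'multihot', got {encoding!r}")
    codes = np.hstack([_encode_dimension(catalog, d) for d in dimensions])
    if pair_index is None:
        pair_index = PairIndex.from_catalog(catalog)
    if distance == "euclidean":
        values = pdist(codes, metric="euclidean")
    elif distance == "hamming":
        values = pdist(codes, metric="hamming")
    else:
        raise ValueError("distance must be 'euclidean' or 'hamming'")
    name = f"{encoding}:{'+'.join(dimensions)}"
    return ModelRDM(values=values, pair_index=pair_index, metric="binary_vector_distance", name=name)


def spearman_rdm(a, b) -> float:
    """Spearman rank correlation (average ranks for ties) of two pair-vectors.

    Returns NaN when either vector is constant (correlation undefined).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    ra, rb = rankdata(a), rankdata(b)
    if ra.std() == 0 or rb.std() == 0:
        return float("nan")
    return float(np.corrcoef(ra, rb)[0, 1])


def partial_spearman_rdm(a, b, control) -> float:
    """First-order partial Spearman correlation of a and b given a control.

    All three vectors are rank-transformed (average ranks), then
    rho = (r_ab - r_ac r_bc) / sqrt((1 - r_ac^2)(1 - r_bc^2)).
    A constant control reduces to the plain Spearman correlation; a control
    rank-identical to a or b makes the partial undefined (NaN).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    c = np.asarray(control, dtype=float).ravel()
    if not (a.size == b.size == c.size) or a.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    ra, rb, rc = rankdata(a), rankdata(b), rankdata(c)
    if ra.std() == 0 or rb.std() == 0:
        return float("nan")
    if rc.std() == 0:
        return float(np.corrcoef(ra, rb)[0, 1])
    r_ab = np.corrcoef(ra, rb)[0, 1]
    r_ac = np.corrcoef(ra, rc)[0, 1]
    r_bc = np.corrcoef(rb, rc)[0, 1]
    num = r_ab - r_ac * r_bc
    denom2 = (1 - r_ac**2) * (1 - r_bc**2)
    if denom2 <= 1e-20:
        # control rank-identical to a or b: numerator vanishes with the
        # denominator (nothing left to explain -> 0); a nonvanishing
        # numerator over a zero denominator is genuinely undefined
        return 0.0 if abs(num) < 1e-8 else float("nan")
    return float(num / np.sqrt(denom2))


def model_timecourse(
    rdm: RDMSeries,
    model: ModelRDM,
    partial_out: ModelRDM | None = None,
    subject: str | None = None,
) -> TimecourseResult:
    """(Partial) Spearman correlation of the brain RDM with a model, per timepoint.

    Alignment is enforced through the shared :class:`PairIndex`; timepoints
    with undefined correlations come back as NaN, never silently dropped.
    """
    if rdm.subset != "all":
        raise ValueError("model comparison requires the full pair set")
    if model.pair_index != rdm.pair_index:
        raise ValueError("model RDM PairIndex does not match the brain RDM")
    if partial_out is not None and partial_out.pair_index != rdm.pair_index:
        raise ValueError("control RDM PairIndex does not match the brain RDM")
    rho = np.empty(rdm.n_times)
    for t in range(rdm.n_times):
        if partial_out is None:
            rho[t] = spearman_rdm(rdm.values[t], model.values)
        else:
            rho[t] = partial_spearman_rdm(rdm.values[t], model.values, partial_out.values)
    return TimecourseResult(
        rho=rho, time_ms=rdm.time_ms.copy(), model=model.name,
        partialled_out=None if partial_out is None else partial_out.name,
        subject=subject,
    )


def timecourse_case_contrast(
    patient: TimecourseResult,
    controls: list[TimecourseResult],
    alpha: float = 0.05,
):
    """Per-timepoint Crawford-Howell contrast of patient vs control rho curves.

    Returns a dict with t, p, df, mask (p < alpha), the direction per
    timepoint (+1 patient above controls, -1 below) and the shared time axis.
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 control timecourses")
    for c in controls:
        if c.rho.size != patient.rho.size or not np.allclose(c.time_ms, patient.time_ms):
            raise ValueError("timecourse axes do not match")
        if c.model != patient.model or c.partialled_out != patient.partialled_out:
            raise ValueError("timecourses compare different models")
    stack = np.stack([c.rho for c in controls])
    t, p, df = crawford_howell_map(patient.rho, stack)
    with np.errstate(invalid="ignore"):
        mask = np.nan_to_num(p, nan=1.0) < alpha
    return {
        "t": t,
        "p": p,
        "df": df,
        "mask": mask,
        "direction": np.sign(np.nan_to_num(t)),
        "time_ms": patient.time_ms,
        "model": patient.model,
    }
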