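"""Synthetic stimulus catalogs, epoched EEG, model features and behavior.

The generator emulates the structure of a one-back EEG experiment on a
49-image stimulus set (24 faces: 8 identities x 3 expressions, plus
animals/objects/scenes), recorded with a high-density montage and epoched
around stimulus onset.  Its central device is a *geometry schedule*: a list
of latency windows, each carrying a latent pattern matrix (stimuli x latent
dimensions) and a gain.  At any timepoint, each stimulus' noiseless
topography is the channel-mixed sum of the active windows' pattern rows;
i.i.d. (optionally AR(1)) Gaussian noise is added per trial.  A nonnegative
``persistence_ms`` time constant lets window gains decay exponentially
*after* their window instead of vanishing — the knob that emulates a
patient whose early representational geometry abnormally persists into
late latencies.

Everything is driven by :class:`numpy.random.Generator` seeded from the
config, so identical config + seed reproduces identical arrays bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preproc import EpochSet

__all__ = [
    "StimulusCatalog",
    "GeometryWindow",
    "GeometrySchedule",
    "SimulationConfig",
    "gen_catalog",
    "gen_epochs",
    "expected_topographies",
    "random_patterns",
    "gen_model_features",
    "gen_behavior",
]

CATEGORIES = ("face", "animal", "object", "plant", "scene")
EXPRESSIONS = ("neutral", "happy", "fearful")


@dataclass
class StimulusCatalog:
    """Stimulus metadata table.

    Columns: ``stimulus_id`` (contiguous from 0), ``category`` (one of
    face/animal/object/plant/scene), and — for faces only —
    ``face_identity``, ``face_gender``, ``face_expression``.
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        n = len(t)
        if not np.array_equal(t["stimulus_id"].to_numpy(), np.arange(n)):
            raise ValueError("stimulus_id must be unique and contiguous from 0")
        bad = set(t["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        is_face = t["category"] == "face"
        for col in ("face_identity", "face_gender", "face_expression"):
            has = t[col].notna()
            if not (has == is_face).all():
                raise ValueError(f"{col} must be present iff category == 'face'")

    @property
    def n_stimuli(self) -> int:
        return len(self.table)

    @property
    def stimulus_ids(self) -> np.ndarray:
        return self.table["stimulus_id"].to_numpy()

    @property
    def is_face(self) -> np.ndarray:
        return (self.table["category"] == "face").to_numpy()

    def to_json(self) -> str:
        return self.table.to_json(orient="records", indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StimulusCatalog":
        t = pd.read_json(__import__("io").StringIO(text), orient="records")
        for col in ("face_identity", "face_gender", "face_expression"):
            if col not in t:
                t[col] = pd.NA
        return cls(t)


def gen_catalog(
    n_faces: int = 24,
    n_nonfaces_per_category: dict[str, int] | None = None,
    seed: int = 0,
) -> StimulusCatalog:
    """Build a stimulus catalog; the default reproduces the 49-image set.

    Faces come as identities x 3 expressions, with half the identities
    (rounded down) female; ``n_faces`` must therefore be divisible by 3.
    The default non-face complement is 8 animals, 8 objects and 9 scenes.
    """
    if n_nonfaces_per_category is None:
        n_nonfaces_per_category = {"animal": 8, "object": 8, "scene": 9}
    if n_faces < 0:
        raise ValueError("n_faces must be nonnegative")
    if n_faces % len(EXPRESSIONS) != 0:
        raise ValueError(
            f"n_faces must be divisible by {len(EXPRESSIONS)} expressions, got {n_faces}"
        )
    rows = []
    n_ident = n_faces // len(EXPRESSIONS)
    n_female = n_ident // 2
    for ident in range(n_ident):
        gender = "female" if ident < n_female else "male"
        for expr in EXPRESSIONS:
            rows.append(("face", ident, gender, expr))
    for cat, count in n_nonfaces_per_category.items():
        if cat not in CATEGORIES or cat == "face":
            raise ValueError(f"invalid non-face category {cat!r}")
        if count < 0:
            raise ValueError(f"negative count for category {cat!r}")
        rows.extend((cat, None, None, None) for _ in range(count))
    if not rows:
        raise ValueError("catalog would be empty")
    table = pd.DataFrame(rows, columns=["category", "face_identity", "face_gender", "face_expression"])
    table.insert(0, "stimulus_id", np.arange(len(table)))
    return StimulusCatalog(table)


@dataclass
class GeometryWindow:
    """One latency window of the representational geometry.

    ``pattern`` is (n_stimuli, n_latent): the latent response pattern of
    every stimulus while the window is active.  ``gain`` scales it.
    """

    t_start_ms: float
    t_end_ms: float
    pattern: np.ndarray
    gain: float = 1.0

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, dtype=float)
        if self.pattern.ndim != 2:
            raise ValueError("pattern must be 2-D (stimuli x latent dims)")
        if self.t_end_ms <= self.t_start_ms:
            raise ValueError("window must have positive duration")
        if self.gain < 0:
            raise ValueError("gain must be nonnegative")


@dataclass
class GeometrySchedule:
    """Time-varying geometry: windows + persistence + noise level.

    ``persistence_ms`` = 0 gives the control regime (gains cross-fade to
    zero at the window edge); > 0 makes every window's gain decay as
    exp(-(t - t_end)/persistence_ms) after its window, so early geometries
    linger into late latencies.
    """

    windows: list[GeometryWindow]
    persistence_ms: float = 0.0
    noise_sd: float = 1.0
    crossfade_ms: float = 20.0
    ar1: float = 0.0

    def __post_init__(self):
        if self.persistence_ms < 0:
            raise ValueError("persistence_ms must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not -1 < self.ar1 < 1:
            raise ValueError("ar1 coefficient must lie in (-1, 1)")
        dims = {w.pattern.shape for w in self.windows}
        if len({d[0] for d in dims}) > 1:
            raise ValueError("all window patterns must cover the same stimuli")

    @property
    def n_latent(self) -> int:
        return max((w.pattern.shape[1] for w in self.windows), default=0)

    def envelope(self, window: GeometryWindow, time_ms: np.ndarray) -> np.ndarray:
        """Gain envelope of one window over the given time axis."""
        t = np.asarray(time_ms, dtype=float)
        cf = max(self.crossfade_ms, 1e-9)
        rise = np.clip((t - window.t_start_ms) / cf, 0.0, 1.0)
        if self.persistence_ms > 0:
            tail = np.where(
                t <= window.t_end_ms, 1.0, np.exp(-(t - window.t_end_ms) / self.persistence_ms)
            )
        else:
            tail = np.clip((window.t_end_ms + cf - t) / cf, 0.0, 1.0)
        return window.gain * rise * tail


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic participant's epoched recording."""

    catalog: StimulusCatalog
    schedule: GeometrySchedule
    n_trials_per_stimulus: int = 60
    n_channels: int = 128
    sampling_rate: float = 256.0
    epoch_window: tuple[float, float] = (-200.0, 1100.0)
    repeat_probability: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_trials_per_stimulus < 1 or self.n_channels < 1:
            raise ValueError("counts must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.repeat_probability < 1:
            raise ValueError("repeat_probability must lie in [0, 1)")
        tmin, tmax = self.epoch_window
        if tmax <= tmin:
            raise ValueError("epoch_window must have positive duration")
        for w in self.schedule.windows:
            if w.t_start_ms < tmin or w.t_end_ms > tmax:
                raise ValueError(
                    f"window [{w.t_start_ms}, {w.t_end_ms}] ms outside epoch {self.epoch_window}"
                )
            if w.pattern.shape[0] != self.catalog.n_stimuli:
                raise ValueError("window pattern rows must match the catalog size")
        if self.schedule.n_latent > self.n_channels:
            raise ValueError("latent dimension cannot exceed the channel count")

    def time_axis(self) -> np.ndarray:
        tmin, tmax = self.epoch_window
        n = int(np.floor((tmax - tmin) / 1000.0 * self.sampling_rate))
        return tmin + np.arange(n) / self.sampling_rate * 1000.0

    def to_dict(self) -> dict:
        """Config summary for YAML/JSON serialization (patterns by shape)."""
        return {
            "n_stimuli": self.catalog.n_stimuli,
            "n_faces": int(self.catalog.is_face.sum()),
            "n_trials_per_stimulus": self.n_trials_per_stimulus,
            "n_channels": self.n_channels,
            "sampling_rate": self.sampling_rate,
            "epoch_window_ms": list(self.epoch_window),
            "repeat_probability": self.repeat_probability,
            "seed": self.seed,
            "schedule": {
                "persistence_ms": self.schedule.persistence_ms,
                "noise_sd": self.schedule.noise_sd,
                "crossfade_ms": self.schedule.crossfade_ms,
                "ar1": self.schedule.ar1,
                "windows": [
                    {"t_start_ms": w.t_start_ms, "t_end_ms": w.t_end_ms,
                     "gain": w.gain, "pattern_shape": list(w.pattern.shape)}
                    for w in self.schedule.windows
                ],
            },
        }


def random_patterns(n_stimuli: int, n_latent: int, seed: int = 0, scale: float = 1.0) -> np.ndarray:
    """I.i.d. Gaussian latent pattern matrix (one row per stimulus)."""
    rng = np.random.default_rng(seed)
    return scale * rng.standard_normal((n_stimuli, n_latent))


def _mixing_matrix(n_channels: int, n_latent: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded random orthonormal channel-mixing matrix (C x k).

    Orthonormal columns preserve the latent pattern geometry in sensor
    space: pairwise pattern distances survive the mixing unchanged.
    """
    a = rng.standard_normal((n_channels, n_latent))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))  # fix QR sign ambiguity for reproducibility


def expected_topographies(config: SimulationConfig) -> np.ndarray:
    """Noiseless per-stimulus sensor topographies, (stimuli x channels x times)."""
    time_ms = config.time_axis()
    # mixing matrix gets its own stream so it is independent of trial noise
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    k = config.schedule.n_latent
    mix = _mixing_matrix(config.n_channels, k, rng) if k else np.zeros((config.n_channels, 0))
    out = np.zeros((config.catalog.n_stimuli, config.n_channels, time_ms.size))
    for w in config.schedule.windows:
        env = config.schedule.envelope(w, time_ms)  # (T,)
        sensor = w.pattern @ mix[:, : w.pattern.shape[1]].T  # (S, C)
        out += sensor[:, :, None] * env[None, None, :]
    return out


def _trial_sequence(config: SimulationConfig, rng: np.random.Generator):
    """One-back stimulus stream: balanced base trials + flagged repetitions."""
    base = np.repeat(config.catalog.stimulus_ids, config.n_trials_per_stimulus)
    rng.shuffle(base)
    labels, flags = [], []
    for stim in base:
        labels.append(stim)
        flags.append(False)
        if rng.random() < config.repeat_probability:
            labels.append(stim)
            flags.append(True)
    return np.asarray(labels, dtype=int), np.asarray(flags, dtype=bool)


def gen_epochs(config: SimulationConfig) -> EpochSet:
    """Simulate one participant's epoched EEG under the geometry schedule."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    time_ms = config.time_axis()
    topo = expected_topographies(config)  # (S, C, T); reuses the same mixing seed
    labels, flags = _trial_sequence(config, rng)
    n_trials = labels.size
    noise = rng.standard_normal((n_trials, config.n_channels, time_ms.size))
    if config.schedule.ar1:
        phi = config.schedule.ar1
        innov_scale = np.sqrt(1.0 - phi**2)
        for t in range(1, time_ms.size):
            noise[:, :, t] = phi * noise[:, :, t - 1] + innov_scale * noise[:, :, t]
    data = topo[labels] + config.schedule.noise_sd * noise
    return EpochSet(
        data=data,
        time_ms=time_ms,
        labels=labels,
        repeat_flag=flags,
        sampling_rate=config.sampling_rate,
    )


def gen_model_features(
    catalog: StimulusCatalog,
    abstraction: float,
    n_features: int,
    seed: int = 0,
) -> np.ndarray:
    """Feature matrix (stimuli x features) with tunable category abstraction.

    ``abstraction`` interpolates between exemplar-unique random features
    (0: every stimulus is its own cluster, the RDM is uniform off-diagonal
    in expectation) and category prototypes (1: stimuli of a category share
    one feature vector, within-category dissimilarity collapses).  This
    mimics the progression from early to deep layers of a visual network.
    """
    if catalog.n_stimuli == 0:
        raise ValueError("catalog is empty")
    if not 0 <= abstraction <= 1:
        raise ValueError("abstraction must lie in [0, 1]")
    if n_features < 1:
        raise ValueError("n_features must be positive")
    rng = np.random.default_rng(seed)
    cats = catalog.table["category"].to_numpy()
    uniq = {c: rng.standard_normal(n_features) for c in dict.fromkeys(cats)}
    proto = np.stack([uniq[c] for c in cats])
    unique = rng.standard_normal((catalog.n_stimuli, n_features))
    return abstraction * proto + (1.0 - abstraction) * unique


def gen_behavior(
    n_controls: int = 18,
    patient_face_deficit: float = 0.0,
    seed: int = 0,
    n_matched: int = 4,
    patient_cfmt_deficit: float | None = None,
) -> pd.DataFrame:
    """Behavioral table: one-back accuracy/RT per condition + a CFMT-like score.

    Controls are drawn i.i.d. Gaussian around realistic one-back accuracies
    (~0.90), RTs (~530 ms) and a face-memory score (~75/102).  The patient
    row's *face* measures are shifted by ``patient_face_deficit`` control
    standard deviations (negative = impaired: lower face accuracy, slower
    face RT); non-face measures stay at control levels, emulating a
    face-selective deficit.  The first ``n_matched`` controls are labelled
    age-matched, the rest young.
    """
    if n_controls < 2:
        raise ValueError("need at least 2 controls")
    if patient_cfmt_deficit is None:
        patient_cfmt_deficit = patient_face_deficit
    rng = np.random.default_rng(seed)
    means = dict(face_acc=0.90, nonface_acc=0.92, face_rt=540.0, nonface_rt=520.0, cfmt=75.0)
    sds = dict(face_acc=0.04, nonface_acc=0.03, face_rt=50.0, nonface_rt=45.0, cfmt=9.0)
    n = n_controls + 1
    cols = {k: means[k] + sds[k] * rng.standard_normal(n) for k in means}
    # row 0 is the patient: shift the face-specific measures
    cols["face_acc"][0] += patient_face_deficit * sds["face_acc"]
    cols["face_rt"][0] -= patient_face_deficit * sds["face_rt"]  # deficit<0 -> slower
    cols["cfmt"][0] += patient_cfmt_deficit * sds["cfmt"]
    for k in ("face_acc", "nonface_acc"):
        cols[k] = np.clip(cols[k], 0.05, 1.0)
    for k in ("face_rt", "nonface_rt"):
        cols[k] = np.maximum(cols[k], 150.0)
    cols["cfmt"] = np.clip(cols["cfmt"], 0.0, 102.0)
    ids = ["patient"] + [f"control{i:02d}" for i in range(1, n)]
    group = ["patient"] + ["control_matched"] * min(n_matched, n_controls)
    group += ["control_young"] * (n_controls - min(n_matched, n_controls))
    return pd.DataFrame(
        {
            "participant_id": ids,
            "group": group,
            "face_acc": cols["face_acc"],
            "nonface_acc": cols["nonface_acc"],
            "face_rt": cols["face_rt"],
            "nonface_rt": cols["nonface_rt"],
            "cfmt_score": cols["cfmt"],
        }
    )
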