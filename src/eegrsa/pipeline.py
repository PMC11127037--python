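"""End-to-end orchestration: simulate/load -> RDMs -> TGMs -> models -> stats.

:func:`run` executes the whole analysis for one patient and a control
group and writes every stage's artifacts (HDF5 epochs and RDMs, CSV TGMs
and contrasts, JSON statistics) plus a manifest with the package version,
a config hash, and per-file checksums — rerunning with the same config and
seed reproduces every numeric artifact byte for byte.

:func:`make_synthetic_run` builds a ready-to-run configuration from the
synthetic generator: controls share a two-window representational geometry
(an early low-abstraction window and a late high-abstraction window); the
patient can deviate by a persistence abnormality (early geometry leaking
into late latencies) and/or a late high-abstraction deficit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import load_epochs, save_config, save_epochs, save_rdm_series, write_csv, write_json
from .models import ModelRDM, model_timecourse, rdm_from_features, timecourse_case_contrast, categorical_rdm
from .preproc import EpochSet
from .rdm import PairIndex, RDMSeries, compute_rdm_series, subset_pairs
from .stats import crawford_howell, face_specific_score, two_sample_t
from .synth import (
    GeometrySchedule,
    GeometryWindow,
    SimulationConfig,
    StimulusCatalog,
    gen_behavior,
    gen_epochs,
    gen_model_features,
    random_patterns,
)
from .tgm import TGM, compute_tgm, mean_tgm, tgm_case_contrast

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "make_synthetic_run", "run"]


@dataclass
class RunConfig:
    """Everything one end-to-end analysis needs.

    ``subjects`` maps subject id to either a :class:`SimulationConfig`
    (simulate) or a path to an epochs HDF5 file (load).  Exactly one id —
    ``patient_id`` — is treated as the patient; all others form the control
    group.  ``model_features`` maps model name to a (features, metric)
    tuple; ``partial_scheme`` maps model name to the name of the model
    whose rank variance is partialled out (or None).
    """

    catalog: StimulusCatalog
    subjects: dict
    patient_id: str
    model_features: dict = field(default_factory=dict)
    partial_scheme: dict = field(default_factory=dict)
    behavior: pd.DataFrame | None = None
    time_range: tuple[float, float] = (-200.0, 800.0)
    contrast_range: tuple[float, float] = (0.0, 800.0)
    tgm_metric: str = "pearson"
    pair_subsets: tuple = ("all", "face_face", "face_nonface", "nonface_nonface")
    alpha: float = 0.05
    n_folds: int = 5
    n_repetitions: int = 5
    include_categorical_model: bool = False
    make_figures: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.patient_id not in self.subjects:
            raise ValueError(f"patient id {self.patient_id!r} not among subjects")
        if len(self.subjects) < 3:
            raise ValueError("need the patient plus at least 2 controls")
        for name, src in self.subjects.items():
            if isinstance(src, (str, Path)) and not Path(src).exists():
                raise FileNotFoundError(f"epochs file for subject {name!r} not found: {src}")
        for m in self.partial_scheme.values():
            if m is not None and m not in self.model_features:
                raise ValueError(f"partial-out model {m!r} is not defined")

    def control_ids(self) -> list[str]:
        return [s for s in self.subjects if s != self.patient_id]

    def config_hash(self) -> str:
        """Stable hash over every parameter that shapes the outputs."""
        h = hashlib.sha256()
        desc = {
            "patient_id": self.patient_id,
            "subjects": sorted(self.subjects),
            "time_range": self.time_range,
            "contrast_range": self.contrast_range,
            "tgm_metric": self.tgm_metric,
            "pair_subsets": list(self.pair_subsets),
            "alpha": self.alpha,
            "n_folds": self.n_folds,
            "n_repetitions": self.n_repetitions,
            "seed": self.seed,
            "models": sorted(self.model_features),
            "partial_scheme": {k: v for k, v in sorted(self.partial_scheme.items())},
            "version": __version__,
        }
        h.update(json.dumps(desc, sort_keys=True).encode())
        h.update(self.catalog.to_json().encode())
        for name, (feats, metric) in sorted(self.model_features.items()):
            h.update(name.encode() + metric.encode() + np.ascontiguousarray(feats).tobytes())
        for name in sorted(self.subjects):
            src = self.subjects[name]
            if isinstance(src, SimulationConfig):
                h.update(f"{name}:sim:{src.seed}:{src.n_trials_per_stimulus}:{src.n_channels}".encode())
            else:
                h.update(f"{name}:file:{src}".encode())
        return h.hexdigest()


@dataclass
class ReportBundle:
    """In-memory results of one run plus the paths of the written artifacts."""

    rdms: dict
    tgms: dict
    group_mean_tgm: dict
    tgm_contrasts: dict
    model_timecourses: dict
    model_contrasts: dict
    behavior_stats: dict | None
    manifest: dict
    outdir: Path


def make_synthetic_run(
    n_controls: int = 8,
    n_stimuli_faces: int = 6,
    n_nonfaces: dict | None = None,
    n_trials_per_stimulus: int = 40,
    n_channels: int = 16,
    sampling_rate: float = 100.0,
    epoch_window: tuple[float, float] = (-100.0, 500.0),
    early_window: tuple[float, float] = (60.0, 160.0),
    late_window: tuple[float, float] = (160.0, 480.0),
    gain: float = 0.5,
    noise_sd: float = 1.0,
    patient_persistence_ms: float = 0.0,
    patient_late_gain: float | None = None,
    patient_face_deficit: float = 0.0,
    n_latent: int = 8,
    n_model_features: int = 48,
    seed: int = 0,
    **run_kwargs,
) -> RunConfig:
    """Build a complete synthetic case-vs-controls configuration.

    Controls share the same two-window geometry (early window driven by
    low-abstraction exemplar features, late window by high-abstraction
    category-clustered features) and differ only in trial noise.  The
    patient may add a persistence abnormality (``patient_persistence_ms``)
    and/or a weakened late window (``patient_late_gain``).
    """
    from .synth import gen_catalog

    catalog = gen_catalog(
        n_faces=n_stimuli_faces,
        n_nonfaces_per_category=n_nonfaces if n_nonfaces is not None else {"object": 3, "scene": 3},
        seed=seed,
    )
    n_stim = catalog.n_stimuli
    # models: exemplar-unique vs category-clustered feature banks, plus a
    # semantic-like embedding of intermediate abstraction
    feats_low = gen_model_features(catalog, abstraction=0.05, n_features=n_model_features, seed=seed + 11)
    feats_high = gen_model_features(catalog, abstraction=0.95, n_features=n_model_features, seed=seed + 12)
    feats_sem = gen_model_features(catalog, abstraction=0.6, n_features=n_model_features, seed=seed + 13)
    # geometry: latent patterns derived from the model features so that the
    # brain's geometry in each window matches the corresponding model RDM
    pat_early = _latent_from_features(feats_low, n_latent)
    pat_late = _latent_from_features(feats_high, n_latent)

    def schedule(persistence_ms: float, late_gain: float) -> GeometrySchedule:
        return GeometrySchedule(
            windows=[
                GeometryWindow(*early_window, pattern=pat_early, gain=gain),
                GeometryWindow(*late_window, pattern=pat_late, gain=late_gain),
            ],
            persistence_ms=persistence_ms,
            noise_sd=noise_sd,
        )

    subjects: dict = {}
    base_ss = np.random.SeedSequence([seed, 77])
    sub_seeds = base_ss.generate_state(n_controls + 1) % (2**31 - 1)
    subjects["patient"] = SimulationConfig(
        catalog=catalog,
        schedule=schedule(patient_persistence_ms, gain if patient_late_gain is None else patient_late_gain),
        n_trials_per_stimulus=n_trials_per_stimulus,
        n_channels=n_channels,
        sampling_rate=sampling_rate,
        epoch_window=epoch_window,
        seed=int(sub_seeds[0]),
    )
    for k in range(n_controls):
        subjects[f"control{k + 1:02d}"] = SimulationConfig(
            catalog=catalog,
            schedule=schedule(0.0, gain),
            n_trials_per_stimulus=n_trials_per_stimulus,
            n_channels=n_channels,
            sampling_rate=sampling_rate,
            epoch_window=epoch_window,
            seed=int(sub_seeds[k + 1]),
        )
    behavior = gen_behavior(
        n_controls=n_controls, patient_face_deficit=patient_face_deficit, seed=seed + 5
    )[: n_controls + 1]
    time_range = run_kwargs.pop("time_range", (epoch_window[0], epoch_window[1]))
    # contrast up to the end of the late window: past it the scheduled
    # geometry is fading out and cells would only measure the fade
    contrast_range = run_kwargs.pop("contrast_range", (0.0, late_window[1]))
    return RunConfig(
        catalog=catalog,
        subjects=subjects,
        patient_id="patient",
        model_features={
            "vision_low": (feats_low, "one_minus_pearson"),
            "vision_high": (feats_high, "one_minus_pearson"),
            "semantic": (feats_sem, "cosine_distance"),
        },
        partial_scheme={
            "vision_low": "semantic",
            "vision_high": "semantic",
            "semantic": "vision_high",
        },
        behavior=behavior,
        time_range=time_range,
        contrast_range=contrast_range,
        seed=seed,
        **run_kwargs,
    )


def _latent_from_features(features: np.ndarray, n_latent: int) -> np.ndarray:
    """Project a feature bank to n_latent dims (SVD), preserving its geometry."""
    F = features - features.mean(axis=0)
    U, s, _ = np.linalg.svd(F, full_matrices=False)
    k = min(n_latent, s.size)
    out = U[:, :k] * s[:k]
    # normalize overall scale so window gains are comparable across banks
    return out / np.sqrt((out**2).mean())


def _get_epochs(src, name: str) -> EpochSet:
    if isinstance(src, SimulationConfig):
        return gen_epochs(src)
    return load_epochs(src)


def _tgm_frame(values: np.ndarray, time_ms: np.ndarray) -> pd.DataFrame:
    cols = [f"t{t:.3f}" for t in time_ms]
    frame = pd.DataFrame(values, columns=cols)
    frame.insert(0, "time_ms", time_ms)
    return frame


def run(config: RunConfig, outdir) -> ReportBundle:
    """Execute the full pipeline and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sub in ("epochs", "rdm", "tgm", "models", "stats"):
        (outdir / sub).mkdir(exist_ok=True)
    (outdir / "catalog.json").write_text(config.catalog.to_json() + "\n")

    pidx = PairIndex.from_catalog(config.catalog)
    controls = config.control_ids()

    # --- stage 1-2: epochs and RDM series per subject -------------------
    rdms: dict[str, RDMSeries] = {}
    for name in sorted(config.subjects):
        src = config.subjects[name]
        epochs = _get_epochs(src, name)
        if isinstance(src, SimulationConfig):
            save_epochs(outdir / "epochs" / f"{name}.h5", epochs, seed=src.seed)
            save_config(outdir / "epochs" / f"{name}.yaml", src)
        logger.info("decoding RDM series for %s", name)
        rdms[name] = compute_rdm_series(
            epochs,
            config.catalog,
            time_range=config.time_range,
            n_folds=config.n_folds,
            n_repetitions=config.n_repetitions,
            seed=config.seed,
        )
        save_rdm_series(outdir / "rdm" / f"{name}.h5", rdms[name])
        frame = pd.DataFrame(rdms[name].values, columns=[f"p{i}_{j}" for i, j in pidx.pairs])
        frame.insert(0, "time_ms", rdms[name].time_ms)
        write_csv(outdir / "rdm" / f"{name}.csv", frame)

    # --- stage 3: TGMs, group mean, case contrast, per pair subset ------
    tgms: dict[str, dict[str, TGM]] = {name: {} for name in rdms}
    group_mean: dict[str, TGM] = {}
    contrasts: dict[str, object] = {}
    for subset in config.pair_subsets:
        for name, series in rdms.items():
            sub_series = subset_pairs(series, config.catalog, subset)
            tgms[name][subset] = compute_tgm(
                sub_series, metric=config.tgm_metric, time_range=config.contrast_range
            )
        group_mean[subset] = mean_tgm([tgms[c][subset] for c in controls])
        contrasts[subset] = tgm_case_contrast(
            tgms[config.patient_id][subset],
            [tgms[c][subset] for c in controls],
            alpha=config.alpha,
        )
        write_csv(outdir / "tgm" / f"group_mean_{subset}.csv",
                  _tgm_frame(group_mean[subset].values, group_mean[subset].time_ms))
        write_csv(outdir / "tgm" / f"patient_{subset}.csv",
                  _tgm_frame(tgms[config.patient_id][subset].values,
                             tgms[config.patient_id][subset].time_ms))
        write_csv(outdir / "tgm" / f"contrast_t_{subset}.csv",
                  _tgm_frame(contrasts[subset].t_map, contrasts[subset].time_ms))
        write_csv(outdir / "tgm" / f"contrast_p_{subset}.csv",
                  _tgm_frame(contrasts[subset].p_map, contrasts[subset].time_ms))

    # --- stage 4: model comparisons -------------------------------------
    model_rdms: dict[str, ModelRDM] = {
        name: rdm_from_features(feats, metric=metric, pair_index=pidx, name=name)
        for name, (feats, metric) in config.model_features.items()
    }
    if config.include_categorical_model:
        model_rdms["categorical"] = categorical_rdm(
            config.catalog, ["category"], encoding="onehot", pair_index=pidx
        )
    timecourses: dict[str, dict[str, object]] = {}
    model_contrasts: dict[str, dict] = {}
    for mname, mrdm in model_rdms.items():
        ctrl_name = config.partial_scheme.get(mname)
        ctrl_rdm = model_rdms.get(ctrl_name) if ctrl_name else None
        percourse = {
            name: model_timecourse(rdms[name], mrdm, partial_out=ctrl_rdm, subject=name)
            for name in rdms
        }
        timecourses[mname] = percourse
        model_contrasts[mname] = timecourse_case_contrast(
            percourse[config.patient_id], [percourse[c] for c in controls], alpha=config.alpha
        )
        frame = pd.DataFrame({"time_ms": percourse[config.patient_id].time_ms})
        for name in sorted(percourse):
            frame[f"rho_{name}"] = percourse[name].rho
        frame["contrast_t"] = model_contrasts[mname]["t"]
        frame["contrast_p"] = model_contrasts[mname]["p"]
        write_csv(outdir / "models" / f"timecourse_{mname}.csv", frame)

    # --- stage 5: behavioral statistics ---------------------------------
    behavior_stats = None
    if config.behavior is not None:
        behavior_stats = _behavior_stats(config.behavior, config.patient_id)
        write_csv(outdir / "stats" / "behavior.csv", config.behavior)
        write_json(outdir / "stats" / "behavior_stats.json", behavior_stats)

    if config.make_figures:
        _write_figures(outdir, group_mean, tgms[config.patient_id], contrasts, timecourses,
                       controls, config)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "package": "eegrsa",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "patient_id": config.patient_id,
        "n_controls": len(controls),
        "files": _checksums(outdir),
    }
    write_json(outdir / "manifest.json", manifest)
    return ReportBundle(
        rdms=rdms,
        tgms=tgms,
        group_mean_tgm=group_mean,
        tgm_contrasts=contrasts,
        model_timecourses=timecourses,
        model_contrasts=model_contrasts,
        behavior_stats=behavior_stats,
        manifest=manifest,
        outdir=outdir,
    )


def _behavior_stats(behavior: pd.DataFrame, patient_id: str) -> dict:
    is_patient = behavior["participant_id"] == patient_id
    if is_patient.sum() != 1:
        raise ValueError("behavior table must contain exactly one patient row")
    score = face_specific_score(
        behavior["face_acc"], behavior["nonface_acc"], behavior["face_rt"], behavior["nonface_rt"]
    )
    p_mask = is_patient.to_numpy()
    ch_face = crawford_howell(score.pc_scores[p_mask][0], score.pc_scores[~p_mask])
    out = {
        "face_score_variance_explained": score.variance_explained,
        "face_score": {
            "t": ch_face.t, "df": ch_face.df, "p": ch_face.p,
            "case_value": ch_face.case_value,
            "control_mean": ch_face.control_mean, "control_sd": ch_face.control_sd,
        },
    }
    if "cfmt_score" in behavior:
        ch_cfmt = crawford_howell(
            behavior.loc[p_mask, "cfmt_score"].iloc[0], behavior.loc[~p_mask, "cfmt_score"]
        )
        out["cfmt"] = {"t": ch_cfmt.t, "df": ch_cfmt.df, "p": ch_cfmt.p}
    groups = behavior.loc[~p_mask, "group"]
    if groups.nunique() == 2 and groups.value_counts().min() >= 2:
        g1, g2 = sorted(groups.unique())
        sub = {}
        for col in ("face_acc", "nonface_acc", "cfmt_score"):
            if col in behavior:
                t, df, p = two_sample_t(
                    behavior.loc[~p_mask][groups == g1][col],
                    behavior.loc[~p_mask][groups == g2][col],
                )
                sub[col] = {"t": t, "df": df, "p": p}
        out["subgroup_contrasts"] = sub
    return out


def _checksums(outdir: Path) -> dict:
    files = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json" and path.suffix != ".png":
            files[str(path.relative_to(outdir))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return files


def _write_figures(outdir, group_mean, patient_tgms, contrasts, timecourses, controls, config):
    """Advisory heatmaps and rho(t) curves (layout: mean / patient / contrast)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    (outdir / "figures").mkdir(exist_ok=True)
    for subset, gm in group_mean.items():
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), constrained_layout=True)
        extent = [gm.time_ms[0], gm.time_ms[-1], gm.time_ms[0], gm.time_ms[-1]]
        for ax, (title, vals) in zip(
            axes,
            [("controls (mean)", gm.values),
             ("patient", patient_tgms[subset].values),
             ("patient - controls (t)", contrasts[subset].t_map)],
        ):
            im = ax.imshow(vals, origin="lower", extent=extent, aspect="auto")
            ax.set_title(title)
            ax.set_xlabel("time (ms)")
            fig.colorbar(im, ax=ax, shrink=0.8)
        axes[2].contour(gm.time_ms, gm.time_ms, contrasts[subset].mask.astype(float),
                        levels=[0.5], colors="k", linewidths=1.0)
        axes[0].set_ylabel("time (ms)")
        fig.suptitle(f"temporal generalization — {subset} pairs")
        fig.savefig(outdir / "figures" / f"tgm_{subset}.png", dpi=110)
        plt.close(fig)
    for mname, percourse in timecourses.items():
        fig, ax = plt.subplots(figsize=(6, 3.2), constrained_layout=True)
        ctrl = np.stack([percourse[c].rho for c in controls])
        t = percourse[config.patient_id].time_ms
        mean, se = ctrl.mean(0), ctrl.std(0, ddof=1) / np.sqrt(len(controls))
        ax.fill_between(t, mean - se, mean + se, alpha=0.3, color="gray", label="controls ±SE")
        ax.plot(t, mean, color="gray")
        ax.plot(t, percourse[config.patient_id].rho, color="crimson", label="patient")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("partial Spearman rho")
        ax.set_title(mname)
        ax.legend(frameon=False)
        fig.savefig(outdir / "figures" / f"timecourse_{mname}.png", dpi=110)
        plt.close(fig)
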