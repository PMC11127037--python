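"""Synthetic catalog, epochs, model features and behavior generators."""

import numpy as np
import pytest

from conftest import two_window_config
from eegrsa.models import categorical_rdm, spearman_rdm
from eegrsa.rdm import decode_pair_timecourse
from eegrsa.stats import crawford_howell, face_specific_score
from eegrsa.synth import (
    GeometrySchedule,
    GeometryWindow,
    SimulationConfig,
    expected_topographies,
    gen_behavior,
    gen_catalog,
    gen_epochs,
    gen_model_features,
    random_patterns,
)


class TestCatalog:
    def test_default_is_49_stimuli_24_faces(self, default_catalog):
        assert default_catalog.n_stimuli == 49
        assert int(default_catalog.is_face.sum()) == 24
        faces = default_catalog.table[default_catalog.is_face]
        assert faces["face_identity"].nunique() == 8
        assert set(faces["face_expression"]) == {"neutral", "happy", "fearful"}
        female = faces[faces["face_gender"] == "female"]
        assert female["face_identity"].nunique() == 4

    def test_degenerate_no_face_catalog(self):
        cat = gen_catalog(n_faces=0, n_nonfaces_per_category={"object": 2})
        assert cat.n_stimuli == 2 and not cat.is_face.any()

    def test_face_fields_present_iff_face(self):
        cat = gen_catalog(n_faces=6, n_nonfaces_per_category={"scene": 2})
        assert cat.n_stimuli == 8
        t = cat.table
        faces = t[t.category == "face"]
        assert faces["face_identity"].notna().all()
        assert faces["face_expression"].notna().all()
        nonfaces = t[t.category != "face"]
        assert nonfaces["face_identity"].isna().all()
        assert nonfaces["face_gender"].isna().all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            gen_catalog(n_faces=7)  # not divisible by 3 expressions
        with pytest.raises(ValueError):
            gen_catalog(n_faces=0, n_nonfaces_per_category={"object": -1})
        with pytest.raises(ValueError):
            gen_catalog(n_faces=0, n_nonfaces_per_category={"faces": 2})

    def test_json_roundtrip(self, tiny_catalog):
        from eegrsa.synth import StimulusCatalog

        back = StimulusCatalog.from_json(tiny_catalog.to_json())
        assert back.table["category"].tolist() == tiny_catalog.table["category"].tolist()


class TestEpochGeneration:
    def test_bit_reproducible(self, tiny_catalog):
        a = gen_epochs(two_window_config(tiny_catalog, seed=5))
        b = gen_epochs(two_window_config(tiny_catalog, seed=5))
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.labels, b.labels)
        c = gen_epochs(two_window_config(tiny_catalog, seed=6))
        assert not np.array_equal(a.data, c.data)

    def test_noiseless_distinct_patterns_decode_perfectly(self, tiny_catalog):
        cfg = two_window_config(tiny_catalog, seed=1, noise_sd=1e-12, n_trials=10)
        ep = gen_epochs(cfg)
        auc = decode_pair_timecourse(ep, 0, 1, seed=0)
        in_window = (ep.time_ms >= 90) & (ep.time_ms <= 150)
        assert np.all(auc[in_window] == 1.0)

    def test_zero_gain_gives_chance_decoding(self, noise_epochs):
        aucs = [decode_pair_timecourse(noise_epochs, i, j, seed=0)
                for i, j in [(0, 1), (2, 5), (3, 7)]]
        per_time = np.stack(aucs).mean(axis=0)
        se = per_time.std(ddof=1) / np.sqrt(per_time.size)
        assert abs(per_time.mean() - 0.5) < 3 * max(se, 1e-3)

    def test_repeats_flagged_and_follow_their_base_trial(self, tiny_catalog):
        cfg = two_window_config(tiny_catalog, seed=2)
        ep = gen_epochs(cfg)
        idx = np.flatnonzero(ep.repeat_flag)
        assert idx.size > 0
        np.testing.assert_array_equal(ep.labels[idx], ep.labels[idx - 1])

    def test_window_outside_epoch_rejected(self, tiny_catalog):
        p = random_patterns(tiny_catalog.n_stimuli, 3, seed=0)
        sched = GeometrySchedule(windows=[GeometryWindow(500.0, 900.0, p)])
        with pytest.raises(ValueError, match="outside epoch"):
            SimulationConfig(catalog=tiny_catalog, schedule=sched,
                             epoch_window=(-100.0, 600.0), n_channels=8)

    def test_geometry_survives_channel_mixing(self, tiny_catalog):
        """Sensor-space distances inside a window reproduce the latent
        pattern distances (orthonormal mixing preserves geometry)."""
        from scipy.spatial.distance import pdist

        cfg = two_window_config(tiny_catalog, seed=3)
        topo = expected_topographies(cfg)
        t_idx = np.argmin(np.abs(cfg.time_axis() - 120.0))  # mid early window
        sensor_rdm = pdist(topo[:, :, t_idx])
        latent_rdm = pdist(cfg.schedule.windows[0].pattern)
        assert spearman_rdm(sensor_rdm, latent_rdm) > 0.99


class TestModelFeatures:
    def test_full_abstraction_clusters_categories(self, default_catalog):
        from eegrsa.models import rdm_from_features

        F = gen_model_features(default_catalog, abstraction=0.95, n_features=64, seed=0)
        rdm = rdm_from_features(F, metric="one_minus_pearson")
        cats = default_catalog.table["category"].to_numpy()
        pairs = rdm.pair_index.pairs
        same = cats[pairs[:, 0]] == cats[pairs[:, 1]]
        assert rdm.values[same].mean() < 0.25 * rdm.values[~same].mean()

    def test_zero_abstraction_uncorrelated_with_categorical_model(self, default_catalog):
        from eegrsa.models import rdm_from_features

        multihot = categorical_rdm(default_catalog, ["category", "face_gender"], "multihot")
        rhos = []
        for seed in range(50):
            F = gen_model_features(default_catalog, abstraction=0.0, n_features=64, seed=seed)
            rdm = rdm_from_features(F, metric="one_minus_pearson")
            rhos.append(spearman_rdm(rdm.values, multihot.values))
        rhos = np.abs(rhos)
        assert rhos.mean() < 0.1
        assert np.all(rhos < 0.15)

    def test_feature_matrix_shape(self, default_catalog):
        F = gen_model_features(default_catalog, abstraction=0.5, n_features=512, seed=1)
        assert F.shape == (49, 512)

    def test_abstraction_bounds_validated(self, tiny_catalog):
        with pytest.raises(ValueError):
            gen_model_features(tiny_catalog, abstraction=1.5, n_features=8)


class TestBehavior:
    def test_table_structure_and_df(self):
        tab = gen_behavior(n_controls=18, seed=0)
        assert len(tab) == 19
        assert tab.loc[0, "participant_id"] == "patient"
        assert (tab["group"] == "control_matched").sum() == 4
        assert (tab["group"] == "control_young").sum() == 14
        score = face_specific_score(tab.face_acc, tab.nonface_acc, tab.face_rt, tab.nonface_rt)
        r = crawford_howell(score.pc_scores[0], score.pc_scores[1:])
        assert r.df == 17

    def test_null_patient_type_one_error_calibrated(self):
        """With no deficit, the Crawford-Howell test on the PCA face score
        should reject at roughly its nominal 5% rate across datasets."""
        hits = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            tab = gen_behavior(n_controls=18, patient_face_deficit=0.0, seed=seed)
            score = face_specific_score(tab.face_acc, tab.nonface_acc,
                                        tab.face_rt, tab.nonface_rt)
            r = crawford_howell(score.pc_scores[0], score.pc_scores[1:])
            hits += r.p < 0.05
        assert 0.025 <= hits / n_seeds <= 0.085

    def test_large_deficit_detected_with_high_power(self):
        sig = 0
        n_seeds = 200
        for seed in range(n_seeds):
            tab = gen_behavior(n_controls=18, patient_face_deficit=-8.0, seed=seed)
            score = face_specific_score(tab.face_acc, tab.nonface_acc,
                                        tab.face_rt, tab.nonface_rt)
            r = crawford_howell(score.pc_scores[0], score.pc_scores[1:])
            sig += (r.p < 0.05) and (r.t < 0)
        assert sig / n_seeds > 0.99


class TestPersistence:
    def test_persistence_raises_early_late_generalization(self, tiny_catalog):
        """At matched seeds, a persistence abnormality strictly increases the
        mean correlation between early-window and late-window RDMs."""
        from eegrsa.rdm import compute_rdm_series
        from eegrsa.tgm import compute_tgm

        for seed in (0, 1):
            vals = {}
            for pers in (0.0, 250.0):
                cfg = two_window_config(tiny_catalog, seed=seed, persistence_ms=pers,
                                        early=(60.0, 160.0), late=(160.0, 480.0))
                series = compute_rdm_series(gen_epochs(cfg), tiny_catalog,
                                            time_range=(-100.0, 500.0), seed=0)
                tg = compute_tgm(series, time_range=(0.0, 480.0))
                early = (tg.time_ms >= 60) & (tg.time_ms <= 160)
                late = tg.time_ms > 200
                vals[pers] = np.nanmean(tg.values[np.ix_(early, late)])
            assert vals[250.0] > vals[0.0]
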