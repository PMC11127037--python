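"""Model RDM construction and (partial) Spearman brain-model comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import partial_spearman_residualization
from eegrsa.models import (
    categorical_rdm,
    model_timecourse,
    partial_spearman_rdm,
    rdm_from_features,
    spearman_rdm,
    timecourse_case_contrast,
)
from eegrsa.rdm import PairIndex, RDMSeries
from eegrsa.synth import gen_catalog


class TestRDMFromFeatures:
    def test_identical_rows_have_zero_dissimilarity(self):
        F = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [0.0, 5.0, 1.0]])
        rdm = rdm_from_features(F, metric="one_minus_pearson")
        assert rdm.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_reach_two(self):
        F = np.array([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0], [0.5, 1.0, 2.0]])
        rdm = rdm_from_features(F, metric="one_minus_pearson")
        assert rdm.values[0] == pytest.approx(2.0, abs=1e-12)

    def test_hand_computed_cosine_toy(self):
        F = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        rdm = rdm_from_features(F, metric="cosine_distance")
        np.testing.assert_allclose(
            rdm.values, [1.0, 1 - 1 / np.sqrt(2), 1 - 1 / np.sqrt(2)], atol=1e-12
        )

    def test_constant_row_error_names_stimulus(self):
        F = np.array([[1.0, 2.0], [3.0, 3.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            rdm_from_features(F, metric="one_minus_pearson")

    def test_pair_index_size_checked(self):
        with pytest.raises(ValueError):
            rdm_from_features(np.eye(3), metric="cosine_distance",
                              pair_index=PairIndex.from_n(4))


class TestCategoricalRDM:
    def test_onehot_category_has_two_levels(self, default_catalog):
        rdm = categorical_rdm(default_catalog, ["category"], encoding="onehot")
        assert len(np.unique(np.round(rdm.values, 12))) == 2
        # same category -> 0; different -> sqrt(2) for one-of-k codes
        assert rdm.values.min() == 0.0
        assert rdm.values.max() == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_face_nonface_structure(self):
        cat = gen_catalog(n_faces=3, n_nonfaces_per_category={"object": 2})
        rdm = categorical_rdm(cat, ["animacy"], encoding="onehot")
        pidx = rdm.pair_index
        assert rdm.values[pidx.position(0, 1)] == 0.0  # face-face
        assert rdm.values[pidx.position(0, 3)] > 0.0  # face-object

    def test_multihot_gender_separates_faces(self, default_catalog):
        rdm = categorical_rdm(default_catalog, ["category", "face_gender"], "multihot")
        pidx = rdm.pair_index
        faces = default_catalog.table[default_catalog.is_face]
        female = faces[faces.face_gender == "female"].stimulus_id.to_numpy()
        male = faces[faces.face_gender == "male"].stimulus_id.to_numpy()
        same = rdm.values[pidx.position(int(female[0]), int(female[1]))]
        cross = rdm.values[pidx.position(int(female[0]), int(male[0]))]
        assert cross > same

    def test_unknown_dimension_rejected(self, default_catalog):
        with pytest.raises(ValueError, match="unknown"):
            categorical_rdm(default_catalog, ["hairstyle"])


class TestSpearman:
    def test_perfect_and_reversed(self):
        a = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        assert spearman_rdm(a, a) == pytest.approx(1.0)
        assert spearman_rdm(a, -a) == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        assert spearman_rdm([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_constant_input_flagged_nan(self):
        assert np.isnan(spearman_rdm([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_agrees_with_scipy(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert spearman_rdm(a, b) == pytest.approx(spearmanr(a, b).statistic, abs=1e-12)


class TestPartialSpearman:
    def test_constant_control_reduces_to_plain_spearman(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(size=12)
        assert partial_spearman_rdm(a, b, np.ones(12)) == pytest.approx(
            spearman_rdm(a, b), abs=1e-12
        )

    def test_control_identical_to_b_leaves_nothing_to_explain(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert partial_spearman_rdm(a, b, b) == pytest.approx(0.0, abs=1e-8)

    def test_control_rank_opposite_to_a_also_leaves_nothing(self):
        # |r_ac| = 1 in ranks: a is fully explained by the control
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert partial_spearman_rdm(a, b, -a) == pytest.approx(0.0, abs=1e-8)

    def test_fixed_six_element_oracle(self):
        a = np.array([0.1, 0.9, 0.4, 0.7, 0.2, 0.6])
        b = np.array([1.0, 3.0, 2.0, 5.0, 0.5, 4.0])
        c = np.array([0.3, 0.8, 0.2, 0.9, 0.1, 0.5])
        assert partial_spearman_rdm(a, b, c) == pytest.approx(
            partial_spearman_residualization(a, b, c), abs=1e-12
        )

    @given(st.integers(0, 500))
    def test_formula_equals_residualization_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=(3, 15))
        ours = partial_spearman_rdm(a, b, c)
        oracle = partial_spearman_residualization(a, b, c)
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        a, b, c = rng.normal(size=(3, 40))
        df = pd.DataFrame({"a": a, "b": b, "c": c})
        ref = pingouin.partial_corr(df, x="a", y="b", covar="c", method="spearman")
        assert partial_spearman_rdm(a, b, c) == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)

    def test_uncorrelated_control_barely_changes_rho(self):
        rng = np.random.default_rng(4)
        n = 2000  # large n: rank correlation with the control -> 0
        a = rng.normal(size=n)
        b = a + rng.normal(size=n)
        c = rng.normal(size=n)
        assert partial_spearman_rdm(a, b, c) == pytest.approx(spearman_rdm(a, b), abs=0.01)


class TestModelTimecourse:
    def _brain(self, model_values, n_times=5, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.tile(model_values, (n_times, 1)) + noise * rng.normal(
            size=(n_times, model_values.size)
        )
        n = int((1 + np.sqrt(1 + 8 * model_values.size)) / 2)
        return RDMSeries(values=vals, time_ms=np.arange(n_times, dtype=float),
                         pair_index=PairIndex.from_n(n))

    def test_model_equal_to_brain_gives_unit_rho(self):
        rng = np.random.default_rng(5)
        mv = rng.uniform(0.2, 0.9, size=15)
        brain = self._brain(mv)
        from eegrsa.models import ModelRDM

        model = ModelRDM(values=mv, pair_index=brain.pair_index,
                         metric="one_minus_pearson", name="m")
        tc = model_timecourse(brain, model)
        np.testing.assert_allclose(tc.rho, 1.0, atol=1e-12)

    def test_noise_brain_rho_near_zero(self):
        rng = np.random.default_rng(6)
        mv = rng.uniform(0.2, 0.9, size=45)
        brain = self._brain(np.full(45, 0.5), n_times=60, noise=0.1, seed=7)
        from eegrsa.models import ModelRDM

        model = ModelRDM(values=mv, pair_index=brain.pair_index,
                         metric="one_minus_pearson", name="m")
        tc = model_timecourse(brain, model)
        se = tc.rho.std(ddof=1) / np.sqrt(tc.rho.size)
        assert abs(tc.rho.mean()) < 3 * se + 1e-3

    def test_misaligned_pair_index_rejected(self):
        rng = np.random.default_rng(8)
        brain = self._brain(rng.uniform(size=15))
        from eegrsa.models import ModelRDM

        model = ModelRDM(values=rng.uniform(size=15),
                         pair_index=PairIndex(tuple(range(2, 8))),
                         metric="one_minus_pearson", name="m")
        with pytest.raises(ValueError, match="PairIndex"):
            model_timecourse(brain, model)


class TestTimecourseContrast:
    def test_patient_at_control_mean_is_null(self):
        rng = np.random.default_rng(9)
        from eegrsa.models import TimecourseResult

        t = np.arange(20.0)
        ctrl = [TimecourseResult(rho=0.4 + 0.05 * rng.normal(size=20), time_ms=t, model="m")
                for _ in range(10)]
        patient = TimecourseResult(
            rho=np.mean([c.rho for c in ctrl], axis=0), time_ms=t, model="m"
        )
        con = timecourse_case_contrast(patient, ctrl)
        assert np.nanmax(np.abs(con["t"])) < 1e-8
        assert not con["mask"].any()
        assert con["df"] == 9

    def test_mismatched_model_rejected(self):
        from eegrsa.models import TimecourseResult

        t = np.arange(5.0)
        patient = TimecourseResult(rho=np.zeros(5), time_ms=t, model="a")
        ctrl = [TimecourseResult(rho=np.zeros(5), time_ms=t, model="b")] * 3
        with pytest.raises(ValueError):
            timecourse_case_contrast(patient, ctrl)
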