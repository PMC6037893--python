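"""Feature assembly, OOB random forest, VIMP and group statistics."""

import numpy as np
import pytest

from qeeg.classify import bonferroni, compare_groups, random_forest_oob
from qeeg.features import FEATURE_NAMES, FeatureVector, build_feature_vector, features_to_frame, frame_to_features


def _noise_cohort(rng, n, label, shift=None):
    """Feature vectors drawn i.i.d. standard normal, optional mean shift."""
    out = []
    for k in range(n):
        v = rng.standard_normal(25)
        if shift is not None:
            v = v + shift
        out.append(FeatureVector(v, subject_id=f"{label}{k}", group_label=label))
    return out


class TestFeatureVector:
    def test_table_order_landmarks(self):
        assert len(FEATURE_NAMES) == 25
        assert FEATURE_NAMES[18] == "theta/alpha ratio"        # position 19
        assert FEATURE_NAMES[22] == "highest degree"           # position 23
        assert FEATURE_NAMES[23] == "leaf number"              # position 24
        assert FEATURE_NAMES[24] == "tree hierarchy"           # position 25
        assert FEATURE_NAMES[0] == "lowest delta power"
        assert FEATURE_NAMES[15] == "lowest peak frequency"
        assert FEATURE_NAMES[19] == "lowest PLI"

    def test_built_from_pipeline_blocks(self):
        from qeeg.pipeline import subject_features
        from qeeg.synthetic import SubjectSpec, generate_subject

        rec = generate_subject(SubjectSpec(seed=8), "s8")
        fv, sp, conn, tree = subject_features(rec)
        assert fv.values.shape == (25,)
        powers = fv.values[:15]
        assert np.all((powers >= 0) & (powers <= 1))
        plis = fv.values[19:22]
        assert np.all((plis >= 0) & (plis <= 1))
        assert fv["highest degree"] == pytest.approx(tree.metrics["degree_max_norm"])

    def test_identical_channels_collapse_reductions(self):
        """With every channel identical, lowest = mean = highest."""
        from qeeg.connectivity import pli_matrix
        from qeeg.network import spanning_tree
        from qeeg.spectral import spectral_summary
        from qeeg.preprocess import extract_epochs
        from qeeg.recording import EEGRecording
        from qeeg.synthetic import SubjectSpec, generate_subject

        one = generate_subject(SubjectSpec(n_channels=1, seed=2))
        samples = np.tile(one.samples, (4, 1))
        rec = EEGRecording(samples, one.fs, ["a", "b", "c", "d"], "x")
        es = extract_epochs(rec)
        fv = build_feature_vector(spectral_summary(es), pli_matrix(es),
                                  spanning_tree(pli_matrix(es)))
        for base in range(0, 15, 3):
            assert fv.values[base] == pytest.approx(fv.values[base + 2], abs=1e-12)
        assert fv.values[15] == pytest.approx(fv.values[17], abs=1e-12)

    def test_missing_component_listed(self):
        with pytest.raises(ValueError, match="spanning tree"):
            build_feature_vector(None, None, None)

    def test_frame_roundtrip(self, rng):
        feats = _noise_cohort(rng, 3, "g")
        df = features_to_frame(feats)
        assert list(df.columns[2:]) == list(FEATURE_NAMES)
        back = frame_to_features(df)
        np.testing.assert_allclose(back[1].values, feats[1].values)


class TestRandomForestOob:
    def test_separable_contrast_has_high_accuracy_and_right_vimp(self):
        """Two cohorts separated by >= 3 SD in the theta/alpha ratio only:
        OOB accuracy >= 0.9 and that feature tops the VIMP ranking."""
        rng = np.random.Generator(np.random.PCG64(1))
        shift = np.zeros(25)
        shift[18] = 3.0
        a = _noise_cohort(rng, 20, "a")
        b = _noise_cohort(rng, 20, "b", shift=shift)
        report = random_forest_oob(a + b, n_tree=500, m_try=5, seed=1)
        assert report.accuracy >= 0.9
        assert max(report.vimp, key=report.vimp.get) == "theta/alpha ratio"

    def test_exchangeable_cohorts_stay_near_chance(self):
        rng = np.random.Generator(np.random.PCG64(2))
        a = _noise_cohort(rng, 20, "a")
        b = _noise_cohort(rng, 20, "b")
        report = random_forest_oob(a + b, n_tree=500, m_try=5, seed=2)
        assert report.accuracy == pytest.approx(0.5, abs=0.15)

    def test_deterministic_given_seed(self, rng):
        feats = _noise_cohort(rng, 12, "a") + _noise_cohort(rng, 12, "b")
        r1 = random_forest_oob(feats, n_tree=50, seed=7)
        r2 = random_forest_oob(feats, n_tree=50, seed=7)
        assert r1.accuracy == r2.accuracy
        assert r1.oob_predictions == r2.oob_predictions
        assert r1.vimp == r2.vimp

    def test_every_subject_receives_oob_votes(self, rng):
        feats = _noise_cohort(rng, 30, "a") + _noise_cohort(rng, 30, "b")
        report = random_forest_oob(feats, n_tree=500, seed=3)
        assert report.never_oob == []
        assert len(report.oob_predictions) == 60

    def test_noise_feature_vimp_below_signal_feature(self):
        """Across seeds, a pure-noise feature never out-ranks the feature
        that carries the group separation (averaged comparison)."""
        deltas = []
        for seed in range(5):
            rng = np.random.Generator(np.random.PCG64(100 + seed))
            shift = np.zeros(25)
            shift[18] = 3.0
            feats = _noise_cohort(rng, 15, "a") + _noise_cohort(rng, 15, "b", shift)
            rep = random_forest_oob(feats, n_tree=200, seed=seed)
            deltas.append(rep.vimp["theta/alpha ratio"] - rep.vimp["lowest delta power"])
        assert np.mean(deltas) > 0

    def test_sensitivity_specificity_positive_label(self, rng):
        shift = np.zeros(25)
        shift[0] = 5.0
        feats = _noise_cohort(rng, 10, "dlb", shift) + _noise_cohort(rng, 10, "ad")
        rep = random_forest_oob(feats, n_tree=200, seed=4, positive_label="dlb")
        assert rep.positive_label == "dlb"
        assert 0 <= rep.sensitivity <= 1 and 0 <= rep.specificity <= 1

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            random_forest_oob(_noise_cohort(rng, 10, "a"), seed=0)

    def test_tiny_class_rejected(self, rng):
        feats = _noise_cohort(rng, 3, "a") + _noise_cohort(rng, 10, "b")
        with pytest.raises(ValueError, match="5 subjects"):
            random_forest_oob(feats, seed=0)


class TestOobFraction:
    def test_oob_probability_matches_bootstrap_theory(self):
        """With a size-ceil(2n/3) bootstrap with replacement, the chance a
        subject is out-of-bag per tree is (1 - 1/n)^ceil(2n/3)."""
        import math

        n, n_tree = 30, 400
        rng = np.random.Generator(np.random.PCG64(0))
        boot = math.ceil(2 * n / 3)
        oob_counts = np.zeros(n)
        for _ in range(n_tree):
            idx = rng.integers(0, n, boot)
            oob_counts[np.setdiff1d(np.arange(n), idx)] += 1
        expected = (1 - 1 / n) ** boot
        assert oob_counts.mean() / n_tree == pytest.approx(expected, rel=0.05)


class TestCompareGroups:
    def test_identical_groups_give_f_zero_p_one(self):
        g = {"a": np.ones(5), "b": np.ones(5), "c": np.ones(5)}
        out = compare_groups(g)
        assert out["anova"]["F"] == 0.0
        assert out["anova"]["p"] == 1.0

    def test_large_offset_detected_by_both_methods(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 10.0
        out = compare_groups({"a": a, "b": b})
        assert out["anova"]["p"] < 1e-6
        assert out["kruskal"]["p"] < 1e-6

    def test_bonferroni_multiplication(self):
        assert bonferroni([0.02, 0.5, 0.9]) == [pytest.approx(0.06), 1.0, 1.0]

    def test_posthoc_capped_at_one(self, rng):
        g = {k: rng.standard_normal(10) for k in "abc"}
        out = compare_groups(g)
        assert all(0 <= p <= 1 for p in out["posthoc_bonferroni"].values())
        assert len(out["posthoc_bonferroni"]) == 3

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})

    def test_null_p_values_approximately_uniform(self):
        """ANOVA p-values under exchangeability are ~Uniform(0,1)
        (Kolmogorov-Smirnov check over simulated datasets)."""
        from scipy import stats as ss

        rng = np.random.Generator(np.random.PCG64(3))
        pvals = [compare_groups({"a": rng.standard_normal(10),
                                 "b": rng.standard_normal(10)})["anova"]["p"]
                 for _ in range(1000)]
        d, _ = ss.kstest(pvals, "uniform")
        assert d < 0.05
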