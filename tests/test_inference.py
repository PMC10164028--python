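import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

import meddecode as md
from meddecode.util import ConfigurationError, ValidationError

from conftest import make_tiny_dataset


class TestPermutationTest:
    def test_separable_data_minimal_p(self):
        # 16 subjects, one perfectly separating feature: no global label
        # shuffle can reproduce accuracy 1.0, so the add-one p is 1/(n+1)
        ds = make_tiny_dataset(n_subjects=16, separation=6.0, seed=0)
        cfg = md.CVConfig(n_repetitions=10, k_features=1, seed=0)
        res = md.permutation_test(ds, cfg, n_perm=200, scheme="global")
        assert res.observed == 1.0
        assert res.p_value == pytest.approx(1 / 201)

    def test_ratio_convention_observed_below_null(self):
        ds = make_tiny_dataset(n_subjects=8, separation=0.0, seed=1)
        cfg = md.CVConfig(n_repetitions=5, k_features=2, seed=0)
        res = md.permutation_test(ds, cfg, n_perm=10, correction="ratio",
                                  observed=0.0)
        assert res.p_value == 1.0

    def test_within_subject_scheme_preserves_balance(self):
        ds = make_tiny_dataset(n_subjects=6, seed=2)
        rng = np.random.default_rng(0)
        y = md.inference.shuffle_labels(ds, rng, "within_subject")
        for s in np.unique(ds.subject):
            idx = ds.subject == s
            assert sorted(y[idx]) == sorted(ds.y[idx])

    def test_p_monotone_in_observed(self):
        ds = make_tiny_dataset(n_subjects=8, separation=0.0, seed=3)
        cfg = md.CVConfig(n_repetitions=5, k_features=2, seed=0)
        res_low = md.permutation_test(ds, cfg, n_perm=20, observed=0.4)
        res_high = md.permutation_test(ds, cfg, n_perm=20, observed=0.9)
        assert res_high.p_value <= res_low.p_value
        np.testing.assert_array_equal(res_low.null_accuracies,
                                      res_high.null_accuracies)

    def test_invalid_n_perm(self):
        ds = make_tiny_dataset()
        with pytest.raises(ConfigurationError):
            md.permutation_test(ds, md.CVConfig(seed=0), n_perm=0)


class TestBonferroni:
    def test_examples(self):
        np.testing.assert_allclose(md.bonferroni([0.005], 2), [0.01])
        np.testing.assert_allclose(md.bonferroni([0.7], 2), [1.0])
        np.testing.assert_allclose(md.bonferroni([0.2, 0.04], 2), [0.4, 0.08])

    def test_m_one_identity(self):
        p = [0.01, 0.5, 0.99]
        np.testing.assert_allclose(md.bonferroni(p[:1], 1), p[:1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(0, 1), m1=st.integers(1, 20), m2=st.integers(1, 20))
    def test_monotone_in_family_size(self, p, m1, m2):
        lo, hi = sorted((m1, m2))
        assert md.bonferroni([p], lo)[0] <= md.bonferroni([p], hi)[0]


def exact_mw_p(a, b, alternative="two-sided"):
    """Enumeration oracle: U statistic over all C(n1+n2, n1) labelings."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    combined = a + b

    def u_stat(x, y):
        return sum(0.5 if xi == yi else float(xi > yi)
                   for xi in x for yi in y)

    obs = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(n1 + n2), n1):
        sel = set(idx)
        xa = [combined[i] for i in sel]
        xb = [combined[i] for i in range(n1 + n2) if i not in sel]
        us.append(u_stat(xa, xb))
    us = np.array(us)
    mean_u = n1 * n2 / 2
    if alternative == "two-sided":
        p = np.mean(np.abs(us - mean_u) >= abs(obs - mean_u) - 1e-12)
    elif alternative == "greater":
        p = np.mean(us >= obs - 1e-12)
    else:
        p = np.mean(us <= obs + 1e-12)
    return obs, float(p)


class TestMannWhitney:
    def test_small_sample_exact_example(self):
        res = md.mann_whitney([1, 2], [3, 4])
        assert res.U == 0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        res = md.mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=7), rng.normal(size=9)
        assert md.mann_whitney(a, b).U + md.mann_whitney(b, a).U == 7 * 9

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(1)
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (5, 5)]:
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            obs_u, obs_p = exact_mw_p(a, b, alternative)
            res = md.mann_whitney(a, b, alternative=alternative)
            assert res.U == pytest.approx(obs_u)
            assert res.p_value == pytest.approx(obs_p, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            md.mann_whitney([], [1.0])


class TestBayesianCorrelatedTTest:
    def test_symmetric_posterior_half(self):
        res = md.bayesian_correlated_ttest([0.4, 0.6, 0.45, 0.55], 0.5)
        assert res.p_greater == pytest.approx(0.5)

    def test_constant_positive_difference(self):
        res = md.bayesian_correlated_ttest([0.7, 0.7, 0.7], 0.5)
        assert res.degenerate and res.p_greater == 1.0

    def test_degenerate_zero(self):
        res = md.bayesian_correlated_ttest([0.5, 0.5], 0.5)
        assert res.degenerate and res.p_greater == 0.5

    def test_posterior_matches_quadrature(self):
        acc = np.array([0.6, 0.7, 0.65, 0.8, 0.55])
        rho = 0.25
        res = md.bayesian_correlated_ttest(acc, 0.5, rho=rho)
        d = acc - 0.5
        scale = np.sqrt(d.var(ddof=1) * (1 / d.size + rho / (1 - rho)))
        val, _ = quad(lambda x: stats.t.pdf(x, d.size - 1, loc=d.mean(),
                                            scale=scale), 0, np.inf)
        assert res.p_greater == pytest.approx(val, abs=1e-6)

    def test_rope_masses_sum_to_one(self):
        res = md.bayesian_correlated_ttest([0.6, 0.7, 0.5, 0.62], 0.5,
                                           rope=(-0.01, 0.01))
        total = res.p_less + res.p_rope + res.p_greater
        assert total == pytest.approx(1.0, abs=1e-9)


class TestBootstrap:
    def test_target_too_large_rejected(self):
        ds = make_tiny_dataset(n_subjects=6)
        with pytest.raises(ConfigurationError):
            md.bootstrap_subsample(ds, 6, md.CVConfig(seed=0))

    def test_percentile_definition(self):
        res = md.BootstrapResult(accuracies=np.array([0.4, 0.5, 0.6]), n_boot=3)
        assert res.percentile_of(0.39) == 0.0
        assert res.percentile_of(0.6) == 100.0
        assert res.percentile_of(0.5) == pytest.approx(200 / 3)

    def test_uninformative_features_give_chance(self):
        ds = make_tiny_dataset(n_subjects=8, separation=0.0, seed=4)
        ds = replace(ds, X=np.zeros_like(ds.X))
        cfg = md.CVConfig(n_repetitions=10, k_features=2, seed=0)
        res = md.bootstrap_subsample(ds, 6, cfg, n_boot=4)
        np.testing.assert_allclose(res.accuracies, 0.5)


class TestRegressOutAge:
    def test_feature_linear_in_age_zeroed(self):
        ds = make_tiny_dataset(n_subjects=8, seed=5)
        X = ds.X.copy()
        X[:, 1] = 0.3 * ds.sample_ages() - 2.0
        ds = replace(ds, X=X)
        out = md.regress_out_age(ds)
        np.testing.assert_allclose(out.X[:, 1], 0.0, atol=1e-10)

    def test_orthogonal_feature_only_centered(self):
        ds = make_tiny_dataset(n_subjects=8, seed=6)
        ages = ds.sample_ages()
        centered_age = ages - ages.mean()
        X = ds.X.copy()
        v = np.random.default_rng(0).normal(size=ds.n_samples)
        v -= v.mean()
        v -= (v @ centered_age) / (centered_age @ centered_age) * centered_age
        X[:, 0] = v + 7.0  # orthogonal to age, nonzero mean
        out = md.regress_out_age(replace(ds, X=X))
        np.testing.assert_allclose(out.X[:, 0], v, atol=1e-10)

    def test_constant_age_identity_with_warning(self):
        ds = make_tiny_dataset(n_subjects=6, seed=7)
        ds = replace(ds, ages={s: 30.0 for s in ds.ages})
        out = md.regress_out_age(ds)
        np.testing.assert_array_equal(out.X, ds.X)

    def test_age_confound_removed_restores_chance(self):
        parc = md.toy_parcellation(8, 2)
        cfg = md.null_config(n_subjects={"expert": 10}, n_volumes=40,
                             age_confound_scale=0.02, seed=8)
        study = md.generate_study(parc, cfg)
        md.preprocess_study(study)
        ds = md.assemble_dataset(study, "expert")
        cleaned = md.regress_out_age(ds)
        cv = md.run_cv(cleaned, md.CVConfig(n_repetitions=30, k_features=10,
                                            seed=0))
        assert cv.mean_accuracy == pytest.approx(0.5, abs=0.15)
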