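import math

import numpy as np
import pytest
from scipy import stats

import geotwin as gt
from geotwin.model_core import CohortData


def mk_pair(y1=0.0, y2=0.0, zyg="MZ", sex1="F", sex2="F", **kw):
    return gt.TwinPairRecord("P0", zyg, sex1, sex2, y1, y2, 0.0, 0.0, **kw)


class TestExpectedCovariance:
    def test_mz_ace(self):
        vc = gt.VarianceComponents(0.65, 0.0, 0.35)
        np.testing.assert_allclose(
            gt.expected_covariance(vc, "MZ"),
            [[1.0, 0.65], [0.65, 1.0]])

    def test_dz_ace_half_a(self):
        vc = gt.VarianceComponents(0.65, 0.0, 0.35)
        sigma = gt.expected_covariance(vc, "DZss")
        assert sigma[0, 1] == pytest.approx(0.325)

    def test_dz_ade_quarter_d(self):
        vc = gt.VarianceComponents(0.5, 0.2, 0.3)
        sigma = gt.expected_covariance(vc, "DZos", gt.ModelSpec("ADE"))
        assert sigma[0, 1] == pytest.approx(0.5 * 0.5 + 0.25 * 0.2)

    def test_dz_c_correlates_fully(self):
        vc = gt.VarianceComponents(0.0, 0.4, 0.6)
        sigma = gt.expected_covariance(vc, "DZss")
        assert sigma[0, 1] == pytest.approx(0.4)

    def test_diagonal_is_total(self):
        vc = gt.VarianceComponents(0.3, 0.25, 0.45)
        for zyg in gt.model_core.ZYGOSITIES:
            sigma = gt.expected_covariance(vc, zyg)
            assert sigma[0, 0] == pytest.approx(vc.total)
            assert sigma[0, 1] == sigma[1, 0]
            assert np.all(np.linalg.eigvalsh(sigma) >= -1e-12)

    def test_rejects_negative_component(self):
        with pytest.raises(ValueError):
            gt.VarianceComponents(-0.1, 0.0, 0.5)

    def test_rejects_unknown_zygosity(self):
        vc = gt.VarianceComponents(0.5, 0.0, 0.5)
        with pytest.raises(ValueError, match="zygosity"):
            gt.expected_covariance(vc, "XZ")

    def test_rejects_proportional_scale(self):
        vc = gt.VarianceComponents(0.5, 0.2, 0.3, scale="proportional")
        with pytest.raises(ValueError, match="raw"):
            gt.expected_covariance(vc, "MZ")


class TestVarianceComponents:
    def test_proportional_must_sum_to_one(self):
        with pytest.raises(ValueError):
            gt.VarianceComponents(0.5, 0.2, 0.2, scale="proportional")

    def test_standardized_sums_to_one(self):
        std = gt.VarianceComponents(1.2, 0.3, 0.5).standardized()
        assert std.a2 + std.c2_or_d2 + std.e2 == pytest.approx(1.0, abs=1e-12)


class TestTwinPairRecord:
    def test_both_missing_rejected(self):
        with pytest.raises(ValueError, match="both phenotypes"):
            mk_pair(y1=None, y2=None)

    def test_mz_opposite_sex_rejected(self):
        with pytest.raises(ValueError, match="same-sex"):
            mk_pair(zyg="MZ", sex1="M", sex2="F")

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError, match="coordinates"):
            gt.TwinPairRecord("P0", "MZ", "F", "F", 0.0, 0.0, math.nan, 0.0)


class TestModelSpec:
    def test_ade_sexlim_rejected(self):
        with pytest.raises(ValueError):
            gt.ModelSpec("ADE", "quantitative")

    def test_unknown_components_rejected(self):
        with pytest.raises(ValueError):
            gt.ModelSpec("ACDE")


class TestPairLoglik:
    def test_independent_standard_normals(self):
        # y=(0,0), identity covariance -> -ln(2*pi)
        vc = gt.VarianceComponents(0.0, 0.0, 1.0)
        ll = gt.pair_loglik(mk_pair(0.0, 0.0), vc, gt.MeanModel(0.0))
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_matches_generic_mvn_density(self):
        # oracle: scipy's generic dense multivariate normal
        vc = gt.VarianceComponents(0.6, 0.1, 0.3)
        mm = gt.MeanModel(0.0)
        for zyg in ("MZ", "DZss"):
            sigma = gt.expected_covariance(vc, zyg)
            expected = stats.multivariate_normal(mean=[0, 0], cov=sigma
                                                 ).logpdf([1.2, -0.4])
            got = gt.pair_loglik(mk_pair(1.2, -0.4, zyg=zyg), vc, mm)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_univariate_marginal_when_missing(self):
        vc = gt.VarianceComponents(0.65, 0.0, 0.35)  # total variance 1
        ll = gt.pair_loglik(mk_pair(0.5, None), vc, gt.MeanModel(0.0))
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi) - 0.125,
                                   abs=1e-12)

    def test_swap_invariance_same_sex(self):
        vc = gt.VarianceComponents(0.5, 0.2, 0.3)
        mm = gt.MeanModel(0.1, beta_sex=0.2)
        a = gt.pair_loglik(mk_pair(1.0, -0.5, zyg="DZss", sex1="M", sex2="M"),
                           vc, mm)
        b = gt.pair_loglik(mk_pair(-0.5, 1.0, zyg="DZss", sex1="M", sex2="M"),
                           vc, mm)
        assert a == pytest.approx(b, abs=1e-12)

    def test_singular_covariance_rejected(self):
        vc = gt.VarianceComponents(1.0, 0.0, 0.0)  # MZ covariance singular
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            gt.pair_loglik(mk_pair(0.1, 0.2), vc, gt.MeanModel(0.0))


class TestWeightedLoglik:
    @pytest.fixture
    def setup(self, tiny_cohort):
        vc = gt.VarianceComponents(0.6, 0.1, 0.3)
        mm = gt.MeanModel(0.05, beta_sex=0.1)
        lls = np.array([gt.pair_loglik(p, vc, mm) for p in tiny_cohort])
        return tiny_cohort, vc, mm, lls

    def test_unit_weights_is_plain_sum(self, setup):
        pairs, vc, mm, lls = setup
        got = gt.weighted_loglik(pairs, np.ones(len(pairs)), vc, mm)
        assert got == pytest.approx(lls.sum(), abs=1e-10)

    def test_linearity_in_weights(self, setup):
        pairs, vc, mm, lls = setup
        full = gt.weighted_loglik(pairs, np.ones(len(pairs)), vc, mm)
        half = gt.weighted_loglik(pairs, np.full(len(pairs), 0.5), vc, mm)
        assert half == pytest.approx(0.5 * full, abs=1e-10)

    def test_zero_weight_excludes_pair(self, setup):
        pairs, vc, mm, lls = setup
        w = np.zeros(len(pairs))
        w[0], w[2] = 1.0, 2.0
        got = gt.weighted_loglik(pairs, w, vc, mm)
        assert got == pytest.approx(lls[0] + 2 * lls[2], abs=1e-10)

    def test_length_mismatch_rejected(self, setup):
        pairs, vc, mm, _ = setup
        with pytest.raises(ValueError, match="weights"):
            gt.weighted_loglik(pairs, np.ones(len(pairs) - 1), vc, mm)

    def test_oracle_equivalence_generic_mvn(self, setup):
        # module invariant: unit-weight objective == brute-force generic
        # multivariate-normal summation on a <=20-pair cohort, to 1e-8
        pairs, vc, mm, _ = setup
        total = 0.0
        for p in pairs:
            sigma = gt.expected_covariance(vc, p.zygosity)
            mu = np.array([mm.intercept + mm.beta_sex * (p.sex1 == "M"),
                           mm.intercept + mm.beta_sex * (p.sex2 == "M")])
            if p.y1 is None:
                total += stats.norm(mu[1], math.sqrt(sigma[1, 1])).logpdf(p.y2)
            elif p.y2 is None:
                total += stats.norm(mu[0], math.sqrt(sigma[0, 0])).logpdf(p.y1)
            else:
                total += stats.multivariate_normal(mu, sigma).logpdf([p.y1, p.y2])
        got = gt.weighted_loglik(pairs, np.ones(len(pairs)), vc, mm)
        assert got == pytest.approx(total, abs=1e-8)


class TestFitModel:
    def test_parameter_recovery_fixed_seed(self, homogeneous_cohort_5000):
        fit = gt.fit_model(homogeneous_cohort_5000,
                           config=gt.FitConfig(compute_ci=False))
        assert fit.converged
        assert fit.components.a2 == pytest.approx(0.65, abs=0.03)
        assert fit.components.c2_or_d2 < 0.05
        assert fit.components.e2 == pytest.approx(0.35, abs=0.03)

    def test_location_invariance(self, homogeneous_cohort_5000):
        from dataclasses import replace
        base = gt.fit_model(homogeneous_cohort_5000,
                            config=gt.FitConfig(compute_ci=False))
        shifted = [replace(p,
                           y1=None if p.y1 is None else p.y1 + 5.0,
                           y2=None if p.y2 is None else p.y2 + 5.0)
                   for p in homogeneous_cohort_5000]
        fit = gt.fit_model(shifted, config=gt.FitConfig(compute_ci=False))
        assert fit.components.a2 == pytest.approx(base.components.a2, abs=1e-4)
        assert fit.components.e2 == pytest.approx(base.components.e2, abs=1e-4)
        assert fit.mean_model.intercept == pytest.approx(
            base.mean_model.intercept + 5.0, abs=1e-3)

    def test_degenerate_identical_twins_flagged(self):
        rng = np.random.default_rng(3)
        pairs = []
        for i in range(40):
            v = float(rng.normal())
            zyg = "MZ" if i % 2 else "DZss"
            pairs.append(gt.TwinPairRecord(f"P{i}", zyg, "F", "F", v, v,
                                           float(i), 0.0))
        fit = gt.fit_model(pairs, config=gt.FitConfig(compute_ci=False))
        assert fit.components.e2 < 1e-3
        assert not fit.converged

    def test_all_mz_rejected(self):
        pairs = gt.simulate_cohort(
            gt.homogeneous_field(0.6, 0.0, 0.4),
            gt.CohortConfig(n_pairs=20, seed=0, mz_fraction=1.0))
        with pytest.raises(ValueError, match="identifiable"):
            gt.fit_model(pairs)

    def test_uniform_weight_value_irrelevant(self, tiny_cohort):
        cfg = gt.FitConfig(compute_ci=False)
        f1 = gt.fit_model(tiny_cohort, np.ones(len(tiny_cohort)), config=cfg)
        f2 = gt.fit_model(tiny_cohort, np.full(len(tiny_cohort), 7.3),
                          config=cfg)
        assert f1.components.a2 == pytest.approx(f2.components.a2, abs=1e-6)
        assert f1.components.e2 == pytest.approx(f2.components.e2, abs=1e-6)

    def test_decomposition_identities(self, tiny_cohort):
        fit = gt.fit_model(tiny_cohort, config=gt.FitConfig(compute_ci=False))
        std = fit.components_std
        assert std.a2 + std.c2_or_d2 + std.e2 == pytest.approx(1.0, abs=1e-10)
        assert fit.components.total == pytest.approx(
            fit.components.a2 + fit.components.c2_or_d2 + fit.components.e2)

    def test_zygosity_covariance_ordering(self, homogeneous_cohort_5000):
        fit = gt.fit_model(homogeneous_cohort_5000,
                           config=gt.FitConfig(compute_ci=False))
        assert fit.components.a2 > 0
        mz = gt.expected_covariance(fit.components, "MZ")[0, 1]
        dz = gt.expected_covariance(fit.components, "DZss")[0, 1]
        assert mz > dz

    def test_ess_bounded_by_pair_counts(self, tiny_cohort):
        fit = gt.fit_model(tiny_cohort, config=gt.FitConfig(compute_ci=False))
        n_mz = sum(p.zygosity == "MZ" for p in tiny_cohort)
        assert fit.ess_mz <= n_mz + 1e-9
        assert fit.ess_dz <= len(tiny_cohort) - n_mz + 1e-9

    def test_ade_fit_runs(self, homogeneous_cohort_5000):
        fit = gt.fit_model(homogeneous_cohort_5000, spec=gt.ModelSpec("ADE"),
                           config=gt.FitConfig(compute_ci=False))
        assert fit.converged
        total = fit.components.total
        assert total == pytest.approx(1.0, abs=0.05)


class TestConfidenceIntervals:
    def test_interval_covers_truth_fixed_seed(self, homogeneous_cohort_5000):
        fit = gt.fit_model(homogeneous_cohort_5000)
        lo, hi = fit.ci["a2"]
        assert lo <= 0.65 <= hi
        assert lo <= fit.components.a2 <= hi

    def test_weight_doubling_leaves_intervals(self, tiny_cohort):
        w = np.linspace(0.5, 2.0, len(tiny_cohort))
        f1 = gt.fit_model(tiny_cohort, w)
        f2 = gt.fit_model(tiny_cohort, 2.0 * w)
        assert f1.components.a2 == pytest.approx(f2.components.a2, abs=1e-6)
        for key in f1.ci:
            np.testing.assert_allclose(f1.ci[key], f2.ci[key], atol=1e-5)

    def test_lower_bounds_truncated_at_zero(self, homogeneous_cohort_5000):
        fit = gt.fit_model(homogeneous_cohort_5000)
        for lo, hi in fit.ci.values():
            assert lo >= 0.0
            assert lo <= hi
        # c2 is estimated at/near its zero boundary here
        assert fit.ci["c2_or_d2"][0] == 0.0


class TestSexLimitation:
    def test_nesting(self, homogeneous_cohort_5000):
        res = gt.fit_sex_limitation(homogeneous_cohort_5000)
        assert res.equated_fit.loglik <= res.loglik + 1e-6
        assert res.lrt_vs_equated[0] >= 0.0
        assert res.lrt_vs_equated[1] == 3

    def test_recovery_sex_specific(self):
        pairs = gt.simulate_sex_limited_cohort(
            (0.7, 0.1, 0.2), (0.5, 0.1, 0.4),
            gt.CohortConfig(n_pairs=6000, seed=3))
        res = gt.fit_sex_limitation(pairs,
                                    config=gt.FitConfig(compute_ci=False))
        assert res.male.a2 == pytest.approx(0.7, abs=0.06)
        assert res.female.a2 == pytest.approx(0.5, abs=0.06)

    def test_warns_without_opposite_sex_pairs(self):
        pairs = gt.simulate_sex_limited_cohort(
            (0.6, 0.1, 0.3), (0.6, 0.1, 0.3),
            gt.CohortConfig(n_pairs=400, seed=2,
                            opposite_sex_dz_fraction=0.0))
        with pytest.warns(UserWarning, match="opposite-sex"):
            gt.fit_sex_limitation(pairs, config=gt.FitConfig(compute_ci=False))


class TestVarianceExplained:
    def test_zero_beta_gives_zero(self, tiny_cohort):
        shares = gt.variance_explained_by_covariates(
            tiny_cohort, gt.MeanModel(0.0, beta_sex=0.0, beta_age=0.0))
        assert shares["sex"] == 0.0
        assert shares["age"] == 0.0

    def test_recovers_generating_share(self):
        pairs = gt.simulate_cohort(
            gt.homogeneous_field(0.65, 0.0, 0.35),
            gt.CohortConfig(n_pairs=8000, seed=4, sex_variance_share=0.026))
        std = gt.standardize_phenotype(pairs)
        fit = gt.fit_model(std, config=gt.FitConfig(compute_ci=False))
        shares = gt.variance_explained_by_covariates(std, fit.mean_model)
        assert shares["sex"] == pytest.approx(0.026, abs=0.005)

    def test_constant_covariate_gives_zero(self):
        rng = np.random.default_rng(1)
        pairs = [gt.TwinPairRecord(f"P{i}", "MZ" if i % 2 else "DZss",
                                   "M", "M", float(rng.normal()),
                                   float(rng.normal()), 0.0, 0.0)
                 for i in range(30)]
        shares = gt.variance_explained_by_covariates(
            pairs, gt.MeanModel(0.0, beta_sex=0.8))
        assert shares["sex"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_phenotype_rejected(self):
        pairs = [gt.TwinPairRecord(f"P{i}", "MZ", "F", "F", 1.0, 1.0, 0.0, 0.0)
                 for i in range(4)]
        with pytest.raises(ValueError, match="variance"):
            gt.variance_explained_by_covariates(pairs, gt.MeanModel(0.0, 0.1))


class TestCohortData:
    def test_roundtrip_identity(self, tiny_cohort):
        data = CohortData.from_pairs(tiny_cohort)
        assert CohortData.from_pairs(data) is data
        assert data.n == len(tiny_cohort)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CohortData([])
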