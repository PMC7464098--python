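"""Fitting tests: recovery, model comparison, uncertainty."""

import math

import numpy as np
import pytest
from scipy import optimize

from aucbind import (
    ComplexModelParams,
    EquilibriumTruth,
    RadialProfile,
    SedimentationEquilibrium,
    compare_models,
    fit_equilibrium,
    kd_with_uncertainty,
    predict_profile,
    simulate_equilibrium_scan,
)
from aucbind.equilibrium_fit import EquilibriumFit, runs_test
from aucbind.errors import ValidationError


@pytest.fixture
def tight_truth(species, conditions):
    return EquilibriumTruth(
        ho1=species["heme_rHO1"], cpr=species["dTGEE"], conditions=conditions,
        kd_M=0.178e-6, total_ho1_uM=5.0, total_cpr_uM=5.0,
    )


@pytest.fixture
def weak_truth(species, conditions):
    return EquilibriumTruth(
        ho1=species["heme_rHO1"], cpr=species["rCPR"], conditions=conditions,
        kd_M=62.1e-6, total_ho1_uM=15.0, total_cpr_uM=15.0,
    )


def noise_free_scan(truth):
    from dataclasses import replace

    return simulate_equilibrium_scan(replace(truth, noise_sd=0.0), seed=0)


class TestFitEquilibrium:
    def test_noise_free_recovery(self, weak_truth, species, conditions):
        scan = noise_free_scan(weak_truth)
        fit = fit_equilibrium(
            scan.profile, weak_truth.ho1, weak_truth.cpr, conditions, "complex"
        )
        assert fit.converged
        assert fit.params.a_ho1_ref == pytest.approx(scan.params.a_ho1_ref, rel=1e-6)
        assert fit.params.a_cpr_ref == pytest.approx(scan.params.a_cpr_ref, rel=1e-6)
        assert fit.params.k_assoc == pytest.approx(scan.params.k_assoc, rel=1e-6)
        assert fit.kd == pytest.approx(weak_truth.kd_M, rel=1e-5)

    def test_wrong_model_fits_worse_with_trending_residuals(self, tight_truth, conditions):
        scan = simulate_equilibrium_scan(tight_truth, seed=3)
        fit_c = fit_equilibrium(
            scan.profile, tight_truth.ho1, tight_truth.cpr, conditions, "complex"
        )
        fit_nc = fit_equilibrium(
            scan.profile, tight_truth.ho1, tight_truth.cpr, conditions, "non_complexed"
        )
        assert fit_nc.rmsd > fit_c.rmsd
        # sign-correlated residual trend: far fewer runs than expected
        runs = runs_test(fit_nc.residuals)
        assert runs["n_runs"] < runs["expected"]
        assert runs["pvalue"] < 1e-6

    def test_underdetermined_profile_rejected(self, species, conditions):
        prof = RadialProfile(
            np.linspace(6.95, 7.05, 5), np.linspace(0.1, 0.4, 5), 455.0
        )
        with pytest.raises(ValidationError, match="at least"):
            fit_equilibrium(prof, species["heme_rHO1"], species["rCPR"], conditions)

    def test_reorder_invariance(self, weak_truth, conditions):
        scan = simulate_equilibrium_scan(weak_truth, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(scan.profile))
        shuffled = RadialProfile(
            scan.profile.radii[perm], scan.profile.absorbances[perm], 455.0
        )
        f1 = fit_equilibrium(
            scan.profile, weak_truth.ho1, weak_truth.cpr, conditions, "complex"
        )
        f2 = fit_equilibrium(
            shuffled, weak_truth.ho1, weak_truth.cpr, conditions, "complex"
        )
        assert f1.params.k_assoc == pytest.approx(f2.params.k_assoc, rel=1e-12)
        assert f1.rmsd == pytest.approx(f2.rmsd, rel=1e-12)

    def test_log_parameterization_matches_natural_scale_bounded_fit(
        self, weak_truth, conditions
    ):
        scan = simulate_equilibrium_scan(weak_truth, seed=7)
        est = SedimentationEquilibrium(
            weak_truth.ho1, weak_truth.cpr, conditions, model="complex"
        ).fit(scan.profile)
        p = est.params_

        # independent route: bounded least squares on the natural scale
        r = scan.profile.radii
        y = scan.profile.absorbances

        def resid(theta):
            a1, a2, k, d = theta
            return (
                predict_profile(
                    ComplexModelParams(a1, a2, k, d),
                    weak_truth.ho1, weak_truth.cpr, conditions, r,
                )
                - y
            )

        res = optimize.least_squares(
            resid,
            [p.a_ho1_ref, p.a_cpr_ref, p.k_assoc, p.baseline],
            bounds=([0, 0, 0, -np.inf], np.inf),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        np.testing.assert_allclose(
            res.x,
            [p.a_ho1_ref, p.a_cpr_ref, p.k_assoc, p.baseline],
            rtol=1e-6, atol=1e-10,
        )

    @pytest.mark.parametrize("kd_uM,totals_uM", [(1.0, 5.0), (30.0, 15.0)])
    def test_median_kd_recovery_small_panel(
        self, species, conditions, kd_uM, totals_uM
    ):
        truth = EquilibriumTruth(
            ho1=species["heme_rHO1"], cpr=species["rCPR"], conditions=conditions,
            kd_M=kd_uM * 1e-6, total_ho1_uM=totals_uM, total_cpr_uM=totals_uM,
        )
        kds = []
        for seed in range(7):
            scan = simulate_equilibrium_scan(truth, seed=seed)
            fit = fit_equilibrium(
                scan.profile, truth.ho1, truth.cpr, conditions, "complex", seed=seed
            )
            kds.append(fit.kd)
        assert np.median(kds) == pytest.approx(truth.kd_M, rel=0.2)


class TestCompareModels:
    def test_equal_fits_prefer_parsimony(self, weak_truth, conditions):
        scan = simulate_equilibrium_scan(weak_truth, seed=1)
        fit_c = fit_equilibrium(
            scan.profile, weak_truth.ho1, weak_truth.cpr, conditions, "complex"
        )
        from dataclasses import replace

        # identical residuals presented as the two nested models
        twin = replace(fit_c, model_kind="non_complexed")
        cmp_rec = compare_models(fit_c, twin)
        assert cmp_rec.f_statistic == 0.0
        assert cmp_rec.preferred == "non_complexed"

    def test_strong_association_prefers_complex(self, tight_truth, conditions):
        scan = simulate_equilibrium_scan(tight_truth, seed=11)
        fit_c = fit_equilibrium(
            scan.profile, tight_truth.ho1, tight_truth.cpr, conditions, "complex"
        )
        fit_nc = fit_equilibrium(
            scan.profile, tight_truth.ho1, tight_truth.cpr, conditions,
            "non_complexed",
        )
        cmp_rec = compare_models(fit_c, fit_nc)
        assert cmp_rec.preferred == "complex"
        assert cmp_rec.f_pvalue < 1e-10
        assert cmp_rec.rmsd_ratio > 1.0

    def test_mismatched_profiles_rejected(self, weak_truth, conditions):
        s1 = simulate_equilibrium_scan(weak_truth, seed=1)
        from dataclasses import replace

        truth2 = replace(weak_truth, radial_step_cm=0.002)
        s2 = simulate_equilibrium_scan(truth2, seed=1)
        f_c = fit_equilibrium(
            s1.profile, weak_truth.ho1, weak_truth.cpr, conditions, "complex"
        )
        f_nc = fit_equilibrium(
            s2.profile, weak_truth.ho1, weak_truth.cpr, conditions, "non_complexed"
        )
        with pytest.raises(ValidationError, match="same profile"):
            compare_models(f_c, f_nc)


class TestKdUncertainty:
    def test_zero_noise_se_near_zero(self, weak_truth, conditions):
        scan = noise_free_scan(weak_truth)
        fit = fit_equilibrium(
            scan.profile, weak_truth.ho1, weak_truth.cpr, conditions, "complex"
        )
        kd, se = kd_with_uncertainty(
            fit, weak_truth.ho1, weak_truth.cpr, conditions, "delta"
        )
        assert se < 1e-6 * kd

    def test_delta_and_bootstrap_agree_within_factor_two(self, weak_truth, conditions):
        scan = simulate_equilibrium_scan(weak_truth, seed=21)
        fit = fit_equilibrium(
            scan.profile, weak_truth.ho1, weak_truth.cpr, conditions, "complex"
        )
        kd_d, se_d = kd_with_uncertainty(
            fit, weak_truth.ho1, weak_truth.cpr, conditions, "delta"
        )
        kd_b, se_b = kd_with_uncertainty(
            fit, weak_truth.ho1, weak_truth.cpr, conditions, "bootstrap",
            n_boot=100, seed=4,
        )
        assert kd_d == kd_b
        assert 0.5 < se_d / se_b < 2.0

    def test_boundary_no_association_propagates(self, weak_truth, conditions):
        scan = noise_free_scan(weak_truth)
        fit = fit_equilibrium(
            scan.profile, weak_truth.ho1, weak_truth.cpr, conditions, "complex"
        )
        from dataclasses import replace

        boundary = replace(
            fit, params=ComplexModelParams(0.1, 0.1, 0.0, 0.0)
        )
        kd, se = kd_with_uncertainty(
            boundary, weak_truth.ho1, weak_truth.cpr, conditions, "delta"
        )
        assert math.isinf(kd) and se is None

    def test_requires_complex_converged(self, weak_truth, conditions):
        scan = noise_free_scan(weak_truth)
        fit_nc = fit_equilibrium(
            scan.profile, weak_truth.ho1, weak_truth.cpr, conditions, "non_complexed"
        )
        with pytest.raises(ValidationError):
            kd_with_uncertainty(
                fit_nc, weak_truth.ho1, weak_truth.cpr, conditions, "delta"
            )
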