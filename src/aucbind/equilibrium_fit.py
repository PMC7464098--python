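"""Nonlinear least-squares fitting of sedimentation-equilibrium scans.

The estimator fits the hetero-association radial model (or its non-complexed
reduction) to one scan.  Amplitudes and the association constant are
log-parameterised so positivity holds without active-set handling — the
association constant spans several orders of magnitude across tight
(sub-μM) and weak (>100 μM) binders — and the fit is restarted from several
seeded initial guesses because the three-exponential mixture has local
minima.  Molar masses are fixed from the species definitions, never floated.

Model comparison follows the usual nested-model route: an F-test on the
one-parameter difference plus a Wald–Wolfowitz runs test on residual signs,
which flags the sign-correlated residual trend a mis-specified monomer-only
model leaves behind.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .equilibrium_model import (
    ComplexModelParams,
    DEFAULT_EXPONENT_CAP,
    RadialProfile,
    RunConditions,
    Species,
    association_from_kd,
    kd_from_association,
    predict_profile,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: below this absorbance-scale association constant (AU⁻¹) the complex term is
#: indistinguishable from zero and Kd is reported as "no detectable association"
K_ASSOC_FLOOR = 1e-6

ModelKind = Literal["complex", "non_complexed"]


@dataclass
class EquilibriumFit:
    """Result of fitting one scan with one model."""

    model_kind: ModelKind
    params: ComplexModelParams
    covariance: np.ndarray  # on the estimated (log-amplitude) scale
    residuals: np.ndarray
    rmsd: float
    n_points: int
    kd: float | None  # molar; inf = no detectable association
    kd_se: float | None
    converged: bool
    n_starts_used: int
    cost: float  # sum of squared residuals
    profile: RadialProfile = field(repr=False)

    @property
    def n_parameters(self) -> int:
        return 4 if self.model_kind == "complex" else 3


@dataclass
class ModelComparison:
    """Complex vs non-complexed comparison on the same scan."""

    rmsd_ratio: float  # non_complexed / complex
    f_statistic: float
    f_pvalue: float
    df: tuple[int, int]
    runs_complex: dict
    runs_non_complexed: dict
    alpha: float
    preferred: ModelKind


def runs_test(residuals: np.ndarray) -> dict:
    """Wald–Wolfowitz runs test on residual signs.

    Returns the number of sign runs, its null expectation, a normal-
    approximation z statistic and two-sided p-value.  Zeros are dropped.
    """
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n = signs.size
    if n < 2:
        return {"n_runs": n, "expected": float(n), "z": 0.0, "pvalue": 1.0}
    n_pos = int(np.sum(signs > 0))
    n_neg = n - n_pos
    n_runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    if n_pos == 0 or n_neg == 0:
        return {"n_runs": n_runs, "expected": 1.0, "z": 0.0, "pvalue": 1.0}
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = (mu - 1.0) * (mu - 2.0) / (n - 1.0)
    z = (n_runs - mu) / math.sqrt(var) if var > 0 else 0.0
    return {
        "n_runs": n_runs,
        "expected": mu,
        "z": z,
        "pvalue": float(2.0 * stats.norm.sf(abs(z))),
    }


class SedimentationEquilibrium(RegressorMixin, BaseEstimator):
    """Sedimentation-equilibrium hetero-association model as an estimator.

    Parameters
    ----------
    ho1, cpr:
        The two species (the absorbing reporter and its partner).
    conditions:
        Rotor/solvent/optics for the run.
    model:
        ``"complex"`` (4 parameters) or ``"non_complexed"`` (3 parameters).
    n_starts:
        Seeded multi-start count; starts are log-uniform draws around
        data-driven heuristics.
    seed:
        Seed for the start draws (and nothing else); fits are deterministic
        given the seed.

    Attributes
    ----------
    params_ : ComplexModelParams
    covariance_ : ndarray on the (log a_HO1, log a_CPR, [log k], δ) scale
    residuals_, rmsd_, cost_, n_points_, converged_, n_starts_used_
    kd_ : float or None — molar Kd (complex model; ``inf`` if no association)
    kd_se_ : float or None — delta-method standard error
    """

    def __init__(
        self,
        ho1: Species,
        cpr: Species,
        conditions: RunConditions,
        model: ModelKind = "complex",
        n_starts: int = 8,
        seed: int = 0,
        max_nfev: int = 2000,
        ftol: float = 1e-10,
        xtol: float = 1e-10,
        exponent_cap: float = DEFAULT_EXPONENT_CAP,
    ):
        self.ho1 = ho1
        self.cpr = cpr
        self.conditions = conditions
        self.model = model
        self.n_starts = n_starts
        self.seed = seed
        self.max_nfev = max_nfev
        self.ftol = ftol
        self.xtol = xtol
        self.exponent_cap = exponent_cap

    # -- internals ---------------------------------------------------------

    def _bases(self, radii: np.ndarray):
        from .equilibrium_model import _mass_exponents

        mh1, mh2 = _mass_exponents(self.ho1, self.cpr, self.conditions)
        xi = radii**2 - self.conditions.reference_radius_cm**2
        worst = float(np.max(np.abs(xi)))
        for mh in (mh1, mh2, mh1 + mh2):
            if abs(mh) * worst > self.exponent_cap:
                # delegate for the detailed message
                predict_profile(
                    ComplexModelParams(0, 0, 0, 0),
                    self.ho1,
                    self.cpr,
                    self.conditions,
                    radii,
                    exponent_cap=self.exponent_cap,
                )
        return np.exp(mh1 * xi), np.exp(mh2 * xi)

    @staticmethod
    def _unpack(theta: np.ndarray, complex_model: bool):
        if complex_model:
            a1, a2, k = np.exp(theta[:3])
            return a1, a2, k, theta[3]
        a1, a2 = np.exp(theta[:2])
        return a1, a2, 0.0, theta[2]

    def _residual_jac(self, y, e1, e2, complex_model: bool):
        e12 = e1 * e2

        def fun(theta):
            a1, a2, k, delta = self._unpack(theta, complex_model)
            model = a1 * e1 + a2 * e2 + delta
            if complex_model:
                model = model + k * a1 * a2 * e12
            return model - y

        def jac(theta):
            a1, a2, k, _ = self._unpack(theta, complex_model)
            cols = []
            if complex_model:
                cross = k * a1 * a2 * e12
                cols = [a1 * e1 + cross, a2 * e2 + cross, cross]
            else:
                cols = [a1 * e1, a2 * e2]
            cols.append(np.ones_like(e1))
            return np.column_stack(cols)

        return fun, jac

    def _starts(self, radii, y, complex_model: bool) -> list[np.ndarray]:
        rng = np.random.default_rng(self.seed)
        a0 = float(np.interp(self.conditions.reference_radius_cm, radii, y))
        a0 = max(a0, 10.0 * np.finfo(float).tiny, 1e-4)
        starts = []
        for _ in range(max(1, int(self.n_starts))):
            u = rng.uniform(0.15, 0.85)
            scale = math.exp(rng.uniform(math.log(0.3), math.log(1.2)))
            a1 = max(u * a0 * scale, 1e-6)
            a2 = max((1 - u) * a0 * scale, 1e-6)
            delta = rng.normal(0.0, 0.01)
            if complex_model:
                k = 10.0 ** rng.uniform(-2.0, 2.0)
                starts.append(np.array([math.log(a1), math.log(a2), math.log(k), delta]))
            else:
                starts.append(np.array([math.log(a1), math.log(a2), delta]))
        return starts

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None):
        """Fit the model to a scan.

        ``X`` may be a :class:`RadialProfile` (then ``y`` is ignored) or an
        array of radii in cm of shape (n,) or (n, 1) with ``y`` the matching
        absorbances.
        """
        if isinstance(X, RadialProfile):
            profile = X
        else:
            r = np.asarray(X, dtype=float)
            if r.ndim == 2 and r.shape[1] == 1:
                r = r[:, 0]
            profile = RadialProfile(r, np.asarray(y, dtype=float), wavelength=0.0)
        complex_model = self.model == "complex"
        n_params = 4 if complex_model else 3
        if len(profile) < max(8, n_params + 4):
            raise ValidationError(
                f"profile has {len(profile)} points; at least "
                f"{max(8, n_params + 4)} are required to fit the "
                f"{self.model} model"
            )
        radii, yobs = profile.radii, profile.absorbances
        e1, e2 = self._bases(radii)
        fun, jac = self._residual_jac(yobs, e1, e2, complex_model)

        best = None
        n_used = 0
        for theta0 in self._starts(radii, yobs, complex_model):
            n_used += 1
            try:
                res = optimize.least_squares(
                    fun,
                    theta0,
                    jac=jac,
                    method="trf",
                    ftol=self.ftol,
                    xtol=self.xtol,
                    max_nfev=self.max_nfev,
                )
            except (ValueError, FloatingPointError):  # pathological start
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise ValidationError("all optimizer starts failed")

        a1, a2, k, delta = self._unpack(best.x, complex_model)
        self.params_ = ComplexModelParams(a1, a2, k, delta)
        self.residuals_ = fun(best.x)
        self.cost_ = float(np.sum(self.residuals_**2))
        self.n_points_ = len(profile)
        self.rmsd_ = math.sqrt(self.cost_ / self.n_points_)
        self.converged_ = bool(best.status > 0)
        self.n_starts_used_ = n_used
        self.profile_ = profile

        dof = self.n_points_ - n_params
        s2 = self.cost_ / max(dof, 1)
        jtj = best.jac.T @ best.jac
        try:
            cov = s2 * np.linalg.inv(jtj)
            self.covariance_singular_ = False
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(jtj)
            self.covariance_singular_ = True
            logger.warning("singular normal matrix; covariance from pseudo-inverse")
        self.covariance_ = cov

        self.kd_ = None
        self.kd_se_ = None
        if complex_model:
            wl = profile.wavelength
            if wl and wl in self.ho1.extinction and wl in self.cpr.extinction:
                self._eps = (self.ho1.extinction_at(wl), self.cpr.extinction_at(wl))
            else:
                self._eps = None
            if self._eps is not None:
                self.kd_, self.kd_se_ = self._kd_delta(k)
        return self

    def _kd_delta(self, k: float) -> tuple[float, float | None]:
        eps1, eps2 = self._eps
        path = self.conditions.path_length_cm
        if k < K_ASSOC_FLOOR:
            return math.inf, None
        kd = kd_from_association(k, eps1, eps2, path)
        var_logk = float(self.covariance_[2, 2])
        se = kd * math.sqrt(var_logk) if var_logk >= 0 else None
        return kd, se

    def predict(self, X):
        """Model absorbance at radii ``X`` (cm), after :meth:`fit`."""
        r = np.asarray(X, dtype=float)
        if r.ndim == 2 and r.shape[1] == 1:
            r = r[:, 0]
        return predict_profile(
            self.params_, self.ho1, self.cpr, self.conditions, r,
            exponent_cap=self.exponent_cap,
        )

    def result(self) -> EquilibriumFit:
        """Bundle the fitted attributes into an :class:`EquilibriumFit`."""
        return EquilibriumFit(
            model_kind=self.model,
            params=self.params_,
            covariance=self.covariance_,
            residuals=self.residuals_,
            rmsd=self.rmsd_,
            n_points=self.n_points_,
            kd=self.kd_,
            kd_se=self.kd_se_,
            converged=self.converged_,
            n_starts_used=self.n_starts_used_,
            cost=self.cost_,
            profile=self.profile_,
        )


def fit_equilibrium(
    profile: RadialProfile,
    ho1: Species,
    cpr: Species,
    conditions: RunConditions,
    model_kind: ModelKind = "complex",
    **options,
) -> EquilibriumFit:
    """Fit one scan with one model; thin wrapper over the estimator."""
    est = SedimentationEquilibrium(ho1, cpr, conditions, model=model_kind, **options)
    est.fit(profile)
    return est.result()


def compare_models(
    fit_c: EquilibriumFit, fit_nc: EquilibriumFit, alpha: float = 0.05
) -> ModelComparison:
    """Nested F-test and residual runs tests for complex vs non-complexed.

    The complex model is preferred iff the one-extra-parameter F-test is
    significant at ``alpha``; ties and non-significant improvements go to the
    simpler model (parsimony).
    """
    if fit_c.model_kind != "complex" or fit_nc.model_kind != "non_complexed":
        raise ValidationError(
            "compare_models expects (complex fit, non_complexed fit), got "
            f"({fit_c.model_kind}, {fit_nc.model_kind})"
        )
    if fit_c.n_points != fit_nc.n_points or not np.array_equal(
        fit_c.profile.radii, fit_nc.profile.radii
    ):
        raise ValidationError("fits are not on the same profile")
    n = fit_c.n_points
    df1, df2 = 1, n - 4
    ss_c, ss_nc = fit_c.cost, fit_nc.cost
    f_stat = max(0.0, (ss_nc - ss_c) / df1 / (ss_c / df2))
    pval = float(stats.f.sf(f_stat, df1, df2))
    preferred: ModelKind = "complex" if pval < alpha else "non_complexed"
    return ModelComparison(
        rmsd_ratio=fit_nc.rmsd / fit_c.rmsd if fit_c.rmsd > 0 else math.inf,
        f_statistic=f_stat,
        f_pvalue=pval,
        df=(df1, df2),
        runs_complex=runs_test(fit_c.residuals),
        runs_non_complexed=runs_test(fit_nc.residuals),
        alpha=alpha,
        preferred=preferred,
    )


def kd_with_uncertainty(
    fit: EquilibriumFit,
    ho1: Species,
    cpr: Species,
    conditions: RunConditions,
    method: Literal["delta", "bootstrap"] = "delta",
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, float | None]:
    """Molar Kd and standard error from a converged complex-model fit.

    ``delta`` propagates Var(log k) from the fit covariance (Kd·SE(log k));
    ``bootstrap`` resamples residuals with replacement, refits, and reports
    the SD of the refitted Kd.  A singular covariance falls back to the
    bootstrap with a logged warning.  A fit at the no-association boundary
    propagates (inf, None).
    """
    if fit.model_kind != "complex":
        raise ValidationError("Kd is defined for the complex model only")
    if not fit.converged:
        raise ValidationError("fit did not converge; Kd uncertainty undefined")
    wl = fit.profile.wavelength
    eps1, eps2 = ho1.extinction_at(wl), cpr.extinction_at(wl)
    path = conditions.path_length_cm
    k = fit.params.k_assoc
    if k < K_ASSOC_FLOOR:
        return math.inf, None
    kd = kd_from_association(k, eps1, eps2, path)

    singular = not np.all(np.isfinite(fit.covariance)) or fit.covariance[2, 2] <= 0
    if method == "delta" and singular:
        logger.warning("covariance unusable for the delta method; bootstrapping")
        method = "bootstrap"
    if method == "delta":
        return kd, kd * math.sqrt(float(fit.covariance[2, 2]))
    if method != "bootstrap":
        raise ValidationError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    fitted = fit.profile.absorbances - fit.residuals
    kds = []
    for _ in range(int(n_boot)):
        y_star = fitted + rng.choice(fit.residuals, size=fit.n_points, replace=True)
        prof = RadialProfile(fit.profile.radii, y_star, fit.profile.wavelength)
        est = SedimentationEquilibrium(
            ho1, cpr, conditions, model="complex", n_starts=2,
            seed=int(rng.integers(2**31 - 1)),
        )
        try:
            est.fit(prof)
        except ValidationError:
            continue
        kb = est.params_.k_assoc
        if kb >= K_ASSOC_FLOOR:
            kds.append(kd_from_association(kb, eps1, eps2, path))
    if len(kds) < 2:
        return kd, None
    return kd, float(np.std(kds, ddof=1))
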