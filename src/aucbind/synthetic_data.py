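"""Seeded generators for every input the analysis pipeline consumes.

Three generators with known ground truth:

* equilibrium radial scans — 1:1 mass action between the two proteins is
  imposed at the reference radius (free concentrations from the positive
  root of the binding quadratic), free concentrations become reference
  absorbances through ε455 and the path length, the association constant on
  the absorbance scale comes from the molar Kd, and the hetero-association
  radial model is evaluated on the grid with i.i.d. Gaussian noise;
* CO-binding heme-reduction traces — exponential approach at each Soret
  channel (406 falling, 420 rising, amplitude ratio fixed by the Δε pair)
  with a pseudo-first-order observed rate proportional to the reductase
  concentration;
* bilirubin assay traces — linear rise at 468 nm until a substrate-
  exhaustion plateau.

All generators are pure functions of (truth, seed); per-trace child seeds
derive from the parent seed by fixed offsets, so replicate sets are
reproducible element-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .equilibrium_model import (
    ComplexModelParams,
    RadialProfile,
    RunConditions,
    Species,
    association_from_kd,
    predict_profile,
)
from .errors import ValidationError
from .kinetics import SpectroConstants, TimeTrace

#: default scan noise, AU (typical XL-A absorbance-optics noise)
DEFAULT_SCAN_NOISE_SD = 0.005

#: default radial grid: a ~0.3 cm solution column near the cell base,
#: 0.001 cm step (the instrument's radial step mode)
DEFAULT_RADIAL_WINDOW = (6.90, 7.20)
DEFAULT_RADIAL_STEP = 0.001


def reference_species() -> dict[str, Species]:
    """Synthetic stand-ins for the proteins of the study system.

    Extinction coefficients at 455 nm are the published values; the molar
    masses and partial specific volumes are nominal synthetic values for the
    soluble constructs (heme–rHO-1 ≈ 30 kDa; soluble CPR forms ≈ 70 kDa,
    with the hinge-deletion mutant ~0.4 kDa lighter), since the real
    constructs' exact masses are not part of the bundled data.
    """
    mk = lambda name, mass, eps455: Species(  # noqa: E731
        name=name,
        molar_mass=mass,
        partial_specific_volume=0.73,
        extinction={455.0: eps455 * 1000.0},
    )
    return {
        "heme_rHO1": mk("heme_rHO1", 30_000.0, 15.1),
        "rCPR": mk("rCPR", 70_000.0, 24.0),
        "dTGEE": mk("dTGEE", 69_600.0, 23.8),
        "147CC514": mk("147CC514", 70_000.0, 23.7),
        "IAM/DTT-147CC514": mk("IAM/DTT-147CC514", 70_000.0, 23.8),
    }


def default_conditions(
    r0_cm: float | None = None,
    radial_window_cm: tuple[float, float] = DEFAULT_RADIAL_WINDOW,
) -> RunConditions:
    """Equilibrium-run defaults: 15,000 rpm, 25 °C, 12 mm path.

    The reference radius defaults to the midpoint of the radial window.
    """
    if r0_cm is None:
        r0_cm = 0.5 * (radial_window_cm[0] + radial_window_cm[1])
    return RunConditions(
        rotor_speed_rpm=15_000.0,
        temperature_K=298.15,
        solvent_density=1.004,
        path_length_cm=1.2,
        reference_radius_cm=r0_cm,
        radial_window_cm=radial_window_cm,
    )


def mass_action_concentrations(
    total_a: float, total_b: float, kd: float
) -> tuple[float, float, float]:
    """Free A, free B and complex for A + B ⇌ AB at equilibrium.

    Totals and Kd share any one concentration unit; the positive root of
    the binding quadratic is evaluated in its numerically stable form.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValidationError("totals must be > 0")
    if kd <= 0 or not math.isfinite(kd):
        if math.isinf(kd):
            return total_a, total_b, 0.0
        raise ValidationError("kd must be > 0")
    s = total_a + total_b + kd
    disc = math.sqrt(s * s - 4.0 * total_a * total_b)
    complex_ = 2.0 * total_a * total_b / (s + disc)  # stable for kd >> totals
    return total_a - complex_, total_b - complex_, complex_


@dataclass(frozen=True)
class EquilibriumTruth:
    """Ground truth for one synthetic equilibrium scan."""

    ho1: Species
    cpr: Species
    conditions: RunConditions
    kd_M: float
    total_ho1_uM: float
    total_cpr_uM: float
    noise_sd: float = DEFAULT_SCAN_NOISE_SD
    wavelength: float = 455.0
    radial_step_cm: float = DEFAULT_RADIAL_STEP
    baseline: float = 0.0
    linearity_cap_AU: float = 1.5

    def __post_init__(self):
        if self.kd_M <= 0 and not math.isinf(self.kd_M):
            raise ValidationError("kd_M must be > 0 (inf = no association)")
        if self.total_ho1_uM <= 0 or self.total_cpr_uM <= 0:
            raise ValidationError("loading concentrations must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class SimulatedScan:
    profile: RadialProfile
    params: ComplexModelParams  # exact generating parameters
    truth: EquilibriumTruth
    warnings: list[str] = field(default_factory=list)


def generating_params(truth: EquilibriumTruth) -> ComplexModelParams:
    """Exact radial-model parameters implied by the truth record."""
    eps1 = truth.ho1.extinction_at(truth.wavelength)
    eps2 = truth.cpr.extinction_at(truth.wavelength)
    path = truth.conditions.path_length_cm
    free1, free2, _ = mass_action_concentrations(
        truth.total_ho1_uM * 1e-6, truth.total_cpr_uM * 1e-6, truth.kd_M
    )
    k_assoc = association_from_kd(truth.kd_M, eps1, eps2, path)
    return ComplexModelParams(
        a_ho1_ref=free1 * eps1 * path,
        a_cpr_ref=free2 * eps2 * path,
        k_assoc=k_assoc,
        baseline=truth.baseline,
    )


def simulate_equilibrium_scan(truth: EquilibriumTruth, seed: int = 0) -> SimulatedScan:
    """One noisy radial scan plus its exact generating parameters."""
    params = generating_params(truth)
    lo, hi = truth.conditions.radial_window_cm
    n = int(round((hi - lo) / truth.radial_step_cm)) + 1
    radii = lo + truth.radial_step_cm * np.arange(n)
    clean = predict_profile(params, truth.ho1, truth.cpr, truth.conditions, radii)
    warnings = []
    if float(np.max(clean)) > truth.linearity_cap_AU:
        warnings.append(
            f"predicted absorbance {np.max(clean):.3g} AU exceeds the optical "
            f"linearity cap {truth.linearity_cap_AU} AU"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5ED0]))
    noisy = clean + rng.normal(0.0, truth.noise_sd, size=n)
    profile = RadialProfile(radii, noisy, truth.wavelength)
    return SimulatedScan(profile=profile, params=params, truth=truth, warnings=warnings)


@dataclass(frozen=True)
class KineticTruth:
    """Ground truth for a set of CO-binding reduction traces.

    ``rate_constant_per_min`` is the apparent second-order reduction rate
    constant (slope of initial rate vs reductase concentration); the
    per-trace observed rate is ``k_obs = rate_constant · [reductase] /
    [heme–HO-1]`` (pseudo-first-order in the heme pool).
    ``rate_noise_frac`` perturbs each trace's k_obs multiplicatively
    (lognormal-free Gaussian on the rate), emulating run-to-run scatter of
    the initial rates; ``absorbance_noise_sd`` adds per-point read noise.
    """

    rate_constant_per_min: float = 122.0
    concentrations_uM: tuple[float, ...] = (0.010, 0.020, 0.030)
    heme_conc_uM: float = 4.3
    constants: SpectroConstants = field(default_factory=SpectroConstants)
    a0_406: float = 0.60
    a0_420: float = 0.25
    rate_noise_frac: float = 0.05
    absorbance_noise_sd: float = 0.001
    dt_s: float = 0.2
    duration_s: float = 120.0

    def __post_init__(self):
        if self.rate_constant_per_min < 0:
            raise ValidationError("rate_constant_per_min must be >= 0")
        if any(c < 0 for c in self.concentrations_uM):
            raise ValidationError("concentrations must be >= 0")
        if self.heme_conc_uM <= 0:
            raise ValidationError("heme_conc_uM must be > 0")
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise ValidationError("time grid must be positive")


def simulate_reduction_traces(truth: KineticTruth, seed: int = 0) -> list[TimeTrace]:
    """One two-channel trace per reductase concentration.

    The 406 nm channel falls and the 420 nm channel rises with exponential
    approach; the amplitude ratio |ΔA420/ΔA406| equals Δε420/Δε406 by
    construction (both report the same heme pool through their Δε).
    """
    times = np.arange(0.0, truth.duration_s + 0.5 * truth.dt_s, truth.dt_s)
    if times.size < 5 or np.any(times < 0):
        raise ValidationError("time grid must be non-negative with >= 5 points")
    heme_mM = truth.heme_conc_uM * 1e-3
    d_a406 = truth.constants.delta_eps_406 * heme_mM  # 1 cm path
    d_a420 = truth.constants.delta_eps_420 * heme_mM
    traces = []
    for i, conc in enumerate(truth.concentrations_uM):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0, i]))
        k_obs_min = truth.rate_constant_per_min * conc / truth.heme_conc_uM
        if truth.rate_noise_frac > 0:
            k_obs_min *= 1.0 + truth.rate_noise_frac * rng.standard_normal()
            k_obs_min = max(k_obs_min, 0.0)
        k_obs_s = k_obs_min / 60.0
        decay = np.exp(-k_obs_s * times)
        a406 = (truth.a0_406 - d_a406) + d_a406 * decay
        a420 = (truth.a0_420 + d_a420) - d_a420 * decay
        if truth.absorbance_noise_sd > 0:
            a406 = a406 + rng.normal(0, truth.absorbance_noise_sd, times.size)
            a420 = a420 + rng.normal(0, truth.absorbance_noise_sd, times.size)
        traces.append(
            TimeTrace(
                times=times,
                channels={406.0: a406, 420.0: a420},
                enzyme_conc_uM=conc,
                label=f"reduction_{conc * 1000:g}nM",
            )
        )
    return traces


def simulate_assay_trace(
    turnover_per_min: float,
    ho1_conc_uM: float,
    eps_bilirubin_468: float,
    duration_s: float = 600.0,
    noise_sd: float = 0.002,
    seed: int = 0,
    substrate_uM: float | None = 40.0,
    dt_s: float = 1.0,
    path_length_cm: float = 1.0,
) -> TimeTrace:
    """Bilirubin-formation trace at 468 nm: linear rise, then a plateau.

    The initial slope is ``turnover · [HO-1] · ε468 · l`` (per minute); the
    rise plateaus once the substrate pool (``substrate_uM``, the heme
    loading) is exhausted.  ``turnover = 0`` gives a flat trace.
    """
    if turnover_per_min < 0:
        raise ValidationError("turnover_per_min must be >= 0")
    if ho1_conc_uM <= 0 or eps_bilirubin_468 <= 0:
        raise ValidationError("ho1_conc_uM and eps_bilirubin_468 must be > 0")
    times = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    rate_uM_min = turnover_per_min * ho1_conc_uM
    produced = rate_uM_min * times / 60.0
    if substrate_uM is not None:
        produced = np.minimum(produced, substrate_uM)
    a468 = produced * 1e-3 * eps_bilirubin_468 * path_length_cm
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB1]))
    if noise_sd > 0:
        a468 = a468 + rng.normal(0.0, noise_sd, times.size)
    return TimeTrace(
        times=times,
        channels={468.0: a468},
        enzyme_conc_uM=ho1_conc_uM,
        label="bilirubin_assay",
    )


def with_kd(truth: EquilibriumTruth, kd_M: float) -> EquilibriumTruth:
    """Copy of ``truth`` with a different dissociation constant."""
    return replace(truth, kd_M=kd_M)
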