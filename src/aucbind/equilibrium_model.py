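"""Forward models for two-protein sedimentation-equilibrium absorbance profiles.

At sedimentation equilibrium each ideal species distributes radially as an
exponential in r², with steepness set by its buoyant molar mass::

    A_i(r) = A_i(r0) * exp( M_i * H_i * (r² − r0²) )

where ``H = (1 − v̄ρ) ω² / (2RT)`` is the per-mass buoyancy coefficient
(v̄ partial specific volume, ρ solvent density, ω rotor angular velocity).
For a hetero-associating pair P + Q ⇌ PQ, the 1:1 complex contributes a third
exponential whose buoyant mass is the sum of the monomer buoyant masses and
whose reference-radius amplitude is tied to the monomer amplitudes by the
association constant on the absorbance scale,
``K = A_PQ(r0) / (A_P(r0) · A_Q(r0))``.  K converts to a molar dissociation
constant through the molar extinction coefficients and the optical path
length::

    Kd = (ε_P + ε_Q) / (ε_P · ε_Q · l) · 1/K

Inputs are accepted in conventional AUC units (rpm, cm, g/mL, mL/g, g/mol);
the buoyancy coefficient is computed in SI and reported in cm⁻² per (g/mol)
so that exponents are dimensionless with radii in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: molar gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.314462618

#: guard against meaningless exponents (bad masses / radii); see docs/methods.md
DEFAULT_EXPONENT_CAP = 50.0


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class Species:
    """A sedimenting protein species.

    Parameters
    ----------
    name:
        Label used in configs and reports.
    molar_mass:
        g/mol.
    partial_specific_volume:
        v̄ in mL/g (equivalently cm³/g).
    extinction:
        Mapping wavelength (nm) → molar extinction coefficient in M⁻¹cm⁻¹.
        Config files list mM⁻¹cm⁻¹ (the conventional printed unit); the
        config loader multiplies by 1000 before constructing a Species.
    """

    name: str
    molar_mass: float
    partial_specific_volume: float
    extinction: dict[float, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (_require_finite("molar_mass", self.molar_mass) > 0):
            raise ValidationError(f"molar_mass must be > 0, got {self.molar_mass}")
        vbar = _require_finite("partial_specific_volume", self.partial_specific_volume)
        if not (0 < vbar < 2):
            raise ValidationError(
                f"partial_specific_volume must be in (0, 2) mL/g, got {vbar}"
            )
        for wl, eps in self.extinction.items():
            if not (_require_finite(f"extinction[{wl}]", eps) > 0):
                raise ValidationError(f"extinction at {wl} nm must be > 0, got {eps}")

    def extinction_at(self, wavelength: float) -> float:
        """Molar extinction coefficient (M⁻¹cm⁻¹) at ``wavelength`` nm."""
        try:
            return self.extinction[wavelength]
        except KeyError:
            raise ValidationError(
                f"species {self.name!r} has no extinction coefficient at "
                f"{wavelength} nm (known: {sorted(self.extinction)})"
            ) from None


@dataclass(frozen=True)
class RunConditions:
    """Rotor, solvent and optical geometry for one equilibrium run."""

    rotor_speed_rpm: float
    temperature_K: float
    solvent_density: float  # g/mL
    path_length_cm: float
    reference_radius_cm: float
    radial_window_cm: tuple[float, float]

    def __post_init__(self):
        if _require_finite("rotor_speed_rpm", self.rotor_speed_rpm) < 0:
            raise ValidationError("rotor_speed_rpm must be >= 0")
        if _require_finite("temperature_K", self.temperature_K) <= 0:
            raise ValidationError("temperature_K must be > 0")
        if _require_finite("solvent_density", self.solvent_density) <= 0:
            raise ValidationError("solvent_density must be > 0")
        if _require_finite("path_length_cm", self.path_length_cm) <= 0:
            raise ValidationError("path_length_cm must be > 0")
        r_min, r_max = (float(x) for x in self.radial_window_cm)
        r0 = _require_finite("reference_radius_cm", self.reference_radius_cm)
        if not (0 < r_min < r_max):
            raise ValidationError(f"invalid radial window {self.radial_window_cm}")
        if not (r_min < r0 <= r_max):
            raise ValidationError(
                f"reference radius {r0} cm must lie inside the radial window "
                f"({r_min}, {r_max}]"
            )

    @property
    def angular_velocity(self) -> float:
        """rad/s."""
        return self.rotor_speed_rpm * 2.0 * math.pi / 60.0


@dataclass(frozen=True)
class RadialProfile:
    """One equilibrium scan: paired radii (cm) and absorbances (AU).

    Radii are sorted on construction; duplicates are rejected.  File readers
    additionally reject non-monotone input (see :mod:`aucbind.io`).
    """

    radii: np.ndarray
    absorbances: np.ndarray
    wavelength: float

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if r.ndim != 1 or a.ndim != 1 or r.size != a.size:
            raise ValidationError(
                f"radii and absorbances must be 1-D of equal length "
                f"(got {r.shape} vs {a.shape})"
            )
        if not (np.isfinite(r).all() and np.isfinite(a).all()):
            raise ValidationError("radii and absorbances must be finite")
        order = np.argsort(r, kind="stable")
        r, a = r[order], a[order]
        if np.any(np.diff(r) <= 0):
            raise ValidationError("radii contain duplicates")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "absorbances", a)
        object.__setattr__(self, "wavelength", float(self.wavelength))

    def __len__(self) -> int:
        return self.radii.size


@dataclass(frozen=True)
class ComplexModelParams:
    """Parameters of the hetero-association radial model.

    ``k_assoc`` is the association constant on the absorbance scale (AU⁻¹);
    fixing it to 0 yields the non-complexed (two independent monomers) model.
    ``baseline`` is the small radially-constant offset δ.
    """

    a_ho1_ref: float
    a_cpr_ref: float
    k_assoc: float
    baseline: float = 0.0

    def __post_init__(self):
        for name in ("a_ho1_ref", "a_cpr_ref", "k_assoc"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        _require_finite("baseline", self.baseline)


def buoyancy_coefficient(species: Species, conditions: RunConditions) -> float:
    """Per-mass buoyancy coefficient H = (1 − v̄ρ)ω²/2RT, in cm⁻² per (g/mol).

    Multiplied by the molar mass it gives the radial exponent coefficient
    M·H such that the species profile is ``exp(M·H·(r² − r0²))`` with radii
    in cm.  Negative H (flotation, v̄ρ > 1) is permitted; H is 0 for a
    neutrally buoyant species or a resting rotor.
    """
    vbar_rho = species.partial_specific_volume * conditions.solvent_density
    omega = conditions.angular_velocity
    h_si = (1.0 - vbar_rho) * omega**2 / (2.0 * GAS_CONSTANT * conditions.temperature_K)
    # per (kg/mol) per m² → per (g/mol) per cm²
    return h_si * 1e-3 * 1e-4


def _mass_exponents(
    ho1: Species, cpr: Species, conditions: RunConditions
) -> tuple[float, float]:
    """(M·H)_HO-1 and (M·H)_CPR in cm⁻²."""
    return (
        ho1.molar_mass * buoyancy_coefficient(ho1, conditions),
        cpr.molar_mass * buoyancy_coefficient(cpr, conditions),
    )


def predict_profile(
    params: ComplexModelParams,
    ho1: Species,
    cpr: Species,
    conditions: RunConditions,
    radii,
    exponent_cap: float = DEFAULT_EXPONENT_CAP,
) -> np.ndarray:
    """Evaluate the hetero-association radial model at ``radii`` (cm).

    Returns the total absorbance: the two monomer exponentials, a complex
    term with amplitude ``k_assoc·a_ho1_ref·a_cpr_ref`` and buoyant-mass
    exponent equal to the sum of the monomer exponents, plus the baseline.
    With ``k_assoc = 0`` this is exactly the non-complexed model.
    """
    r = np.asarray(radii, dtype=float)
    if not np.isfinite(r).all() or np.any(r <= 0):
        raise ValidationError("radii must be finite and > 0")
    mh1, mh2 = _mass_exponents(ho1, cpr, conditions)
    xi = r**2 - conditions.reference_radius_cm**2
    worst = np.max(np.abs(xi)) if xi.size else 0.0
    for label, mh in (("HO-1", mh1), ("CPR", mh2), ("complex", mh1 + mh2)):
        if abs(mh) * worst > exponent_cap:
            bad = r[np.argmax(np.abs(xi))]
            raise ValidationError(
                f"radial exponent for the {label} term exceeds the cap "
                f"{exponent_cap} at r = {bad:.4f} cm "
                f"(|{mh:.4g} cm⁻² × {worst:.4g} cm²|); check masses, rotor "
                f"speed and radial window"
            )
    e1 = np.exp(mh1 * xi)
    e2 = np.exp(mh2 * xi)
    return (
        params.a_ho1_ref * e1
        + params.a_cpr_ref * e2
        + params.k_assoc * params.a_ho1_ref * params.a_cpr_ref * e1 * e2
        + params.baseline
    )


def kd_from_association(
    k_assoc: float, eps_ho1: float, eps_cpr: float, path_length_cm: float
) -> float:
    """Convert an absorbance-scale association constant to a molar Kd.

    ``Kd = ((ε_HO-1 + ε_CPR) / (ε_HO-1 · ε_CPR · l)) · (1 / K)`` with ε in
    M⁻¹cm⁻¹ and l in cm.  ``k_assoc = 0`` means no detectable association and
    returns ``math.inf`` (not an overflow).
    """
    for name, v in (
        ("eps_ho1", eps_ho1),
        ("eps_cpr", eps_cpr),
        ("path_length_cm", path_length_cm),
    ):
        if not (_require_finite(name, v) > 0):
            raise ValidationError(f"{name} must be > 0, got {v}")
    k_assoc = _require_finite("k_assoc", k_assoc)
    if k_assoc < 0:
        raise ValidationError(f"k_assoc must be >= 0, got {k_assoc}")
    if k_assoc == 0.0:
        return math.inf
    return (eps_ho1 + eps_cpr) / (eps_ho1 * eps_cpr * path_length_cm) / k_assoc


def association_from_kd(
    kd: float, eps_ho1: float, eps_cpr: float, path_length_cm: float
) -> float:
    """Inverse of :func:`kd_from_association`; ``kd = inf`` maps to 0."""
    if math.isinf(kd):
        return 0.0
    if not (_require_finite("kd", kd) > 0):
        raise ValidationError(f"kd must be > 0, got {kd}")
    return (eps_ho1 + eps_cpr) / (eps_ho1 * eps_cpr * path_length_cm) / kd
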