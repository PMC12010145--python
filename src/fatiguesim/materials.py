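"""Local constitutive laws for the cycle-domain fatigue damage model.

The material is small-strain isotropic linear elasticity degraded by a scalar
damage variable ``d`` through the stiffness factor ``f(d) = exp(-d)``, with
optional von Mises viscoplasticity and isotropic hardening.  All evolution laws
are written in the cycle coordinate ``N = omega * t``: a "rate" here is a
per-cycle rate (denoted with a tilde in the continuum formulation), related to
the physical time rate by ``x_dot = omega * x_tilde``.

Symmetric second-order tensors use the 6-component Voigt convention

    strain = [e11, e22, e33, 2*e23, 2*e13, 2*e12]   (engineering shear)
    stress = [s11, s22, s33, s23,  s13,  s12]

so that ``stress @ strain`` is twice the elastic energy density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaterialParams",
    "InternalState",
    "LocalFields",
    "isotropic_stiffness",
    "damage_stiffness_function",
    "effective_elastic_energy",
    "stress",
    "damage_driving_force",
    "damage_rate",
    "plastic_flow_rate",
    "dissipation_increment",
    "uniaxial_strain",
    "deviatoric_norm",
]

# Index helpers for the Voigt convention.
_NORMAL = slice(0, 3)
_SHEAR = slice(3, 6)

#: Tolerance on trace(eps_p) = 0 (plastic incompressibility).
TRACE_TOL = 1e-12


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive constants of the elastic–damage–viscoplastic model.

    Defaults are the reference parameter set for additively manufactured,
    heat-treated Ti-6Al-4V cycled at 10 Hz.

    Parameters
    ----------
    youngs_modulus : float
        Tensile Young's modulus E in Pa.
    poisson_ratio : float
        Poisson's ratio, in (0, 0.5).
    beta_regularization : float
        Gradient-regularization parameter beta in N (energy density times
        length squared); penalizes spatial gradients of f(d).
    eta_d : float
        Damage viscosity eta_d in Pa (per-time damage rate scale).
    eta_p : float
        Plastic viscosity eta_p in Pa.
    r_d : float
        Damage dissipation threshold r_d in Pa; driving forces below it
        produce no damage (endurance behaviour).
    r_p : float
        Plastic dissipation threshold r_p in Pa (initial yield radius of the
        deviatoric over-stress rule).
    k_hardening : float
        Isotropic hardening modulus k in Pa.
    omega : float
        Loading frequency in cycles/s; the cycle coordinate is N = omega * t.
    plasticity_enabled : bool
        If False (default) the plastic internal variables are frozen and the
        model is purely elastic–damage.
    """

    youngs_modulus: float = 110e9
    poisson_ratio: float = 0.32
    beta_regularization: float = 0.1
    eta_d: float = 0.2e6
    eta_p: float = 100e9
    r_d: float = 6.0
    r_p: float = 100.0
    k_hardening: float = 80.0
    omega: float = 10.0
    plasticity_enabled: bool = False

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError(f"youngs_modulus must be > 0, got {self.youngs_modulus}")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError(f"poisson_ratio must be in (0, 0.5), got {self.poisson_ratio}")
        for name in ("beta_regularization", "eta_d", "eta_p", "r_d", "r_p", "k_hardening"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")

    @property
    def eta_d_omega(self) -> float:
        """Product eta_d * omega (Pa·cycles): the damage time-scale in N."""
        return self.eta_d * self.omega

    def with_eta_d_omega(self, eta_d_omega: float) -> "MaterialParams":
        """Return a copy whose eta_d realizes the given eta_d*omega at fixed omega."""
        return replace(self, eta_d=eta_d_omega / self.omega)

    def stiffness(self) -> np.ndarray:
        return isotropic_stiffness(self.youngs_modulus, self.poisson_ratio)


def _zero_voigt() -> np.ndarray:
    return np.zeros(6)


@dataclass
class InternalState:
    """Internal variables nu = {d, eps_p, h} of one material point.

    ``stiffness_factor`` caches f = exp(-d) and is kept consistent by
    :meth:`add_damage`; damage is irreversible (nondecreasing).
    """

    damage: float = 0.0
    plastic_strain: np.ndarray = field(default_factory=_zero_voigt)
    hardening: float = 0.0
    stiffness_factor: float = 1.0

    def __post_init__(self) -> None:
        self.plastic_strain = np.asarray(self.plastic_strain, dtype=float)
        if self.plastic_strain.shape != (6,):
            raise ValueError("plastic_strain must be a 6-component Voigt vector")
        if self.damage < 0:
            raise ValueError(f"damage must be >= 0, got {self.damage}")
        tr = float(self.plastic_strain[_NORMAL].sum())
        if abs(tr) > 1e-9:
            raise ValueError(f"plastic strain must be trace-free, got trace {tr}")
        self.stiffness_factor = damage_stiffness_function(self.damage)

    def add_damage(self, delta: float) -> None:
        """Accumulate damage (delta >= 0) and refresh the cached f."""
        if delta < -TRACE_TOL:
            raise ValueError("damage is irreversible; negative increment rejected")
        self.damage += max(delta, 0.0)
        self.stiffness_factor = damage_stiffness_function(self.damage)

    def copy(self) -> "InternalState":
        return InternalState(
            damage=self.damage,
            plastic_strain=self.plastic_strain.copy(),
            hardening=self.hardening,
        )


@dataclass
class LocalFields:
    """Kinematic/energetic fields at a material point for one evaluation.

    ``laplacian_f`` is the discrete Laplacian of the stiffness-factor field at
    the point, in 1/m^2; it is supplied by the finite-element layer and is zero
    for isolated material-point runs.
    """

    total_strain: np.ndarray
    stress: np.ndarray
    psi0: float
    laplacian_f: float = 0.0

    def __post_init__(self) -> None:
        if self.psi0 < 0:
            raise ValueError("psi0 must be >= 0")


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """Isotropic linear-elastic stiffness, 6x6 in Voigt convention.

    Raises ValueError for non-physical inputs (E <= 0 or nu outside (0, 0.5);
    nu = 0 is admitted for convenience in analytic checks).
    """
    if E <= 0:
        raise ValueError(f"Young's modulus must be > 0, got {E}")
    if not (0 <= nu < 0.5):
        raise ValueError(f"Poisson ratio must be in [0, 0.5), got {nu}")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[_NORMAL, _NORMAL] = lam
    np.fill_diagonal(C[:3, :3], lam + 2 * mu)
    C[3, 3] = C[4, 4] = C[5, 5] = mu
    return C


def damage_stiffness_function(d: float) -> float:
    """Monotonically decreasing stiffness factor f(d) = exp(-d), f(0) = 1."""
    if d < 0:
        raise ValueError(f"damage must be >= 0, got {d}")
    return float(np.exp(-d))


def effective_elastic_energy(
    total_strain: np.ndarray, plastic_strain: np.ndarray, stiffness: np.ndarray
) -> float:
    """Undamaged elastic energy density psi0 = 1/2 (e - e_p) : C : (e - e_p), Pa."""
    eps_el = np.asarray(total_strain, dtype=float) - np.asarray(plastic_strain, dtype=float)
    if eps_el.shape != (6,):
        raise ValueError("strain tensors must be 6-component Voigt vectors")
    return float(0.5 * eps_el @ stiffness @ eps_el)


def stress(
    total_strain: np.ndarray, state: InternalState, stiffness: np.ndarray
) -> np.ndarray:
    """Damage-degraded stress sigma = f(d) * C : (e - e_p), Voigt, Pa."""
    eps_el = np.asarray(total_strain, dtype=float) - state.plastic_strain
    return state.stiffness_factor * (stiffness @ eps_el)


def damage_driving_force(f: float, psi0: float, laplacian_f: float, beta: float) -> float:
    """Driving force q (Pa) conjugate to damage.

    q = f * (psi0 - beta * laplacian_f).  The gradient term is the variational
    derivative of the regularization energy 1/2 beta |grad f|^2: at a damage
    hotspot (local minimum of f, positive Laplacian) it *reduces* the driving
    force, diffusing damage away from sharp localizations.  For a homogeneous
    point laplacian_f = 0 and q = f * psi0.
    """
    if not 0 < f <= 1:
        raise ValueError(f"stiffness factor must be in (0, 1], got {f}")
    return f * (psi0 - beta * laplacian_f)


def damage_rate(q: float, params: MaterialParams) -> float:
    """Per-cycle damage rate d_tilde = max(0, q - r_d) / (eta_d * omega).

    Viscous over-force rule: below the threshold r_d the rate is exactly zero
    (endurance domain); above it the rate is linear in the over-force.
    """
    if not np.isfinite(q):
        raise ValueError("driving force must be finite")
    over = q - params.r_d
    if over <= 0:
        return 0.0
    denom = params.eta_d * params.omega
    if denom == 0:
        raise ZeroDivisionError("eta_d * omega = 0 with positive over-force: rate undefined")
    return over / denom


def deviatoric_norm(sigma: np.ndarray) -> float:
    """Frobenius norm of the deviatoric part of a Voigt stress vector."""
    sigma = np.asarray(sigma, dtype=float)
    mean = sigma[_NORMAL].sum() / 3.0
    dev_normal = sigma[_NORMAL] - mean
    # off-diagonal components appear twice in the full tensor
    return float(np.sqrt(np.sum(dev_normal**2) + 2.0 * np.sum(sigma[_SHEAR] ** 2)))


def plastic_flow_rate(
    sigma: np.ndarray, state: InternalState, params: MaterialParams
) -> tuple[np.ndarray, float]:
    """Per-cycle plastic strain rate tensor and hardening rate.

    Deviatoric over-stress (Perzyna-type) rule with isotropic hardening:
    flow occurs only when ||dev sigma|| exceeds r_p + k*h; the flow direction
    is dev sigma / ||dev sigma|| (trace-free by construction, enforcing plastic
    volume conservation), and the magnitude is the over-stress divided by
    eta_p * omega.  The hardening rate equals the accumulated flow magnitude.
    """
    if not params.plasticity_enabled:
        return np.zeros(6), 0.0
    sigma = np.asarray(sigma, dtype=float)
    s_norm = deviatoric_norm(sigma)
    yield_radius = params.r_p + params.k_hardening * state.hardening
    over = s_norm - yield_radius
    if over <= 0 or s_norm == 0:
        return np.zeros(6), 0.0
    mean = sigma[_NORMAL].sum() / 3.0
    direction = sigma.copy()
    direction[_NORMAL] -= mean
    direction /= s_norm
    magnitude = over / (params.eta_p * params.omega)
    rate = magnitude * direction
    # convert tensor direction to strain-type Voigt (engineering shear doubles)
    rate[_SHEAR] *= 2.0
    return rate, magnitude


def dissipation_increment(
    d_tilde: float, eps_p_tilde: np.ndarray, params: MaterialParams
) -> float:
    """Per-cycle dissipation Delta >= 0 for given per-cycle rates.

    Delta = r_p w ||e_p~|| + 1/2 eta_p w^2 ||e_p~||^2
          + r_d w d~     + 1/2 eta_d w^2 d~^2

    (w = omega).  First-order terms are rate-independent dissipation at the
    thresholds; second-order terms are the viscous contributions.
    """
    w = params.omega
    eps_p_tilde = np.asarray(eps_p_tilde, dtype=float)
    # tensor norm of a strain-type Voigt vector (undo engineering shears)
    p_norm = float(
        np.sqrt(np.sum(eps_p_tilde[_NORMAL] ** 2) + 0.5 * np.sum(eps_p_tilde[_SHEAR] ** 2))
    )
    return (
        params.r_p * w * p_norm
        + 0.5 * params.eta_p * w**2 * p_norm**2
        + params.r_d * w * d_tilde
        + 0.5 * params.eta_d * w**2 * d_tilde**2
    )


def uniaxial_strain(eps_axial: float, nu: float) -> np.ndarray:
    """Voigt strain for a uniaxial-stress state with axial strain ``eps_axial``.

    Lateral strains are -nu * eps_axial, so Hooke's law returns a stress with
    only the axial component nonzero (sigma_axial = E * eps_axial).
    """
    return np.array([eps_axial, -nu * eps_axial, -nu * eps_axial, 0.0, 0.0, 0.0])
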