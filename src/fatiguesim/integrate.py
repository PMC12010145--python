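"""Cycle-domain integration of the damage/plasticity evolution at a material point.

High-cycle fatigue makes cycle-by-cycle time stepping intractable, so the
internal variables are integrated directly in the cycle coordinate N = omega*t
("time-to-cycle transformation").  One solver step then spans many load cycles;
the step size is adapted so the damage increment per step stays below a cap,
which yields the cycle-jump speedup that makes lifetimes of 10^6+ cycles cheap.

Two control modes are supported for the isolated material point (a 1-D
uniaxial-stress idealization):

* ``strain``: the total axial strain is held at its virgin-state amplitude
  sigma_a / E.  The driving force f*psi0 then decays with damage, so lives are
  long and runout is possible (this mirrors the displacement-held specimen with
  a homogeneous state).
* ``stress``: the axial stress amplitude is held at sigma_a; the elastic strain
  grows as stiffness degrades, the driving force grows like exp(d), and damage
  runs away in finite cycles.

:func:`closed_form_life` provides an independent quadrature oracle for the
elastic–damage case used to verify the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .materials import MaterialParams, damage_rate, damage_stiffness_function

__all__ = [
    "LoadProgram",
    "StepControls",
    "Trajectory",
    "adapt_cycle_increment",
    "step_material_point",
    "simulate_material_point",
    "closed_form_life",
    "RUNOUT",
]

#: Sentinel lifetime for runout (censored) results of the closed-form oracle.
RUNOUT = math.inf

TRAJECTORY_COLUMNS = [
    "N_cycles",
    "damage",
    "stiffness_factor",
    "psi0_pa",
    "reaction",
    "step_dN",
    "status",
]


@dataclass(frozen=True)
class LoadProgram:
    """One constant-amplitude load program.

    ``stress_ratio`` (R = sigma_min/sigma_max) is recorded as metadata only;
    the driving force is amplitude-based and R does not enter the model.
    """

    sigma_a: float
    control_mode: Literal["stress", "strain", "displacement"] = "displacement"
    omega: float | None = None
    stress_ratio: float = -1.0
    max_cycles: float = 1e7

    def __post_init__(self) -> None:
        if self.sigma_a < 0:
            raise ValueError(f"sigma_a must be >= 0, got {self.sigma_a}")
        if self.max_cycles <= 0:
            raise ValueError(f"max_cycles must be > 0, got {self.max_cycles}")


@dataclass(frozen=True)
class StepControls:
    """Adaptive cycle-jump step controls.

    ``delta_d_max`` caps the damage increment of the fastest-evolving point per
    step; ``delta_n_max`` defaults to max_cycles/100 so even a damage-free run
    terminates in ~100 records.  ``scheme`` selects the update: explicit
    forward Euler in N, or semi-implicit (implicit in d for the local ODE) for
    stiff near-failure behaviour.
    """

    delta_d_max: float = 0.01
    delta_n_min: float = 1e-3
    delta_n_max: float | None = None
    failure_fraction: float = 0.1
    sub_step_bisection_tol: float = 1e-9
    scheme: Literal["explicit", "semi-implicit"] = "explicit"
    rate_growth_max: float = 1.2

    def __post_init__(self) -> None:
        if not 0 < self.delta_d_max < 1:
            raise ValueError(f"delta_d_max must be in (0, 1), got {self.delta_d_max}")
        if self.delta_n_max is not None and self.delta_n_min > self.delta_n_max:
            raise ValueError("delta_n_min must be <= delta_n_max")
        if not 0 < self.failure_fraction < 1:
            raise ValueError("failure_fraction must be in (0, 1)")
        if not self.rate_growth_max > 1:
            raise ValueError("rate_growth_max must be > 1")

    def resolved_delta_n_max(self, max_cycles: float) -> float:
        return self.delta_n_max if self.delta_n_max is not None else max_cycles / 100.0


@dataclass
class Trajectory:
    """Recorded evolution of one simulation in the cycle coordinate.

    Records are (N, d, f, psi0, reaction, step dN); ``status`` is one of
    ``failed``, ``runout``, ``diverged``.  ``n_f`` is the failure cycle (None
    unless failed); ``steps`` counts solver steps taken.
    """

    records: list[tuple[float, float, float, float, float, float]] = field(default_factory=list)
    status: str = "running"
    n_f: float | None = None
    steps: int = 0

    def append(self, N, d, f, psi0, reaction, step_dn) -> None:
        if self.records and N < self.records[-1][0] - 1e-12:
            raise ValueError("cycle coordinate must be nondecreasing")
        self.records.append((float(N), float(d), float(f), float(psi0), float(reaction), float(step_dn)))

    @property
    def N(self) -> np.ndarray:
        return np.array([r[0] for r in self.records])

    @property
    def damage(self) -> np.ndarray:
        return np.array([r[1] for r in self.records])

    @property
    def reaction(self) -> np.ndarray:
        return np.array([r[4] for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=TRAJECTORY_COLUMNS[:-1])
        df["status"] = self.status
        return df

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_dataframe().to_csv(fh, index=False)


def adapt_cycle_increment(current_rates, controls: StepControls, max_cycles: float = 1e7) -> float:
    """Cycle-jump step size from the current per-cycle rates.

    dN = clamp(delta_d_max / d_tilde_max, delta_n_min, delta_n_max); if every
    rate is zero the step jumps straight to delta_n_max.
    """
    rates = np.atleast_1d(np.asarray(current_rates, dtype=float))
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    dn_max = controls.resolved_delta_n_max(max_cycles)
    peak = rates.max() if rates.size else 0.0
    if peak <= 0:
        return dn_max
    return float(np.clip(controls.delta_d_max / peak, controls.delta_n_min, dn_max))


def shrink_for_rate_growth(
    dn: float,
    rate: float,
    candidate_rate: float,
    controls: StepControls,
) -> float | None:
    """Step-rejection control: shrink ``dn`` if the rate grew too fast across it.

    Near the endurance threshold the damage rate grows quasi-exponentially
    from a tiny seed while the damage increment stays negligible, so
    damage-increment control alone would jump the whole growth phase in a few
    maximal steps and quantize the lifetime.  If the candidate end-of-step
    rate exceeds ``rate_growth_max`` times the start-of-step rate, the step is
    rejected and retried with a size extrapolated from exponential growth.
    The rule is symmetric: a rate *collapse* by more than the same factor is
    also rejected, which resolves the slow terminal creep toward a stall or a
    near-threshold failure instead of overshooting it.  Returns the reduced
    step, or None if the step is acceptable (or already at the minimum step
    size).
    """
    if rate <= 0 or dn <= controls.delta_n_min:
        return None
    gmax = controls.rate_growth_max
    if candidate_rate <= 0:
        return float(max(0.5 * dn, controls.delta_n_min))
    g = candidate_rate / rate
    if 1.0 / gmax <= g <= gmax:
        return None
    shrunk = dn * math.log(gmax) / abs(math.log(g))
    return float(max(min(shrunk, 0.5 * dn), controls.delta_n_min))


class _PointModel:
    """Closed-form driving force q(d) for the elastic-damage uniaxial point."""

    def __init__(self, load: LoadProgram, params: MaterialParams):
        self.params = params
        self.mode = load.control_mode
        E = params.youngs_modulus
        self.psi0_virgin = load.sigma_a**2 / (2.0 * E)

    def psi0(self, d: float) -> float:
        if self.mode == "stress":
            # elastic strain grows as 1/f at held stress
            return self.psi0_virgin * math.exp(2.0 * d)
        return self.psi0_virgin

    def q(self, d: float) -> float:
        return damage_stiffness_function(d) * self.psi0(d)

    def rate(self, d: float) -> float:
        return damage_rate(self.q(d), self.params)

    def stall_damage(self) -> float:
        """Damage level where the driving force meets the threshold (strain
        control only; the stress-control driving force grows without bound)."""
        if self.mode == "stress" or self.params.r_d <= 0:
            return math.inf
        if self.psi0_virgin <= self.params.r_d:
            return 0.0
        return math.log(self.psi0_virgin / self.params.r_d)

    def reaction(self, d: float) -> float:
        """Axial stress amplitude (Pa) as the material-point reaction proxy."""
        if self.mode == "stress":
            return self.psi0_virgin * 2.0 * self.params.youngs_modulus
        f = damage_stiffness_function(d)
        return f * math.sqrt(2.0 * self.params.youngs_modulus * self.psi0_virgin)


def step_material_point(
    state_d: float,
    model: _PointModel,
    dn: float,
    controls: StepControls,
) -> float:
    """Advance the damage variable of a material point by one cycle step.

    Explicit mode freezes the rate at the step start (d += rate * dN); the
    semi-implicit mode solves d_new = d + dN * rate(d_new) for the local ODE.
    If the driving force crosses the endurance threshold inside an explicit
    step (strain control), the step is clamped at the crossing by bisection so
    the discrete trajectory stalls where the ODE stalls.
    """
    r0 = model.rate(state_d)
    if r0 <= 0:
        return state_d
    if controls.scheme == "explicit":
        d_new = state_d + r0 * dn
        if model.rate(d_new) <= 0.0 and model.mode != "stress":
            # stalled inside the step: find where q(d) = r_d
            lo, hi = state_d, d_new
            g = lambda d: model.q(d) - model.params.r_d
            if g(hi) < 0 < g(lo):
                d_new = brentq(g, lo, hi, xtol=controls.sub_step_bisection_tol)
        return d_new
    # semi-implicit: bracket the root of x - d - dN*rate(x)
    g = lambda x: x - state_d - dn * model.rate(x)
    hi = state_d + r0 * dn
    for _ in range(200):
        if g(hi) >= 0:
            break
        hi = state_d + 2.0 * (hi - state_d)
    else:
        raise FloatingPointError("semi-implicit update failed to bracket")
    if hi == state_d:
        return state_d
    return brentq(g, state_d, hi, xtol=controls.sub_step_bisection_tol)


def simulate_material_point(
    load: LoadProgram,
    params: MaterialParams,
    controls: StepControls | None = None,
) -> Trajectory:
    """Integrate the elastic–damage material point to failure or runout.

    Failure mirrors the structural reaction-force criterion: under a held
    displacement the reaction is proportional to f, so the point fails when
    f <= failure_fraction, i.e. at d* = -ln(failure_fraction).  Budget
    exhaustion yields a ``runout`` trajectory, not an exception.
    """
    controls = controls or StepControls()
    if load.control_mode == "displacement":
        load = LoadProgram(
            sigma_a=load.sigma_a,
            control_mode="strain",
            omega=load.omega,
            stress_ratio=load.stress_ratio,
            max_cycles=load.max_cycles,
        )
    model = _PointModel(load, params)
    d_star = -math.log(controls.failure_fraction)
    traj = Trajectory()
    N, d = 0.0, 0.0
    traj.append(N, d, 1.0, model.psi0(0.0), model.reaction(0.0), 0.0)
    while N < load.max_cycles:
        r = model.rate(d)
        # runout shortcuts: the rate is (or will become) zero before the
        # failure damage is reached, or the whole remaining budget cannot
        # advance the damage by a meaningful fraction of one control increment
        if (
            r <= 0
            or model.stall_damage() <= d_star
            or r * (load.max_cycles - N) < 1e-6 * controls.delta_d_max
        ):
            N = load.max_cycles
            traj.append(N, d, damage_stiffness_function(d), model.psi0(d), model.reaction(d), 0.0)
            traj.status = "runout"
            traj.steps = len(traj.records) - 1
            return traj
        dn = adapt_cycle_increment(r, controls, load.max_cycles)
        dn = min(dn, load.max_cycles - N)
        # step rejection: keep the per-step rate growth bounded
        for _ in range(200):
            d_new = step_material_point(d, model, dn, controls)
            shrunk = shrink_for_rate_growth(dn, r, model.rate(min(d_new, d_star)), controls)
            if shrunk is None:
                break
            dn = shrunk
        if d_new >= d_star:
            # locate the failure crossing inside the step
            if controls.scheme == "explicit":
                dn_cross = (d_star - d) / r  # rate frozen in step: exact
            else:
                dn_cross = dn * (d_star - d) / max(d_new - d, 1e-300)
            N += dn_cross
            d = d_star
            traj.append(N, d, damage_stiffness_function(d), model.psi0(d), model.reaction(d), dn_cross)
            traj.status = "failed"
            traj.n_f = N
            traj.steps = len(traj.records) - 1
            return traj
        N += dn
        d = d_new
        traj.append(N, d, damage_stiffness_function(d), model.psi0(d), model.reaction(d), dn)
    traj.status = "runout"
    traj.steps = len(traj.records) - 1
    return traj


def closed_form_life(
    load: LoadProgram,
    params: MaterialParams,
    failure_damage: float | None = None,
) -> float:
    """Quadrature oracle for the elastic–damage material-point lifetime.

    Separating the local damage ODE gives

    * strain control:  N_f = eta_d*w * integral_0^d* dd / (psi0 e^{-d} - r_d)
    * stress control:  N_f = eta_d*w * integral_0^d* dd / (psi0 e^{+d} - r_d)

    with psi0 = sigma_a^2 / (2E) at the virgin state.  Returns ``RUNOUT``
    (inf) when the integrand loses positivity on [0, d*] (endurance/stall).
    Evaluated by adaptive quadrature, independent of the stepping engine.
    """
    if failure_damage is None:
        failure_damage = math.log(10.0)
    E = params.youngs_modulus
    psi0 = load.sigma_a**2 / (2.0 * E)
    r_d = params.r_d
    scale = params.eta_d * params.omega
    mode = "stress" if load.control_mode == "stress" else "strain"
    sign = 1.0 if mode == "stress" else -1.0

    def denom(d: float) -> float:
        return psi0 * math.exp(sign * d) - r_d

    d_min = 0.0 if mode == "stress" else failure_damage
    if denom(d_min) <= 0:
        return RUNOUT
    val, _ = quad(lambda d: 1.0 / denom(d), 0.0, failure_damage, limit=200)
    return scale * val
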