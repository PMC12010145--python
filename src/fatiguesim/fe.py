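"""1-D gradient-damage finite-element engine for the hourglass bar.

The 3-D hourglass specimen is idealized as an axial bar of variable
cross-section A(x), discretized with 2-node linear elements.  Internal
variables (damage, plastic strain, hardening) live on elements; the stiffness
factor f is projected to nodes to evaluate the discrete Laplacian that feeds
the gradient regularization term.  The fatigue loop is staggered: at frozen
internal state the bar is linear elastic, so each cycle step costs one
tridiagonal solve, followed by an explicit cycle-jump update of the internal
variables.

Failure of the specimen is a 10% drop of the reaction-force amplitude at the
prescribed-displacement boundary, mirroring the reaction criterion used to
define the failure cycle N_f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solveh_banded

from .integrate import (
    LoadProgram,
    StepControls,
    Trajectory,
    adapt_cycle_increment,
    shrink_for_rate_growth,
)
from .materials import MaterialParams
from .specimen import AreaProfile

__all__ = [
    "Mesh",
    "FieldState",
    "build_bar_mesh",
    "solve_equilibrium",
    "project_f_to_nodes",
    "discrete_laplacian_f",
    "simulate_specimen",
]

_SQ23 = math.sqrt(2.0 / 3.0)


@dataclass(frozen=True)
class Mesh:
    """Uniform 1-D bar mesh: node coordinates, element areas, boundary nodes.

    The bottom node (index 0) is fixed; the top node (index -1) carries the
    prescribed displacement.
    """

    nodes: np.ndarray          # (n+1,) axial coordinates, m, strictly increasing
    areas: np.ndarray          # (n,) element cross-section areas, m^2

    def __post_init__(self) -> None:
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("node coordinates must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("element areas must be > 0")
        if len(self.areas) != len(self.nodes) - 1:
            raise ValueError("need exactly one area per element")

    @property
    def n_elements(self) -> int:
        return len(self.areas)

    @property
    def h(self) -> np.ndarray:
        return np.diff(self.nodes)

    @property
    def length(self) -> float:
        return float(self.nodes[-1] - self.nodes[0])

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.nodes[:-1] + self.nodes[1:])

    def to_dataframes(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(node table, element table) for CSV export."""
        nodes = pd.DataFrame({"node": np.arange(len(self.nodes)), "x_m": self.nodes})
        elems = pd.DataFrame(
            {
                "element": np.arange(self.n_elements),
                "x_mid_m": self.midpoints,
                "area_m2": self.areas,
            }
        )
        return nodes, elems


@dataclass
class FieldState:
    """Per-element internal variables and the last computed nodal fields."""

    damage: np.ndarray
    plastic_strain: np.ndarray     # axial plastic strain per element
    hardening: np.ndarray
    displacements: np.ndarray | None = None
    nodal_f: np.ndarray | None = None
    psi0: np.ndarray | None = None
    laplacian_f: np.ndarray | None = None

    @classmethod
    def virgin(cls, n_elements: int) -> "FieldState":
        return cls(
            damage=np.zeros(n_elements),
            plastic_strain=np.zeros(n_elements),
            hardening=np.zeros(n_elements),
        )

    @property
    def stiffness_factor(self) -> np.ndarray:
        return np.exp(-self.damage)


def build_bar_mesh(profile: AreaProfile, n_elements: int) -> Mesh:
    """Uniform axial subdivision with midpoint-sampled element areas."""
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    nodes = np.linspace(0.0, profile.total_length, n_elements + 1)
    mids = 0.5 * (nodes[:-1] + nodes[1:])
    areas = np.asarray(profile.area(mids), dtype=float)
    if np.any(areas <= 0):
        raise ValueError("profile produced non-positive element areas")
    return Mesh(nodes=nodes, areas=areas)


def solve_equilibrium(
    mesh: Mesh,
    f_elements: np.ndarray,
    top_displacement: float,
    E: float,
    plastic_strain: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Linear equilibrium of the damage-degraded bar at a held end displacement.

    Element stiffnesses are k_e = f_e E A_e / h_e; the bottom node is fixed and
    the top node prescribed.  Returns the nodal displacements and the reaction
    force (axial force in the bar, tension positive).  Raises
    FloatingPointError when the system is numerically singular (all f -> 0).
    """
    f_elements = np.asarray(f_elements, dtype=float)
    h = mesh.h
    k = f_elements * E * mesh.areas / h
    if not np.all(np.isfinite(k)) or np.all(k <= 0):
        raise FloatingPointError("degenerate stiffness: equilibrium solve failed")
    n_nodes = mesh.n_elements + 1
    # prestress force from plastic strain: element force = k*(du) - s
    s = (
        f_elements * E * mesh.areas * np.asarray(plastic_strain, dtype=float)
        if plastic_strain is not None
        else np.zeros(mesh.n_elements)
    )
    u = np.zeros(n_nodes)
    u[-1] = top_displacement
    if n_nodes > 2:
        diag = k[:-1] + k[1:]
        upper = -k[1:-1]
        ab = np.zeros((2, n_nodes - 2))
        ab[0, 1:] = upper
        ab[1, :] = diag
        rhs = s[1:] - s[:-1]
        rhs[-1] += k[-1] * top_displacement
        try:
            u[1:-1] = solveh_banded(ab, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise FloatingPointError("equilibrium solve failed") from exc
    force = k[0] * (u[1] - u[0]) - s[0]
    if not np.isfinite(force):
        raise FloatingPointError("non-finite reaction force")
    return u, float(force)


def project_f_to_nodes(mesh: Mesh, f_elements: np.ndarray) -> np.ndarray:
    """Volume-weighted projection of element stiffness factors to nodes."""
    w = mesh.areas * mesh.h
    nodal = np.zeros(mesh.n_elements + 1)
    weight = np.zeros_like(nodal)
    np.add.at(nodal, np.arange(mesh.n_elements), w * f_elements)
    np.add.at(nodal, np.arange(1, mesh.n_elements + 1), w * f_elements)
    np.add.at(weight, np.arange(mesh.n_elements), w)
    np.add.at(weight, np.arange(1, mesh.n_elements + 1), w)
    return nodal / weight


def discrete_laplacian_f(mesh: Mesh, nodal_f: np.ndarray) -> np.ndarray:
    """FE-consistent discrete Laplacian of the nodal f field, 1/m^2.

    Lumped-mass inverse of the area-weighted stiffness form:
    (lap f)_i = -(K f)_i / M_i with K_ij = int A phi_i' phi_j' dx and
    M_i = int A phi_i dx (lumped).  Natural (zero-flux) ends: the
    volume-weighted total, sum_i M_i (lap f)_i, is exactly zero for any f.
    On a uniform-area mesh the interior stencil reduces to the standard
    second difference (f_{i-1} - 2 f_i + f_{i+1}) / h^2.
    """
    nodal_f = np.asarray(nodal_f, dtype=float)
    h = mesh.h
    w = mesh.areas / h
    # K f, assembled element-wise: element e contributes w_e*(f_i - f_j) pattern
    df = nodal_f[1:] - nodal_f[:-1]
    Kf = np.zeros_like(nodal_f)
    Kf[:-1] -= w * df
    Kf[1:] += w * df
    M = np.zeros_like(nodal_f)
    vol = mesh.areas * h / 2.0
    M[:-1] += vol
    M[1:] += vol
    return -Kf / M


def _plastic_rates(
    sigma: np.ndarray, hardening: np.ndarray, params: MaterialParams
) -> tuple[np.ndarray, np.ndarray]:
    """Axial plastic strain rate and hardening rate per element (1-D bar).

    For uniaxial stress the deviatoric norm is sqrt(2/3)|sigma| and the axial
    component of the flow direction is sqrt(2/3) sign(sigma).
    """
    if not params.plasticity_enabled:
        z = np.zeros_like(sigma)
        return z, z
    s_norm = _SQ23 * np.abs(sigma)
    over = s_norm - (params.r_p + params.k_hardening * hardening)
    mag = np.maximum(over, 0.0) / (params.eta_p * params.omega)
    return _SQ23 * np.sign(sigma) * mag, mag


def simulate_specimen(
    mesh: Mesh,
    load: LoadProgram,
    params: MaterialParams,
    controls: StepControls | None = None,
    state: FieldState | None = None,
) -> tuple[Trajectory, FieldState]:
    """Staggered cycle-jump fatigue simulation of the full specimen.

    Per step: (i) linear equilibrium at the prescribed top displacement,
    (ii) element psi0 and the nodal Laplacian of f, (iii) explicit update of
    the internal variables, (iv) adaptive cycle increment.  Terminates when
    the reaction amplitude drops below ``failure_fraction`` of its initial
    value (failure; N_f located by interpolation between records), when the
    cycle budget is exhausted (runout), or on solver breakdown (diverged).

    ``load.control_mode = "displacement"`` (default) holds the top
    displacement at the virgin amplitude that produces nominal stress
    ``load.sigma_a`` at the waist; ``"stress"`` re-targets the displacement
    each step to hold the waist nominal stress, in which case failure is
    declared when min f drops below the failure fraction (the reaction is
    constant by construction).
    """
    controls = controls or StepControls()
    state = state or FieldState.virgin(mesh.n_elements)
    E = params.youngs_modulus
    beta = params.beta_regularization
    h = mesh.h
    a_min = float(mesh.areas.min())
    # mesh-consistent virgin compliance: displacement at nominal waist stress
    compliance0 = float(np.sum(h / (E * mesh.areas)))
    force_target = load.sigma_a * a_min
    u_top = force_target * compliance0

    hold_displacement = load.control_mode != "stress"
    traj = Trajectory()
    N = 0.0
    last_dn = 0.0
    r0: float | None = None
    prev_record: tuple[float, float] | None = None  # (N, |reaction|)
    d_cap = 60.0  # guard against f underflow far past structural failure

    def evaluate(damage, plastic, hardening):
        """Staggered evaluation at frozen internal state: equilibrium, fields, rates."""
        f = np.exp(-damage)
        if hold_displacement:
            u_t = u_top
        else:
            compliance = float(np.sum(h / (f * E * mesh.areas)))
            u_t = force_target * compliance + float(np.sum(plastic * h))
        u, reaction = solve_equilibrium(mesh, f, u_t, E, plastic)
        eps = np.diff(u) / h
        eps_el = eps - plastic
        sigma = f * E * eps_el
        psi0 = 0.5 * E * eps_el**2
        nodal_f = project_f_to_nodes(mesh, f)
        lap_nodes = discrete_laplacian_f(mesh, nodal_f)
        lap_elems = 0.5 * (lap_nodes[:-1] + lap_nodes[1:])
        q = f * (psi0 - beta * lap_elems)
        d_rates = np.maximum(q - params.r_d, 0.0) / (params.eta_d * params.omega)
        d_rates[damage >= d_cap] = 0.0
        p_rates, h_rates = _plastic_rates(sigma, hardening, params)
        return {
            "f": f,
            "u": u,
            "reaction": reaction,
            "psi0": psi0,
            "nodal_f": nodal_f,
            "lap_nodes": lap_nodes,
            "d_rates": d_rates,
            "p_rates": p_rates,
            "h_rates": h_rates,
        }

    try:
        cur = evaluate(state.damage, state.plastic_strain, state.hardening)
    except FloatingPointError:
        traj.status = "diverged"
        return traj, state

    while True:
        f = cur["f"]
        reaction = cur["reaction"]
        psi0 = cur["psi0"]
        d_rates = cur["d_rates"]
        p_rates = cur["p_rates"]
        h_rates = cur["h_rates"]

        state.displacements = cur["u"]
        state.nodal_f = cur["nodal_f"]
        state.psi0 = psi0
        state.laplacian_f = cur["lap_nodes"]

        if r0 is None:
            r0 = abs(reaction)
            if r0 <= 0 and load.sigma_a > 0:
                traj.status = "diverged"
                return traj, state
        traj.append(N, float(state.damage.max()), float(f.min()), float(psi0.max()), reaction, last_dn)

        # failure: reaction amplitude below fraction of its initial value,
        # N_f interpolated between the bracketing records
        if hold_displacement and load.sigma_a > 0:
            threshold = controls.failure_fraction * r0
            r_abs = abs(reaction)
            if r_abs < threshold:
                if prev_record is None:
                    n_f = N
                else:
                    n_prev, r_prev = prev_record
                    frac = (r_prev - threshold) / max(r_prev - r_abs, 1e-300)
                    n_f = n_prev + frac * (N - n_prev)
                traj.status = "failed"
                traj.n_f = n_f
                traj.steps = len(traj.records) - 1
                return traj, state
            prev_record = (N, r_abs)
        elif load.sigma_a > 0 and f.min() <= controls.failure_fraction:
            traj.status = "failed"
            traj.n_f = N
            traj.steps = len(traj.records) - 1
            return traj, state

        if N >= load.max_cycles:
            traj.status = "runout"
            traj.steps = len(traj.records) - 1
            return traj, state

        all_rates = np.concatenate([d_rates, np.abs(p_rates)])
        # endurance or effective stall: nothing evolves, or even the full
        # remaining budget cannot advance damage by a fraction of one control
        # increment — jump straight to the budget
        if not np.any(all_rates > 0) or (
            float(all_rates.max()) * (load.max_cycles - N) < 1e-6 * controls.delta_d_max
        ):
            N = load.max_cycles
            continue
        dn = adapt_cycle_increment(d_rates if d_rates.max() > 0 else all_rates, controls, load.max_cycles)
        dn = min(dn, load.max_cycles - N)
        peak_rate = float(d_rates.max())
        # explicit update with step rejection bounding the per-step rate growth
        for _ in range(200):
            cand_damage = state.damage + d_rates * dn
            cand_plastic = state.plastic_strain + p_rates * dn
            cand_hardening = state.hardening + h_rates * dn
            try:
                cand = evaluate(cand_damage, cand_plastic, cand_hardening)
            except FloatingPointError:
                traj.status = "diverged"
                traj.steps = len(traj.records) - 1
                return traj, state
            shrunk = shrink_for_rate_growth(dn, peak_rate, float(cand["d_rates"].max()), controls)
            if shrunk is None:
                break
            dn = shrunk
        state.damage = cand_damage
        state.plastic_strain = cand_plastic
        state.hardening = cand_hardening
        cur = cand
        N += dn
        last_dn = dn
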