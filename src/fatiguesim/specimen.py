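"""Hourglass specimen geometry, load mapping, and failure detection.

The fatigue specimen is an axisymmetric hourglass: cylindrical ends with a
smoothly waisted gauge section whose minimum cross-section concentrates
stress.  It is idealized here as a 1-D variable-area bar; the profile supplies
the cross-section area A(x) along the axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.integrate import quad

__all__ = [
    "AreaProfile",
    "FailureCriterion",
    "hourglass_profile",
    "amplitude_to_displacement",
    "detect_failure",
]


@dataclass(frozen=True)
class AreaProfile:
    """Cross-section area A(x), m^2, of an axisymmetric specimen.

    ``area`` evaluates A at axial position x in [0, total_length]; the profile
    is continuous, symmetric about midspan, and minimal at the waist.
    """

    gauge_diameter: float
    end_diameter: float
    gauge_length: float
    total_length: float
    waist_shape: Literal["cosine", "arc"]
    area: Callable[[np.ndarray], np.ndarray]
    flat_length: float = 0.0

    @property
    def min_area(self) -> float:
        return math.pi * self.gauge_diameter**2 / 4.0


@dataclass(frozen=True)
class FailureCriterion:
    """Reaction-drop failure rule: fail when |R| < fraction * initial |R|."""

    fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError(f"fraction must be in (0, 1), got {self.fraction}")


def hourglass_profile(
    gauge_diameter: float = 5e-3,
    end_diameter: float = 12e-3,
    gauge_length: float = 60e-3,
    total_length: float = 60e-3,
    waist_shape: Literal["cosine", "arc"] = "cosine",
    flat_length: float = 40e-3,
) -> AreaProfile:
    """Smooth symmetric hourglass area profile with an optional flat waist.

    A central cylindrical gauge section of length ``flat_length`` (possibly
    zero) at ``gauge_diameter`` is blended out to ``end_diameter`` across the
    rest of the gauge window (length ``gauge_length`` centred at midspan) —
    by a half-cosine (C1-continuous at the junctions) or a circular arc;
    outside the window the section is the constant end diameter.

    Defaults approximate a standard round fatigue coupon: gauge diameter
    5 mm, end diameter 12 mm, overall length 60 mm, a 40 mm cylindrical gauge
    section, and smoothly waisted 10 mm transitions.  The extended
    near-critical gauge region keeps a substantial share of the bar's
    compliance in the damaging zone, so the reaction force can drop well
    below the failure criterion before the zone unloads elastically.
    """
    if min(gauge_diameter, end_diameter, gauge_length, total_length) <= 0:
        raise ValueError("all specimen dimensions must be > 0")
    if flat_length < 0:
        raise ValueError("flat_length must be >= 0")
    if gauge_diameter > end_diameter:
        raise ValueError("gauge_diameter must be <= end_diameter")
    if gauge_length > total_length:
        raise ValueError("gauge_length must be <= total_length")
    if flat_length > gauge_length:
        raise ValueError("flat_length must be <= gauge_length")
    if waist_shape not in ("cosine", "arc"):
        raise ValueError(f"unknown waist_shape {waist_shape!r}")

    mid = total_length / 2.0
    half_flat = flat_length / 2.0
    half_trans = max((gauge_length - flat_length) / 2.0, 0.0)
    dd = end_diameter - gauge_diameter

    def diameter(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        s = np.abs(x - mid) - half_flat
        if half_trans > 0:
            xi = np.clip(s / half_trans, 0.0, 1.0)
        else:
            xi = (s > 0).astype(float)
        if waist_shape == "cosine":
            blend = 0.5 * (1.0 - np.cos(math.pi * xi))
        else:  # circular-arc waist in the diameter profile
            blend = 1.0 - np.sqrt(np.clip(1.0 - xi**2, 0.0, 1.0))
        return gauge_diameter + dd * blend

    def area(x: np.ndarray) -> np.ndarray:
        return math.pi * diameter(x) ** 2 / 4.0

    return AreaProfile(
        gauge_diameter=gauge_diameter,
        end_diameter=end_diameter,
        gauge_length=gauge_length,
        total_length=total_length,
        waist_shape=waist_shape,
        area=area,
        flat_length=flat_length,
    )


def amplitude_to_displacement(sigma_a: float, profile: AreaProfile, E: float) -> float:
    """Top displacement that produces nominal stress sigma_a at the waist.

    For the virgin (undamaged) bar the axial force at nominal waist stress
    sigma_a is F = sigma_a * A_min, and the end displacement is
    u = F * integral_0^L dx / (E A(x)).  The displacement amplitude obtained
    here is then held fixed for the whole life under displacement control.
    """
    if sigma_a == 0:
        return 0.0
    compliance, _ = quad(lambda x: 1.0 / (E * float(profile.area(x))), 0.0, profile.total_length, limit=200)
    return sigma_a * profile.min_area * compliance


def detect_failure(
    reaction_history,
    cycles,
    criterion: FailureCriterion = FailureCriterion(),
) -> tuple[float | None, bool]:
    """Locate the failure cycle on a reaction-amplitude history.

    Returns ``(N_f, censored)``: the first cycle where |reaction| drops below
    ``fraction`` of the initial amplitude, linearly interpolated between
    stored records; ``(None, True)`` if the criterion is never met.  The
    result is invariant under uniform positive rescaling of the history.
    """
    reaction = np.abs(np.asarray(reaction_history, dtype=float))
    cycles = np.asarray(cycles, dtype=float)
    if reaction.size == 0 or reaction.size != cycles.size:
        raise ValueError("reaction history and cycles must be nonempty and equal length")
    r0 = reaction[0]
    if r0 <= 0:
        raise ValueError("initial reaction amplitude must be positive")
    threshold = criterion.fraction * r0
    below = reaction < threshold
    if not below.any():
        return None, True
    i = int(np.argmax(below))
    if i == 0:
        return float(cycles[0]), False
    r_prev, r_cur = reaction[i - 1], reaction[i]
    n_prev, n_cur = cycles[i - 1], cycles[i]
    frac = (r_prev - threshold) / max(r_prev - r_cur, 1e-300)
    return float(n_prev + frac * (n_cur - n_prev)), False
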