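"""Model-wide physical constants for the three-state motility-assay model.

Units are fixed across the package: lengths in nm, times in s (lifetimes
reported in ms), rates in s^-1, forces in pN, stiffness in pN/nm, energy per
ATP in zJ (1 zJ = 1 pN·nm, so 62.5 zJ == 62.5 pN·nm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelConstants:
    """Constants shared by the analytic model and the stochastic engine.

    Parameters
    ----------
    x_d : float
        Binding-site spacing along the actin filament, nm. Actin's helical
        repeat places target zones every 36 nm.
    x_z : float
        Binding-zone width, nm: how close a site must come to a myosin head's
        capture position for attachment to be possible. Not directly
        measurable; the default 1.15 nm is calibrated so that a 60-myosin
        chicken-skeletal ensemble gliding at its unloaded velocity has a
        contact probability of ~91% (see :func:`calibrate_binding_zone`).
    e_atp : float
        Usable energy per ATP turnover, zJ (= pN·nm).
    theta : float
        Lever-arm step angle in degrees, used when an isoform is specified by
        lever length instead of power-stroke length.
    dX : float
        Spatial step of the discretised engine, nm. The filament translates
        dX every simulation step, over dT = dX / v.
    dissociation_window : float
        Duration of continuous zero attachment that terminates a processive
        run, ms. Represents the mean time before a filament diffuses out of
        reach of the myosin bed.
    se_threshold : float
        Standard-error target, pN, on the per-myosin mean force at which a
        steady-state simulation is considered converged.
    v_increment : float
        Grid step, nm/s, for the iterative unloaded-velocity search.
    """

    x_d: float = 36.0
    x_z: float = 1.15
    e_atp: float = 62.5
    theta: float = 30.0
    dX: float = 1.0
    dissociation_window: float = 1.0
    se_threshold: float = 0.005
    v_increment: float = 100.0

    def __post_init__(self) -> None:
        for name in (
            "x_d",
            "x_z",
            "e_atp",
            "theta",
            "dX",
            "dissociation_window",
            "se_threshold",
            "v_increment",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not self.x_z < self.x_d:
            raise ValueError(
                f"binding zone x_z={self.x_z} nm must be narrower than the site "
                f"spacing x_d={self.x_d} nm (zones of adjacent sites must not overlap)"
            )

    def with_(self, **overrides) -> "ModelConstants":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **overrides)


DEFAULT_CONSTANTS = ModelConstants()


def calibrate_binding_zone(
    k_on: float,
    k_off: float,
    delta_plus: float,
    *,
    target_pc: float = 0.91,
    n: int = 60,
    x_d: float = 36.0,
) -> float:
    """Solve for the binding-zone width x_z that yields a given contact probability.

    The calibration anchor is the one operating point with an empirical
    handle: a chicken-skeletal ensemble saturates filament velocity at about
    N = 60 myosins, where the analytic contact probability is ~91%. Given the
    isoform and that anchor, invert P_C = 1 - (1 - r)^N for the duty ratio r,
    then invert r = delta_on / Delta with Delta = x_d / P_on and
    P_on = 1 - exp(-k_on * x_z / v_u) for x_z.

    Returns x_z in nm. With the default anchor (0.91 at N=60) the chicken
    skeletal parameters give x_z ~= 1.140 nm; the package default of 1.15 nm
    corresponds to P_C = 0.9117 at the same point.
    """
    if not 0 < target_pc < 1:
        raise ValueError("target_pc must lie strictly between 0 and 1")
    if n < 1:
        raise ValueError("n must be a positive integer")
    v_u = (math.sqrt(2.0) / 2.0) * delta_plus * k_off
    delta_minus = v_u / k_off
    delta_on = delta_plus + delta_minus
    r = 1.0 - (1.0 - target_pc) ** (1.0 / n)
    p_on = r * x_d / delta_on
    if not 0 < p_on < 1:
        raise ValueError(
            "calibration anchor is unreachable: implied per-passage binding "
            f"probability {p_on:.4f} outside (0, 1)"
        )
    return -v_u * math.log(1.0 - p_on) / k_on
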