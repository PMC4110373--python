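"""Quadriceps-force restart controller.

During the squat the vertical ankle reaction (ground reaction force, GRF)
must stay inside a prescribed band (default 50-55 N).  After each load step
the GRF is measured; if it is out of band the step is restarted with an
adapted vastus intermedius force until the band is reached.  The adaptation
law is bracketed bisection towards the band midpoint with geometric bracket
expansion — derivative-free, guaranteed to terminate on any monotone plant
whose range covers the band, and accepting the first in-band iterate (band
endpoints inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GrfBand",
    "ControllerConfig",
    "ControllerError",
    "ControlOutcome",
    "control_step",
    "control_scalar_plant",
    "probe_sensitivity",
]


@dataclass(frozen=True)
class GrfBand:
    """Admissible ground-reaction-force window (N), endpoints inclusive."""

    lower: float = 50.0
    upper: float = 55.0

    def __post_init__(self) -> None:
        if not 0.0 < self.lower < self.upper:
            raise ValueError(f"band must satisfy 0 < lower < upper, got [{self.lower}, {self.upper}]")

    def contains(self, grf: float) -> bool:
        return self.lower <= grf <= self.upper

    @property
    def mid(self) -> float:
        return 0.5 * (self.lower + self.upper)


@dataclass(frozen=True)
class ControllerConfig:
    initial_quad_force: float = 21.0  # N, used for step 1 (later steps warm-start)
    max_restarts: int = 50
    update_rule: str = "bisection"
    bracket_expansion: float = 2.0
    probe_delta: float = 5.0  # N, finite-difference step for the sensitivity probe
    #: "secant": predict each step's starting force from the last accepted
    #: (force, GRF) pair and the estimated plant slope, aiming at the band
    #: midpoint; "previous": reuse the last accepted force unchanged
    warm_start: str = "secant"

    def __post_init__(self) -> None:
        if self.max_restarts < 1:
            raise ValueError("max_restarts must be >= 1")
        if self.update_rule not in ("bisection",):
            raise ValueError(f"unknown update rule {self.update_rule!r}")
        if self.bracket_expansion <= 1.0:
            raise ValueError("bracket_expansion must be > 1")
        if self.warm_start not in ("secant", "previous"):
            raise ValueError(f"unknown warm_start {self.warm_start!r}")


class ControllerError(RuntimeError):
    """Band unreachable, non-monotone plant, or restart budget exhausted."""

    def __init__(self, message: str, probe_report: dict | None = None):
        super().__init__(message)
        self.probe_report = probe_report or {}


@dataclass
class ControlOutcome:
    quad_force: float
    grf: float
    n_restarts: int
    result: object = None  # solver StepResult for the accepted iterate
    evaluations: list = None  # (quad_force, grf) pairs probed this step


def probe_sensitivity(solve_fn, quad_force: float, delta: float, tol: float = 1e-9) -> int:
    """Sign of dGRF/dF from a two-point finite difference; 0 when indeterminate."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    g0 = _grf_of(solve_fn(quad_force))
    g1 = _grf_of(solve_fn(quad_force + delta))
    slope = (g1 - g0) / delta
    if abs(slope) < tol:
        return 0
    return 1 if slope > 0 else -1


def _grf_of(solved) -> float:
    """Accept either a bare GRF or a (state, GRF)-like solver result."""
    if isinstance(solved, (int, float)):
        return float(solved)
    if hasattr(solved, "grf"):
        return float(solved.grf)
    return float(solved[1])


def control_scalar_plant(solve_fn, band: GrfBand, config: ControllerConfig, f_init: float) -> ControlOutcome:
    """Bisection control loop on an arbitrary plant ``quad_force -> GRF``.

    ``solve_fn`` may return a bare GRF value or an object with a ``grf``
    attribute; the last accepted full result is carried on the outcome.
    Raises :class:`ControllerError` if the band is unreachable (GRF above the
    band at zero force), the plant is non-monotone over the probed bracket, or
    the restart budget is exhausted.
    """
    evaluations: list[tuple[float, float]] = []

    def solve(f: float):
        r = solve_fn(f)
        evaluations.append((f, _grf_of(r)))
        return r

    f = max(0.0, f_init)
    result = solve(f)
    grf = _grf_of(result)
    if band.contains(grf):
        return ControlOutcome(f, grf, 0, result, evaluations)

    target = band.mid
    # establish a bracket [f_lo, f_hi] with GRF(f_lo) < target < GRF(f_hi),
    # assuming GRF weakly increasing in quad force; direction verified below.
    f_lo = f_hi = f
    g_lo = g_hi = grf
    r_lo = r_hi = result
    n = 1
    step = max(config.probe_delta, 0.25 * max(f, 1.0))
    while g_lo > target and n < config.max_restarts:
        f_new = max(0.0, f_lo - step)
        r_new = solve(f_new)
        g_new = _grf_of(r_new)
        if band.contains(g_new):
            return ControlOutcome(f_new, g_new, n, r_new, evaluations)
        if g_new > g_lo + 1e-12:
            raise ControllerError(
                "non-monotone plant detected while bracketing downwards",
                {"evaluations": evaluations},
            )
        if g_new > target:  # still too high: this is a tighter upper bracket end
            f_hi, g_hi, r_hi = f_new, g_new, r_new
        f_lo, g_lo, r_lo = f_new, g_new, r_new
        n += 1
        if f_new == 0.0:
            break
        step *= config.bracket_expansion
    if g_lo > target:
        raise ControllerError(
            f"GRF band unreachable: GRF at zero quadriceps force is {g_lo:.2f} N, above target {target:.2f} N",
            {"evaluations": evaluations},
        )
    step = max(config.probe_delta, 0.25 * max(f_hi, 1.0))
    while g_hi < target and n < config.max_restarts:
        f_new = f_hi + step
        r_hi = solve(f_new)
        g_new = _grf_of(r_hi)
        if band.contains(g_new):
            return ControlOutcome(f_new, g_new, n, r_hi, evaluations)
        if g_new < g_hi - 1e-12:
            raise ControllerError(
                "non-monotone plant detected while bracketing upwards",
                {"evaluations": evaluations},
            )
        f_hi, g_hi = f_new, g_new
        n += 1
        step *= config.bracket_expansion
    if g_hi < target:
        raise ControllerError(
            f"GRF band unreachable within restart budget: max GRF {g_hi:.2f} N below target",
            {"evaluations": evaluations},
        )
    # bisection on the bracket
    f_mid, g_mid = f_hi, g_hi
    while n < config.max_restarts:
        f_mid = 0.5 * (f_lo + f_hi)
        r_mid = solve(f_mid)
        g_mid = _grf_of(r_mid)
        n += 1
        if band.contains(g_mid):
            return ControlOutcome(f_mid, g_mid, n - 1, r_mid, evaluations)
        if g_mid < target:
            f_lo, g_lo = f_mid, g_mid
        else:
            f_hi, g_hi = f_mid, g_mid
    raise ControllerError(
        f"max restarts ({config.max_restarts}) exceeded; last GRF {g_mid:.2f} N at F={f_mid:.2f} N",
        {"evaluations": evaluations},
    )


def control_step(
    model, state, drop: float, band: GrfBand, config: ControllerConfig, memory: dict | None = None
) -> ControlOutcome:
    """Force-control one squat load step of a :class:`~kneesquat.solver.KneeModel`.

    The starting quadriceps force derives from the previous step's converged
    value (mirroring the restart-from-last-load-step structure): either reused
    unchanged (``warm_start="previous"``) or corrected towards the band
    midpoint through a secant model of the plant slope (``"secant"``, the
    default — it keeps the force curve smooth instead of plateauing until the
    GRF drifts out of band).  ``memory`` is a mutable dict carrying the slope
    estimate and last GRF across steps.

    The inner solves always warm-start from the previous converged pose.
    """

    def solve_fn(f_quad: float):
        return model.solve_load_step(state, drop, f_quad)

    f_init = state.quad_force if state.quad_force > 0 else config.initial_quad_force
    if config.warm_start == "secant" and memory is not None and memory.get("last_grf") is not None:
        slope = memory.get("slope", 0.25)
        f_init = max(0.0, f_init + (band.mid - memory["last_grf"]) / slope)
    out = control_scalar_plant(solve_fn, band, config, f_init)
    if memory is not None:
        memory["last_grf"] = out.grf
        evals = out.evaluations or []
        for (f1, g1), (f2, g2) in zip(evals, evals[1:]):
            if abs(f2 - f1) > 1.0:
                slope = (g2 - g1) / (f2 - f1)
                if 0.01 < slope < 10.0:
                    memory["slope"] = slope
    return out


def bisection_bound(bracket_width: float, band_width: float) -> int:
    """Worst-case bisection iterations to land a monotone plant inside the band."""
    if bracket_width <= band_width:
        return 2
    return math.ceil(math.log2(bracket_width / band_width)) + 2
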