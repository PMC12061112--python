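"""Fixed-step and adaptive solvers for ordinary differential equations.

A residual layer computes ``g + F(g)``, which is exactly one Euler step of
``dg/dt = F(g, t)`` over a unit time span; taking more, smaller steps (or a
higher-order scheme) turns the layer into a continuous-depth block.  The
solvers here are written against plain arithmetic (``+`` and scalar ``*``),
so the same code integrates python floats, numpy arrays and autodiff
tensors — in the last case the solver is unrolled onto the gradient tape and
is differentiable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["SolverConfig", "euler_step", "rk4_step", "solve_ode"]


@dataclass(frozen=True)
class SolverConfig:
    """How to integrate an ODE block.

    method: "euler" | "rk4" (fixed step) or "adaptive" (RK45 with error
    control).  ``step`` is the fixed step size Δk; ``tolerance`` is the local
    error bound for the adaptive method; ``t_span`` is the integration
    interval.
    """

    method: str = "rk4"
    step: float = 0.25
    tolerance: float = 1e-6
    t_span: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.method not in ("euler", "rk4", "adaptive"):
            raise ValueError(f"unknown solver method: {self.method!r}")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.t_span[1] <= self.t_span[0]:
            raise ValueError("t_span must satisfy t1 > t0")


def euler_step(g, k: float, dk: float, dynamics: Callable):
    """One explicit Euler step: ``g + Δk * f(g, k)``."""
    if dk <= 0:
        raise ValueError("step must be positive")
    f = dynamics(g, k)
    _check_finite(f, k)
    return g + dk * f


def rk4_step(g, k: float, dk: float, dynamics: Callable):
    """One classical Runge–Kutta step of order 4."""
    if dk <= 0:
        raise ValueError("step must be positive")
    k1 = dynamics(g, k)
    k2 = dynamics(g + (dk / 2.0) * k1, k + dk / 2.0)
    k3 = dynamics(g + (dk / 2.0) * k2, k + dk / 2.0)
    k4 = dynamics(g + dk * k3, k + dk)
    _check_finite(k4, k + dk)
    return g + (dk / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def solve_ode(g0, dynamics: Callable, config: SolverConfig):
    """Integrate ``dg/dt = dynamics(g, t)`` over ``config.t_span``.

    Fixed-step methods take ``ceil((t1 - t0) / step)`` steps, shortening the
    final step to land on t1 exactly.  The adaptive method is an embedded
    RK45 (Dormand–Prince) with per-step error control against
    ``config.tolerance``; it operates on numeric state only.
    """
    t0, t1 = config.t_span
    if config.method == "adaptive":
        return _solve_rk45(g0, dynamics, t0, t1, config.tolerance)
    stepper = euler_step if config.method == "euler" else rk4_step
    n_steps = int(np.ceil((t1 - t0) / config.step))
    g, t = g0, t0
    for i in range(n_steps):
        dk = min(config.step, t1 - t)
        g = stepper(g, t, dk, dynamics)
        t = t0 + (i + 1) * config.step
    return g


# Dormand–Prince 5(4) tableau
_DP_C = (0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0)
_DP_A = (
    (),
    (1 / 5,),
    (3 / 40, 9 / 40),
    (44 / 45, -56 / 15, 32 / 9),
    (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729),
    (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656),
    (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84),
)
_DP_B5 = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0)
_DP_B4 = (5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200,
          187 / 2100, 1 / 40)


def _solve_rk45(g0, dynamics, t0, t1, tol, max_steps: int = 10000):
    g = np.asarray(g0, dtype=np.float64)
    t = t0
    h = (t1 - t0) / 10.0
    for _ in range(max_steps):
        if t >= t1:
            return g
        h = min(h, t1 - t)
        ks = []
        for i in range(7):
            gi = g + h * sum(a * k for a, k in zip(_DP_A[i], ks)) if ks else g
            ks.append(np.asarray(dynamics(gi, t + _DP_C[i] * h)))
        g5 = g + h * sum(b * k for b, k in zip(_DP_B5, ks))
        g4 = g + h * sum(b * k for b, k in zip(_DP_B4, ks))
        err = float(np.max(np.abs(g5 - g4)))
        scale = tol * max(1.0, float(np.max(np.abs(g))))
        if not np.isfinite(err):
            raise FloatingPointError(f"adaptive solver diverged at t={t:.4g}")
        if err <= scale:
            t += h
            g = g5
        h *= min(5.0, max(0.2, 0.9 * (scale / (err + 1e-300)) ** 0.2))
    raise FloatingPointError("adaptive solver exceeded the step budget")


def _check_finite(f, t: float) -> None:
    data = getattr(f, "data", f)
    if not np.all(np.isfinite(data)):
        raise FloatingPointError(
            f"dynamics returned non-finite values at t={t:.4g}")
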