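"""Lorenz-system utilities shared by the chaos-related tests.

Provides the reference trajectory and an independent two-trajectory
(Benettin-style) largest-Lyapunov-exponent oracle: a perturbed copy of
the system is repeatedly renormalised onto the reference trajectory and
the mean exponential stretching rate is accumulated.  The oracle never
touches the delay-embedding estimator it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

SIGMA, RHO, BETA = 10.0, 28.0, 8.0 / 3.0


def lorenz_rhs(t, s):
    x, y, z = s
    return [SIGMA * (y - x), x * (RHO - z) - y, x * y - BETA * z]


def _integrate(state, t_span, t_eval=None):
    return solve_ivp(lorenz_rhs, t_span, state, t_eval=t_eval,
                     rtol=1e-9, atol=1e-11)


def lorenz_trajectory(duration: float, fs: float,
                      transient: float = 20.0) -> np.ndarray:
    """x-coordinate of the Lorenz attractor sampled at fs after discarding
    the transient."""
    total = duration + transient
    sol = _integrate([1.0, 1.0, 1.0], (0.0, total),
                     t_eval=np.arange(0.0, total, 1.0 / fs))
    return sol.y[0][int(transient * fs):]


def benettin_lyapunov(duration: float = 80.0, dt: float = 0.5,
                      d0: float = 1e-7) -> float:
    """Two-trajectory divergence oracle for the largest exponent (1/s)."""
    ref = _integrate([1.0, 1.0, 1.0], (0.0, 20.0)).y[:, -1]
    pert = ref + np.array([d0, 0.0, 0.0])
    log_sum = 0.0
    for _ in range(int(duration / dt)):
        a = _integrate(ref, (0.0, dt)).y[:, -1]
        b = _integrate(pert, (0.0, dt)).y[:, -1]
        d = np.linalg.norm(b - a)
        log_sum += np.log(d / d0)
        ref = a
        pert = a + (b - a) * (d0 / d)
    return log_sum / duration
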