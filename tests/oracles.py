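"""Independent numerical oracles used by the tests.

These deliberately avoid the package's own solution paths: the tissue oracle
is a two-point boundary-value solve of the radial diffusion equation with
*spatially varying* Michaelis-Menten consumption (the package uses the
closed form with one effective rate per slice), and the content-inversion
oracle is plain interval bisection.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_bvp


def bvp_slice(p_cap, m0, p_crit, k_diff, r_c, r_t, n_init=64):
    """Solve K*(1/r)*d/dr(r*dP/dr) = M(P) with P(r_c)=p_cap, P'(r_t)=0.

    Returns (radii, po2, volume-weighted mean po2).
    """

    def consumption(p):
        p = np.maximum(p, 0.0)
        if p_crit == 0.0:
            return np.where(p > 0, m0, 0.0)
        return m0 * p / (p + p_crit)

    # nondimensionalize the radius (x = r/r_c) to condition the solve
    x_t = r_t / r_c
    scale = r_c**2 / k_diff  # mmHg per unit consumption rate

    def rhs(x, y):
        return np.vstack([y[1], scale * consumption(y[0]) - y[1] / x])

    def bc(ya, yb):
        return np.array([ya[0] - p_cap, yb[1]])

    x = np.linspace(1.0, x_t, n_init)
    # uniform-consumption closed form as the initial guess
    guess_p = (p_cap + scale * m0 * ((x**2 - 1.0) / 4.0 - (x_t**2 / 2.0) * np.log(x)))
    guess_dp = scale * m0 * (x / 2.0 - x_t**2 / (2.0 * x))
    guess = np.vstack([np.maximum(guess_p, 0.0), guess_dp])
    sol = solve_bvp(rhs, bc, x, guess, tol=1e-6, max_nodes=100000)
    if not sol.success:
        raise RuntimeError(f"BVP oracle failed: {sol.message}")
    xx = np.linspace(1.0, x_t, 801)
    rr = xx * r_c
    po2 = np.maximum(sol.sol(xx)[0], 0.0)
    mean = np.trapezoid(po2 * rr, rr) / np.trapezoid(rr, rr)
    return rr, po2, float(mean)


def bisect_content_inversion(content, hct, constants, lo=0.0, hi=5000.0, iters=200):
    """Bisection solve of alpha_p*P + hct*c0*Hill(P) = content."""

    def f(p):
        s = (p / constants.p50_tissue) ** constants.hill_n
        so2 = s / (1.0 + s)
        return constants.alpha_p * p + hct * constants.c0 * so2 - content

    assert f(lo) <= 0 <= f(hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
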