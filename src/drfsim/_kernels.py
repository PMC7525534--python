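"""Hot-loop risk summation.

The controller evaluates the scalar risk C = sum(z * cost) * delta^2 many
times per step while optimizing the steering angle, so the sum is written
as an explicit loop with early exits (zero-cost cells, out-of-support
cells, negligible Gaussian tails) and compiled with numba when present.
The numpy field evaluation in :mod:`drfsim.field` is the reference
implementation; a test pins the two against each other.
"""

from __future__ import annotations

import math

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def risk_sum(X, Y, cost, x0, y0, phi, v, delta, L, p, tla, m, c, k1, k2, eps):
    """Sum of z*cost over flat cell arrays (no cell-area factor)."""
    smax = v * tla
    if smax <= 0.0:
        return 0.0
    total = 0.0
    ad = abs(delta)
    ki = m + k1 * ad
    ko = m + k2 * ad
    if ad < eps:
        cph = math.cos(phi)
        sph = math.sin(phi)
        for i in range(X.size):
            ci = cost[i]
            if ci == 0.0:
                continue
            dx = X[i] - x0
            dy = Y[i] - y0
            s = dx * cph + dy * sph
            if s < 0.0 or s > smax:
                continue
            lat = -dx * sph + dy * cph
            sig = (ki if lat >= 0.0 else ko) * s + c
            if sig <= 0.0:
                continue
            d = abs(lat)
            if d > 6.0 * sig:
                continue
            total += ci * p * (s - smax) ** 2 * math.exp(-0.5 * (d / sig) ** 2)
    else:
        sgn = 1.0 if delta > 0.0 else -1.0
        R = L / math.tan(ad)
        xc = x0 + sgn * R * (-math.sin(phi))
        yc = y0 + sgn * R * math.cos(phi)
        th0 = math.atan2(y0 - yc, x0 - xc)
        twopi = 2.0 * math.pi
        for i in range(X.size):
            ci = cost[i]
            if ci == 0.0:
                continue
            ex = X[i] - xc
            ey = Y[i] - yc
            dist = math.sqrt(ex * ex + ey * ey)
            d = abs(dist - R)
            dth = (sgn * (math.atan2(ey, ex) - th0)) % twopi
            s = R * dth
            if s > smax:
                continue
            sig = (ki if dist < R else ko) * s + c
            if sig <= 0.0:
                continue
            if d > 6.0 * sig:
                continue
            total += ci * p * (s - smax) ** 2 * math.exp(-0.5 * (d / sig) ** 2)
    return total
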