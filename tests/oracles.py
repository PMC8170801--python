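"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's characteristics/cohort representation:
the metastatic density is solved on a fixed log-size grid with a conservative
first-order upwind finite-volume scheme, with the primary tumor handled as a
separate exact trajectory feeding the seeding boundary condition.
"""

from __future__ import annotations

import numpy as np


def finite_volume_reference(
    a: float,
    K: float,
    m: float,
    alpha: float,
    t_end: float,
    n_cells: int = 3000,
    cfl: float = 0.9,
    secondary: bool = True,
):
    """Upwind finite-volume solution of the size-structured transport equation.

    Works in log-size ``y = ln x`` on ``[0, ln K]`` where the therapy-free
    transport speed is ``v(y) = a (ln K - y)``.  The metastasis density per
    unit ``y`` is ``phi(y, t) = x rho(x, t)``; the primary tumor (the Dirac
    part of the initial condition) follows the exact Gompertz trajectory and
    enters only through the boundary influx

    ``v(0) phi(0, t) = m exp(alpha y_p(t)) + int m exp(alpha y) phi dy``.

    Returns a dict with the metastasis count, total burden (primary
    included), the cell grid and final density, and a callable binning the
    final density plus primary into arbitrary size bins.
    """
    lk = np.log(K)
    edges = np.linspace(0.0, lk, n_cells + 1)
    dy = edges[1] - edges[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    v_edge = a * (lk - edges)  # speed at cell edges; zero at y = ln K
    dt = cfl * dy / v_edge[0]
    n_steps = int(np.ceil(t_end / dt))
    dt = t_end / n_steps

    phi = np.zeros(n_cells)
    w_seed = m * np.exp(alpha * centers) * dy  # quadrature weights for the influx

    t = 0.0
    for _ in range(n_steps):
        y_p = lk * (1.0 - np.exp(-a * t))
        influx = m * np.exp(alpha * y_p)
        if secondary:
            influx += float(w_seed @ phi)
        flux = np.empty(n_cells + 1)
        flux[0] = influx
        flux[1:] = v_edge[1:] * phi  # upwind: speed is non-negative
        phi += dt / dy * (flux[:-1] - flux[1:])
        t += dt

    x_p = np.exp(lk * (1.0 - np.exp(-a * t_end)))
    n_mets = float(phi.sum() * dy)
    burden = x_p + float((phi * np.exp(centers)).sum() * dy)

    def histogram(bin_edges):
        counts = np.zeros(len(bin_edges) - 1)
        log_edges = np.log(np.asarray(bin_edges, dtype=float))
        cum = np.concatenate([[0.0], np.cumsum(phi * dy)])  # mass below edges[i]
        mass_below = np.interp(log_edges, edges, cum)
        counts = np.diff(mass_below)
        idx = np.searchsorted(bin_edges, x_p, side="right") - 1
        if 0 <= idx < len(counts):
            counts[idx] += 1.0
        return counts

    return {
        "n_mets": n_mets,
        "n_total": 1.0 + n_mets,
        "burden": burden,
        "primary": x_p,
        "centers_log": centers,
        "phi": phi,
        "histogram": histogram,
    }
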