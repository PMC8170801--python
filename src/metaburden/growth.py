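"""Therapy-free Gompertz growth kinetics.

The tumor size law used throughout this package is the Gompertz model

.. math::

    \\frac{dx}{dt} = a \\ln\\!\\left(\\frac{K}{x}\\right) x, \\qquad x(0) = 1,

whose specific growth rate decays exponentially in time.  Starting from one
renegade cell the closed-form solution is

.. math::

    x(t) = K^{\\,1 - e^{-a t}},

so the initial exponential rate is :math:`r = a \\ln K` and the size
saturates at the carrying capacity ``K``.  The module also provides the
inverse relation (tumor age as a function of size) and the clinically used
tumor volume doubling time (TVDT), both derived from the same closed form.

All functions accept scalars or NumPy arrays for the size/time argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_K

__all__ = [
    "GompertzParams",
    "size_at",
    "tumor_age",
    "tvdt",
    "growth_rate",
    "propagate",
    "cell_cycle_hours",
]


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the Gompertz growth law.

    Parameters
    ----------
    a : float
        Decay factor of the specific growth rate [1/day]; strictly positive.
    K : float
        Carrying capacity [cells]; the asymptotic tumor size.  Defaults to
        ``10^12`` cells, the commonly used lethal burden scale.

    Notes
    -----
    The initial exponential growth rate ``r = a ln(K)`` is exposed as a
    derived property and never stored independently, so the identity
    ``K = exp(r / a)`` holds exactly by construction.
    """

    a: float
    K: float = DEFAULT_K

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"growth-rate decay factor a must be > 0, got {self.a}")
        if not self.K > 1:
            raise ValueError(f"carrying capacity K must be > 1, got {self.K}")

    @property
    def r(self) -> float:
        """Initial exponential growth rate ``r = a ln(K)`` [1/day]."""
        return self.a * np.log(self.K)

    @property
    def log_K(self) -> float:
        """Natural log of the carrying capacity (cached-by-recompute)."""
        return float(np.log(self.K))


def _as_float(x):
    arr = np.asarray(x, dtype=float)
    return arr


def size_at(params: GompertzParams, t):
    """Tumor size after ``t`` days of therapy-free growth from one cell.

    Implements ``x(t) = K^(1 - exp(-a t))``.

    Parameters
    ----------
    params : GompertzParams
    t : float or array_like
        Time since tumor origin [day]; must be non-negative.

    Returns
    -------
    float or ndarray
        Tumor size [cells]; strictly increasing in ``t`` and bounded by ``K``.
    """
    t = _as_float(t)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(params.log_K * (1.0 - np.exp(-params.a * t)))
    return float(out) if out.ndim == 0 else out


def tumor_age(params: GompertzParams, x):
    """Age of a therapy-free tumor of size ``x`` [day].

    The inverse of :func:`size_at`:
    ``T(x) = -(1/a) ln(1 - ln(x)/ln(K))``, defined for ``1 <= x < K``.
    """
    x = _as_float(x)
    if np.any(x < 1):
        raise ValueError("size must be >= 1 cell")
    if np.any(x >= params.K):
        raise ValueError("size must be below the carrying capacity K; the asymptote is never reached")
    out = -np.log1p(-np.log(x) / params.log_K) / params.a
    return float(out) if out.ndim == 0 else out


def tvdt(params: GompertzParams, x):
    """Tumor volume doubling time at size ``x`` [day].

    ``TVDT(x) = T(2x) - T(x)``; increases with ``x`` because Gompertz growth
    decelerates.  Requires ``x > 1`` and ``2x < K``.
    """
    x = _as_float(x)
    if np.any(x <= 1):
        raise ValueError("TVDT requires size > 1 cell")
    if np.any(2.0 * x >= params.K):
        raise ValueError("2x must stay below the carrying capacity K")
    return tumor_age(params, 2.0 * x) - tumor_age(params, x)


def growth_rate(params: GompertzParams, x):
    """Instantaneous therapy-free growth rate ``a ln(K/x) x`` [cells/day].

    Zero at the carrying capacity; maximal at ``x = K/e``.
    """
    x = _as_float(x)
    if np.any(x < 1):
        raise ValueError("size must be >= 1 cell")
    out = params.a * np.log(params.K / x) * x
    return float(out) if out.ndim == 0 else out


def propagate(params: GompertzParams, x, dt: float):
    """Advance a therapy-free tumor of size ``x`` by ``dt`` days (exact).

    Uses the Gompertz flow map
    ``x(t + dt) = K^(1 - (1 - ln(x)/ln(K)) exp(-a dt))``, which is exact for
    any step size; the numerical solvers in this package use it on
    treatment-free intervals.
    """
    x = _as_float(x)
    lk = params.log_K
    out = np.exp(lk - (lk - np.log(x)) * np.exp(-params.a * dt))
    return float(out) if out.ndim == 0 else out


def cell_cycle_hours(params: GompertzParams) -> float:
    """Indirectly estimated tumor cell cycle length, reported in hours.

    Clinical convention: the numeric value of ``ln(2)/a`` with ``a`` in
    1/day is read as a cycle length in hours (e.g. ``a = 7.284e-3``/day
    corresponds to about 95 h, consistent with observed cycle lengths of
    two to four days).
    """
    return float(np.log(2.0) / params.a)
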