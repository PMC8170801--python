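"""Size-structured metastatic density solved on characteristics.

The expected number of tumors per unit size, ``rho(x, t)``, obeys the
transport equation

.. math::

    \\partial_t \\rho + \\partial_x ( g(x,t) \\rho ) = 0

with the seeding boundary condition

.. math::

    g(1,t)\\,\\rho(1,t) = \\int_1^\\infty \\beta(\\tilde x)\\,
        \\rho(\\tilde x, t)\\, d\\tilde x,
    \\qquad \\beta(x) = m x^{\\alpha},

and initial condition ``rho(1,0) = 1`` embedding the primary tumor as one
cell at the origin of time.  ``g`` is the therapy-aware growth law of
:mod:`metaburden.therapy`; all tumors share it, so characteristics never
cross and the density can be integrated exactly along them.

Discretization
--------------
The solver tracks the primary tumor plus one *cohort* per time step: the
expected number of metastases seeded during the step (trapezoidal quadrature
of the seeding rate), dated at the step midpoint, entering at one cell and
then transported along its own characteristic.  Because the growth law is
shared, every step update is an affine map in log-size,

``u -> ln K - (ln K - u) e^{-a dt} - J``,

where ``J`` accumulates the (size-independent) Hill kill; chemotherapy days
apply the exact multiplicative log-kill instead.  Both maps are exact in the
absence of the Hill term and vectorize over all cohorts.

Counts are real-valued expectations, not stochastic realizations.  Tumors
driven below one cell are clamped at one cell by default; the
``eradicate_below_one`` option removes them instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from .constants import CELLS_PER_ML, DEFAULT_ALPHA
from .growth import GompertzParams
from .therapy import TherapySchedule

__all__ = [
    "SeedingParams",
    "Cohort",
    "MetastaticState",
    "SolverOptions",
    "SimulationResult",
    "simulate",
    "seeding_rate",
    "n_total",
    "n_visible",
    "total_burden",
    "size_distribution",
]


@dataclass(frozen=True)
class SeedingParams:
    """Dissemination rate ``beta(x) = m x^alpha``.

    ``m`` is the colonization coefficient [1/(cell day)], the per-cell
    per-day probability scale of completing the whole metastatic cascade;
    ``alpha`` the fractal dimension of the cells able to metastasize
    (2/3 = surface of a spheroid, 1 = every cell, 0 = constant pool).
    """

    m: float
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        if self.m < 0:
            raise ValueError("colonization coefficient m must be >= 0")
        if not 0 <= self.alpha <= 1:
            raise ValueError("fractal dimension alpha must lie in [0, 1]")


@dataclass
class Cohort:
    """Metastases seeded within one step: identical size, expected count."""

    birth_day: float
    size: float
    count: float


class MetastaticState:
    """Primary tumor plus metastasis cohorts at one time point.

    Cohort data are stored as parallel arrays (birth day, log-size, count);
    the :attr:`cohorts` property materializes :class:`Cohort` records.
    """

    def __init__(
        self,
        t: float,
        primary_size: float,
        growth: GompertzParams,
        seeding: SeedingParams,
        birth_days=None,
        log_sizes=None,
        counts=None,
        primary_alive: bool = True,
    ):
        self.t = float(t)
        self.primary_size = float(primary_size)
        self.growth = growth
        self.seeding = seeding
        self.birth_days = np.asarray(birth_days if birth_days is not None else [], dtype=float)
        self.log_sizes = np.asarray(log_sizes if log_sizes is not None else [], dtype=float)
        self.counts = np.asarray(counts if counts is not None else [], dtype=float)
        self.primary_alive = primary_alive

    # -- views ----------------------------------------------------------------

    @property
    def sizes(self) -> np.ndarray:
        """Cohort sizes [cells]."""
        return np.exp(self.log_sizes)

    @property
    def cohorts(self) -> list[Cohort]:
        return [
            Cohort(b, s, c)
            for b, s, c in zip(self.birth_days, self.sizes, self.counts)
        ]

    # -- observables -----------------------------------------------------------

    def seeding_rate(self, secondary: bool = True) -> float:
        """Total dissemination rate ``integral beta rho dx`` [metastases/day].

        With ``secondary=True`` (default) metastases re-seed; otherwise only
        the primary contributes.
        """
        sp = self.seeding
        rate = sp.m * self.primary_size**sp.alpha if self.primary_alive else 0.0
        if secondary and self.counts.size:
            rate += sp.m * float(self.counts @ np.exp(sp.alpha * self.log_sizes))
        return rate

    def n_total(self) -> float:
        """Total expected number of tumors, primary included."""
        return (1.0 if self.primary_alive else 0.0) + float(self.counts.sum())

    def n_visible(self, s_vis: float) -> float:
        """Expected number of tumors at or above the detection limit ``s_vis``."""
        if s_vis < 1:
            raise ValueError("detection limit must be >= 1 cell")
        n = 1.0 if (self.primary_alive and self.primary_size >= s_vis) else 0.0
        if self.counts.size:
            n += float(self.counts[self.sizes >= s_vis].sum())
        return n

    def total_burden(self) -> float:
        """Total tumor burden: primary plus expected metastatic mass [cells]."""
        b = self.primary_size if self.primary_alive else 0.0
        if self.counts.size:
            b += float(self.counts @ self.sizes)
        return b

    def total_burden_ml(self) -> float:
        return self.total_burden() / CELLS_PER_ML

    def size_distribution(self, bin_edges) -> np.ndarray:
        """Expected tumor counts per size bin (primary included).

        ``bin_edges`` must be increasing; tumors outside the outer edges are
        not counted, so the histogram sums to :meth:`n_total` whenever the
        edges span ``[1, K]``.
        """
        edges = np.asarray(bin_edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be a strictly increasing 1-d sequence")
        sizes = self.sizes
        weights = self.counts
        if self.primary_alive:
            sizes = np.append(sizes, self.primary_size)
            weights = np.append(weights, 1.0)
        hist, _ = np.histogram(sizes, bins=edges, weights=weights)
        return hist

    def to_frame(self) -> pd.DataFrame:
        """Cohort table (birth_day, size_cells, count), primary first."""
        rows = {
            "birth_day": np.concatenate([[0.0], self.birth_days]),
            "size_cells": np.concatenate([[self.primary_size], self.sizes]),
            "count": np.concatenate([[1.0 if self.primary_alive else 0.0], self.counts]),
        }
        return pd.DataFrame(rows)

    def copy(self) -> "MetastaticState":
        return MetastaticState(
            self.t,
            self.primary_size,
            self.growth,
            self.seeding,
            self.birth_days.copy(),
            self.log_sizes.copy(),
            self.counts.copy(),
            self.primary_alive,
        )


# module-level aliases mirroring the functional interface


def seeding_rate(state: MetastaticState, secondary: bool = True) -> float:
    return state.seeding_rate(secondary=secondary)


def n_total(state: MetastaticState) -> float:
    return state.n_total()


def n_visible(state: MetastaticState, s_vis: float) -> float:
    return state.n_visible(s_vis)


def total_burden(state: MetastaticState) -> float:
    return state.total_burden()


def size_distribution(state: MetastaticState, bin_edges) -> np.ndarray:
    return state.size_distribution(bin_edges)


@dataclass(frozen=True)
class SolverOptions:
    """Numerical options of the characteristics solver.

    dt : base step [day]; therapy switch times and recording times are always
        inserted as additional step boundaries.
    secondary_seeding : whether metastases themselves seed (full boundary
        integral) or only the primary does.
    eradicate_below_one : remove tumors driven below one cell instead of
        clamping them at one cell.
    """

    dt: float = 1.0
    secondary_seeding: bool = True
    eradicate_below_one: bool = False


@dataclass
class SimulationResult:
    """Output of :func:`simulate`: recorded time series and the final state."""

    history: pd.DataFrame
    state: MetastaticState
    snapshots: dict = field(default_factory=dict)

    def snapshot_at(self, t: float) -> "MetastaticState":
        """State kept at snapshot time ``t`` (keys are rounded to 1e-9 days)."""
        return self.snapshots[float(np.round(t, 9))]


def _build_grid(t_end, dt, schedule, record_times, extra_breakpoints):
    pts = [0.0, float(t_end)]
    pts.extend(np.arange(0.0, t_end, dt))
    if schedule is not None:
        pts.extend(schedule.breakpoints(t_end))
    pts.extend(float(t) for t in record_times if 0.0 <= t <= t_end)
    pts.extend(float(t) for t in extra_breakpoints if 0.0 <= t <= t_end)
    grid = np.unique(np.round(np.asarray(pts, dtype=float), 9))
    return grid


def _hill_shift_integrals(grid, schedule, a):
    """Per-interval integrals J = int exp(-a (t1-s)) h(s) ds of the Hill kill.

    ``h(s) = sum_i chi_i c_i(s)/(c50_i + c_i(s))`` is smooth inside every
    interval (dose boundaries are grid points), so 5-node Simpson quadrature
    is used; returns both the full-interval and first-half-interval values
    (the latter initializes newborn cohorts at the step midpoint).
    """
    n = grid.size - 1
    if schedule is None or not schedule.immuno:
        return np.zeros(n), np.zeros(n)
    t0 = grid[:-1]
    d = np.diff(grid)
    frac = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    nodes = t0[:, None] + d[:, None] * frac[None, :]
    h = np.zeros_like(nodes)
    for c in schedule.immuno:
        conc = c.concentration(nodes.ravel()).reshape(nodes.shape)
        h += c.chi * conc / (c.c50 + conc)
    damp = np.exp(-a * d[:, None] * (1.0 - frac)[None, :])
    f = h * damp
    J = d / 12.0 * (f[:, 0] + 4 * f[:, 1] + 2 * f[:, 2] + 4 * f[:, 3] + f[:, 4])
    # Simpson on [t0, t0 + d/2] with damping referenced to the midpoint
    damp_h = np.exp(-a * d[:, None] * (0.5 - frac[:3])[None, :])
    fh = h[:, :3] * damp_h
    J_half = d / 12.0 * (fh[:, 0] + 4 * fh[:, 1] + fh[:, 2])
    return J, J_half


def _chemo_kills(grid, schedule):
    """Per-interval chemo log-kill; an interval is a chemo interval iff > 0 kill
    or any course is active on it (zero-efficacy applications still suppress
    growth by model definition)."""
    n = grid.size - 1
    kills = np.zeros(n)
    active = np.zeros(n, dtype=bool)
    if schedule is None:
        return kills, active
    t0, t1 = grid[:-1], grid[1:]
    mids = 0.5 * (t0 + t1)
    for c in schedule.chemo:
        days = np.array(c.application_days)
        if not days.size:
            continue
        idx = np.searchsorted(days, mids, side="right") - 1
        on = (idx >= 0) & (mids < days[np.maximum(idx, 0)] + c.window)
        if not on.any():
            continue
        active |= on
        # application windows never straddle grid intervals (their start/end
        # times are grid points), so the closed form applies per interval
        s0 = np.maximum(t0[on], days[idx[on]])
        s1 = np.minimum(t1[on], days[idx[on]] + c.window)
        a0 = c.cumulative_application(s0)
        if c.mu_star > 0:
            kills[on] += (
                c.mu0 / c.mu_star * np.exp(-c.mu_star * a0) * (-np.expm1(-c.mu_star * (s1 - s0)))
            )
        else:
            kills[on] += c.mu0 * (s1 - s0)
    return kills, active


@numba.njit(cache=True)
def _advance_kernel(
    i0, i1, d, decay, J, kills, chemo_on, u_new_tab, mids,
    lk, m, alpha, secondary, eradicate,
    u, counts, births, n, u_p, alive, r0,
    rec_flag, rec_pos, rec_burden, rec_ntotal, rec_primary, rec_rate,
    rec_nvis, log_svis,
):
    """Sequential interval loop of the characteristics solver.

    Mutates the cohort arrays in place and fills the record arrays at grid
    points flagged in ``rec_flag``; returns the updated scalar state.
    """
    for i in range(i0, i1):
        if chemo_on[i]:
            du = -kills[i]
            if alive:
                u_p += du
            for j in range(n):
                u[j] += du
        else:
            u_p = lk - (lk - u_p) * decay[i] - J[i]
            for j in range(n):
                u[j] = lk - (lk - u[j]) * decay[i] - J[i]
        if eradicate:
            if alive and u_p < 0.0:
                alive = False
            for j in range(n):
                if u[j] < 0.0:
                    counts[j] = 0.0
                    u[j] = 0.0
        else:
            if u_p < 0.0:
                u_p = 0.0
            for j in range(n):
                if u[j] < 0.0:
                    u[j] = 0.0
        # seeding rate after transport, trapezoidal increment over the step
        r1 = m * np.exp(alpha * u_p) if alive else 0.0
        if secondary:
            for j in range(n):
                r1 += m * counts[j] * np.exp(alpha * u[j])
        inc = 0.5 * (r0 + r1) * d[i]
        if inc > 0.0:
            un = u_new_tab[i]
            if un < 0.0:
                un = 0.0
            u[n] = un
            counts[n] = inc
            births[n] = mids[i]
            n += 1
            if secondary:
                r1 += m * inc * np.exp(alpha * un)
        r0 = r1
        if rec_flag[i + 1]:
            burden = np.exp(u_p) if alive else 0.0
            ntot = 1.0 if alive else 0.0
            for j in range(n):
                burden += counts[j] * np.exp(u[j])
                ntot += counts[j]
            rec_burden[rec_pos] = burden
            rec_ntotal[rec_pos] = ntot
            rec_primary[rec_pos] = np.exp(u_p) if alive else 0.0
            rec_rate[rec_pos] = r0
            if np.isfinite(log_svis):
                vis = 1.0 if (alive and u_p >= log_svis) else 0.0
                for j in range(n):
                    if u[j] >= log_svis:
                        vis += counts[j]
                rec_nvis[rec_pos] = vis
            rec_pos += 1
    return n, u_p, alive, r0, rec_pos


def simulate(
    growth: GompertzParams,
    seeding: SeedingParams,
    t_end: float,
    schedule: TherapySchedule | None = None,
    options: SolverOptions | None = None,
    record_times=None,
    s_vis: float | None = None,
    snapshot_times=(),
) -> SimulationResult:
    """Integrate primary tumor and metastatic density from one cell at t=0.

    Parameters
    ----------
    growth, seeding : model parameters shared by all tumors.
    t_end : simulation horizon [day].
    schedule : therapy plan; ``None`` for therapy-free growth.
    options : :class:`SolverOptions`.
    record_times : days at which to record the history; default: every
        multiple of ``dt`` plus ``t_end``.
    s_vis : detection limit for the recorded visible count (optional).
    snapshot_times : days at which to keep a full copy of the state.

    Returns
    -------
    SimulationResult
        ``history`` columns: day, primary_cells, n_total, burden_cells,
        burden_ml, seeding_rate, concentration (and n_visible if ``s_vis``).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    opts = options or SolverOptions()
    if opts.dt <= 0:
        raise ValueError("dt must be positive")
    if record_times is None:
        record_times = np.arange(0.0, t_end + opts.dt * 0.5, opts.dt)
    record_times = np.asarray(record_times, dtype=float)
    snapshot_times = np.asarray(list(snapshot_times), dtype=float)
    grid = _build_grid(t_end, opts.dt, schedule, record_times, snapshot_times)
    n_int = grid.size - 1
    lk = growth.log_K
    a = growth.a

    J, J_half = _hill_shift_integrals(grid, schedule, a)
    kills, chemo_on = _chemo_kills(grid, schedule)
    d = np.diff(grid)
    decay = np.exp(-a * d)
    decay_half = np.exp(-a * d * 0.5)

    # grid values are already rounded to 1e-9 d by _build_grid, so rounded
    # record/snapshot times compare exactly against grid entries
    rec_keys = np.unique(np.round(record_times, 9))
    snap_keys = {float(t) for t in np.round(snapshot_times, 9)}
    rec_flag = np.isin(grid, rec_keys)
    n_rec = int(rec_flag.sum())
    mids = 0.5 * (grid[:-1] + grid[1:])

    # cohort arrays (one potential cohort per interval)
    u = np.zeros(n_int + 1)
    counts = np.zeros(n_int + 1)
    births = np.zeros(n_int + 1)

    u_new = np.where(chemo_on, -0.5 * kills, lk * (1.0 - decay_half) - J_half)
    m, alpha = seeding.m, seeding.alpha
    log_svis = np.log(s_vis) if s_vis is not None else np.nan

    rec_burden = np.zeros(n_rec)
    rec_ntotal = np.zeros(n_rec)
    rec_primary = np.zeros(n_rec)
    rec_rate = np.zeros(n_rec)
    rec_nvis = np.zeros(n_rec)

    n = 0
    u_p = 0.0
    alive = True
    r0 = m * 1.0**alpha  # seeding rate of the one-cell primary
    rec_pos = 0
    snapshots = {}

    def make_state(t):
        return MetastaticState(
            t,
            np.exp(u_p) if alive else 1.0,
            growth,
            seeding,
            births[:n].copy(),
            u[:n].copy(),
            counts[:n].copy(),
            primary_alive=alive,
        )

    if rec_flag[0]:
        rec_burden[0] = 1.0
        rec_ntotal[0] = 1.0
        rec_primary[0] = 1.0
        rec_rate[0] = r0
        rec_nvis[0] = 1.0 if (np.isfinite(log_svis) and 0.0 >= log_svis) else (
            1.0 if not np.isfinite(log_svis) else 0.0
        )
        rec_pos = 1
    if float(grid[0]) in snap_keys:
        snapshots[float(grid[0])] = make_state(grid[0])

    # segment the run at snapshot times so full states can be materialized
    snap_idx = [i for i, k in enumerate(grid) if float(k) in snap_keys and i > 0]
    seg_bounds = [0] + snap_idx + ([n_int] if n_int not in snap_idx else [])

    for s0, s1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        n, u_p, alive, r0, rec_pos = _advance_kernel(
            s0, s1, d, decay, J, kills, chemo_on, u_new, mids,
            lk, m, alpha, opts.secondary_seeding, opts.eradicate_below_one,
            u, counts, births, n, u_p, alive, r0,
            rec_flag, rec_pos, rec_burden, rec_ntotal, rec_primary, rec_rate,
            rec_nvis, log_svis,
        )
        key = float(grid[s1])
        if key in snap_keys:
            snapshots[key] = make_state(grid[s1])

    rec_days = grid[rec_flag]
    history = pd.DataFrame(
        {
            "day": rec_days,
            "primary_cells": rec_primary,
            "n_total": rec_ntotal,
            "burden_cells": rec_burden,
            "burden_ml": rec_burden / CELLS_PER_ML,
            "seeding_rate": rec_rate,
            "concentration": (
                np.asarray(schedule.total_concentration(rec_days), dtype=float)
                if schedule is not None and schedule.immuno
                else np.zeros(n_rec)
            ),
        }
    )
    if s_vis is not None:
        history["n_visible"] = rec_nvis
    return SimulationResult(history=history, state=make_state(grid[-1]), snapshots=snapshots)
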