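"""Therapy dynamics: chemotherapy log-kill with kinetic resistance and
checkpoint-inhibitor pharmacokinetics with a Hill-type kill term.

Chemotherapy
------------
An application of drug *i* on a calendar day switches the growth law to a
pure log-kill ``dx/dt = -mu_i(t) x`` (tumor growth is neglected while a
short-half-life cytotoxic drug is active).  The kill fraction decays with
cumulative exposure ("kinetic resistance"):

``d mu/dt = -mu_star * mu`` while the drug is applied, 0 otherwise,

so ``mu(t) = mu0 * exp(-mu_star * A(t))`` with ``A(t)`` the cumulative
application time before ``t``.

Immunotherapy
-------------
Monoclonal antibodies have half-lives of weeks, so a one-compartment
pharmacokinetic balance is tracked in molecules per (fixed) body volume:

``dc/dt = -(ln 2 / t_half) c + (N_A / M) d(t)``

with dosing active on application days.  Under q-``l``-weekly dosing the
cycle-mean concentration converges to the steady state
``c_st = (N_A/M) (d/l) t_half / ln 2``.  The pharmacodynamic effect is a
first-order Hill kill ``chi * c / (c50 + c)`` per cell per day added to the
Gompertz growth law.

Both course types are immutable value objects; concentration evaluation uses
the exact piecewise-exponential solution of the linear PK equation.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .constants import AVOGADRO
from .growth import GompertzParams, growth_rate

__all__ = [
    "ChemoCourse",
    "ImmunoCourse",
    "ConcentrationTrace",
    "TherapySchedule",
    "drug_catalog",
    "chemo_efficacy",
    "pk_concentration",
    "steady_state_concentration",
    "effective_growth",
]

LN2 = float(np.log(2.0))


@functools.lru_cache(maxsize=1)
def drug_catalog() -> pd.DataFrame:
    """Catalog of approved PD-1/PD-L1 antibodies and their regimens.

    Columns: drug_id, antibody, type, molar_mass_kda, dose_mg, cycle_days,
    half_life_days, note.  Weight-based regimens are listed at a 75 kg
    reference body mass.
    """
    with resources.files("metaburden.data").joinpath("drugs.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class ChemoCourse:
    """A chemotherapy course: application calendar plus efficacy parameters.

    Parameters
    ----------
    drug_id : str
        Label, e.g. ``"cisplatin-pemetrexed"`` for the standard combination.
    application_days : tuple of float
        Day on which each administration starts; the drug is considered
        active over ``[d, d + window)``.
    mu0 : float
        Initial fractional kill efficacy [1/day], >= 0.
    mu_star : float
        Refractory decay fraction per day of application, >= 0.
    window : float
        Duration of one application [day]; default one calendar day.
    """

    drug_id: str
    application_days: tuple
    mu0: float
    mu_star: float
    window: float = 1.0

    def __post_init__(self):
        days = tuple(float(d) for d in self.application_days)
        object.__setattr__(self, "application_days", days)
        if any(d < 0 for d in days):
            raise ValueError("application days must be non-negative")
        if list(days) != sorted(days):
            raise ValueError("application days must be sorted")
        if any(b - a < self.window for a, b in zip(days, days[1:])):
            raise ValueError("applications must not overlap")
        if self.mu0 < 0 or self.mu_star < 0:
            raise ValueError("mu0 and mu_star must be non-negative")
        if not self.window > 0:
            raise ValueError("application window must be positive")

    # -- exposure bookkeeping -------------------------------------------------

    def cumulative_application(self, t):
        """Cumulative drug application time ``A(t)`` before time ``t`` [day]."""
        t = np.asarray(t, dtype=float)
        days = np.array(self.application_days)
        out = np.clip(t[..., None] - days, 0.0, self.window).sum(axis=-1)
        return float(out) if out.ndim == 0 else out

    def is_active(self, t: float) -> bool:
        """Whether the drug is applied at time ``t``."""
        days = np.array(self.application_days)
        return bool(np.any((days <= t) & (t < days + self.window)))

    def efficacy(self, t):
        """Kill fraction ``mu(t) = mu0 exp(-mu_star A(t))`` [1/day].

        Non-increasing in ``t``; before the course starts it equals ``mu0``.
        """
        return self.mu0 * np.exp(-self.mu_star * self.cumulative_application(t))

    def log_kill(self, t0: float, t1: float) -> float:
        """Exact ``integral of 1_C(s) mu(s) ds`` over ``[t0, t1]``.

        The tumor shrinks multiplicatively by ``exp(-log_kill)`` over the
        interval.  Closed form per application window: while the drug is
        active ``A`` increases at unit rate, so the integral telescopes to
        ``(mu0/mu_star) (e^{-mu_star A0} - e^{-mu_star A1})``.
        """
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        total = 0.0
        for d in self.application_days:
            s0, s1 = max(t0, d), min(t1, d + self.window)
            if s1 <= s0:
                continue
            a0 = self.cumulative_application(s0)
            if self.mu_star > 0:
                total += self.mu0 / self.mu_star * np.exp(-self.mu_star * a0) * (
                    -np.expm1(-self.mu_star * (s1 - s0))
                )
            else:
                total += self.mu0 * (s1 - s0)
        return float(total)


@dataclass(frozen=True)
class ImmunoCourse:
    """An immunotherapy course: cyclic antibody dosing plus Hill efficacy.

    Doses are modeled as one-day infusions by default (``infusion_days=1``);
    setting ``infusion_days=0`` switches to an instantaneous bolus.  The
    cycle-mean steady state is identical for both.  ``doses_mg`` allows
    per-application dose overrides (e.g. a doubled loading dose) while
    ``dose_mg`` remains the nominal regimen dose used for the steady state.
    """

    drug_id: str
    dose_mg: float
    cycle_days: float
    molar_mass_kda: float
    half_life_days: float
    application_days: tuple
    chi: float
    c50: float
    infusion_days: float = 1.0
    doses_mg: tuple | None = None

    def __post_init__(self):
        days = tuple(float(d) for d in self.application_days)
        object.__setattr__(self, "application_days", days)
        if self.molar_mass_kda <= 0 or self.half_life_days <= 0:
            raise ValueError("molar mass and half-life must be positive")
        if self.chi < 0:
            raise ValueError("chi must be non-negative")
        if not self.c50 > 0:
            raise ValueError("c50 must be positive")
        if self.infusion_days < 0:
            raise ValueError("infusion duration must be >= 0")
        if list(days) != sorted(days):
            raise ValueError("application days must be sorted")
        if self.doses_mg is not None and len(self.doses_mg) != len(days):
            raise ValueError("doses_mg must match application_days in length")

    @classmethod
    def from_catalog(
        cls,
        drug_id: str,
        start_day: float,
        n_doses: int,
        chi: float,
        c50: float,
        dose_mg: float | None = None,
        doses_mg: tuple | None = None,
        infusion_days: float = 1.0,
    ) -> "ImmunoCourse":
        """Build a course from the packaged regimen table (:func:`drug_catalog`)."""
        cat = drug_catalog()
        row = cat[cat.drug_id == drug_id]
        if row.empty:
            raise KeyError(f"unknown drug_id {drug_id!r}; known: {list(cat.drug_id)}")
        row = row.iloc[0]
        l = float(row.cycle_days)
        days = tuple(start_day + j * l for j in range(int(n_doses)))
        return cls(
            drug_id=drug_id,
            dose_mg=float(dose_mg if dose_mg is not None else row.dose_mg),
            cycle_days=l,
            molar_mass_kda=float(row.molar_mass_kda),
            half_life_days=float(row.half_life_days),
            application_days=days,
            chi=chi,
            c50=c50,
            infusion_days=infusion_days,
            doses_mg=doses_mg,
        )

    # -- pharmacokinetics ------------------------------------------------------

    @property
    def clearance_rate(self) -> float:
        """First-order clearance rate ``ln(2)/t_half`` [1/day]."""
        return LN2 / self.half_life_days

    def molecules_per_dose(self, dose_mg: float | None = None) -> float:
        """Number of drug molecules per administered dose."""
        d = self.dose_mg if dose_mg is None else dose_mg
        # dose [mg] -> g -> mol (M in kDa = 1000 g/mol) -> molecules
        return d * AVOGADRO / (self.molar_mass_kda * 1e6)

    def concentration(self, t):
        """Exact drug concentration at time(s) ``t`` [molecules per body volume].

        Piecewise-exponential superposition of all administered doses; a dose
        at day ``d`` is infused at constant rate over ``[d, d + w)`` and then
        cleared with rate ``ln 2 / t_half``.
        """
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        k = self.clearance_rate
        w = self.infusion_days
        days = np.array(self.application_days)
        doses = (
            np.array(self.doses_mg, dtype=float)
            if self.doses_mg is not None
            else np.full(days.shape, self.dose_mg)
        )
        n_mol = doses * AVOGADRO / (self.molar_mass_kda * 1e6)
        out = np.zeros_like(t)
        if days.size:
            dt = t[:, None] - days[None, :]
            if w > 0:
                rate = n_mol / w
                during = (dt >= 0) & (dt < w)
                after = dt >= w
                contrib = np.zeros_like(dt)
                contrib[during] = -np.expm1(-k * dt[during])
                # value at end of infusion, then pure decay
                end_val = -np.expm1(-k * w)
                contrib[after] = end_val * np.exp(-k * (dt[after] - w))
                out = (contrib * (rate / k)[None, :]).sum(axis=1)
            else:
                after = dt >= 0
                contrib = np.where(after, np.exp(-k * np.maximum(dt, 0.0)), 0.0)
                out = (contrib * n_mol[None, :]).sum(axis=1)
        return float(out[0]) if scalar else out

    def steady_state_concentration(self) -> float:
        """Cycle-mean steady-state concentration ``c_st`` (closed form).

        ``c_st = (N_A / M) (d / l) t_half / ln 2``, i.e. mean input rate over
        clearance rate; independent of the infusion-vs-bolus choice.
        """
        return self.molecules_per_dose() / self.cycle_days / self.clearance_rate

    def hill_kill_rate(self, t):
        """Per-cell kill rate ``chi c(t) / (c50 + c(t))`` [1/day]."""
        c = self.concentration(t)
        return self.chi * c / (self.c50 + c)


@dataclass(frozen=True)
class ConcentrationTrace:
    """Sampled drug concentration on a day grid."""

    times: np.ndarray
    conc: np.ndarray

    def at(self, t):
        return np.interp(t, self.times, self.conc)


def chemo_efficacy(course: ChemoCourse, t):
    """Kill fraction ``mu(t)`` of a chemotherapy course (module-level alias)."""
    return course.efficacy(t)


def pk_concentration(course: ImmunoCourse, horizon: float, dt: float) -> ConcentrationTrace:
    """Sample the exact PK solution on a uniform grid up to ``horizon``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    times = np.arange(0.0, horizon + dt * 0.5, dt)
    return ConcentrationTrace(times=times, conc=np.atleast_1d(course.concentration(times)))


def steady_state_concentration(course: ImmunoCourse) -> float:
    """Closed-form cycle-mean steady state ``c_st`` (module-level alias)."""
    return course.steady_state_concentration()


def cycle_average_concentration(course: ImmunoCourse, cycle_start: float) -> float:
    """Average concentration over one dosing cycle starting at ``cycle_start``.

    Computed by fine trapezoidal quadrature of the exact PK solution.
    """
    ts = np.linspace(cycle_start, cycle_start + course.cycle_days, 2001)
    return float(np.trapezoid(course.concentration(ts), ts) / course.cycle_days)


@dataclass(frozen=True)
class TherapySchedule:
    """A patient's full therapy plan: chemo course(s) followed by immunotherapy.

    A joint administration of both modalities is clinically not applicable and
    rejected: every chemotherapy application must end before the first
    immunotherapy dose.
    """

    chemo: tuple = ()
    immuno: tuple = ()

    def __post_init__(self):
        chemo = tuple(self.chemo) if not isinstance(self.chemo, ChemoCourse) else (self.chemo,)
        immuno = tuple(self.immuno) if not isinstance(self.immuno, ImmunoCourse) else (self.immuno,)
        object.__setattr__(self, "chemo", chemo)
        object.__setattr__(self, "immuno", immuno)
        first_immuno = min(
            (min(c.application_days) for c in immuno if c.application_days), default=np.inf
        )
        for c in chemo:
            if c.application_days and max(c.application_days) + c.window > first_immuno:
                raise ValueError(
                    "chemotherapy applications overlap the immunotherapy era; "
                    "joint treatment is not supported"
                )

    def chemo_active(self, t: float) -> bool:
        return any(c.is_active(t) for c in self.chemo)

    def total_concentration(self, t):
        out = 0.0
        for c in self.immuno:
            out = out + c.concentration(t)
        return out

    def hill_kill_rate(self, t):
        out = 0.0
        for c in self.immuno:
            out = out + c.hill_kill_rate(t)
        return out

    def breakpoints(self, t_end: float):
        """Time points where the right-hand side switches branch."""
        pts = []
        for c in self.chemo:
            for d in c.application_days:
                if d < t_end:
                    pts += [d, min(d + c.window, t_end)]
        for c in self.immuno:
            for d in c.application_days:
                if d < t_end:
                    pts.append(d)
                    if c.infusion_days > 0:
                        pts.append(min(d + c.infusion_days, t_end))
        return pts


def effective_growth(
    g_params: GompertzParams,
    chemo: ChemoCourse | None,
    immuno: ImmunoCourse | None,
    conc: ConcentrationTrace | None,
    x,
    t: float,
):
    """Therapy-aware growth rate ``g(x, t)`` [cells/day].

    On a chemotherapy application day the rate is the pure log-kill
    ``-mu(t) x`` (growth neglected).  Otherwise it is the Gompertz term minus,
    if an immunotherapy course is present, the Hill kill driven by the current
    concentration (taken from ``conc`` if given, else from the course's exact
    PK solution).  Raises if both modalities are active at ``t``.
    """
    chemo_on = chemo is not None and chemo.is_active(t)
    immuno_on = immuno is not None and immuno.application_days and t >= min(immuno.application_days)
    if chemo_on and immuno_on:
        raise ValueError("chemo and immunotherapy must not be active simultaneously")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    if chemo_on:
        out = -chemo.efficacy(t) * x
    else:
        out = np.asarray(growth_rate(g_params, x), dtype=float)
        if immuno is not None:
            c = conc.at(t) if conc is not None else immuno.concentration(t)
            out = out - immuno.chi * c / (immuno.c50 + c) * x
    return float(out) if scalar else out
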