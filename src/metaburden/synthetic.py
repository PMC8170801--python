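"""Virtual patients with known ground truth.

The clinical series behind this framework are sparse: a handful of CT visits
per patient, each yielding a total tumor burden (sum of all volumetrically
measured lesions) plus a lesion list thresholded at the scanner's effective
detection limit.  This module forward-simulates the full model — Gompertz
primary growth, metastatic seeding, platinum-doublet chemotherapy followed by
checkpoint-inhibitor immunotherapy — for a chosen parameter vector and emits
exactly that kind of dataset, with multiplicative lognormal noise on the
measured burdens, so every downstream stage can be tested against a known
truth.

Default parameter magnitudes follow the fitted NSCLC patients (growth rate
``a ~ 7e-3``/day, colonization ``m ~ 2e-7``, Hill efficacy ``chi ~ 0.07-0.1``
per day, ``c50 ~ 1e16`` molecules/volume); the default clinical timeline is
four q3w chemotherapy cycles from diagnosis, second-line immunotherapy from
day 90, and five CT visits spread over eight months.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import qmc

from .constants import DEFAULT_ALPHA, DEFAULT_K
from .growth import GompertzParams, tumor_age
from .density import SeedingParams, SolverOptions, simulate
from .fitting import PatientDataset
from .therapy import drug_catalog

__all__ = ["VirtualPatientSpec", "generate", "cohort", "apply_measurement_noise"]


@dataclass(frozen=True)
class VirtualPatientSpec:
    """Ground-truth parameters and study design of one virtual patient."""

    a: float = 7.2e-3
    m: float = 1.8e-7
    alpha: float = DEFAULT_ALPHA
    K: float = DEFAULT_K
    mu0: float = 0.18
    mu_star: float = 0.13
    chi: float = 0.08
    c50: float = 1.01e16
    chemo_cycles: int = 4
    chemo_cycle_days: float = 21.0
    chemo_drug: str = "cisplatin-pemetrexed"
    immuno_drug: str = "pembrolizumab"
    immuno_start_offset: float = 90.0
    diagnosis_size_cells: float = 2e11
    visit_offsets: tuple = (0.0, 60.0, 120.0, 180.0, 240.0)
    noise_sd: float = 0.05
    s_vis: float = 1e8
    seed: int = 0
    patient_id: str = "virtual"

    def __post_init__(self):
        object.__setattr__(self, "visit_offsets", tuple(float(v) for v in self.visit_offsets))
        if not 1 < self.diagnosis_size_cells < self.K:
            raise ValueError("diagnosis size must lie in (1, K)")
        if any(b <= a for a, b in zip(self.visit_offsets, self.visit_offsets[1:])):
            raise ValueError("visit offsets must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.s_vis < 1:
            raise ValueError("detection limit must be >= 1 cell")


def apply_measurement_noise(burdens, sd: float, rng: np.random.Generator):
    """Multiplicative lognormal measurement noise: ``b * exp(N(0, sd))``.

    CT volumetry error scales with lesion volume, hence a multiplicative
    model; ``sd`` is the standard deviation of the log measurement.
    """
    burdens = np.asarray(burdens, dtype=float)
    if sd == 0:
        return burdens.copy()
    return burdens * np.exp(rng.normal(0.0, sd, size=burdens.shape))


def generate(spec: VirtualPatientSpec, options: SolverOptions | None = None):
    """Forward-simulate a virtual patient and emit dataset plus truth record.

    Returns
    -------
    dataset : PatientDataset
        Noisy total-burden measurements at the visit days, with the
        structural therapy schedule attached.
    truth : dict
        True parameters, diagnosis day, noise-free burdens, visible lesion
        lists (size, expected count) per visit, and tumor counts at
        diagnosis.  Deterministic given ``spec.seed``.
    """
    gp = GompertzParams(spec.a, spec.K)
    diagnosis_day = tumor_age(gp, spec.diagnosis_size_cells)
    last_visit = spec.visit_offsets[-1]
    chemo_offsets = tuple(j * spec.chemo_cycle_days for j in range(spec.chemo_cycles))
    cat = drug_catalog()
    row = cat[cat.drug_id == spec.immuno_drug]
    if row.empty:
        raise KeyError(f"unknown immuno drug {spec.immuno_drug!r}")
    l = float(row.iloc[0].cycle_days)
    if chemo_offsets and spec.immuno_start_offset < chemo_offsets[-1] + 1:
        raise ValueError("immunotherapy must start after the chemotherapy era")
    n_doses = int(np.floor((last_visit - spec.immuno_start_offset) / l)) + 1
    immuno_offsets = (
        tuple(spec.immuno_start_offset + j * l for j in range(max(n_doses, 0)))
        if spec.immuno_start_offset <= last_visit
        else ()
    )

    dataset_schedule = PatientDataset(
        patient_id=spec.patient_id,
        days=spec.visit_offsets,
        burdens_cells=tuple(1.0 + i for i in range(len(spec.visit_offsets))),  # placeholder
        primary_size_at_diagnosis=spec.diagnosis_size_cells,
        chemo_offsets=chemo_offsets,
        chemo_drug=spec.chemo_drug,
        immuno_offsets=immuno_offsets,
        immuno_drug=spec.immuno_drug,
        K=spec.K,
        alpha=spec.alpha,
        s_vis=spec.s_vis,
    )
    params = {
        "a": spec.a, "m": spec.m, "mu0": spec.mu0, "mu_star": spec.mu_star,
        "chi": spec.chi, "c50": spec.c50,
    }
    schedule = dataset_schedule.build_schedule(params, diagnosis_day)
    visit_days = np.asarray(spec.visit_offsets) + diagnosis_day
    res = simulate(
        gp,
        SeedingParams(spec.m, spec.alpha),
        float(visit_days[-1]) + 1e-6,
        schedule=schedule,
        options=options,
        record_times=visit_days,
        s_vis=spec.s_vis,
        snapshot_times=visit_days,
    )
    hist = res.history.set_index("day")
    true_burdens = np.interp(visit_days, hist.index.values, hist["burden_cells"].values)

    rng = np.random.default_rng(spec.seed)
    measured = apply_measurement_noise(true_burdens, spec.noise_sd, rng)

    lesion_lists = []
    for t in visit_days:
        st = res.snapshot_at(t)
        visible = [
            (float(s), float(c))
            for s, c in zip(st.sizes, st.counts)
            if s >= spec.s_vis and c > 0
        ]
        if st.primary_alive and st.primary_size >= spec.s_vis:
            visible.append((float(st.primary_size), 1.0))
        lesion_lists.append(sorted(visible, reverse=True))

    diag_state = res.snapshot_at(visit_days[0])
    truth = {
        "params": params,
        "alpha": spec.alpha,
        "K": spec.K,
        "diagnosis_day": float(diagnosis_day),
        "visit_days_absolute": [float(t) for t in visit_days],
        "true_burdens_cells": [float(b) for b in true_burdens],
        "n_total_at_diagnosis": diag_state.n_total(),
        "n_visible_at_diagnosis": diag_state.n_visible(spec.s_vis),
        "visible_lesions": lesion_lists,
        "spec": asdict(spec),
    }

    dataset = PatientDataset(
        patient_id=spec.patient_id,
        days=spec.visit_offsets,
        burdens_cells=tuple(measured),
        primary_size_at_diagnosis=spec.diagnosis_size_cells,
        chemo_offsets=chemo_offsets,
        chemo_drug=spec.chemo_drug,
        immuno_offsets=immuno_offsets,
        immuno_drug=spec.immuno_drug,
        K=spec.K,
        alpha=spec.alpha,
        s_vis=spec.s_vis,
    )
    return dataset, truth


#: parameter ranges for cohort sampling, centered on the fitted-patient scales
DEFAULT_COHORT_RANGES = {
    "a": (5.5e-3, 9e-3),
    "m": (1e-7, 4e-7),
    "mu0": (0.08, 0.30),
    "chi": (0.05, 0.12),
}

_LOG_SAMPLED = frozenset({"m", "c50"})


def cohort(n: int, ranges: dict | None = None, seed: int = 0, **spec_overrides):
    """Latin-hypercube sample of ``n`` virtual-patient specs.

    ``ranges`` maps parameter names (fields of :class:`VirtualPatientSpec`)
    to ``(lo, hi)``; ``m`` and ``c50`` are sampled log-uniformly.  ``n = 1``
    returns the range midpoints.  Each spec receives its own child seed, so
    the cohort is reproducible from ``seed`` alone.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ranges = dict(DEFAULT_COHORT_RANGES if ranges is None else ranges)
    if not ranges:
        raise ValueError("empty parameter ranges")
    names = sorted(ranges)
    lo = np.array([np.log10(ranges[k][0]) if k in _LOG_SAMPLED else ranges[k][0] for k in names])
    hi = np.array([np.log10(ranges[k][1]) if k in _LOG_SAMPLED else ranges[k][1] for k in names])
    if np.any(hi <= lo):
        raise ValueError("each range must satisfy lo < hi")
    if n == 1:
        unit = np.full((1, len(names)), 0.5)
    else:
        unit = qmc.LatinHypercube(d=len(names), seed=seed).random(n)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    specs = []
    for i in range(n):
        vals = lo + (hi - lo) * unit[i]
        kwargs = dict(spec_overrides)
        for k, v in zip(names, vals):
            kwargs[k] = float(10.0**v) if k in _LOG_SAMPLED else float(v)
        kwargs.setdefault("patient_id", f"virtual-{i:03d}")
        specs.append(VirtualPatientSpec(seed=int(child_seeds[i]), **kwargs))
    return specs
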