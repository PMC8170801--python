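"""Characteristics solver for the size-structured metastatic density."""

import numpy as np
import pytest
from scipy.integrate import quad

from metaburden.density import (
    MetastaticState,
    SeedingParams,
    SolverOptions,
    n_total,
    n_visible,
    seeding_rate,
    simulate,
    size_distribution,
    total_burden,
)
from metaburden.growth import GompertzParams, size_at
from metaburden.therapy import ChemoCourse, ImmunoCourse, TherapySchedule

GP = GompertzParams(7.284e-3)
SP = SeedingParams(1.635e-7)


def two_cohort_state():
    return MetastaticState(
        t=100.0, primary_size=8.0, growth=GP, seeding=SeedingParams(1.0, 2 / 3),
        birth_days=[40.0, 80.0], log_sizes=np.log([27.0, 8.0]), counts=[2.0, 3.5],
    )


class TestSeedingRate:
    def test_zero_colonization_means_no_seeding(self):
        st = MetastaticState(0.0, 8.0, GP, SeedingParams(0.0))
        assert seeding_rate(st) == 0.0

    def test_spheroid_surface_scaling(self):
        st = MetastaticState(0.0, 8.0, GP, SeedingParams(1.0, 2 / 3))
        assert seeding_rate(st) == pytest.approx(4.0)  # 8^(2/3)

    def test_matches_brute_force_sum(self):
        st = two_cohort_state()
        brute = 8.0 ** (2 / 3) + 2.0 * 27.0 ** (2 / 3) + 3.5 * 8.0 ** (2 / 3)
        assert seeding_rate(st) == pytest.approx(brute, rel=1e-12)
        assert seeding_rate(st, secondary=False) == pytest.approx(8.0 ** (2 / 3), rel=1e-12)


class TestObservables:
    def test_counts_and_burden(self):
        st = two_cohort_state()
        assert n_total(st) == pytest.approx(1 + 2.0 + 3.5)
        assert total_burden(st) == pytest.approx(8.0 + 2 * 27.0 + 3.5 * 8.0)

    def test_visible_count_is_tail_of_distribution(self):
        st = two_cohort_state()
        assert n_visible(st, 1.0) == pytest.approx(n_total(st))
        assert n_visible(st, GP.K * 2) == 0.0
        svis = np.array([1.0, 8.0, 9.0, 28.0])
        vals = [n_visible(st, s) for s in svis]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_histogram_sums_to_total_and_survives_rebinning(self):
        st = two_cohort_state()
        coarse = st.size_distribution([1.0, 1e3, 1e12])
        fine = st.size_distribution(np.logspace(0, 12, 25))
        assert coarse.sum() == pytest.approx(n_total(st))
        assert fine.sum() == pytest.approx(n_total(st))
        with pytest.raises(ValueError):
            size_distribution(st, [10.0, 1.0])

    def test_single_tumor_occupies_one_bin(self):
        st = MetastaticState(0.0, 50.0, GP, SP)
        hist = st.size_distribution([1.0, 10.0, 100.0, 1000.0])
        assert hist.tolist() == [0.0, 1.0, 0.0]


class TestTherapyFreeTransport:
    def test_no_seeding_reduces_to_single_gompertz(self):
        res = simulate(GP, SeedingParams(0.0), 407.0, record_times=[100.0, 407.0])
        assert res.state.n_total() == 1.0
        assert res.state.total_burden() == pytest.approx(size_at(GP, 407.0), rel=1e-12)
        np.testing.assert_allclose(
            res.history["burden_cells"], size_at(GP, res.history["day"].values), rtol=1e-12
        )

    def test_cohorts_follow_shifted_closed_form(self):
        res = simulate(GP, SP, 407.0, record_times=[407.0])
        st = res.state
        expected = size_at(GP, 407.0 - st.birth_days)
        np.testing.assert_allclose(st.sizes, expected, rtol=1e-10)

    def test_characteristics_never_cross(self):
        res = simulate(GP, SP, 407.0)
        st = res.state
        assert np.all(np.diff(st.birth_days) > 0)
        assert np.all(np.diff(st.sizes) < 0)

    def test_mass_balance_with_seeding(self):
        # d N_total / dt = seeding rate: the recorded rate integrates to N - 1
        res = simulate(GP, SP, 407.0)
        h = res.history
        integral = np.trapezoid(h["seeding_rate"].values, h["day"].values)
        assert res.state.n_total() - 1.0 == pytest.approx(integral, rel=2e-3)

    def test_primary_only_seeding_matches_quadrature(self):
        res = simulate(GP, SP, 407.0, options=SolverOptions(secondary_seeding=False),
                       record_times=[407.0])
        expected = quad(lambda t: SP.m * size_at(GP, t) ** SP.alpha, 0, 407.0, limit=200)[0]
        assert res.state.n_total() - 1.0 == pytest.approx(expected, rel=5e-3)

    def test_halving_dt_changes_results_below_one_percent(self):
        r1 = simulate(GP, SP, 407.0, record_times=[407.0])
        r2 = simulate(GP, SP, 407.0, options=SolverOptions(dt=0.5), record_times=[407.0])
        assert r2.state.n_total() == pytest.approx(r1.state.n_total(), rel=1e-2)
        assert r2.state.total_burden() == pytest.approx(r1.state.total_burden(), rel=1e-2)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            simulate(GP, SP, -1.0)
        with pytest.raises(ValueError):
            simulate(GP, SP, 10.0, options=SolverOptions(dt=-0.5))


def immuno_schedule(chi, start=300.0, n=6):
    return TherapySchedule(
        immuno=(ImmunoCourse.from_catalog("pembrolizumab", start, n, chi=chi, c50=1e16),)
    )


class TestTherapyCoupling:
    def test_zero_efficacy_immunotherapy_is_bit_identical_to_therapy_free(self):
        sched = immuno_schedule(chi=0.0)
        rec = np.arange(0.0, 401.0, 1.0)
        res_t = simulate(GP, SP, 400.0, schedule=sched, record_times=rec)
        # therapy-free run on the identical step grid (dose days as snapshots)
        res_f = simulate(GP, SP, 400.0, record_times=rec,
                         snapshot_times=sched.breakpoints(400.0))
        assert np.array_equal(res_t.history["burden_cells"].values,
                              res_f.history["burden_cells"].values)
        assert np.array_equal(res_t.state.log_sizes, res_f.state.log_sizes)
        assert np.array_equal(res_t.state.counts, res_f.state.counts)

    def test_immunotherapy_shrinks_burden(self):
        res_f = simulate(GP, SP, 420.0, record_times=[420.0])
        res_t = simulate(GP, SP, 420.0, schedule=immuno_schedule(chi=0.1), record_times=[420.0])
        assert res_t.state.total_burden() < res_f.state.total_burden()

    def test_chemo_day_applies_exact_log_kill_to_all_tumors(self):
        chemo = ChemoCourse("cis-pem", (350.0,), mu0=0.3, mu_star=0.1)
        sched = TherapySchedule(chemo=(chemo,))
        res = simulate(GP, SP, 352.0, schedule=sched, snapshot_times=[350.0, 351.0])
        before = res.snapshot_at(350.0)
        after = res.snapshot_at(351.0)
        factor = np.exp(-chemo.log_kill(350.0, 351.0))
        assert after.primary_size == pytest.approx(before.primary_size * factor, rel=1e-12)
        nc = len(before.log_sizes)
        big = before.sizes[: nc // 2]  # cohorts far from the 1-cell floor
        np.testing.assert_allclose(after.sizes[: nc // 2], big * factor, rtol=1e-12)

    def test_kill_clamps_at_one_cell_by_default(self):
        chemo = ChemoCourse("cis-pem", tuple(300.0 + j for j in range(5)), mu0=30.0, mu_star=0.0)
        res = simulate(GP, SeedingParams(1e-7), 310.0, schedule=TherapySchedule(chemo=(chemo,)),
                       record_times=[310.0])
        st = res.state
        assert st.primary_alive
        assert st.sizes.min() >= 1.0
        assert st.n_total() == pytest.approx(1.0 + st.counts.sum())

    def test_eradication_option_removes_dead_cohorts(self):
        chemo = ChemoCourse("cis-pem", tuple(300.0 + j for j in range(5)), mu0=30.0, mu_star=0.0)
        res = simulate(
            GP, SeedingParams(1e-7), 310.0, schedule=TherapySchedule(chemo=(chemo,)),
            options=SolverOptions(eradicate_below_one=True), record_times=[310.0],
        )
        clamped = simulate(GP, SeedingParams(1e-7), 310.0,
                           schedule=TherapySchedule(chemo=(chemo,)), record_times=[310.0])
        assert res.state.n_total() < clamped.state.n_total()


class TestAgainstFiniteVolumeOracle:
    def test_small_instance_matches_upwind_solver(self):
        """Cohort tracking vs an independent conservative upwind scheme."""
        from oracles import finite_volume_reference

        a, K, m, alpha, T = 0.1, 1e6, 1e-4, 2 / 3, 200.0
        fv = finite_volume_reference(a, K, m, alpha, T, n_cells=3000)
        res = simulate(GompertzParams(a, K), SeedingParams(m, alpha), T, record_times=[T])
        st = res.state
        assert st.n_total() == pytest.approx(fv["n_total"], rel=2e-2)
        assert st.total_burden() == pytest.approx(fv["burden"], rel=2e-2)
        bins = np.logspace(0, 6, 7)
        h_cohort = st.size_distribution(bins)
        h_fv = fv["histogram"](bins)
        np.testing.assert_array_less(
            np.abs(h_cohort - h_fv) / st.n_total(), 2e-2,
            err_msg="per-bin counts deviate by more than 2 % of the total",
        )
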