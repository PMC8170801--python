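"""Forward prediction, bounded least squares, standard errors, regimens."""

import numpy as np
import pytest
from scipy.integrate import quad

from metaburden.density import SolverOptions
from metaburden.fitting import (
    PatientDataset,
    compare_regimens,
    fit,
    simulate_for_fit,
    standard_errors,
)
from metaburden.growth import GompertzParams, size_at, tumor_age
from metaburden.synthetic import VirtualPatientSpec, generate
from metaburden.therapy import ImmunoCourse


@pytest.fixture(scope="module")
def noise_free_patient():
    spec = VirtualPatientSpec(noise_sd=0.0, seed=3)
    return spec, *generate(spec)


class TestSimulateForFit:
    def test_zero_residuals_at_truth_on_noise_free_data(self, noise_free_patient):
        spec, ds, truth = noise_free_patient
        pred = simulate_for_fit(truth["params"], ds)
        np.testing.assert_allclose(pred, np.asarray(ds.burdens_cells), rtol=1e-9)

    def test_metastatic_seeding_strictly_adds_burden(self, noise_free_patient):
        spec, ds, truth = noise_free_patient
        with_m = simulate_for_fit(truth["params"], ds)
        without_m = simulate_for_fit({**truth["params"], "m": 0.0}, ds)
        assert np.all(with_m > without_m)

    def test_diagnosis_prediction_matches_quadrature_oracle(self):
        # primary-only seeding: burden(diagnosis) = x_p + m int x_p(s)^alpha
        # x_c(T - s) ds, everything in closed form under the integral
        gp = GompertzParams(7.284e-3)
        m, alpha = 1.635e-7, 2 / 3
        x_diag = 2.4074e11
        T = tumor_age(gp, x_diag)
        ds = PatientDataset("oracle", (0.0, 10.0), (x_diag, 1.1 * x_diag), x_diag)
        pred = simulate_for_fit(
            {"a": gp.a, "m": m}, ds, options=SolverOptions(secondary_seeding=False)
        )
        met_mass = quad(
            lambda s: m * size_at(gp, s) ** alpha * size_at(gp, T - s), 0.0, T, limit=400
        )[0]
        assert pred[0] == pytest.approx(x_diag + met_mass, rel=5e-3)

    def test_requires_enough_measurements(self):
        ds = PatientDataset("p", (0.0,), (1e11,), 1e11)
        with pytest.raises(ValueError):
            fit(ds, free=("a", "m"))


class TestFit:
    def test_noise_free_recovery_is_exact_to_optimizer_tolerance(self, noise_free_patient):
        spec, ds, truth = noise_free_patient
        res = fit(
            ds,
            free=("a", "m", "mu0", "chi"),
            fixed={"mu_star": spec.mu_star, "c50": spec.c50},
            n_starts=4,
            seed=11,
            log_residuals=True,
            compute_se=False,
        )
        assert res.converged
        assert res.sse < 1e-6 * np.sum(np.asarray(ds.burdens_cells) ** 2)
        for name in ("a", "m", "chi"):
            assert res.params[name] == pytest.approx(truth["params"][name], rel=0.02)

    def test_deterministic_given_seed(self, noise_free_patient):
        spec, ds, _ = noise_free_patient
        kw = dict(free=("a", "m"), fixed={"mu0": spec.mu0, "mu_star": spec.mu_star,
                                          "chi": spec.chi, "c50": spec.c50},
                  n_starts=3, seed=5, log_residuals=True, compute_se=False)
        r1, r2 = fit(ds, **kw), fit(ds, **kw)
        assert r1.params == r2.params
        assert r1.start_points == r2.start_points

    def test_estimates_respect_bounds(self, noise_free_patient):
        spec, ds, _ = noise_free_patient
        bounds = {"a": (6e-3, 8e-3), "m": (1e-8, 1e-6)}
        res = fit(ds, free=("a", "m"),
                  fixed={"mu0": spec.mu0, "mu_star": spec.mu_star, "chi": spec.chi,
                         "c50": spec.c50},
                  bounds=bounds, n_starts=3, seed=5, log_residuals=True, compute_se=False)
        assert bounds["a"][0] <= res.params["a"] <= bounds["a"][1]
        assert bounds["m"][0] <= res.params["m"] <= bounds["m"][1]

    def test_explicit_starts_accepted(self, noise_free_patient):
        spec, ds, truth = noise_free_patient
        res = fit(ds, free=("a", "m"),
                  fixed={"mu0": spec.mu0, "mu_star": spec.mu_star, "chi": spec.chi,
                         "c50": spec.c50},
                  starts=[{"a": 6e-3, "m": 1e-7}], log_residuals=True, compute_se=False)
        assert res.n_starts == 1
        assert res.params["a"] == pytest.approx(truth["params"]["a"], rel=0.02)


class TestStandardErrors:
    def test_quadratic_objective_gives_exact_errors(self):
        H = np.array([[4.0, 1.0], [1.0, 9.0]])
        theta0 = np.array([0.7, -1.2])

        def obj(th):
            d = th - theta0
            return 0.5 * float(d @ H @ d) + 3.0

        se, reliable = standard_errors(obj, theta0)
        np.testing.assert_allclose(se, np.sqrt(np.diag(np.linalg.inv(H))), rtol=1e-5)
        assert reliable

    def test_collinear_objective_flags_singularity(self):
        # objective depends only on theta1 + theta2: Hessian is singular
        def obj(th):
            return (th[0] + th[1] - 1.0) ** 2

        se, reliable = standard_errors(obj, np.array([0.5, 0.5]))
        assert not reliable
        assert np.all(np.isfinite(se))

    def test_errors_shrink_with_more_measurements(self):
        # Monte-Carlo-free check: a least-squares objective with n replicate
        # residuals has Hessian ~ n, hence SE ~ 1/sqrt(n)
        def make_obj(n):
            def obj(th):
                return float(n * (th[0] - 2.0) ** 2)
            return obj

        se4, _ = standard_errors(make_obj(4), np.array([2.0]))
        se16, _ = standard_errors(make_obj(16), np.array([2.0]))
        assert se16[0] == pytest.approx(0.5 * se4[0], rel=1e-4)


class TestInvariances:
    def test_fit_invariant_to_volume_units(self, noise_free_patient):
        """Burdens given in ml, mm3 or cells yield the same estimates."""
        from metaburden.constants import CELLS_PER_ML, CELLS_PER_MM3
        from metaburden.io import volumes_to_cells

        spec, ds, _ = noise_free_patient
        b = np.asarray(ds.burdens_cells)
        np.testing.assert_allclose(volumes_to_cells(b / CELLS_PER_ML, "ml"), b, rtol=1e-12)
        np.testing.assert_allclose(volumes_to_cells(b / CELLS_PER_MM3, "mm3"), b, rtol=1e-12)


@pytest.fixture(scope="module")
def fitted():
    spec = VirtualPatientSpec(noise_sd=0.0, seed=9, chemo_cycles=0,
                              immuno_start_offset=30.0,
                              visit_offsets=(0.0, 60.0, 120.0, 180.0))
    ds, truth = generate(spec)
    return truth["params"], ds


class TestCompareRegimens:
    def test_identical_candidate_changes_nothing(self, fitted):
        params, ds = fitted
        df = compare_regimens(params, ds, {"reference": {}, "same": {}}, horizon=180.0)
        assert df.loc["reference", "metastatic_change_pct"] == 0.0
        assert df.loc["same", "metastatic_change_pct"] == pytest.approx(0.0, abs=1e-9)

    def test_doubled_loading_dose_reduces_metastatic_mass(self, fitted):
        params, ds = fitted
        doses = (400.0,) + (200.0,) * (len(ds.immuno_offsets) - 1)
        df = compare_regimens(
            params, ds,
            {"reference": {}, "loading": {"immuno_doses_mg": doses}},
            horizon=180.0,
        )
        change = df.loc["loading", "metastatic_change_pct"]
        assert -15.0 < change < 0.0  # better, and by a modest margin

    def test_doubled_first_dose_reaches_steady_state_within_first_cycle(self):
        # for pembrolizumab the cycle length ~ half-life, so a doubled
        # loading dose puts the first-cycle mean within 5 % of c_st
        base = ImmunoCourse.from_catalog("pembrolizumab", 0.0, 12, chi=0.1, c50=1e16)
        loaded = ImmunoCourse.from_catalog(
            "pembrolizumab", 0.0, 12, chi=0.1, c50=1e16,
            doses_mg=(400.0,) + (200.0,) * 11,
        )
        ts = np.linspace(0.0, base.cycle_days, 2001)
        first_cycle_mean = np.trapezoid(loaded.concentration(ts), ts) / base.cycle_days
        assert first_cycle_mean == pytest.approx(base.steady_state_concentration(), rel=0.05)

    def test_half_dose_halves_the_plateau(self):
        base = ImmunoCourse.from_catalog("nivolumab", 0.0, 40, chi=0.1, c50=1e16)
        half = ImmunoCourse.from_catalog("nivolumab", 0.0, 40, chi=0.1, c50=1e16, dose_mg=120.0)
        assert half.steady_state_concentration() == pytest.approx(
            0.5 * base.steady_state_concentration(), rel=1e-12
        )
        # relative approach to the plateau is dose-independent: same number
        # of cycles to (say) 90 % of the respective steady state
        t = np.linspace(0.0, 40 * 14.0, 4001)
        rb = base.concentration(t) / base.steady_state_concentration()
        rh = half.concentration(t) / half.steady_state_concentration()
        np.testing.assert_allclose(rb, rh, rtol=1e-9)
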