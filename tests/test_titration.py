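"""Protection transform, Hill fitting, bootstrap errors and thermodynamics."""

import numpy as np
import pytest

from qmapseq.profiling import MutationProfile
from qmapseq.simulate import SimulationSpec, hill_fraction, simulate_profile_counts
from qmapseq.titration import (
    DEFAULT_MG_GRID,
    GAS_CONSTANT_KCAL,
    STATUS_BELOW_DETECTION,
    STATUS_OK,
    STATUS_QC_FAIL,
    FitConfig,
    ProtectionCurve,
    QCError,
    TitrationPoint,
    TitrationSeries,
    analyze_series,
    bootstrap_fit,
    compute_ddG,
    compute_protection,
    fit_hill,
    mg_half_to_dG,
    single_point_estimator,
)

SEQ = "GAAAG"
DB = "....."
PROBES = [1, 2, 3]


def make_profile(reactivity: float, depth: int = 100_000) -> MutationProfile:
    count = int(round(reactivity * depth))
    return MutationProfile(
        construct="x",
        sequence=SEQ,
        dot_bracket=DB,
        depth=np.full(len(SEQ), depth),
        mut_count=np.full(len(SEQ), count),
    )


def make_series(mg_values, reactivities, masks=None, depth=100_000):
    masks = masks or [False] * len(mg_values)
    pts = [
        TitrationPoint(mg=m, profile=make_profile(r, depth), mask=k)
        for m, r, k in zip(mg_values, reactivities, masks)
    ]
    return TitrationSeries("x", pts, PROBES)


def noiseless_curve(mg, A, K, n) -> ProtectionCurve:
    mg = np.asarray(mg, dtype=float)
    f = hill_fraction(mg, A, K, n)
    return ProtectionCurve(
        construct="x", mg=mg, f=f,
        avg_reactivity=0.05 * (1 - f), max_reactivity=0.05,
    )


class TestComputeProtection:
    def test_printed_formula_arithmetic(self):
        series = make_series([0.0, 0.1, 0.5, 5.0], [0.05, 0.04, 0.025, 0.005])
        curve = compute_protection(series)
        assert curve.max_reactivity == pytest.approx(0.05)
        assert curve.f == pytest.approx([0.0, 0.2, 0.5, 0.9])

    def test_flat_series_gives_zero_protection(self):
        series = make_series([0.0, 0.1, 1.0, 10.0], [0.03] * 4)
        curve = compute_protection(series)
        assert curve.f == pytest.approx([0.0] * 4)

    def test_full_protection_reaches_one(self):
        series = make_series([0.0, 0.1, 1.0, 40.0], [0.05, 0.03, 0.01, 0.0])
        curve = compute_protection(series)
        assert curve.f[-1] == pytest.approx(1.0)

    def test_masked_points_excluded_before_max(self):
        series = make_series(
            [0.0, 0.1, 1.0, 10.0, 40.0],
            [0.08, 0.05, 0.025, 0.01, 0.005],
            masks=[True, False, False, False, False],
        )
        curve = compute_protection(series)
        assert curve.max_reactivity == pytest.approx(0.05)
        assert len(curve) == 4

    def test_zero_dynamic_range_fails_qc(self):
        series = make_series([0.0, 0.1, 1.0, 10.0], [0.0] * 4)
        with pytest.raises(QCError, match="no dynamic range"):
            compute_protection(series)

    def test_series_requires_four_unmasked_points(self):
        with pytest.raises(ValueError, match="4 unmasked"):
            make_series([0.0, 0.1, 1.0], [0.05, 0.03, 0.01])


def grid_search_oracle(mg, f):
    """Dense grid over (A, K, n) minimizing RSS - independent of curve_fit."""
    best, best_rss = None, np.inf
    for A in np.linspace(0.5, 1.2, 36):
        for K in np.logspace(-2, 2, 161):
            for n in np.linspace(0.5, 4, 36):
                rss = float(np.sum((hill_fraction(mg, A, K, n) - f) ** 2))
                if rss < best_rss:
                    best, best_rss = (A, K, n), rss
    return best


class TestFitHill:
    def test_noiseless_unit_parameters_recovered_exactly(self):
        curve = noiseless_curve(DEFAULT_MG_GRID, 1.0, 1.0, 1.0)
        fit = fit_hill(curve)
        assert fit.status == STATUS_OK
        assert fit.amplitude_A == pytest.approx(1.0, abs=1e-6)
        assert fit.mg_half == pytest.approx(1.0, abs=1e-6)
        assert fit.hill_n == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_wildtype_like_parameters_match_grid_oracle(self):
        mg = np.asarray(DEFAULT_MG_GRID)
        curve = noiseless_curve(mg, 0.95, 0.22, 2.0)
        fit = fit_hill(curve)
        oracle = grid_search_oracle(mg, curve.f)
        # the oracle grid brackets the truth; curve_fit should land on it
        assert abs(oracle[0] - 0.95) <= 0.02
        assert abs(np.log(oracle[1] / 0.22)) <= np.log(1.07)
        assert fit.amplitude_A == pytest.approx(0.95, abs=1e-3)
        assert fit.mg_half == pytest.approx(0.22, abs=1e-3)
        assert fit.hill_n == pytest.approx(2.0, abs=1e-3)

    def test_midpoint_beyond_range_flags_below_detection(self):
        curve = noiseless_curve(DEFAULT_MG_GRID, 1.0, 100.0, 1.0)
        fit = fit_hill(curve, max_tested_mg=40.0)
        assert fit.status == STATUS_BELOW_DETECTION
        assert fit.mg_half > 40.0

    def test_scale_equivariance(self):
        mg = np.asarray(DEFAULT_MG_GRID)
        c = 10.0
        f1 = fit_hill(noiseless_curve(mg, 0.9, 0.5, 1.5))
        f2 = fit_hill(noiseless_curve(mg * c, 0.9, 0.5 * c, 1.5))
        assert f2.mg_half == pytest.approx(c * f1.mg_half, rel=1e-4)
        assert f2.hill_n == pytest.approx(f1.hill_n, rel=1e-4)


class TestBootstrap:
    def test_noiseless_data_gives_near_zero_se(self):
        curve = noiseless_curve(DEFAULT_MG_GRID, 1.0, 1.0, 1.0)
        res = bootstrap_fit(curve, n_boot=50, seed=1)
        assert res.se_mg_half < 1e-6

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(0)
        mg = np.asarray(DEFAULT_MG_GRID)
        f = np.clip(hill_fraction(mg, 0.95, 0.3, 1.5) + rng.normal(0, 0.02, mg.size), 0, 1)
        curve = ProtectionCurve("x", mg, f, 0.05 * (1 - f), 0.05)
        r1 = bootstrap_fit(curve, n_boot=40, seed=11)
        r2 = bootstrap_fit(curve, n_boot=40, seed=11)
        assert r1.se_mg_half == r2.se_mg_half
        assert r1.ci_mg_half == r2.ci_mg_half

    def test_bootstrap_se_within_factor_two_of_monte_carlo(self, wt_construct):
        """SE(K) from one bootstrap tracks the sampling SD over replicated
        titrations generated at the same depth."""
        k_hats, boot_ses = [], []
        rng = np.random.default_rng(42)
        for rep in range(40):
            spec = SimulationSpec(
                construct=wt_construct,
                mg_concentrations=DEFAULT_MG_GRID,
                true_mg_half=0.22,
                true_hill_n=2.0,
                depth=5000,
                seed=0,
            )
            pts = []
            for mg in DEFAULT_MG_GRID:
                d, m = simulate_profile_counts(spec, mg, rng)
                pts.append(
                    TitrationPoint(
                        mg=mg,
                        profile=MutationProfile(
                            "WT", wt_construct.rna_sequence,
                            wt_construct.dot_bracket, d, m,
                        ),
                    )
                )
            series = TitrationSeries("WT", pts, wt_construct.probe_positions)
            curve = compute_protection(series)
            fit = fit_hill(curve)
            res = bootstrap_fit(curve, fit, n_boot=50, seed=rep)
            k_hats.append(fit.mg_half)
            boot_ses.append(res.se_mg_half)
        mc_sd = np.std(k_hats, ddof=1)
        mean_se = np.mean(boot_ses)
        assert mean_se == pytest.approx(mc_sd, rel=1.0)  # within a factor of 2


class TestThermo:
    def test_unit_midpoint_gives_zero_dG(self):
        assert mg_half_to_dG(1.0).dG == 0.0

    def test_closed_form_values(self):
        assert mg_half_to_dG(0.22).dG == pytest.approx(0.882, abs=1e-3)
        assert mg_half_to_dG(1.37).dG == pytest.approx(-0.183, abs=1e-3)

    def test_delta_method_se(self):
        res = mg_half_to_dG(0.22, se=0.004)
        rt = GAS_CONSTANT_KCAL * 293.15
        assert res.se_dG == pytest.approx(rt * 0.004 / 0.22)

    def test_nonpositive_midpoint_rejected(self):
        with pytest.raises(ValueError):
            mg_half_to_dG(0.0)

    def test_ddG_identity_and_antisymmetry(self):
        a = mg_half_to_dG(0.22, construct="a")
        b = mg_half_to_dG(1.37, construct="b")
        assert compute_ddG(a, a).ddG == 0.0
        assert compute_ddG(a, b).ddG == pytest.approx(-compute_ddG(b, a).ddG)

    def test_ddG_se_propagation(self):
        a = mg_half_to_dG(0.22, se=0.004, construct="a")
        b = mg_half_to_dG(1.37, se=0.17, construct="b")
        dd = compute_ddG(b, a)
        assert dd.se_ddG == pytest.approx(np.hypot(a.se_dG, b.se_dG))

    def test_temperature_mismatch_rejected(self):
        a = mg_half_to_dG(0.22, temperature_K=293.15)
        b = mg_half_to_dG(1.37, temperature_K=310.0)
        with pytest.raises(ValueError, match="temperature"):
            compute_ddG(a, b)

    def test_ddG_invariant_to_mg_units_but_dG_is_not(self):
        # mM -> M divides every K by 1000; dG shifts, ddG cancels
        a_mM, b_mM = mg_half_to_dG(0.22), mg_half_to_dG(1.37)
        a_M, b_M = mg_half_to_dG(0.22e-3), mg_half_to_dG(1.37e-3)
        assert a_M.dG != pytest.approx(a_mM.dG)
        assert compute_ddG(b_M, a_M).ddG == pytest.approx(
            compute_ddG(b_mM, a_mM).ddG
        )


class TestAnalyzeSeries:
    def test_flat_series_fails_qc_not_crash(self):
        series = make_series([0.0, 0.1, 1.0, 10.0], [0.0] * 4)
        fit, thermo = analyze_series(series)
        assert fit.status == STATUS_QC_FAIL
        assert thermo is None

    def test_recovers_simulated_midpoint(self, wt_construct):
        rng = np.random.default_rng(9)
        spec = SimulationSpec(
            construct=wt_construct,
            mg_concentrations=DEFAULT_MG_GRID,
            true_mg_half=0.22,
            true_hill_n=2.0,
            depth=5000,
            seed=0,
        )
        pts = []
        for mg in DEFAULT_MG_GRID:
            d, m = simulate_profile_counts(spec, mg, rng)
            pts.append(
                TitrationPoint(
                    mg=mg,
                    profile=MutationProfile(
                        "WT", wt_construct.rna_sequence,
                        wt_construct.dot_bracket, d, m,
                    ),
                )
            )
        series = TitrationSeries("WT", pts, wt_construct.probe_positions)
        fit, thermo = analyze_series(series, n_boot=100, seed=4)
        assert fit.status == STATUS_OK
        assert fit.mg_half == pytest.approx(0.22, rel=0.2)
        assert thermo is not None and thermo.dG == pytest.approx(0.88, abs=0.2)


class TestSinglePointEstimator:
    def test_collinear_input_gives_r2_one(self):
        reactivities = {f"c{i}": r for i, r in enumerate([0.01, 0.02, 0.04, 0.08])}
        dg = {name: 1.0 + 2.0 * np.log(r) for name, r in reactivities.items()}
        model = single_point_estimator(reactivities, dg)
        assert model.r_squared == pytest.approx(1.0)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)

    def test_monte_carlo_recovery_within_two_se(self):
        rng = np.random.default_rng(77)
        a, b, sigma = -9.0, 0.8, 0.15
        reactivities = {f"c{i}": float(r) for i, r in enumerate(rng.uniform(0.002, 0.08, 40))}
        dg = {
            name: a + b * np.log(r) + rng.normal(0, sigma)
            for name, r in reactivities.items()
        }
        model = single_point_estimator(reactivities, dg)
        x = np.log(list(reactivities.values()))
        se_b = sigma / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(model.slope - b) <= 2.5 * se_b

    def test_nonpositive_reactivity_excluded(self):
        reactivities = {"a": 0.01, "b": 0.02, "c": 0.04, "bad": 0.0}
        dg = {k: -9.0 + np.log(max(v, 1e-9)) for k, v in reactivities.items()}
        model = single_point_estimator(reactivities, dg)
        assert model.excluded == ["bad"]
        assert model.n_used == 3

    def test_prediction_interval_contains_point_prediction(self):
        reactivities = {f"c{i}": r for i, r in enumerate([0.01, 0.02, 0.04, 0.08, 0.05])}
        rng = np.random.default_rng(1)
        dg = {k: -9 + 0.8 * np.log(v) + rng.normal(0, 0.05) for k, v in reactivities.items()}
        model = single_point_estimator(reactivities, dg)
        pred, (lo, hi) = model.predict(0.03)
        assert lo < pred < hi
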