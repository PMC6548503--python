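"""Batch-assay regression estimators."""

import numpy as np
import pandas as pd
import pytest

from crossfeed import (
    AssayTable,
    MoserParams,
    calibrate_bioassay,
    density_from_beads,
    fit_moser,
    infer_concentration,
    max_growth_rate,
    propagate_ratio_error,
    release_rate_batch,
    steady_state_rate,
    utilization_per_birth,
)
from crossfeed.phenotyping import UM_TO_FMOLE_PER_ML
from crossfeed.synthetic import gen_growth_curves, gen_release_assay, gen_yield_assay

UM = UM_TO_FMOLE_PER_ML


class TestMaxGrowthRate:
    def test_exact_exponential_any_window(self):
        t = np.arange(0, 10.0, 1.0)
        curve = pd.DataFrame({"time": t, "fluorescence": 3.0 * np.exp(0.3 * t)})
        for w in (3, 4):
            est = max_growth_rate(curve, window_points=w)
            assert est.value == pytest.approx(0.3, rel=1e-10)
            assert est.se == pytest.approx(0.0, abs=1e-9)
            assert est.flag is None or est.flag == "max_at_end"

    def test_decreasing_curve_flagged(self):
        t = np.arange(0, 8.0, 1.0)
        curve = pd.DataFrame({"time": t, "fluorescence": np.exp(-0.1 * t)})
        assert max_growth_rate(curve).flag == "no_positive_slope"

    def test_rescaling_invariance(self):
        t = np.arange(0, 12.0, 0.5)
        f = np.exp(0.25 * t) * (1 + 0.01 * np.sin(t))
        base = max_growth_rate(pd.DataFrame({"time": t, "fluorescence": f}))
        scaled = max_growth_rate(pd.DataFrame({"time": t, "fluorescence": 537.0 * f}))
        assert scaled.value == pytest.approx(base.value, rel=1e-12)
        assert scaled.window == base.window

    def test_nonpositive_fluorescence_rejected(self):
        curve = pd.DataFrame({"time": [0, 1, 2], "fluorescence": [1.0, 0.0, 2.0]})
        with pytest.raises(ValueError):
            max_growth_rate(curve)

    def test_recovery_under_noise(self):
        """Moser-limited curves, 2% noise: early-phase rate 0.25/hr recovered."""
        law = MoserParams(0.45, 1e6, 2.0)
        L0 = law.inverse(0.25)
        table, truth = gen_growth_curves(
            law, concentrations=[L0], noise_cv=0.02, n_replicates=200, seed=5,
            times=np.arange(0, 16.01, 1.0),
        )
        errs = []
        for _, grp in table.data.groupby("replicate"):
            est = max_growth_rate(
                grp[["time", "fluorescence"]], window_points=4,
                exclude_before=truth.params["residual_hr"],
            )
            errs.append(abs(est.value - 0.25))
        errs = np.array(errs)
        assert np.median(errs) < 0.02
        assert np.mean(errs < 0.02) >= 0.90


class TestFitMoser:
    def test_noiseless_recovery_four_sig_figs(self):
        law = MoserParams(gmax=0.45, K=1e6, n=2.0)
        L = np.array([0.1, 0.3, 0.7, 1.0, 2.0, 3.0, 10.0, 30.0]) * 1e6
        fit = fit_moser(pd.DataFrame({"concentration": L, "rate": law.rate(L)}))
        assert fit.converged
        assert fit.params.gmax == pytest.approx(0.45, rel=1e-4)
        assert fit.params.K == pytest.approx(1e6, rel=1e-4)
        assert fit.params.n == pytest.approx(2.0, rel=1e-4)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_moser(pd.DataFrame({"concentration": [1, 2, 2, 1], "rate": [0.1] * 4}))

    def test_noisy_recovery(self):
        law = MoserParams(0.45, 1e6, 2.0)
        L = np.array([0.2, 0.5, 1.0, 1.5, 2.0, 4.0, 10.0, 30.0]) * 1e6
        rng = np.random.default_rng(0)
        g_err, K_err = [], []
        for _ in range(30):
            g = law.rate(L) * rng.lognormal(0, 0.05, len(L))
            fit = fit_moser(pd.DataFrame({"concentration": L, "rate": g}))
            assert fit.converged
            g_err.append(abs(fit.params.gmax - 0.45) / 0.45)
            K_err.append(abs(fit.params.K - 1e6) / 1e6)
        assert np.median(g_err) < 0.05
        assert np.median(K_err) < 0.15


class TestReleaseRate:
    def test_constant_density_exact(self):
        t = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        table = pd.DataFrame(
            {"time": t, "live_density": 1e6, "concentration": 0.2 * 1e6 * t}
        )
        est = release_rate_batch(table)
        assert est.value == pytest.approx(0.2, rel=1e-12)

    def test_zero_concentration_zero_slope(self):
        t = np.array([0.0, 6.0, 12.0, 18.0])
        table = pd.DataFrame({"time": t, "live_density": 1e6, "concentration": 0.0})
        assert release_rate_batch(table).value == 0.0

    def test_free_intercept_absorbs_t0_carryover(self):
        t = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        table = pd.DataFrame(
            {"time": t, "live_density": 1e6, "concentration": 5e5 + 0.2 * 1e6 * t}
        )
        assert release_rate_batch(table).value == pytest.approx(0.2, rel=1e-12)

    def test_declining_density_noisy_recovery(self):
        errs = []
        for seed in range(50):
            table, truth = gen_release_assay(
                r_true=0.3, death_rate=0.01, noise_cv=0.05, seed=seed
            )
            est = release_rate_batch(table)
            errs.append(abs(est.value - 0.3) / 0.3)
        assert np.median(errs) < 0.10

    def test_too_few_points_rejected(self):
        table = pd.DataFrame(
            {"time": [0.0, 6.0], "live_density": [1e6, 1e6], "concentration": [0, 1]}
        )
        with pytest.raises(ValueError):
            release_rate_batch(table)


class TestUtilization:
    def test_printed_example(self):
        table = AssayTable(
            pd.DataFrame(
                {"input_concentration": [5.0, 10.0, 20.0],
                 "final_density": [2.5e6, 5e6, 1e7]}
            ),
            units={"input_concentration": "uM"},
        )
        est = utilization_per_birth(table)
        assert est.value == pytest.approx(2.0, rel=1e-12)
        assert est.sigma == pytest.approx(0.0, abs=1e-12)

    def test_doubling_densities_halves_u(self):
        base = pd.DataFrame(
            {"input_concentration": np.array([5e6, 1e7, 2e7]),
             "final_density": [2.5e6, 5e6, 1e7]}
        )
        doubled = base.assign(final_density=base["final_density"] * 2)
        assert utilization_per_birth(doubled).value == pytest.approx(
            utilization_per_birth(base).value / 2
        )

    def test_saturation_biases_without_linear_max(self):
        table, truth = gen_yield_assay(u_true=2.0, noise_cv=0.03, seed=3)
        inoc = truth.params["inoculum"]
        restricted = utilization_per_birth(
            table, linear_max=truth.params["linear_max"], inoculum=inoc
        )
        unrestricted = utilization_per_birth(table, linear_max=np.inf, inoculum=inoc)
        assert restricted.value == pytest.approx(2.0, rel=0.05)
        assert unrestricted.value > restricted.value  # plateau points inflate u

    def test_nonpositive_slope_rejected(self):
        table = pd.DataFrame(
            {"input_concentration": [1e6, 2e6, 3e6], "final_density": [0.0, 0.0, 0.0]}
        )
        with pytest.raises(ValueError):
            utilization_per_birth(table)


class TestRatioError:
    def test_printed_example(self):
        est = propagate_ratio_error(10.0, 1.0, 5.0, 0.5)
        assert est.value == pytest.approx(2.0)
        assert est.sigma == pytest.approx(0.2828, abs=5e-4)

    def test_zero_sigmas(self):
        assert propagate_ratio_error(3.0, 0.0, 4.0, 0.0).sigma == 0.0

    def test_zero_numerator_cases(self):
        assert propagate_ratio_error(0.0, 0.0, 4.0, 0.1).value == 0.0
        with pytest.raises(ValueError):
            propagate_ratio_error(0.0, 0.5, 4.0, 0.1)
        with pytest.raises(ValueError):
            propagate_ratio_error(1.0, 0.1, 0.0, 0.1)

    def test_exchange_ratio_invariant_under_joint_scaling(self):
        """Scale release-assay concentrations by kappa and yield densities by
        1/kappa: r and u both scale by kappa, the ratio r/u does not."""
        kappa = 2.0
        rel, _ = gen_release_assay(r_true=0.3, noise_cv=0.0, seed=0)
        yld, truth = gen_yield_assay(u_true=2.0, noise_cv=0.0, seed=0)
        inoc = truth.params["inoculum"]

        def ratio(rel_df, yld_df):
            r = release_rate_batch(rel_df)
            u = utilization_per_birth(
                yld_df, linear_max=truth.params["linear_max"], inoculum=inoc
            )
            return propagate_ratio_error(r.value, r.se, u.value, u.sigma)

        base = ratio(rel.data, yld.data)
        scaled_rel = rel.data.assign(concentration=rel.data["concentration"] * kappa)
        # keep metabolite-supported yield (not the inoculum) scaling cleanly
        scaled_yld = yld.data.assign(
            final_density=(yld.data["final_density"] - inoc) / kappa + inoc
        )
        scaled = ratio(scaled_rel, scaled_yld)
        assert scaled.value == pytest.approx(base.value, rel=1e-10)


class TestBeadDensity:
    def test_printed_example(self):
        got = density_from_beads(
            cell_events=5000, bead_events=5000, bead_stock_density=6e6,
            vol_sample=90.0, vol_beads=10.0, dilution_factor=100.0,
        )
        assert got == pytest.approx(6.67e7, rel=1e-3)

    def test_zero_cells(self):
        assert density_from_beads(0, 1000, 6e6, 90, 10, 100) == 0.0

    def test_zero_beads_rejected(self):
        with pytest.raises(ValueError):
            density_from_beads(100, 0, 6e6, 90, 10, 100)

    def test_triplicate_poisson_cv_within_protocol_bound(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            cells = rng.poisson(2e4, 3)
            beads = rng.poisson(1e4, 3)
            est = [
                density_from_beads(c, b, 6e6, 90, 10, 100)
                for c, b in zip(cells, beads)
            ]
            cv = np.std(est, ddof=1) / np.mean(est)
            assert cv < 0.10


class TestBioassay:
    def test_linear_standards_invert_exactly(self):
        conc = np.array([0.0, 2e6, 4e6, 8e6])
        standards = pd.DataFrame({"concentration": conc, "turbidity": conc / 2e6})
        cal = calibrate_bioassay(standards)
        value, flag = infer_concentration(cal, 1.5)
        assert flag is None
        assert value == pytest.approx(3e6)

    def test_out_of_range_flagged(self):
        standards = pd.DataFrame(
            {"concentration": [1e6, 2e6, 4e6], "turbidity": [0.2, 0.4, 0.8]}
        )
        cal = calibrate_bioassay(standards)
        assert infer_concentration(cal, 0.1) == (None, "below_range")
        assert infer_concentration(cal, 0.9) == (None, "above_range")

    def test_non_monotone_rejected(self):
        standards = pd.DataFrame(
            {"concentration": [1e6, 2e6, 4e6], "turbidity": [0.2, 0.5, 0.4]}
        )
        with pytest.raises(ValueError, match="not monotone"):
            calibrate_bioassay(standards)

    def test_saturating_curve_midrange_accuracy(self):
        # tester-yield model: turbidity saturating in concentration
        K = 10 * UM
        conc = np.linspace(0, 30, 11) * UM
        turb = conc / (conc + K)
        cal = calibrate_bioassay(pd.DataFrame({"concentration": conc, "turbidity": turb}))
        true = 7.3 * UM
        value, flag = infer_concentration(cal, true / (true + K))
        assert flag is None
        assert value == pytest.approx(true, rel=0.03)

    def test_replicates_averaged(self):
        standards = pd.DataFrame(
            {"concentration": [1e6, 1e6, 2e6, 2e6, 4e6, 4e6],
             "turbidity": [0.19, 0.21, 0.4, 0.4, 0.75, 0.85]}
        )
        cal = calibrate_bioassay(standards)
        assert cal.turbidity == pytest.approx([0.2, 0.4, 0.8])


class TestSteadyStateRate:
    def test_pure_exponential(self):
        t = np.arange(0, 30.0, 2.0)
        table = pd.DataFrame({"time": t, "density": 1e4 * np.exp(0.1 * t)})
        est = steady_state_rate(table, lag_policy=0.0, density_cap=np.inf)
        assert est.value == pytest.approx(0.1, rel=1e-10)
        assert est.se == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("lag_policy", [10.0, "auto"])
    def test_lag_then_exponential(self, lag_policy):
        t = np.arange(0, 40.0, 2.0)
        density = np.where(t < 10, 1e4, 1e4 * np.exp(0.1 * (t - 10)))
        table = pd.DataFrame({"time": t, "density": density})
        est = steady_state_rate(table, lag_policy=lag_policy, density_cap=np.inf)
        assert est.value == pytest.approx(0.1, rel=0.01)

    def test_density_cap_excludes_saturation(self):
        t = np.arange(0, 60.0, 2.0)
        density = np.minimum(1e4 * np.exp(0.2 * t), 2e8)
        table = pd.DataFrame({"time": t, "density": density})
        est = steady_state_rate(table, lag_policy=0.0)
        assert est.value == pytest.approx(0.2, rel=0.01)

    def test_too_few_points_rejected(self):
        table = pd.DataFrame({"time": [0, 1], "density": [1e4, 2e4]})
        with pytest.raises(ValueError):
            steady_state_rate(table, lag_policy=0.0)


class TestAssayTable:
    def test_unit_conversion(self):
        at = AssayTable(
            pd.DataFrame({"concentration": [2.0]}), units={"concentration": "uM"}
        )
        assert at.column("concentration")[0] == pytest.approx(2e6)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            AssayTable(pd.DataFrame({"density": [-1.0]}))

    def test_decreasing_times_rejected(self):
        with pytest.raises(ValueError):
            AssayTable(pd.DataFrame({"time": [2.0, 1.0], "fluorescence": [1, 2]}))

    def test_round_trip(self, tmp_path):
        at = AssayTable(pd.DataFrame({"time": [0.0, 1.0], "fluorescence": [1.0, 2.5]}))
        path = tmp_path / "curve.tsv"
        at.write(path)
        back = AssayTable.read(path)
        pd.testing.assert_frame_equal(back.data, at.data)
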