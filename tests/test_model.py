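"""Tests for joint least-squares fitting, CIs, identifiability and the t-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from repairkinetics import (
    CONTROL,
    CompartmentState,
    MeasurementTable,
    RateConstants,
    StrandBreakRepairModel,
    UnderdeterminedError,
    ValidationError,
    compare_at_endpoint,
    generate_dataset,
    GeneratorConfig,
    reference_config,
)


def _flat_table(value_super=1.0):
    rows = [
        {
            "condition": "control",
            "time_h": t,
            "replicate": r,
            "observable": obs,
            "value": value_super if obs == "supercoiled" else 1.0 - value_super,
        }
        for t in (0.0, 1.0, 2.0)
        for r in (1, 2, 3)
        for obs in ("supercoiled", "linear_total")
    ]
    return MeasurementTable.from_records(rows)


class TestFit:
    def test_recovers_generating_rates_from_noiseless_data(self, noiseless_fit):
        p = noiseless_fit.params
        assert abs(p["k_s"] - 0.21) / 0.21 <= 1e-3
        assert abs(p["k_d"] - 0.74) / 0.74 <= 1e-3
        assert noiseless_fit.ssr <= 1e-10
        assert noiseless_fit.init.LSSB == pytest.approx(0.95, abs=1e-3)
        assert noiseless_fit.init.L == pytest.approx(0.05, abs=1e-3)

    def test_ssr_matches_independent_recomputation(self, noiseless_fit):
        m = noiseless_fit.model
        resid = []
        from repairkinetics import observe, solve

        frame = m.data.frame
        for _, row in frame.iterrows():
            traj = solve(
                noiseless_fit.rates,
                m.scenarios[row["condition"]],
                noiseless_fit.init,
                [row["time_h"]] if row["time_h"] > 0 else [0.0],
            )
            obs = observe(traj)
            pred = {
                "linear_total": obs.linear_total[0],
                "supercoiled": obs.supercoiled[0],
            }[row["observable"]]
            resid.append(row["value"] - pred)
        assert abs(noiseless_fit.ssr - np.sum(np.square(resid))) < 1e-12

    def test_zero_residual_at_generating_parameters(
        self, noiseless_table, ref_rates, ref_init
    ):
        model = StrandBreakRepairModel(noiseless_table)
        assert model.ssr(ref_rates, ref_init) < 1e-20

    def test_seeded_fit_is_bit_identical(self, noiseless_table):
        model = StrandBreakRepairModel(noiseless_table)
        a = model.fit(n_starts=4, seed=9)
        b = model.fit(n_starts=4, seed=9)
        assert np.array_equal(a.x, b.x)
        assert a.ssr == b.ssr

    def test_single_time_point_is_underdetermined(self):
        rows = [
            {"condition": "control", "time_h": 0.0, "replicate": r,
             "observable": o, "value": 0.5}
            for r in (1, 2) for o in ("linear_total", "supercoiled")
        ]
        with pytest.raises(UnderdeterminedError):
            StrandBreakRepairModel(MeasurementTable.from_records(rows))

    def test_unknown_condition_rejected(self):
        rows = [
            {"condition": "mystery", "time_h": t, "replicate": 1,
             "observable": "supercoiled", "value": 0.5}
            for t in (0.0, 1.0)
        ]
        with pytest.raises(ValidationError):
            StrandBreakRepairModel(MeasurementTable.from_records(rows))

    def test_static_supercoiled_data_flags_rates_unidentifiable(self):
        model = StrandBreakRepairModel(_flat_table())
        res = model.fit(n_starts=15, seed=3)
        assert any(f.startswith("non_identifiable") for f in res.flags)

    @given(
        k_s=st.floats(0.05, 2.0),
        k_d=st.floats(0.05, 2.0),
    )
    @settings(max_examples=8, deadline=None, derandomize=True)
    def test_recovery_across_generating_rates(self, k_s, k_d, scenarios):
        cfg = GeneratorConfig(
            rates=RateConstants.tied_rates(k_s, k_d), noise_sd=0.0, seed=0
        )
        table = generate_dataset(cfg)
        res = StrandBreakRepairModel(table, scenarios=scenarios).fit(
            n_starts=10, seed=1
        )
        assert abs(res.params["k_s"] - k_s) / k_s <= 1e-3
        assert abs(res.params["k_d"] - k_d) / k_d <= 1e-3

    def test_unshared_init_fits_one_state_per_condition(self, noiseless_table):
        model = StrandBreakRepairModel(noiseless_table, share_init=False)
        res = model.fit(n_starts=10, seed=2)
        assert len(res.inits) == 2
        assert res.ssr <= 1e-8


class TestConfidenceIntervals:
    def test_noiseless_fit_gives_degenerate_intervals(self, noiseless_fit):
        ci = noiseless_fit.conf_int(n_boot=60, seed=0)
        assert np.allclose(ci["ci_lower"], ci["estimate"])
        assert np.allclose(ci["ci_upper"], ci["estimate"])

    def test_intervals_cover_truth_on_noisy_data(self):
        table = generate_dataset(reference_config(seed=21, noise_sd=0.03))
        res = StrandBreakRepairModel(table).fit(n_starts=6, seed=21)
        ci = res.conf_int(n_boot=200, seed=21)
        assert ci.loc["k_s", "ci_lower"] <= 0.21 <= ci.loc["k_s", "ci_upper"]
        assert ci.loc["k_d", "ci_lower"] <= 0.74 <= ci.loc["k_d", "ci_upper"]
        # intervals always contain the point estimate
        assert (ci["ci_lower"] <= ci["estimate"] + 1e-12).all()
        assert (ci["ci_upper"] >= ci["estimate"] - 1e-12).all()

    def test_same_seed_gives_identical_intervals(self):
        table = generate_dataset(reference_config(seed=22, noise_sd=0.03))
        res = StrandBreakRepairModel(table).fit(n_starts=4, seed=22)
        a = res.conf_int(n_boot=60, seed=7)
        b = res.conf_int(n_boot=60, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_small_bootstrap_sets_stability_flag(self):
        table = generate_dataset(reference_config(seed=23, noise_sd=0.03))
        res = StrandBreakRepairModel(table).fit(n_starts=3, seed=23)
        res.conf_int(n_boot=20, seed=0)
        assert "ci_unstable" in res.flags


class TestIdentifiabilityScan:
    def test_scan_requires_data_with_rows(self):
        with pytest.raises(ValidationError):
            MeasurementTable.from_records([])

    def test_tied_model_is_practically_identifiable(self, noiseless_table):
        model = StrandBreakRepairModel(noiseless_table, tie_rates=True)
        report = model.identifiability_scan(n_starts=12, seed=5)
        assert not report.non_identifiable
        for name in ("k_s", "k_d"):
            assert report.spreads[name] <= 0.01 * report.best_rates[name]

    def test_untied_model_flags_multistart_sensitivity_on_noisy_data(self):
        # practical non-identifiability appears at the assay noise level
        flagged = []
        for seed in (0, 2, 3):
            table = generate_dataset(reference_config(seed=seed, noise_sd=0.03))
            model = StrandBreakRepairModel(table, tie_rates=False)
            report = model.identifiability_scan(n_starts=40, seed=seed)
            flagged.append(report.non_identifiable)
        assert any(flagged)


class TestEndpointComparison:
    def test_identical_groups_give_null_result(self):
        t = _flat_table(0.6)
        res = compare_at_endpoint(t, t, "supercoiled", 2.0)
        assert res.mean_diff == 0.0
        assert res.t_stat == 0.0
        assert res.p_value == 1.0

    def test_pooled_t_test_matches_closed_form(self):
        def table(values):
            return MeasurementTable.from_records(
                [
                    {"condition": "control", "time_h": 2.0, "replicate": i + 1,
                     "observable": "supercoiled", "value": v}
                    for i, v in enumerate(values)
                ]
                + [
                    {"condition": "control", "time_h": 0.0, "replicate": 1,
                     "observable": "supercoiled", "value": 0.0}
                ]
            )

        a = table([0.5, 0.6, 0.7])
        b = table([0.1, 0.2, 0.3])
        res = compare_at_endpoint(a, b, "supercoiled", 2.0)
        # closed form: pooled s = 0.1, SE = 0.1*sqrt(2/3), t = 4.899, df = 4
        assert res.mean_diff == pytest.approx(0.4)
        assert res.t_stat == pytest.approx(4.898979, abs=1e-5)
        assert res.df == 4
        assert res.p_value == pytest.approx(0.0080499, abs=1e-6)

    def test_single_replicate_rejected(self):
        a = MeasurementTable.from_records(
            [{"condition": "control", "time_h": 2.0, "replicate": 1,
              "observable": "supercoiled", "value": 0.5}]
        )
        with pytest.raises(ValidationError):
            compare_at_endpoint(a, a, "supercoiled", 2.0)

    def test_missing_time_point_rejected(self):
        t = _flat_table(0.6)
        with pytest.raises(ValidationError):
            compare_at_endpoint(t, t, "supercoiled", 7.0)


class TestResultsInterface:
    def test_summary_contains_estimates_and_half_times(self, noiseless_fit):
        text = noiseless_fit.summary()
        assert "k_s" in text and "k_d" in text
        assert "SSR" in text
        # half-times in minutes for the fitted rates
        assert f"{noiseless_fit.half_times_min['k_d']:.1f}" in text

    def test_predict_matches_generating_observables(self, noiseless_fit):
        obs = noiseless_fit.predict("control", times=[0.0, 1.0, 2.0])
        from repairkinetics import observe, solve

        expected = observe(
            solve(
                RateConstants.tied_rates(0.21, 0.74),
                CONTROL,
                CompartmentState(S=0.0, L=0.05, LSSB=0.95, CSSB=0.0),
                [0.0, 1.0, 2.0],
            )
        )
        assert np.allclose(obs.linear_total, expected.linear_total, atol=1e-4)
        assert np.allclose(obs.supercoiled, expected.supercoiled, atol=1e-4)

    def test_plot_fit_returns_axes(self, noiseless_fit):
        import matplotlib

        matplotlib.use("Agg")
        ax = noiseless_fit.plot_fit()
        assert ax.lines  # curves and data points drawn
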