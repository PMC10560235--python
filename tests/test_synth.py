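"""Synthetic-data generators: rosters, networks, evoked trials, behavior."""

import numpy as np
import pandas as pd
import pytest

from ecognet.synth import (
    EXTENDED_DESIGN,
    INTRAOP_DESIGN,
    Coupling,
    EvokedEffectSpec,
    InvalidDesignError,
    NetworkSpec,
    NodeDynamics,
    PsychometricParams,
    StabilityError,
    evoked_template,
    label_congruency,
    make_task_roster,
    simulate_behavior,
    simulate_evoked_trials,
    simulate_network_trials,
)
from ecognet.evoked import vot_peak_measures, latency_slope


class TestTaskRoster:
    @pytest.mark.parametrize(
        "design, n_total, n_exp",
        [
            (EXTENDED_DESIGN, 693, 504),
            (INTRAOP_DESIGN, 360, 288),
            (dict(word_pairs=0, reps=0, filler=0, catch=0), 0, 0),
        ],
    )
    def test_design_totals(self, design, n_total, n_exp):
        r = make_task_roster(design, seed=0)
        assert len(r) == n_total
        assert (r["trial_class"] == "experimental").sum() == n_exp

    def test_cells_balanced(self):
        r = make_task_roster(INTRAOP_DESIGN, seed=1)
        exp = r[r["trial_class"] == "experimental"]
        cells = exp.groupby(["bias", "vot_step"]).size()
        assert len(cells) == 12
        assert (cells == 24).all()

    def test_counting_identity(self):
        for wp, reps, fil, cat in [(2, 1, 5, 3), (7, 6, 126, 63), (1, 2, 0, 0)]:
            d = dict(word_pairs=wp, reps=reps, filler=fil, catch=cat)
            r = make_task_roster(d, seed=0)
            n_exp = (r["trial_class"] == "experimental").sum()
            assert len(r) == n_exp + fil + cat
            assert n_exp == wp * 6 * 2 * reps

    def test_invalid_design(self):
        with pytest.raises(InvalidDesignError):
            make_task_roster(dict(word_pairs=3, reps=0), seed=0)
        with pytest.raises(InvalidDesignError):
            make_task_roster(dict(word_pairs=1, reps=-1), seed=0)

    def test_seed_determinism(self):
        a = make_task_roster(EXTENDED_DESIGN, seed=42)
        b = make_task_roster(EXTENDED_DESIGN, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = make_task_roster(EXTENDED_DESIGN, seed=43)
        assert not a["word_pair"].equals(c["word_pair"])


class TestCongruency:
    def test_intraop_contrast_counts(self, intraop_roster):
        assert (intraop_roster["congruency"] == "congruent").sum() == 96
        assert (intraop_roster["congruency"] == "incongruent").sum() == 96

    @pytest.mark.parametrize(
        "bias, step, expected",
        [
            ("b", 1, "congruent"), ("b", 2, "congruent"),
            ("b", 5, "incongruent"), ("b", 6, "incongruent"),
            ("p", 1, "incongruent"), ("p", 2, "incongruent"),
            ("p", 5, "congruent"), ("p", 6, "congruent"),
            ("b", 3, "n/a"), ("p", 4, "n/a"),
        ],
    )
    def test_rule(self, bias, step, expected):
        r = pd.DataFrame(
            [dict(trial_id=0, trial_class="experimental", word_pair="w",
                  bias=bias, vot_step=step, vot_ms=8.0 * (step - 1),
                  congruency="n/a", phase="pre")]
        )
        assert label_congruency(r)["congruency"].iloc[0] == expected

    def test_middle_steps_excluded(self, intraop_roster):
        mid = intraop_roster[intraop_roster["vot_step"].isin([3, 4])]
        assert (mid["congruency"] == "n/a").all()

    def test_missing_bias_errors(self):
        r = pd.DataFrame(
            [dict(trial_class="experimental", bias="x", vot_step=1)]
        )
        with pytest.raises(ValueError):
            label_congruency(r)


class TestNetworkSimulation:
    def test_uncoupled_channels_uncorrelated(self):
        spec = NetworkSpec(
            2, [NodeDynamics(10, 0.2), NodeDynamics(30, 0.2)], [], noise_sd=1.0
        )
        ep = simulate_network_trials(spec, "pre", 20, 500, 100.0, seed=0)
        x = ep.data[:, 0, :].ravel()
        y = ep.data[:, 1, :].ravel()
        n = len(x)
        for lag in (0, 1, 5):
            r = np.corrcoef(x[: n - lag], y[lag:])[0, 1]
            assert abs(r) < 3 / np.sqrt(n - lag)

    def test_coupling_recovered_by_least_squares(self):
        """Brute-force VAR regression on a long realisation recovers the
        planted cross-coefficient at the right lag."""
        spec = NetworkSpec(
            2, [NodeDynamics(10, 0.3), NodeDynamics(20, 0.3)],
            [Coupling(0, 1, 0.5, 2)], noise_sd=1.0,
        )
        ep = simulate_network_trials(spec, "pre", 1, 100_000, 100.0, seed=1)
        y = ep.data[0]  # (2, T)
        p = 3
        T = y.shape[1]
        X = np.vstack([y[:, p - k : T - k] for k in range(1, p + 1)])
        B = np.linalg.lstsq(X.T, y[:, p:].T, rcond=None)[0].T
        coef_lag2 = B[1, (2 - 1) * 2 + 0]  # target ch1, lag-2 block, source ch0
        assert abs(coef_lag2 - 0.5) < 0.03

    def test_condition_delta_removes_edge(self):
        spec = NetworkSpec(
            2, [NodeDynamics(10, 0.2), NodeDynamics(30, 0.2)],
            [Coupling(0, 1, 0.5, 1)],
            condition_deltas={"post": [Coupling(0, 1, 0.0, 1)]},
        )
        A_pre = spec.var_coefficients("pre", 100.0)
        A_post = spec.var_coefficients("post", 100.0)
        assert A_pre[0, 1, 0] == 0.5
        assert A_post[0, 1, 0] == 0.0

    def test_unstable_spec_raises(self):
        spec2 = NetworkSpec(
            2, [NodeDynamics(5, 0.05), NodeDynamics(5, 0.05)],
            [Coupling(0, 1, 2.0, 1), Coupling(1, 0, 2.0, 1)],
        )
        with pytest.raises(StabilityError, match="modulus"):
            simulate_network_trials(spec2, "pre", 2, 50, 100.0, seed=0)

    def test_seed_determinism(self, small_network):
        a = simulate_network_trials(small_network, "pre", 3, 100, 100.0, seed=9)
        b = simulate_network_trials(small_network, "pre", 3, 100, 100.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_yaml_round_trip(self, small_network, tmp_path):
        p = tmp_path / "net.yaml"
        small_network.to_yaml(p)
        back = NetworkSpec.from_yaml(p)
        assert back.n_nodes == small_network.n_nodes
        assert back.couplings == small_network.couplings
        np.testing.assert_allclose(
            back.var_coefficients("pre", 100.0),
            small_network.var_coefficients("pre", 100.0),
        )


class TestEvokedSimulation:
    def test_zero_spec_pure_noise(self, intraop_roster):
        from ecognet.synth import PeakSpec

        spec = EvokedEffectSpec(
            peak1=PeakSpec(0.25, 0.0), peak2=PeakSpec(0.35, 0.0),
            mismatch_amplitude=0.0, noise_sd=1.0,
        )
        ep = simulate_evoked_trials(intraop_roster, spec, fs=250.0, seed=0)
        grand = ep.data.mean(axis=(0, 1))
        assert np.abs(grand).max() < 5 * 1.0 / np.sqrt(ep.n_trials)

    def test_vot_slope_on_clean_template(self, intraop_roster):
        """With the mismatch component off, peak picking on the near
        noise-free ensemble recovers the planted 8 ms/step latency slope."""
        spec = EvokedEffectSpec(mismatch_amplitude=0.0, noise_sd=0.01)
        ep = simulate_evoked_trials(intraop_roster, spec, fs=500.0, seed=1)
        exp = np.where(ep.annotations["trial_class"] == "experimental")[0]
        peaks = vot_peak_measures(ep.select_trials(exp))
        slope_ms = latency_slope(peaks, "peak1") * 1000
        assert abs(slope_ms - 8.0) < 1.0
        lat_diff = (
            peaks.loc[peaks.vot_step == 6, "peak1_latency"].iloc[0]
            - peaks.loc[peaks.vot_step == 1, "peak1_latency"].iloc[0]
        )
        assert abs(lat_diff - 0.040) < 0.004

    def test_mismatch_window_outside_epoch_errors(self, intraop_roster):
        spec = EvokedEffectSpec(mismatch_window=(0.9, 1.0))
        with pytest.raises(ValueError, match="mismatch window"):
            simulate_evoked_trials(intraop_roster, spec, fs=250.0,
                                   window=(-0.15, 0.8), seed=0)

    def test_template_deterministic_part(self):
        spec = EvokedEffectSpec()
        t = np.linspace(-0.15, 0.8, 476)
        w_c = evoked_template(spec, t, 1, incongruent=False)
        w_i = evoked_template(spec, t, 1, incongruent=True)
        diff = w_i - w_c
        inside = (t >= 0.27) & (t <= 0.35)
        assert np.abs(diff[~inside]).max() < np.abs(diff[inside]).max() / 3
        assert diff.max() == pytest.approx(spec.mismatch_for("pre"), rel=1e-6)


class TestBehaviorSimulation:
    def test_null_params_half_rate(self):
        roster = make_task_roster(EXTENDED_DESIGN, seed=0)
        tab = simulate_behavior(roster, PsychometricParams(0, 0, 0, 0, 0, 0),
                                seed=1)
        rate = tab["response"].mean()
        assert abs(rate - 0.5) < 3 * 0.5 / np.sqrt(len(tab))

    def test_steep_slope_step_function(self):
        roster = make_task_roster(EXTENDED_DESIGN, seed=0)
        tab = simulate_behavior(
            roster, PsychometricParams(0.0, 1e6, 0, 0, 0, 0), seed=2
        )
        by_step = tab.groupby("vot_step")["response"].mean()
        assert (by_step.loc[[1, 2, 3]] == 0).all()
        assert (by_step.loc[[4, 5, 6]] == 1).all()

    def test_determinism(self):
        roster = make_task_roster(EXTENDED_DESIGN, seed=0)
        a = simulate_behavior(roster, PsychometricParams(), seed=5)
        b = simulate_behavior(roster, PsychometricParams(), seed=5)
        pd.testing.assert_frame_equal(a, b)
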