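"""Depolarization scoring: threshold, kinetics, trace amplitude, Fluo-4."""

import numpy as np
import pandas as pd
import pytest

from catscreen.assays import (
    delta_afu,
    fluo4_summary,
    score_em,
    set_disc3_threshold,
)
from catscreen.preprocess import preprocess_tube
from catscreen.simulate import WellSimSpec, simulate_trace, simulate_well
from catscreen.thresholds import UnimodalError


def _gated_live(spec, seed, spillover=None):
    df = simulate_well(spec, seed=seed)
    live, _ = preprocess_tube(df, spillover=spillover)
    return live


class TestDisc3Threshold:
    def test_threshold_separates_synthetic_modes(self, neg_well, spillover):
        spec, df = neg_well
        live, _ = preprocess_tube(df, spillover=spillover)
        thr = set_disc3_threshold(live)
        basal = live[live["time"] < spec.t_egta_s]
        hyper = basal[basal["em_state"] == "hyperpolarized"]
        depol = basal[basal["em_state"] == "depolarized"]
        assert spec.disc3_low_median_afu < thr < spec.disc3_high_median_afu
        assert (hyper["disc3"] > thr).mean() >= 0.99
        assert (depol["disc3"] <= thr).mean() >= 0.99

    def test_unimodal_distribution_raises(self):
        spec = WellSimSpec(n_events=5000, disc3_high_fraction=1.0, p_mig=0.0,
                           debris_fraction=0, doublet_fraction=0, dead_fraction=0)
        df = simulate_well(spec, seed=1)
        with pytest.raises(UnimodalError):
            set_disc3_threshold(df)

    def test_threshold_shifts_with_uniform_gain(self, neg_well, spillover):
        _, df = neg_well
        live, _ = preprocess_tube(df, spillover=spillover)
        thr = set_disc3_threshold(live)
        scaled = live.copy()
        scaled["disc3"] = scaled["disc3"] * 8.0
        thr_scaled = set_disc3_threshold(scaled)
        assert thr_scaled / 8.0 == pytest.approx(thr, rel=0.05)


class TestScoreEm:
    def test_uninhibited_well_migrates_at_least_seventy_percent(
        self, neg_well, spillover
    ):
        _, df = neg_well
        live, _ = preprocess_tube(df, spillover=spillover)
        thr = set_disc3_threshold(live)
        r = score_em(live, thr)
        assert r.qc_pass
        assert r.migration_fraction >= 0.70
        assert r.normalized_mean[0] == pytest.approx(1.0)

    def test_blocked_well_neither_migrates_nor_shifts(self, spillover):
        spec = WellSimSpec(p_mig=0.0, n_events=20_000, spillover=spillover)
        live = _gated_live(spec, seed=2, spillover=spillover)
        thr = set_disc3_threshold(live)
        r = score_em(live, thr)
        assert r.migration_fraction <= 0.05
        assert np.nanmax(np.abs(r.normalized_mean - 1.0)) < 0.05

    def test_stationary_population_stays_normalized_to_one(self):
        # static events with no EGTA effect: every bin's normalized mean ~ 1
        rng = np.random.default_rng(3)
        n = 30_000
        df = pd.DataFrame(
            {
                "time": rng.uniform(0, 180, n),
                "disc3": np.where(
                    rng.random(n) < 0.8,
                    rng.lognormal(np.log(1500), 0.3, n),
                    rng.lognormal(np.log(150), 0.3, n),
                ),
            }
        )
        r = score_em(df, threshold=500.0)
        assert np.nanmax(np.abs(r.normalized_mean - 1.0)) < 0.03
        assert r.migration_fraction <= 0.02

    @pytest.mark.parametrize("seed", [0, 1])
    def test_migration_monotone_in_true_probability(self, seed, spillover):
        migrations = []
        for p in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            spec = WellSimSpec(p_mig=p, n_events=10_000, spillover=spillover)
            live = _gated_live(spec, seed=seed, spillover=spillover)
            thr = set_disc3_threshold(live)  # basal window is bimodal for any p
            migrations.append(score_em(live, thr).migration_fraction)
        assert all(b >= a - 0.03 for a, b in zip(migrations, migrations[1:]))
        assert migrations[-1] > migrations[0] + 0.8

    def test_invariant_to_event_order_and_gain(self, neg_well, spillover):
        _, df = neg_well
        live, _ = preprocess_tube(df, spillover=spillover)
        thr = set_disc3_threshold(live)
        base = score_em(live, thr)
        shuffled = live.sample(frac=1.0, random_state=0)
        r_shuf = score_em(shuffled, thr)
        assert r_shuf.migration_fraction == base.migration_fraction
        np.testing.assert_allclose(r_shuf.normalized_mean, base.normalized_mean)
        scaled = live.copy()
        scaled["disc3"] = scaled["disc3"] * 5.0
        r_scaled = score_em(scaled, thr * 5.0)
        assert r_scaled.migration_fraction == base.migration_fraction
        np.testing.assert_allclose(r_scaled.normalized_mean, base.normalized_mean)

    def test_underpowered_sample_flagged_without_score(self):
        df = pd.DataFrame({"time": np.linspace(0, 180, 50),
                           "disc3": np.full(50, 1000.0)})
        r = score_em(df, threshold=500.0)
        assert not r.qc_pass
        assert r.migration_fraction is None


class TestDeltaAfu:
    def test_flat_trace_gives_zero(self):
        tr = simulate_trace(amplitude=0.0, noise_sd=0.0, t_egta=120.0)
        assert delta_afu(tr).delta == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_step_recovers_amplitude_exactly(self):
        tr = simulate_trace(amplitude=320.0, noise_sd=0.0, t_egta=120.0, rise_tau=0.0)
        r = delta_afu(tr)
        assert r.delta == 320.0
        assert r.stable_found

    def test_default_rise_recovers_amplitude(self):
        tr = simulate_trace(amplitude=320.0, noise_sd=0.0, t_egta=120.0)
        assert delta_afu(tr).delta == pytest.approx(320.0, rel=1e-3)

    def test_linearity_of_summed_steps(self):
        a = simulate_trace(amplitude=100.0, noise_sd=0.0, t_egta=120.0, rise_tau=0.0)
        b = simulate_trace(amplitude=250.0, noise_sd=0.0, t_egta=120.0, rise_tau=0.0)
        combined = type(a)(
            time_s=a.time_s, fluorescence=a.fluorescence + b.fluorescence,
            t_egta_s=a.t_egta_s,
        )
        assert delta_afu(combined).delta == pytest.approx(
            delta_afu(a).delta + delta_afu(b).delta
        )

    def test_noisy_traces_recover_mean_amplitude(self):
        deltas = [
            delta_afu(simulate_trace(200.0, noise_sd=10.0, t_egta=120.0, seed=s)).delta
            for s in range(30)
        ]
        assert np.mean(deltas) == pytest.approx(200.0, rel=0.05)

    def test_blocked_vs_control_normalization(self):
        # functional (control-like) traces show a large step; blocked ones do not
        ctrl = [
            delta_afu(simulate_trace(400.0, noise_sd=8.0, t_egta=120.0, seed=s)).delta
            for s in range(5)
        ]
        het = delta_afu(simulate_trace(400.0, 8.0, 120.0, seed=10), control_deltas=ctrl)
        ko = delta_afu(simulate_trace(30.0, 8.0, 120.0, seed=11), control_deltas=ctrl)
        assert ko.normalized < 0.3 * het.normalized

    def test_short_trace_rejected(self):
        tr = simulate_trace(100.0, t_egta=30.0, duration=60.0)
        with pytest.raises(ValueError):
            delta_afu(tr)


class TestFluo4:
    def test_identity_sample_matches_control(self):
        rng = np.random.default_rng(0)
        c = np.where(rng.random(20_000) < 0.6,
                     rng.lognormal(np.log(2000), 0.4, 20_000),
                     rng.lognormal(np.log(100), 0.4, 20_000))
        r = fluo4_summary(c, c)
        assert r.normalized_median == 1.0
        assert r.percent_responders == r.control_percent_responders

    def test_doubled_intensity_doubles_normalized_median(self):
        rng = np.random.default_rng(1)
        c = rng.lognormal(np.log(500), 0.5, 10_000)
        r = fluo4_summary(2.0 * c, c)
        assert r.normalized_median == pytest.approx(2.0)

    def test_nonresponding_sample_scores_below_control(self):
        rng = np.random.default_rng(2)
        n = 20_000
        responder_share = 0.6
        control = np.where(
            rng.random(n) < responder_share,
            rng.lognormal(np.log(2000), 0.4, n),
            rng.lognormal(np.log(100), 0.4, n),
        )
        ko = rng.lognormal(np.log(100), 0.4, n)  # no capacitation Ca2+ rise
        r = fluo4_summary(ko, control)
        sd = 100 * np.sqrt(responder_share * (1 - responder_share) / n)
        assert r.percent_responders < r.control_percent_responders - 3 * sd
        assert r.normalized_median < 0.5
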