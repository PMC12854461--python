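"""Generator correctness: determinism, programmed rates, table structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st_h

from co2sense import synthetic as syn


class TestRecordingSimulator:
    def test_seed_determinism(self):
        cfg = syn.RecordingConfig(seed=7, n_replicates=1, rest_duration=0.5,
                                  pre_stimulus=0.5)
        rec1, truth1 = syn.simulate_recording(cfg)
        rec2, truth2 = syn.simulate_recording(cfg)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)
        for u in truth1.spike_times:
            np.testing.assert_array_equal(truth1.spike_times[u],
                                          truth2.spike_times[u])

    def test_epoch_layout(self):
        cfg = syn.RecordingConfig(seed=0)
        rec, _ = syn.simulate_recording(cfg)
        assert len(rec.epochs) == cfg.n_replicates
        onsets = [on for on, _ in rec.epochs]
        assert np.allclose(np.diff(onsets), 12.0)  # 2 s stimulus + 10 s rest
        assert rec.duration == pytest.approx(62.0)

    def test_ground_truth_respects_refractory(self):
        _, truth = syn.simulate_recording(syn.RecordingConfig(seed=3))
        for u, times in truth.spike_times.items():
            if len(times) > 1:
                assert np.min(np.diff(times)) >= truth.config.units[u].refractory

    def test_onset_rate_matches_programmed_rate(self):
        """Empirical onset rate over 200 seeded simulations stays within
        3 SE of the programmed 250 spikes/s peak."""
        units = (
            syn.UnitSpec(amplitude=8.0, baseline_rate=0.0),
            syn.UnitSpec(amplitude=14.0, baseline_rate=0.0, peak_rate=250.0,
                         adaptation_tau=10.0, steady_rate=50.0),
            syn.UnitSpec(amplitude=20.0, baseline_rate=0.0),
            syn.UnitSpec(amplitude=26.0, baseline_rate=0.0),
        )
        rates = []
        for seed in range(200):
            cfg = syn.RecordingConfig(units=units, seed=seed, n_replicates=1,
                                      stimulus_duration=0.5, rest_duration=0.2,
                                      pre_stimulus=0.2)
            _, truth = syn.simulate_recording(cfg)
            t = truth.spike_times[1]
            on = cfg.epochs[0][0]
            rates.append(np.count_nonzero((t >= on) & (t < on + 0.1)) / 0.1)
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - 250.0) < 3 * se

    def test_rejects_bad_configs(self):
        with pytest.raises(ValueError):
            syn.RecordingConfig(sampling_rate=0.0)
        with pytest.raises(ValueError):
            syn.RecordingConfig(units=syn.RecordingConfig().units[:3])
        with pytest.raises(ValueError):
            syn.UnitSpec(amplitude=-1.0, baseline_rate=1.0)
        with pytest.raises(ValueError):
            syn.UnitSpec(amplitude=1.0, baseline_rate=1.0, peak_rate=10.0,
                         steady_rate=20.0)
        with pytest.raises(ValueError):
            syn.LfpSpec(onset_slope=1.0)


class TestRateTable:
    def test_noiseless_cells_are_exact(self):
        df, truth = syn.simulate_rate_table([1.0, 2.0, 0.5], [1.0, 3.0, 0.25],
                                            80.0, 0.0, 5, seed=0)
        for (cl, dl), mean in truth["cell_means"].items():
            cell = df[(df.cis == cl) & (df.cds == dl)]["onset_rate"]
            assert np.allclose(cell, mean)

    def test_identity_factors_give_flat_table(self):
        df, _ = syn.simulate_rate_table([1, 1, 1], [1, 1, 1], 55.0, 0.0, 4, seed=0)
        assert np.allclose(df["onset_rate"], 55.0)

    @given(st_h.integers(min_value=0, max_value=10_000))
    def test_noiseless_multiplicativity(self, seed):
        """cell(i,j) * cell(k,l) == cell(i,l) * cell(k,j) with no noise."""
        rng = np.random.default_rng(seed)
        cis = rng.uniform(0.5, 2.0, 3)
        cds = rng.uniform(0.5, 2.0, 3)
        df, _ = syn.simulate_rate_table(cis, cds, 100.0, 0.0, 1, seed=seed)
        m = df.pivot_table(index="cis", columns="cds", values="onset_rate")
        v = m.to_numpy()
        assert np.allclose(v[0, 0] * v[1, 1], v[0, 1] * v[1, 0])
        assert np.allclose(v[1, 2] * v[2, 0], v[1, 0] * v[2, 2])

    def test_cell_means_recover_under_noise(self):
        """Per-cell sample means stay within the CLT band in >= 95% of
        500 seeded tables (noise_cv 0.1, n 10)."""
        ok = 0
        n_tables = 500
        for seed in range(n_tables):
            df, truth = syn.simulate_rate_table([1.0, 1.3, 0.9], [1.0, 0.7, 2.0],
                                                100.0, 0.1, 10, seed=seed)
            cl, dl = "sub", "suz"
            mean = truth["cell_means"][(cl, dl)]
            sample = df[(df.cis == cl) & (df.cds == dl)]["onset_rate"].mean()
            if abs(sample - mean) < 4 * (0.1 * mean / np.sqrt(10)):
                ok += 1
        assert ok / n_tables >= 0.95

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            syn.simulate_rate_table([1, 1, 1], [1, 1, 1], 100.0, 0.1, 0)
        with pytest.raises(ValueError):
            syn.simulate_rate_table([1, -1, 1], [1, 1, 1], 100.0, 0.1, 5)


class TestOvipositionSimulator:
    def test_full_preference_puts_all_eggs_high(self):
        for seed in range(20):
            rec = syn.simulate_oviposition_trial(
                syn.TrialConfig(true_opi=1.0, seed=seed))
            assert rec.eggs_low == 0

    def test_neutral_preference_pools_to_zero_opi(self):
        high = low = 0
        seed = 0
        while high + low < 10_000:
            rec = syn.simulate_oviposition_trial(
                syn.TrialConfig(true_opi=0.0, seed=seed))
            high += rec.eggs_high
            low += rec.eggs_low
            seed += 1
        assert abs((high - low) / (high + low)) < 0.05

    def test_zero_mean_gives_zero_egg_trial(self):
        rec = syn.simulate_oviposition_trial(
            syn.TrialConfig(mean_eggs_per_fly=0.0, seed=0))
        assert rec.total_eggs == 0

    def test_control_conditions_pool_counts(self):
        rec = syn.simulate_oviposition_trial(
            syn.TrialConfig(condition="air", seed=1))
        assert rec.eggs_pooled is not None and rec.eggs_high is None

    def test_rejects_out_of_range_opi(self):
        with pytest.raises(ValueError):
            syn.TrialConfig(true_opi=1.5)


class TestCtSimulator:
    def test_structure_and_determinism(self):
        cfg = syn.CtConfig(means={("Gr63a", "mel"): 30.0, ("TBP", "mel"): 24.0},
                           biological_sd=0.3, technical_sd=0.2, seed=5)
        t1 = syn.simulate_ct_table(cfg)
        t2 = syn.simulate_ct_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        assert len(t1) == 2 * 3 * 3
        assert set(t1.columns) == {"gene", "sample", "bio_replicate",
                                   "tech_replicate", "ct"}

    def test_technical_sd_recovered(self):
        """Pooled within-(sample, bio) SD across 200 tables within 10% of
        the programmed technical SD."""
        cfg0 = dict(means={("Gr63a", "mel"): 30.0, ("TBP", "mel"): 24.0},
                    biological_sd=0.3, technical_sd=0.2)
        devs = []
        for seed in range(200):
            t = syn.simulate_ct_table(syn.CtConfig(seed=seed, **cfg0))
            g = t.groupby(["gene", "sample", "bio_replicate"])["ct"]
            devs.extend((t["ct"] - g.transform("mean")).to_numpy())
        # each tech triple loses one df: scale up by sqrt(n/(n-1))
        pooled = np.sqrt(np.mean(np.square(devs)) * 3 / 2)
        assert abs(pooled - 0.2) < 0.02

    def test_programmed_rq_recovered_exactly_when_noiseless(self):
        from co2sense.stats import qpcr_rq

        cfg = syn.ct_config_from_rq({"mel": 1.0, "suz": 1.2, "sub": 5.0},
                                    calibrator="mel")
        table = syn.simulate_ct_table(cfg)
        res = qpcr_rq(table, reference_gene="TBP", calibrator="mel")
        assert res.mean_rq["mel"] == pytest.approx(1.0)
        assert res.mean_rq["sub"] == pytest.approx(5.0)
        assert res.mean_rq["suz"] == pytest.approx(1.2)

    def test_rejects_bad_ct_means(self):
        with pytest.raises(ValueError):
            syn.CtConfig(means={("g", "s"): 45.0})


class TestRecordingIO:
    def test_round_trip(self, tmp_path):
        cfg = syn.RecordingConfig(seed=2, n_replicates=2, rest_duration=0.5,
                                  pre_stimulus=0.5)
        rec, truth = syn.simulate_recording(cfg)
        path = tmp_path / "rec.h5"
        syn.write_recording(path, rec, truth)
        back = syn.read_recording(path)
        np.testing.assert_allclose(back.samples, rec.samples)
        assert back.epochs == rec.epochs
        assert back.metadata["co2_fraction"] == cfg.co2_fraction
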