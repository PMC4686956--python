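import numpy as np
import pytest
from scipy import stats

from swiftag import (
    REFERENCE_NOISE_FREQS_HZ,
    cycle_average,
    fdr_bh,
    noise_frequency_set,
    percent_signal_change,
    phase_map,
    power_spectrum,
    snr_spectrum,
    tagging_pvalues,
)
from swiftag.bold import simulate_voxel
from swiftag.tagging import FrequencyTaggingModel


class TestPercentSignalChange:
    def test_constant_maps_to_100(self):
        out = percent_signal_change(np.full(50, 500.0))
        assert np.allclose(out, 100.0)

    def test_mean_is_100_and_scale_invariant(self, rng):
        x = 500 + rng.standard_normal(216)
        out = percent_signal_change(x)
        assert out.mean() == pytest.approx(100.0)
        assert np.allclose(percent_signal_change(2 * x), out)

    def test_nonpositive_mean_flagged(self):
        x = np.stack([np.full(20, 10.0), np.full(20, -1.0)])
        with pytest.warns(UserWarning, match="non-positive"):
            out = percent_signal_change(x)
        assert np.isnan(out[1]).all() and not np.isnan(out[0]).any()


class TestPowerSpectrum:
    def test_exact_bin_sinusoid(self):
        tr, n = 2.0, 128
        t = np.arange(n) * tr
        f = 8 / (n * tr)
        sp = power_spectrum(np.sin(2 * np.pi * f * t), tr, detrend=False)
        assert np.argmax(sp.power) == 8
        assert sp.power[np.arange(sp.power.size) != 8].max() < 1e-12 * sp.power[8]

    def test_grid_resolution_216_volumes(self, rng):
        sp = power_spectrum(rng.standard_normal(216), 2.46)
        assert sp.df == pytest.approx(1 / 531.36)

    def test_parseval(self, rng):
        from scipy.signal import detrend

        x = rng.standard_normal(200)
        sp = power_spectrum(x, 1.0)
        xd = detrend(x)
        assert sp.power.sum() == pytest.approx((xd ** 2).sum(), rel=1e-6)

    def test_white_noise_flat_slope(self, rng):
        """Regression of expected power on frequency is ~flat for noise."""
        p = np.mean(
            [power_spectrum(rng.standard_normal(128), 1.0).power for _ in range(400)],
            axis=0,
        )[1:-1]
        k = np.arange(p.size)
        slope = np.polyfit(k, p / p.mean(), 1)[0]
        assert abs(slope) < 5e-3

    def test_nan_rejected(self):
        x = np.zeros(64)
        x[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            power_spectrum(x, 1.0)


class TestSnrSpectrum:
    def _flat(self, value=3.0, n=64):
        from swiftag.tagging import Spectrum

        return Spectrum(np.arange(n) / n, np.full(n, value), 1.0, n)

    def test_flat_spectrum_gives_unity(self):
        snr = snr_spectrum(self._flat())
        assert np.allclose(snr[7:-7], 1.0)
        assert np.isnan(snr[:7]).all() and np.isnan(snr[-7:]).all()

    def test_delta_bin_snr_equals_ratio(self):
        sp = self._flat(1.0)
        sp.power[30] = 15.0
        snr = snr_spectrum(sp)
        assert snr[30] == pytest.approx(15.0)

    def test_neighbor_of_delta_below_unity(self):
        sp = self._flat(1.0)
        sp.power[30] = 15.0
        snr = snr_spectrum(sp)
        assert snr[29] < 1.0 and snr[31] < 1.0

    def test_white_noise_mean_snr_near_unity(self, rng):
        """Across 200 seeded noise series the average SNR is ~1."""
        vals = []
        for _ in range(200):
            sp = power_spectrum(rng.standard_normal(128), 1.0)
            snr = snr_spectrum(sp)
            vals.append(np.nanmean(snr))
        m = np.mean(vals)
        assert 0.9 <= m <= 1.1

    def test_odd_band_rejected(self):
        with pytest.raises(ValueError, match="even"):
            snr_spectrum(self._flat(), band_bins=13)


class TestNoiseFrequencySet:
    def test_reference_configuration_has_22(self):
        freqs = noise_frequency_set((0.06, 0.08, 0.10), df=1 / 540)
        assert len(freqs) == 22
        assert len(np.unique(freqs)) == 22

    def test_packaged_constant_matches_rule_structure(self):
        """The packaged enumeration and the generative rule agree bin by
        bin (4 groups of 5/6/6/5 between and around the three tags)."""
        assert len(REFERENCE_NOISE_FREQS_HZ) == 22
        rule = noise_frequency_set((0.06, 0.08, 0.10), df=1 / 540)
        # same frequencies within half a bin (the printed grid constant
        # differs slightly from 1/540)
        assert np.abs(np.sort(REFERENCE_NOISE_FREQS_HZ) - np.sort(rule)).max() < 0.5 / 540

    def test_single_isolated_tag(self):
        freqs = noise_frequency_set([0.1], df=0.01, half_band=7, guard=0)
        assert len(freqs) == 14

    def test_adjacent_tags_union_smaller(self):
        freqs = noise_frequency_set([0.05, 0.06], df=0.01, half_band=7, guard=0)
        assert len(freqs) < 28

    def test_guard_must_be_smaller(self):
        with pytest.raises(ValueError):
            noise_frequency_set([0.1], df=0.01, half_band=3, guard=3)


def _null_pvals(rng, n_vox=400, n_runs=3, tr=2.46, n=216):
    runs = [
        power_spectrum(
            percent_signal_change(500 + 5 * rng.standard_normal((n_vox, n))), tr
        )
        for _ in range(n_runs)
    ]
    noise = noise_frequency_set((0.06, 0.08, 0.10), df=1 / (n * tr))
    p, t = tagging_pvalues(runs, 0.10, noise)
    return p


class TestTaggingPvalues:
    def test_null_uniform(self, rng):
        p = _null_pvals(rng)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_strong_signal_detected(self, rng):
        tr, n = 2.46, 216
        onsets = np.arange(3.0, n * tr, 10.0)
        runs = []
        for s in range(3):
            vox = np.stack(
                [simulate_voxel(onsets, 3.0, tr=tr, n_volumes=n, noise_sd=2.0,
                                seed=rng) for _ in range(4)]
            )
            runs.append(power_spectrum(percent_signal_change(vox), tr))
        noise = noise_frequency_set((0.06, 0.08, 0.10), df=1 / (n * tr))
        p, t = tagging_pvalues(runs, 0.10, noise)
        assert np.all(p < 1e-4)
        assert np.all(t > 0)

    def test_degenerate_constant_powers(self):
        from swiftag.tagging import Spectrum

        sp = [Spectrum(np.arange(64) / 64.0, np.ones(64), 1.0, 64) for _ in range(3)]
        with pytest.warns(UserWarning, match="zero variance"):
            p, t = tagging_pvalues(sp, 0.25, [0.1, 0.15])
        assert p == pytest.approx(1.0)

    def test_single_run_rejected(self, rng):
        sp = power_spectrum(rng.standard_normal((4, 64)), 1.0)
        with pytest.raises(ValueError, match="two runs"):
            tagging_pvalues([sp], 0.1, [0.2])


class TestFdrBh:
    def test_all_tiny_rejected(self):
        assert fdr_bh(np.full(10, 0.001), q=0.05).all()

    def test_hand_computed_step_up(self):
        # sorted p (0.04, 0.5); BH thresholds (0.025, 0.05): no rejection
        assert not fdr_bh(np.array([0.04, 0.5]), q=0.05).any()
        # (0.02, 0.04): 0.04 <= 2/2*0.05 -> both rejected by step-up
        assert fdr_bh(np.array([0.02, 0.04]), q=0.05).all()

    def test_global_null_family_rejection_rate(self, rng):
        """Under the global null the proportion of families with any
        rejection stays at ~q."""
        q = 0.05
        hits = sum(
            fdr_bh(rng.uniform(size=100), q=q).any() for _ in range(400)
        )
        rate = hits / 400
        assert rate <= q + 3 * np.sqrt(q * (1 - q) / 400)

    def test_empty_input(self):
        assert fdr_bh(np.array([])).size == 0


class TestPhaseMap:
    def test_injected_phase_recovered(self):
        tr, n = 1.0, 128
        t = np.arange(n) * tr
        f = 16 / (n * tr)
        x = 100 + np.cos(2 * np.pi * f * t + np.pi / 3)[None, :]
        ph = phase_map(x, tr, f, snr_threshold=2)
        assert abs(ph[0] - np.pi / 3) < 2 * np.pi / n

    def test_noise_voxels_mostly_masked(self, rng):
        x = rng.standard_normal((300, 128))
        ph = phase_map(x, 1.0, 16 / 128.0, snr_threshold=2)
        assert np.isnan(ph).mean() > 0.5

    def test_threshold_zero_masks_nothing(self, rng):
        x = rng.standard_normal((50, 128))
        ph = phase_map(x, 1.0, 16 / 128.0, snr_threshold=0)
        assert not np.isnan(ph).any()


class TestCycleAverage:
    def test_noise_free_recovers_cycle(self):
        """Aligned onsets on the TR grid: the cycle average equals any
        single steady-state cycle exactly (the first ~60 s are excluded
        because the HRF undershoot tail has not yet summed to steady
        state there)."""
        tr, n = 2.5, 200
        onsets = np.arange(0.0, n * tr, 10.0)
        s = simulate_voxel(onsets, 2.0, tr=tr, n_volumes=n, noise_sd=0)
        rel, mean, sem = cycle_average(s, onsets[6:-2], tr, window=10.0)
        # compare against the directly extracted epoch at one onset
        i0 = int(onsets[10] / tr)
        direct = s[i0 : i0 + len(rel)]
        assert np.abs(mean - direct).max() < 1e-9

    def test_constant_series_flat_zero_sem(self):
        s = np.full(100, 7.0)
        rel, mean, sem = cycle_average(s, [10.0, 30.0, 50.0], 1.0, window=15.0)
        assert np.allclose(mean, 7.0) and np.allclose(sem, 0.0)

    def test_window_exceeding_gap_rejected(self):
        s = np.zeros(100)
        with pytest.raises(ValueError, match="gap"):
            cycle_average(s, [10.0, 20.0], 1.0, window=12.5)
        # wraparound opt-in allows it
        cycle_average(s, [10.0, 20.0], 1.0, window=12.5, wraparound=True)


def test_model_results_summary(rng):
    """The model front end produces per-ROI tables with high FDR hit
    rates in strongly tagged ROIs and near-zero in null ROIs."""
    from swiftag.bold import RoiSpec, generate_study

    spec = {
        "V1": RoiSpec(60, 0.0, 2.0, 0.1),
        "FFA": RoiSpec(30, 1.0, 3.0, 0.1),
    }
    study = generate_study(spec, n_runs=3, noise_sd=3.0, seed=21)
    res = FrequencyTaggingModel(study, tag_freqs=(0.1,)).fit()
    tab = res.summary(q=0.05).set_index("roi")
    assert tab.loc["FFA", "frac_fdr_q0.05"] > 0.9
    assert tab.loc["V1", "frac_fdr_q0.05"] < 0.1
    assert tab.loc["FFA", "median_snr"] > 2
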