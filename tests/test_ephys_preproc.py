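"""MUA extraction chain, baseline correction, normalization, QC."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from gestaltfbm.ephys_preproc import (MUADataset, QCConfig, SiteRecording,
                                      baseline_correct, mua_from_broadband,
                                      normalize_to_peak, qc_filter,
                                      window_mask)
from gestaltfbm.synthetic_data import (SimConfig, make_cohort,
                                       simulate_mua_dataset)

FS = 24414.0625


class TestMUAFromBroadband:
    def test_zero_in_zero_out(self):
        env, fr = mua_from_broadband(np.zeros(30000), FS)
        assert np.abs(env).max() == 0.0
        assert fr == pytest.approx(FS / 32)

    def test_rectified_sine_mean(self):
        # a 1-kHz sine of amplitude A rectifies to mean 2A/pi
        t = np.arange(int(FS * 1.2)) / FS
        A = 2.0
        env, fr = mua_from_broadband(A * np.sin(2 * np.pi * 1000 * t), FS)
        mid = env[int(0.3 * fr):int(0.9 * fr)]
        assert mid.mean() == pytest.approx(2 * A / np.pi, rel=0.02)

    def test_notch_removes_50hz_line(self):
        rng = np.random.default_rng(0)
        carrier = rng.normal(0, 1, int(FS * 4))
        line = 1.0 + 0.5 * np.sin(2 * np.pi * 50 * np.arange(carrier.size)
                                  / FS)
        contaminated = carrier * line
        with_notch, fr = mua_from_broadband(contaminated, FS, notch=True)
        without, _ = mua_from_broadband(contaminated, FS, notch=False)

        def line_power(x):
            x = x - x.mean()
            w = np.hanning(x.size)
            f = np.fft.rfftfreq(x.size, 1 / fr)
            p = np.abs(np.fft.rfft(x * w)) ** 2
            i = int(np.argmin(np.abs(f - 50.0)))
            return p[i - 1:i + 2].sum()

        ratio_db = 10 * np.log10(line_power(with_notch)
                                 / line_power(without))
        assert ratio_db <= -20.0

    def test_nan_input_rejected(self):
        x = np.zeros(30000)
        x[5] = np.nan
        with pytest.raises(ValueError):
            mua_from_broadband(x, FS)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            mua_from_broadband(np.zeros(100), FS)

    def test_pipeline_order_matters(self):
        # rectifying before the band-pass is a different (wrong) pipeline
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40000)
        env, _ = mua_from_broadband(x, FS)
        sos_bp = signal.butter(4, [500, 5000], btype="bandpass", fs=FS,
                               output="sos")
        swapped = signal.sosfiltfilt(sos_bp, np.abs(x))
        sos_lp = signal.butter(4, 200, btype="low", fs=FS, output="sos")
        swapped = signal.sosfiltfilt(sos_lp, np.abs(swapped))[::32]
        assert not np.allclose(env[50:-50],
                               swapped[50:-50], atol=1e-3)


def _toy_dataset(n_trials=120, drift=None, seed=0, n_time=300,
                 rate=763.0):
    rng = np.random.default_rng(seed)
    t = np.arange(n_time) / rate * 1000.0 - 150.0
    resp = np.where(t > 0, np.exp(-0.5 * ((t - 60) / 25.0) ** 2), 0.0)
    data = resp[None, :] * 2.0 + rng.normal(0, 0.05, (n_trials, n_time))
    if drift is not None:
        data = data + drift[:, None]
    trials = pd.DataFrame({"day": 0, "well_centered": True,
                           "cue": "all_cues", "figground": "figure",
                           "trial": np.arange(n_trials)})
    site = SiteRecording("s0", data, trials)
    return MUADataset(sites=[site], time_ms=t, sample_rate=rate)


class TestBaselineCorrect:
    def test_linear_drift_removed(self):
        n = 400
        drift = np.linspace(0, 0.5, n)
        ds = baseline_correct(_toy_dataset(n, drift=drift))
        mask = window_mask(ds.time_ms, (-100, 0))
        base = ds.sites[0].data[:, mask].mean(axis=1)
        slope = np.polyfit(np.arange(n), base, 1)[0] * n
        assert abs(slope) < 0.01

    def test_driftfree_data_unchanged_up_to_constant(self):
        raw = _toy_dataset(150)
        ds = baseline_correct(raw)
        delta = raw.sites[0].data - ds.sites[0].data
        assert np.ptp(delta.mean(axis=1)) < 0.05

    def test_outlier_trial_does_not_distort_neighbors(self):
        raw = _toy_dataset(200)
        spiked = raw.copy()
        spiked.sites[0].data[100] += 10.0
        a = baseline_correct(raw).sites[0].data
        b = baseline_correct(spiked).sites[0].data
        neighbors = np.r_[80:95, 106:121]
        assert np.abs(a[neighbors] - b[neighbors]).max() < 0.05

    def test_few_trials_fall_back_with_warning(self):
        with pytest.warns(UserWarning):
            baseline_correct(_toy_dataset(5))


class TestNormalizeToPeak:
    def test_peak_becomes_one_and_scaling_is_linear(self):
        ds = baseline_correct(_toy_dataset(150))
        doubled = ds.copy()
        doubled.sites[0].data = doubled.sites[0].data * 2.0
        n1 = normalize_to_peak(ds)
        n2 = normalize_to_peak(doubled)
        np.testing.assert_allclose(n1.sites[0].data, n2.sites[0].data,
                                   atol=1e-12)
        m = n1.sites[0].data.mean(axis=0)
        sm = np.convolve(m, np.ones(20) / 20, mode="same")
        w = window_mask(n1.time_ms, (30, 100))
        assert sm[w].max() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent(self):
        ds = normalize_to_peak(baseline_correct(_toy_dataset(150)))
        again = normalize_to_peak(ds)
        np.testing.assert_allclose(ds.sites[0].data, again.sites[0].data,
                                   rtol=1e-6)

    def test_late_peak_not_used(self):
        # response peaking at 120 ms: normalization must use the 30-100 ms
        # maximum, not the global one
        rate = 763.0
        t = np.arange(300) / rate * 1000.0 - 150.0
        resp = np.exp(-0.5 * ((t - 120) / 12.0) ** 2) * 3.0
        data = np.tile(resp, (40, 1))
        site = SiteRecording("s0", data, pd.DataFrame(
            {"day": np.zeros(40, int), "well_centered": True}))
        ds = normalize_to_peak(MUADataset([site], t, rate))
        m = ds.sites[0].data.mean(axis=0)
        sm = np.convolve(m, np.ones(20) / 20, mode="same")
        w = window_mask(t, (30, 100))
        assert sm[w].max() == pytest.approx(1.0, abs=1e-9)
        assert sm.max() > 1.0

    def test_nonpositive_peak_excluded_with_reason(self):
        t = np.arange(300) / 763.0 * 1000.0 - 150.0
        site = SiteRecording("dead", np.zeros((30, 300)), pd.DataFrame(
            {"day": np.zeros(30, int), "well_centered": True}))
        ds = normalize_to_peak(MUADataset([site], t, 763.0))
        assert ds.sites == []
        assert ds.meta["excluded_sites"]["dead"] == "nonpositive_peak"


@pytest.fixture(scope="module")
def planted():
    good = make_cohort(6, seed=0, days=2, snr_true=5.0)
    bad = [replace(s, site_id=s.site_id + "_bad", day_snr={1: 0.3})
           for s in make_cohort(2, seed=50, days=2, snr_true=5.0)]
    cfg = SimConfig(seed=1, design="constant_stimuli",
                    cues=("all_cues",), n_trials_per_site_condition=30,
                    n_crf_trials=40)
    ds = normalize_to_peak(baseline_correct(
        simulate_mua_dataset(good + bad, cfg)))
    rf = pd.DataFrame([{"site_id": s.site_id, "x": -3.0, "y": -4.0}
                       for s in good + bad])
    return ds, rf, good, bad


class TestQCFilter:
    def test_exactly_planted_low_snr_days_excluded(self, planted):
        ds, rf, good, bad = planted
        report, filtered = qc_filter(ds, rf)
        excl = report.day_table[~report.day_table["included"]]
        assert set(excl["site_id"]) == {s.site_id for s in bad}
        assert set(excl["day"]) == {1}
        assert all(excl["reason"] == "low_snr")
        assert len(filtered.sites) == len(good) + len(bad)

    def test_rf_centering_rules(self, planted):
        ds, rf, good, bad = planted
        rf = rf.copy()
        rf.loc[rf["site_id"] == good[0].site_id, "x"] = -4.5   # dx = 1.5
        rf.loc[rf["site_id"] == good[1].site_id, "y"] = -5.5   # dy = 1.5
        report, _ = qc_filter(ds, rf)
        tbl = report.site_table.set_index("site_id")
        assert not tbl.loc[good[0].site_id, "included"]
        assert "rf_offset_x" in tbl.loc[good[0].site_id, "reason"]
        assert tbl.loc[good[1].site_id, "included"]

    def test_missing_rf_excludes_site(self, planted):
        ds, rf, good, bad = planted
        report, _ = qc_filter(ds, rf[rf["site_id"] != good[0].site_id])
        tbl = report.site_table.set_index("site_id")
        assert "missing_rf" in tbl.loc[good[0].site_id, "reason"]

    def test_permissive_config_excludes_nothing(self, planted):
        ds, rf, good, bad = planted
        cfg = QCConfig(day_snr_min=0.0, day_correlation_min=-1.1,
                       site_snr_min=0.0, rf_offset_max_x=99,
                       rf_offset_max_y=99)
        report, filtered = qc_filter(ds, rf, config=cfg)
        assert report.day_table["included"].all()
        assert report.site_table["included"].all()

    def test_deterministic_report(self, planted):
        ds, rf, *_ = planted
        a, _ = qc_filter(ds, rf)
        b, _ = qc_filter(ds, rf)
        pd.testing.assert_frame_equal(a.day_table, b.day_table)
        pd.testing.assert_frame_equal(a.site_table, b.site_table)
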