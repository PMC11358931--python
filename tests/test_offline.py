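"""Offline pipeline: FIR band-pass, artifact rejection, STFT, relative
beta, timepoint tables, and the statistical battery."""

import itertools

import numpy as np
import pandas as pd
import pytest

import betanf as b
from betanf.offline import condition_anova, session_trial_table
from betanf.recording import Epoch

FS = 500.0


def _epoch(samples, anchor="precue", window=(-2.0, 4.0), **meta):
    return Epoch(samples=np.asarray(samples, dtype=float), rate_hz=FS,
                 window_s=window, anchor=anchor,
                 trial_index=meta.pop("trial_index", 0), **meta)


def _sine_epoch(freq, amp=1.0, window=(-2.0, 4.0), **meta):
    n = int((window[1] - window[0]) * FS)
    t = np.arange(n) / FS + window[0]
    return _epoch(amp * np.sin(2 * np.pi * freq * t), window=window, **meta)


class TestBandpass:
    def test_band_center_passes(self):
        ep = _sine_epoch(21.0)
        out = b.bandpass_individual([ep], (16, 26))[0]
        # compare RMS away from filter edges
        sl = slice(500, -500)
        atten = 1 - out.samples[sl].std() / ep.samples[sl].std()
        assert atten < 0.05

    def test_out_of_band_rejected_hard(self):
        ep = _sine_epoch(50.0)
        out = b.bandpass_individual([ep], (16, 26))[0]
        sl = slice(500, -500)
        assert out.samples[sl].std() / ep.samples[sl].std() < 0.05

    def test_zero_in_zero_out(self):
        ep = _epoch(np.zeros(3000))
        out = b.bandpass_individual([ep], (16, 26))[0]
        assert np.allclose(out.samples, 0)

    def test_band_above_nyquist_raises(self):
        with pytest.raises(ValueError):
            b.bandpass_individual([_epoch(np.zeros(3000))], (200, 300))


class TestRejectArtifacts:
    def _clean_epochs(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return [
            _epoch(rng.standard_normal(3000) * 5, trial_index=i)
            for i in range(n)
        ]

    def test_clean_epochs_all_retained(self):
        eps = self._clean_epochs()
        kept, log = b.reject_artifacts(eps)
        assert len(kept) == len(eps)
        assert log == []

    def test_injected_artifact_epoch_rejected(self):
        eps = self._clean_epochs()
        eps[3].samples[1500:1560] += 300.0
        kept, log = b.reject_artifacts(eps)
        assert [e["trial_index"] for e in log] == [3]
        assert all(ep.trial_index != 3 for ep in kept)

    def test_infinite_thresholds_are_identity(self):
        eps = self._clean_epochs()
        eps[3].samples[1500:1560] += 300.0
        kept, log = b.reject_artifacts(eps, amplitude_uv=np.inf,
                                       variance_mult=np.inf)
        assert len(kept) == len(eps)

    def test_all_rejected_raises(self):
        eps = self._clean_epochs(n=3)
        with pytest.raises(ValueError):
            b.reject_artifacts(eps, amplitude_uv=1e-6)


class TestStft:
    def test_frame_count_for_6s_epoch(self):
        tf = b.stft_timefreq(_sine_epoch(20.0))
        assert tf.power.shape[1] == 5
        assert np.allclose(np.diff(tf.times_s), 1.0)
        assert np.allclose(np.diff(tf.freqs_hz), 1.0)

    def test_stationary_sinusoid_peaks_in_every_frame(self):
        tf = b.stft_timefreq(_sine_epoch(20.0))
        for j in range(tf.power.shape[1]):
            assert tf.freqs_hz[np.argmax(tf.power[:, j])] == pytest.approx(20.0)

    def test_amplitude_step_quarters_carrier_power(self):
        n = 3000
        t = np.arange(n) / FS - 2.0
        amp = np.where(t < 1.0, 2.0, 1.0)
        ep = _epoch(amp * np.sin(2 * np.pi * 20 * t))
        tf = b.stft_timefreq(ep)
        row = tf.power[tf.freqs_hz == 20.0][0]
        # frames centered at -1 s (fully loud) and +3 s (fully quiet)
        assert row[-1] / row[0] == pytest.approx(0.25, rel=0.05)

    def test_frame_energy_tracks_time_domain(self):
        """Per-frame one-sided total power obeys Parseval against the
        detrended, Hann-tapered frame energy."""
        from scipy.signal import detrend, windows

        rng = np.random.default_rng(1)
        ep = _epoch(rng.standard_normal(3000))
        nwin = 1000
        taper = windows.hann(nwin, sym=False)
        # recompute on the native grid: pairs sum back to native total
        for j, s in enumerate(range(0, 2001, 500)):
            seg = detrend(ep.samples[s:s + nwin], type="linear") * taper
            native = np.abs(np.fft.rfft(seg)) ** 2
            onesided = native[0] + native[-1] + 2 * native[1:-1].sum()
            assert onesided / nwin == pytest.approx(np.sum(seg**2), rel=0.01)

    def test_too_short_epoch_raises(self):
        with pytest.raises(ValueError):
            b.stft_timefreq(_epoch(np.zeros(500), window=(0.0, 1.0)))


class TestRelativeBeta:
    def test_stationary_signal_is_zero_db(self):
        rb = b.relative_beta(_sine_epoch(20.0), (16, 26))
        assert rb.value_db == pytest.approx(0.0, abs=0.2)

    def test_quarter_power_is_minus_6db(self):
        n = 3000
        t = np.arange(n) / FS - 2.0
        amp = np.where(t < 0, 2.0, 1.0)
        ep = _epoch(amp * np.sin(2 * np.pi * 20 * t))
        rb = b.relative_beta(ep, (16, 26))
        assert rb.value_db == pytest.approx(10 * np.log10(0.25), abs=0.15)

    def test_desync_trial_is_negative(self):
        n = 3000
        t = np.arange(n) / FS - 2.0
        amp = np.where(t < 0, 2.0, np.sqrt(2.0))  # agent halves the power
        ep = _epoch(amp * np.sin(2 * np.pi * 20 * t))
        assert b.relative_beta(ep, (16, 26)).value_db < -1.0

    def test_requires_precue_anchor_and_coverage(self):
        with pytest.raises(ValueError):
            b.relative_beta(_sine_epoch(20.0, window=(-1.0, 4.0)), (16, 26))
        ep = _sine_epoch(20.0)
        ep.anchor = "ic"
        with pytest.raises(ValueError):
            b.relative_beta(ep, (16, 26))


class TestTimecourseTable:
    def test_constant_power_flat_across_timepoints(self):
        eps = [
            _sine_epoch(20.0, participant="P01", condition="real",
                        nf_direction="left", trial_index=i)
            for i in range(4)
        ]
        out = b.beta_timecourse_table(eps, (16, 26))
        assert len(out) == 7
        assert out["mean"].max() / out["mean"].min() == pytest.approx(1.0, abs=0.02)

    def test_single_participant_sd_is_null(self):
        eps = [_sine_epoch(20.0, participant="P01", condition="real",
                           nf_direction="left", trial_index=i) for i in range(3)]
        out = b.beta_timecourse_table(eps, (16, 26))
        assert out.sd.isna().all()
        assert (out.n_participants == 1).all()

    def test_mrbd_profile_dips_after_onset(self, ic_epochs):
        go = [ep for ep in ic_epochs if ep.trial_type == "go"]
        for i, ep in enumerate(go):
            ep.participant = "P01"
            ep.condition = "real"
            ep.nf_direction = "left"
        out = b.beta_timecourse_table(go, (14, 31))
        t_min = out.loc[out["mean"].idxmin(), "timepoint_s"]
        assert t_min in (0, 1)   # the desynchronization window


def exact_signed_rank_p(d):
    """Brute-force oracle: enumerate all 2^n sign assignments of the
    absolute-difference ranks; two-sided p as 2*min(tail), capped at 1."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestPairedSignedRank:
    def test_identical_samples_degenerate(self):
        x = np.arange(8.0)
        res = b.paired_signed_rank(x, x)
        assert res.degenerate

    def test_z_sign_matches_shift_direction(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        res = b.paired_signed_rank(x, x + 1.0)   # x below y
        assert res.statistic < 0
        res2 = b.paired_signed_rank(x + 1.0, x)
        assert res2.statistic > 0

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (8, 3),
                                        (9, 4), (10, 5)])
    def test_matches_exact_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n) * 0.8 + 0.5
        res = b.paired_signed_rank(x, y)
        assert res.p_value == pytest.approx(exact_signed_rank_p(x - y),
                                            abs=5e-4)


class TestRtBetaCorrelation:
    def _trials(self, rows):
        return pd.DataFrame(rows, columns=["participant", "condition",
                                           "nf_direction", "rt_s",
                                           "relative_beta"])

    def test_constant_rt_cell_flagged_null(self):
        rows = [("P01", "real", "left", 0.5, x) for x in np.linspace(-3, 1, 8)]
        with pytest.warns(UserWarning, match="null"):
            out = b.rt_beta_correlation(self._trials(rows))
        assert np.isnan(out.r.iloc[0])
        assert not out.valid.iloc[0]

    def test_exact_linear_relation_gives_r_1(self):
        beta = np.linspace(-3, 1, 10)
        rows = [("P01", "real", "left", 0.4 + 0.05 * x, x) for x in beta]
        out = b.rt_beta_correlation(self._trials(rows))
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_planted_cell_has_highest_mean_r(self):
        trials = b.simulate_cohort(seed=1)
        out = b.rt_beta_correlation(trials)
        means = out.groupby(["condition", "nf_direction"]).r.mean()
        assert means.idxmax() == ("real", "left")
        assert means[("real", "left")] > 0.2
        others = means.drop(index=[("real", "left")])
        assert (others.abs() < 0.1).all()


class TestConditionAnova:
    def _corr_df(self, values):
        rows = []
        for pid, cells in values.items():
            for (cond, d), r in cells.items():
                rows.append({"participant": pid, "condition": cond,
                             "nf_direction": d, "r": r})
        return pd.DataFrame(rows)

    def test_flat_cells_give_zero_f(self):
        cells = list(itertools.product(["real", "sham"], ["left", "right"]))
        values = {
            f"P{i}": {c: r for c in cells}
            for i, r in enumerate([0.1, 0.2, -0.1, 0.05, 0.0])
        }
        res, contrasts = condition_anova(self._corr_df(values))
        assert res.statistic == 0.0
        assert res.degenerate
        assert (contrasts.p_tukey.dropna() > 0.05).all()

    def test_df_with_two_participants(self):
        rng = np.random.default_rng(0)
        cells = list(itertools.product(["real", "sham"], ["left", "right"]))
        values = {
            f"P{i}": {c: rng.uniform(-0.3, 0.3) for c in cells}
            for i in range(2)
        }
        res, _ = condition_anova(self._corr_df(values))
        assert res.df == (3, 3)

    def test_planted_effect_detected(self):
        trials = b.simulate_cohort(seed=2)
        corr = b.rt_beta_correlation(trials)
        res, contrasts = condition_anova(corr)
        assert res.df == (3, 48)
        assert res.p_value < 0.001
        sig = contrasts.set_index("contrast").p_tukey
        assert sig["real-left vs real-right"] < 0.05
        assert sig["real-left vs sham-right"] < 0.05

    def test_incomplete_participant_excluded(self):
        trials = b.simulate_cohort(n_participants=6, seed=3)
        corr = b.rt_beta_correlation(trials)
        corr = corr[~((corr.participant == "P01")
                      & (corr.condition == "sham"))]
        with pytest.warns(UserWarning, match="excluded"):
            res, _ = condition_anova(corr)
        assert res.n == 5


class TestSessionTrialTable:
    def test_columns_and_values(self):
        eps = [
            _sine_epoch(20.0, participant="P01", condition="real",
                        nf_direction="left", trial_index=i, trial_type="go",
                        rt_s=0.4)
            for i in range(3)
        ]
        out = session_trial_table(eps, (16, 26))
        assert len(out) == 3
        assert out.relative_beta.abs().max() < 0.5
        assert (out.rt_s == 0.4).all()
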