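"""MUA chain: re-referencing, filtering, epoching, tests, taxonomy, habituation."""

import numpy as np
import pytest
from scipy import stats

from accmirror import mua, synth
from accmirror.venn import VennCounts
from conftest import make_epoch_set


def _rec(data, fs=8000.0, shafts=5, contacts=6):
    geom = synth.ProbeGeometry(shafts, contacts)
    return synth.ContinuousRecording(
        data=np.asarray(data, np.float32), fs_hz=fs, shaft_map=geom.shaft_map
    )


class TestRereference:
    def test_5x6_probe_yields_25_difference_channels(self):
        rec = _rec(np.random.default_rng(0).normal(size=(30, 100)))
        out = mua.pairwise_rereference(rec)
        assert out.n_channels == 25
        assert len(out.meta["parent_contacts"]) == 25

    def test_common_mode_rejection_is_exact(self):
        common = np.sin(np.linspace(0, 10, 500))
        rec = _rec(np.tile(common, (30, 1)))
        out = mua.pairwise_rereference(rec)
        assert np.all(out.data == 0)

    def test_linear_ramp_across_contacts_gives_constant_differences(self):
        data = np.array([[i * 1.0] * 50 for i in range(30)])
        out = mua.pairwise_rereference(_rec(data))
        assert np.allclose(out.data, -1.0)

    def test_single_contact_shaft_rejected(self):
        rec = synth.ContinuousRecording(
            data=np.zeros((1, 10), np.float32), fs_hz=8000.0, shaft_map=[[0]]
        )
        with pytest.raises(ValueError):
            mua.pairwise_rereference(rec)


class TestExtractMua:
    def test_zero_input_zero_output(self):
        assert np.allclose(mua.extract_mua(np.zeros(4000), 8000.0), 0.0)

    def test_50hz_sine_attenuated_vs_3khz_sine(self):
        """Filter-response oracle: the 1 kHz high-pass must crush 50 Hz."""
        fs = 8000.0
        t = np.arange(0, 2.0, 1 / fs)
        out_lo = mua.extract_mua(np.sin(2 * np.pi * 50 * t), fs)
        out_hi = mua.extract_mua(np.sin(2 * np.pi * 3000 * t), fs)
        assert np.mean(out_lo**2) < 0.01 * np.mean(out_hi**2)

    def test_homogeneity_of_degree_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8000)
        a = mua.extract_mua(x, 8000.0)
        b = mua.extract_mua(2 * x, 8000.0)
        assert np.allclose(b, 2 * a, atol=1e-9)

    def test_too_low_fs_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            mua.extract_mua(np.zeros(100), 1500.0)
        with pytest.raises(ValueError):
            mua.extract_mua(np.array([1.0, np.nan]), 8000.0)


class TestEpochZtransform:
    def _schedule(self, onsets):
        import pandas as pd

        trials = pd.DataFrame(
            {
                "trial_index": np.arange(len(onsets)),
                "condition": "High",
                "intensity_code": pd.array([2] * len(onsets), dtype="Int64"),
                "onset_s": onsets,
                "duration_s": 1.0,
            }
        )
        return synth.TrialSchedule("ShockObs", trials)

    def test_reference_window_mean0_sd1_by_construction(self):
        fs = 1000.0
        rng = np.random.default_rng(0)
        sig = 5.0 + rng.normal(0, 2.0, int(20 * fs))
        ep = mua.epoch_and_ztransform(sig, fs, self._schedule([5.0, 12.0]), span=(-3.0, 3.0))
        ref = ep.z[:, :, ep.times < 0]
        assert np.allclose(ref.mean(axis=2), 0.0, atol=1e-9)
        assert np.allclose(ref.std(axis=2), 1.0, atol=1e-9)

    def test_step_of_2sd_reads_as_z2(self):
        fs = 1000.0
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1.0, int(20 * fs))
        sd = noise[: int(5 * fs)].std()
        sig = noise.copy()
        sig[int(5 * fs) :] += 2 * sd
        ep = mua.epoch_and_ztransform(sig, fs, self._schedule([5.0]), span=(-3.0, 3.0))
        post = ep.z[0, 0, (ep.times > 0.1) & (ep.times < 2.9)]
        assert post.mean() == pytest.approx(2.0, abs=0.2)

    def test_trial_near_edge_raises(self):
        fs = 1000.0
        with pytest.raises(ValueError):
            mua.epoch_and_ztransform(np.zeros(int(4 * fs)), fs, self._schedule([1.0]))

    def test_constant_signal_flagged_degenerate_not_divided(self):
        fs = 1000.0
        ep = mua.epoch_and_ztransform(
            np.ones(int(20 * fs)), fs, self._schedule([5.0]), span=(-3.0, 3.0)
        )
        assert ep.degenerate[0, 0]
        assert np.all(np.isfinite(ep.z))


class TestArtifactDetection:
    def test_clean_epochs_unflagged(self):
        ep = make_epoch_set(25, ["High"] * 8, noise_sd=1.0, seed=2)
        assert mua.detect_artifact_trials(ep).sum() == 0

    def test_allchannel_artifact_flags_exactly_that_trial(self):
        ep = make_epoch_set(25, ["High"] * 10, noise_sd=0.5, seed=3)
        ep.z[:, 7, 100] = 50.0
        flags = mua.detect_artifact_trials(ep)
        assert flags[7] and flags.sum() == 1
        assert ep.excluded[7]

    def test_single_channel_artifact_below_fraction_not_flagged(self):
        ep = make_epoch_set(25, ["High"] * 10, noise_sd=0.5, seed=4)
        ep.z[0, 7, 100] = 50.0
        assert mua.detect_artifact_trials(ep, channel_fraction=0.5).sum() == 0

    def test_synth_render_roundtrip_artifact_detected(self):
        """An artifact injected on all contacts is flagged downstream."""
        d = synth.ScheduleDesign("ShockObs", {"Ctrl": 5}, (12.0,), 1.0, 8.0)
        sched = synth.make_schedule(d, 0)
        art_onset = float(sched.onsets[2]) + 0.2
        rec = synth.render_continuous(
            [],
            [],
            duration=sched.session_duration,
            noise=synth.NoiseConfig(
                white_sd=5.0, pink_sd=0.0, artifact_onsets=(art_onset,),
                artifact_amplitude=500.0,
            ),
            seed=5,
        )
        env = mua.extract_mua(mua.pairwise_rereference(rec).data, rec.fs_hz)
        ep = mua.epoch_and_ztransform(env, rec.fs_hz, sched)
        flags = mua.detect_artifact_trials(ep)
        assert flags[2] and flags.sum() == 1


class TestAuc:
    def test_constant_one_over_1s_is_1(self):
        times = np.arange(-2, 3, 0.001) + 0.0005
        z = np.ones_like(times)
        assert mua.auc(z, times, (0.0, 1.0)) == pytest.approx(1.0, abs=2e-3)

    def test_linear_ramp_closed_form(self):
        times = np.arange(-2, 3, 0.001) + 0.0005
        z = np.where((times >= 0) & (times <= 1), times, 0.0)
        assert mua.auc(z, times, (0.0, 1.0)) == pytest.approx(0.5, abs=2e-3)

    def test_linearity(self):
        times = np.arange(-2, 3, 0.01) + 0.005
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=len(times)), rng.normal(size=len(times))
        assert mua.auc(a + b, times, (0, 1)) == pytest.approx(
            mua.auc(a, times, (0, 1)) + mua.auc(b, times, (0, 1))
        )

    def test_window_outside_span_raises(self):
        times = np.arange(-2, 3, 0.01)
        with pytest.raises(ValueError):
            mua.auc(np.ones_like(times), times, (2.5, 3.5))


class TestActivation:
    def test_identical_groups_t0_p05(self):
        x = np.arange(10.0)
        t, p, flag = mua.test_activation(x, x.copy(), paired=False)
        assert t == 0.0 and p == pytest.approx(0.5) and not flag

    def test_identical_paired_vectors_report_no_evidence(self):
        x = np.arange(10.0)
        t, p, flag = mua.test_activation(x, x.copy(), paired=True)
        assert (t, p, flag) == (0.0, 1.0, False)

    def test_constant_unit_difference_closed_form_t(self):
        """Paired diffs ≈ 1 with tiny jitter: t = mean/(sd/√n) is huge."""
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 5)
        resp = base + 1.0 + rng.normal(0, 1e-3, 5)
        t, p, flag = mua.test_activation(base, resp, paired=True)
        d = resp - base
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(t_expected, rel=1e-9)
        assert p < 0.01 and flag

    def test_zero_variance_reports_no_test(self):
        t, p, flag = mua.test_activation(np.ones(5), np.ones(5), paired=True)
        assert (t, p, flag) == (0.0, 1.0, False)

    def test_insufficient_n_raises(self):
        with pytest.raises(ValueError):
            mua.test_activation([1.0], [2.0], paired=True)


class TestClassifyChannels:
    def test_printed_channel_counts_mirror_share(self):
        """Mirror channels = |s∩l| + |s∩c| − |slc| = 137 = 71% of 193."""
        counts = VennCounts.from_intersections(
            social=193, laser=110 + 50, cs=60 + 40, social_laser=110,
            social_cs=60, laser_cs=33 + 10, all_three=33, n_responsive=313,
        )
        assert counts.mirror == 137
        assert round(100 * counts.mirror_share()) == 71

    def test_no_significant_contrasts_all_zero(self):
        import pandas as pd

        rows = [
            (ch, c, 0.0, 0.5, False) for ch in range(10) for c in mua.CONTRASTS
        ]
        stats_df = pd.DataFrame(rows, columns=["channel", "contrast", "t", "p", "flag"])
        counts, flags = mua.classify_channels(stats_df)
        assert counts.mirror == 0 and sum(counts.regions.values()) == 0

    def test_planted_channel_classes_recovered(self):
        """Strong planted social+laser responses make every channel a mirror
        channel (spurious cs flags may promote some to the triple region)."""
        n = 12
        conds = ["High"] * 10 + ["Ctrl"] * 10
        ep_so = make_epoch_set(n, conds, {"High": 4.0}, seed=9)
        ep_l = make_epoch_set(n, conds, {"High": 4.0}, "Laser", response=(0.3, 1.3), seed=10)
        ep_cs = make_epoch_set(n, ["CS"] * 10, {}, "CS", seed=11)
        stats_df = mua.channel_stats({"ShockObs": ep_so, "Laser": ep_l, "CS": ep_cs})
        counts, flags = mua.classify_channels(stats_df)
        assert counts.social_and_laser == n
        assert counts.mirror == n

    def test_venn_arithmetic_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(12)
        s, l, c = (rng.random(200) < 0.5 for _ in range(3))
        counts = VennCounts.from_flags(s, l, c)
        assert counts.mirror == int(np.sum(s & (l | c)))
        assert counts.social_and_laser == int(np.sum(s & l))
        assert sum(counts.regions.values()) == int(np.sum(s | l | c))

    def test_deactivation_scan_near_zero_on_activation_only_data(self):
        conds = ["High"] * 10 + ["Ctrl"] * 10
        ep_so = make_epoch_set(40, conds, {"High": 4.0}, seed=13)
        ep_l = make_epoch_set(40, conds, {"High": 4.0}, "Laser", response=(0.3, 1.3), seed=14)
        ep_cs = make_epoch_set(40, ["CS"] * 10, {"CS": 4.0}, "CS", seed=15)
        stats_df = mua.channel_stats(
            {"ShockObs": ep_so, "Laser": ep_l, "CS": ep_cs}, deactivation=True
        )
        base = stats_df[stats_df["contrast"].isin(mua.RESPONSIVE_CONTRASTS)]
        assert base["flag"].mean() < 0.02


class TestHabituation:
    def test_identical_first_and_last_trials_give_t0(self):
        ep = make_epoch_set(20, ["High"] * 10, {"High": 2.0}, seed=16, decay=1.0)
        # make last 5 exactly equal to first 5
        ep.z[:, 5:, :] = ep.z[:, :5, :]
        eps = {"ShockObs": ep, "Laser": ep, "CS": ep}
        res = mua.habituation_test(eps, {"ShockObs": "High", "Laser": "High", "CS": "High"})
        assert np.allclose(res.per_condition["t"], 0.0)

    def test_planted_habituation_detected_only_where_planted(self):
        eps = {
            "ShockObs": make_epoch_set(40, ["High"] * 10, {"High": 3.0}, seed=17, decay=0.8),
            "Laser": make_epoch_set(40, ["High"] * 10, {"High": 3.0}, "Laser",
                                    response=(0.3, 1.3), seed=18, decay=1.0),
            "CS": make_epoch_set(40, ["CS"] * 10, {"CS": 3.0}, "CS", seed=19, decay=0.8),
        }
        res = mua.habituation_test(eps, {"ShockObs": "High", "Laser": "High", "CS": "CS"})
        byc = res.per_condition.set_index("condition")
        assert byc.loc["ShockObs", "p"] < 0.01
        assert byc.loc["ShockObs", "t"] > 0  # first > last: a decrease
        assert byc.loc["Laser", "p"] > 0.05
        assert res.interaction_p < 0.01

    def test_too_few_trials_raise(self):
        ep = make_epoch_set(5, ["High"] * 8, seed=20)
        with pytest.raises(ValueError):
            mua.habituation_test(
                {"ShockObs": ep, "Laser": ep, "CS": ep},
                {"ShockObs": "High", "Laser": "High", "CS": "High"},
            )


class TestBayesFactor:
    def test_zero_t_large_n_favors_null(self):
        assert mua.bayes_factor_null(0.0, 200) > 1.0

    def test_large_positive_t_favors_alternative(self):
        """Cross-checked against an independent quadrature implementation."""
        bf = mua.bayes_factor_null(5.0, 50)
        assert bf < 1.0
        # independent oracle: trapezoidal integration on a fine grid
        from scipy import stats as ss

        d = np.linspace(1e-6, 5.0, 20000)
        with np.errstate(all="ignore"):
            like = ss.nct.pdf(5.0, 49, d * np.sqrt(50))
        like = np.nan_to_num(like)
        m1 = np.trapezoid(like * 2 * ss.cauchy.pdf(d, scale=0.707), d)
        assert bf == pytest.approx(ss.t.pdf(5.0, 49) / m1, rel=1e-3)

    def test_non_finite_t_rejected(self):
        with pytest.raises(ValueError):
            mua.bayes_factor_null(np.nan, 10)
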