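"""Behavioral scoring, spectrogram statistics, muscimol ANOVA, power arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accmirror import behavior, synth
from accmirror.synth import AudioEnergyTrack, Ethogram


class TestAttention:
    @pytest.mark.parametrize(
        "alpha,score", [(70.0, 2 / 3), (30.0, 1.0), (150.0, 0.0), (90.0, 0.5), (0.0, 1.0), (180.0, 0.0)]
    )
    def test_anchor_and_interpolation_values(self, alpha, score):
        assert behavior.attention_score(alpha) == pytest.approx(score, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            behavior.attention_score(-1.0)
        with pytest.raises(ValueError):
            behavior.attention_score(181.0)

    @given(a=st.floats(0, 180), b=st.floats(0, 180))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing_and_bounded(self, a, b):
        sa, sb = behavior.attention_score(a), behavior.attention_score(b)
        assert 0.0 <= sa <= 1.0
        if a <= b:
            assert sa >= sb


def _etho(bouts):
    return Ethogram(
        intervals=pd.DataFrame(
            [("freezing", s, e) for s, e in bouts], columns=["behavior", "start_s", "stop_s"]
        ),
        head_angle=pd.DataFrame({"time_s": [], "alpha_deg": []}),
    )


class TestFreezing:
    def test_no_freezing_zero(self):
        assert behavior.freezing_percentage(_etho([]), (0, 720)) == 0.0

    def test_full_epoch_bout_100(self):
        assert behavior.freezing_percentage(_etho([(0, 720)]), (0, 720)) == 100.0

    def test_partial_bout_closed_form(self):
        assert behavior.freezing_percentage(_etho([(100, 200)]), (0, 720)) == pytest.approx(
            100 * 100 / 720
        )

    def test_bout_clipped_at_epoch_edges(self):
        assert behavior.freezing_percentage(_etho([(700, 800)]), (0, 720)) == pytest.approx(
            100 * 20 / 720
        )

    def test_invariant_to_splitting_bouts(self):
        whole = behavior.freezing_percentage(_etho([(100, 300)]), (0, 720))
        split = behavior.freezing_percentage(_etho([(100, 180), (180, 300)]), (0, 720))
        assert whole == pytest.approx(split)

    def test_zero_length_epoch_rejected(self):
        with pytest.raises(ValueError):
            behavior.freezing_percentage(_etho([]), (5, 5))

    def test_roundtrip_zero_freezing_fraction(self):
        d = synth.ScheduleDesign("ShockObs", {"High": 3}, (60,), 1.0, 10.0)
        sched = synth.make_schedule(d, 0)
        bd = synth.simulate_behavior(sched, synth.BehaviorParams(freezing_fraction=0.0), 0)
        assert behavior.freezing_percentage(bd.ethogram, (0, 100)) == 0.0


def _track(duration=300.0, dt=0.05, nf=20, base=1.0):
    times = np.arange(0, duration, dt) + dt / 2
    freqs = np.linspace(0, 80_000, nf)
    return AudioEnergyTrack(times, freqs, np.full((nf, len(times)), base))


class TestTrialTriggeredSpectrogram:
    def test_planted_bursts_raise_post_stimulus_energy(self):
        d = synth.ScheduleDesign("ShockObs", {"High": 10}, (20.0,), 1.0, 10.0)
        sched = synth.make_schedule(d, 1)
        bd = synth.simulate_behavior(sched, synth.BehaviorParams(squeak_prob_high=1.0), 1)
        stack = behavior.trial_triggered_spectrogram(bd.audio, sched.onsets_for("High"))
        g = stack.grand_average
        post = g[:, (stack.lags >= 0) & (stack.lags < 1)].mean()
        pre = g[:, (stack.lags >= -2) & (stack.lags < 0)].mean()
        assert post > pre + 3.0

    def test_constant_track_flat_average(self):
        stack = behavior.trial_triggered_spectrogram(_track(), np.array([50.0, 100.0]))
        assert np.allclose(stack.grand_average, 1.0)

    def test_averaging_linearity_over_animal_partition(self):
        tr = _track()
        onsets = np.array([50.0, 100.0, 150.0, 200.0])
        whole = behavior.trial_triggered_spectrogram(tr, onsets).grand_average
        halves = [
            behavior.trial_triggered_spectrogram(tr, onsets[:2]).grand_average,
            behavior.trial_triggered_spectrogram(tr, onsets[2:]).grand_average,
        ]
        assert np.allclose(whole, np.mean(halves, axis=0))

    def test_onset_near_edge_rejected(self):
        with pytest.raises(ValueError):
            behavior.trial_triggered_spectrogram(_track(duration=10.0), np.array([9.5]))


class TestPixelTtest:
    def test_identical_conditions_empty_mask(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 8, 10))
        mask, p = behavior.pixel_ttest(a, a.copy())
        assert mask.sum() == 0

    def test_planted_block_detected_with_calibrated_false_positives(self):
        rng = np.random.default_rng(1)
        n_animals, nf, nt = 17, 30, 60
        a = rng.normal(0, 1, (n_animals, nf, nt))
        b = rng.normal(0, 1, (n_animals, nf, nt))
        a[:, 5:10, 20:30] += 4.0  # planted block
        mask, p = behavior.pixel_ttest(a, b)
        assert mask[5:10, 20:30].all()
        outside = mask.copy()
        outside[5:10, 20:30] = False
        n_out = nf * nt - 50
        assert outside.sum() <= n_out * 0.001 + 3 * np.sqrt(n_out * 0.001)

    def test_fewer_than_two_animals_rejected(self):
        with pytest.raises(ValueError):
            behavior.pixel_ttest(np.zeros((1, 4, 4)), np.zeros((1, 4, 4)))


class TestInstantaneousRate:
    def test_regular_train_constant_rate(self):
        t, r = behavior.instantaneous_rate(np.arange(0, 1.0, 0.1))
        assert np.allclose(r, 10.0)

    def test_isi_arithmetic(self):
        t, r = behavior.instantaneous_rate(np.array([0.0, 0.1, 0.6]))
        assert np.allclose(r, [10.0, 2.0])

    def test_duplicate_or_single_spikes_rejected(self):
        with pytest.raises(ValueError):
            behavior.instantaneous_rate(np.array([1.0]))
        with pytest.raises(ValueError):
            behavior.instantaneous_rate(np.array([1.0, 1.0, 2.0]))


class TestSpikeTriggeredSpectrogram:
    def test_spikes_locked_to_bursts_show_broadband_signature(self):
        rng = np.random.default_rng(2)
        tr = _track(duration=600.0)
        burst_times = np.arange(60.0, 560.0, 25.0)
        for b in burst_times:
            m = (tr.times >= b) & (tr.times < b + 0.5)
            tr.energy[:, m] += 10.0
        # high firing exactly during bursts, sparse elsewhere
        spikes = np.sort(
            np.concatenate(
                [b + np.sort(rng.uniform(0, 0.5, 30)) for b in burst_times]
                + [np.sort(rng.uniform(0, 600, 300))]
            )
        )
        t, r = behavior.instantaneous_rate(spikes)
        stack = behavior.spike_triggered_spectrogram(t, r, tr, top_pct=5)
        avg = stack.grand_average
        center = avg[:, np.abs(stack.lags) < 0.5].mean()
        edges = avg[:, np.abs(stack.lags) > 4.0].mean()
        assert center > edges + 1.0

    def test_independent_spikes_null_centered(self):
        rng = np.random.default_rng(3)
        tr = _track(duration=600.0)
        tr.energy += rng.normal(0, 1, tr.energy.shape) ** 2
        spikes = np.sort(rng.uniform(0, 600, 2000))
        t, r = behavior.instantaneous_rate(spikes)
        stack = behavior.spike_triggered_spectrogram(t, r, tr, top_pct=5)
        vals = stack.grand_average.ravel()
        se = tr.energy.std() / np.sqrt(stack.stack.shape[0])
        assert abs(vals.mean()) < 3 * se

    def test_all_moments_on_stationary_track_exactly_zero(self):
        tr = _track(duration=100.0)
        spikes = np.arange(10.0, 90.0, 0.1)
        t, r = behavior.instantaneous_rate(spikes)
        stack = behavior.spike_triggered_spectrogram(t, r, tr, top_pct=100)
        assert np.allclose(stack.grand_average, 0.0, atol=1e-12)

    def test_no_qualifying_moments_rejected(self):
        tr = _track(duration=5.0)
        with pytest.raises(ValueError):
            behavior.spike_triggered_spectrogram(
                np.array([2.5]), np.array([10.0]), tr, half_window_s=10.0
            )


class TestMuscimolAnova:
    def test_all_equal_freezing_all_zero_statistics(self):
        rows = []
        for grp, n in (("muscimol", 6), ("saline", 8)):
            for i in range(n):
                for sess in ("Shock", "CS"):
                    for ep in ("baseline", "test"):
                        rows.append((f"{grp}{i}", grp, sess, ep, 30.0))
        tab = pd.DataFrame(rows, columns=["animal_id", "group", "session", "epoch", "freezing"])
        res = behavior.muscimol_anova(tab)
        assert np.allclose(res.anova["F"], 0.0)
        assert res.interaction_F == 0.0

    def test_planted_social_deficit_detected_in_90pct_of_replicates(self):
        hits = 0
        n_rep = 60
        for i in range(n_rep):
            tab = behavior.simulate_freezing_table(seed=1000 + i)
            res = behavior.muscimol_anova(tab)
            hits += res.interaction_p < 0.05
        assert hits / n_rep >= 0.9

    def test_shuffled_groups_nominal_type1_rate(self):
        rng = np.random.default_rng(4)
        rej = 0
        n_rep = 200
        for i in range(n_rep):
            tab = behavior.simulate_freezing_table(
                muscimol_shock_reduction=0.0, seed=2000 + i
            )
            ids = tab["animal_id"].unique()
            perm = dict(zip(ids, rng.permutation([g for g in tab.groupby("animal_id")["group"].first()])))
            tab["group"] = tab["animal_id"].map(perm)
            res = behavior.muscimol_anova(tab)
            rej += res.interaction_p < 0.05
        ci = 1.96 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) < ci + 0.02

    def test_collapsed_design_reduces_to_paired_t(self):
        """With the session factor collapsed, group×epoch F = t² of the
        two-sample t on per-animal epoch differences."""
        tab = behavior.simulate_freezing_table(seed=5)
        res = behavior.muscimol_anova(tab)
        wide = tab.pivot_table(index=["animal_id", "group"], columns=["session", "epoch"], values="freezing")
        diff = (
            (wide[("Shock", "test")] + wide[("CS", "test")]) / 2
            - (wide[("Shock", "baseline")] + wide[("CS", "baseline")]) / 2
        )
        g = wide.index.get_level_values("group")
        t, dfree = behavior._pooled_two_sample_t(
            diff[g == "muscimol"].to_numpy(), diff[g == "saline"].to_numpy()
        )
        F = res.anova.set_index("effect").loc["group*epoch", "F"]
        assert F == pytest.approx(t**2, rel=1e-9)

    def test_incomplete_table_rejected(self):
        tab = behavior.simulate_freezing_table(seed=6)
        with pytest.raises(ValueError):
            behavior.muscimol_anova(tab.iloc[:-1])


class TestPowerArithmetic:
    def test_effect_size_worked_example(self):
        assert round(behavior.cohens_d(33, 0, 27), 2) == 1.22

    def test_mirror_yield_worked_example(self):
        assert behavior.mirror_yield(2, 30, 0.0) == 15

    def test_huge_effect_size_gives_minimum_n(self):
        assert behavior.sample_size(100.0) == 2

    def test_sample_size_matches_normal_approximation(self):
        from scipy import stats as ss

        d = 1.22
        za, zb = ss.norm.ppf(0.95), ss.norm.ppf(0.8)
        assert behavior.sample_size(d, 0.05, 0.8, one_sided=True) == int(
            np.ceil(2 * ((za + zb) / d) ** 2)
        )

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            behavior.cohens_d(1, 0, 0)
        with pytest.raises(ValueError):
            behavior.sample_size(0.5, alpha=1.5)
        with pytest.raises(ValueError):
            behavior.mirror_yield(0, 30)
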