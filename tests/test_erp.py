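"""ERP preprocessing contracts and the cluster permutation machinery."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from facesd import behavior, erp, synthdata
from facesd.erp import (
    baseline_correct,
    cluster_effect_size,
    cluster_permutation_test,
    condition_erps,
    lowpass_butterworth,
    rereference,
    spatial_adjacency,
)
from facesd.validation import small_erp_model


class TestRereference:
    def test_common_average_sums_to_zero_over_scalp(self, small_epochs):
        out = rereference(small_epochs, "common_average")
        scalp = out.scalp_picks
        assert np.allclose(out.data[scalp].sum(axis=0), 0.0, atol=1e-9)

    def test_linked_mastoid_idempotent(self, small_epochs):
        once = rereference(small_epochs, "linked_mastoid")
        twice = rereference(once, "linked_mastoid")
        assert np.allclose(once.data, twice.data)

    def test_channel_differences_invariant(self, small_epochs):
        a = rereference(small_epochs, "common_average")
        b = rereference(small_epochs, "linked_mastoid")
        d_a = a.data[0] - a.data[1]
        d_b = b.data[0] - b.data[1]
        assert np.allclose(d_a, d_b, atol=1e-9)

    def test_missing_mastoids_rejected(self, small_epochs):
        idx = small_epochs.scalp_picks
        stripped = replace(
            small_epochs,
            data=small_epochs.data[idx],
            channel_names=[small_epochs.channel_names[i] for i in idx],
            positions=small_epochs.positions[idx],
        )
        with pytest.raises(ValueError, match="mastoid"):
            rereference(stripped, "linked_mastoid")


def _sine_epochs(freq, sfreq=512.0, amp=1.0, n_sec=4.0):
    t = np.arange(int(n_sec * sfreq)) / sfreq
    data = (amp * np.sin(2 * np.pi * freq * t))[None, :, None]
    times = (t - 0.5) * 1000.0
    trials = pd.DataFrame({"participant": [1]})
    return erp.Epochs(
        data=data, channel_names=["Cz"], positions=np.zeros((1, 2)),
        sfreq=sfreq, times=times, trials=trials,
    )


class TestButterworth:
    def test_dc_gain_unity(self):
        ep = _sine_epochs(5.0)
        ep = replace(ep, data=np.full_like(ep.data, 3.7))
        out = lowpass_butterworth(ep)
        assert np.allclose(out.data, 3.7, atol=1e-9)

    @pytest.mark.parametrize("freq", [5.0, 100.0])
    def test_attenuation_matches_analytic_two_pass_response(self, freq):
        """Forward-backward filtering squares the Butterworth magnitude:
        |H(f)|^2 = 1 / (1 + (f/fc)^(2*order))."""
        ep = _sine_epochs(freq)
        out = lowpass_butterworth(ep, cutoff=30.0, order=4)
        mid = slice(len(ep.times) // 4, 3 * len(ep.times) // 4)
        gain = out.data[0, mid, 0].std() / ep.data[0, mid, 0].std()
        expected = 1.0 / (1.0 + (freq / 30.0) ** 8)
        assert gain == pytest.approx(expected, abs=0.005)
        if freq == 5.0:
            assert 1.0 - gain < 0.01  # passband loss under 1%
        else:
            assert gain < 0.01  # stopband attenuation over 99%

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_butterworth(_sine_epochs(5.0, sfreq=100.0), cutoff=60.0)


class TestBaseline:
    def test_baseline_window_mean_exactly_zero(self, small_epochs):
        out = baseline_correct(small_epochs)
        mask = out.time_mask((-200.0, 0.0))
        base = out.data[:, mask, :].mean(axis=1)
        assert np.allclose(base, 0.0, atol=1e-12)

    def test_idempotent(self, small_epochs):
        once = baseline_correct(small_epochs)
        twice = baseline_correct(once)
        assert np.allclose(once.data, twice.data)

    def test_constant_signal_zeroed(self, small_epochs):
        const = replace(small_epochs, data=np.full_like(small_epochs.data, 5.0))
        out = baseline_correct(const)
        assert np.allclose(out.data, 0.0)

    def test_window_outside_epoch_rejected(self, small_epochs):
        with pytest.raises(ValueError, match="outside"):
            baseline_correct(small_epochs, (-500.0, -300.0))


class TestConditionAverages:
    def test_identical_trials_average_to_single_trial(self, small_epochs):
        ep = replace(
            small_epochs,
            data=np.repeat(small_epochs.data[:, :, :1], small_epochs.data.shape[2],
                           axis=2),
        )
        avgs = condition_erps(ep, by=("bin",), keep=list(behavior.BIN_ORDER))
        for j in range(len(avgs.conditions)):
            assert np.allclose(avgs.data[0, j], ep.data[:, :, 0])

    def test_counts_sum_to_retained_trials(self, small_epochs):
        avgs = condition_erps(small_epochs, by=("bin",),
                              keep=list(behavior.BIN_ORDER))
        kept = small_epochs.trials["bin"].isin(behavior.BIN_ORDER).sum()
        assert avgs.counts["n_trials"].sum() == kept

    def test_empty_condition_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            condition_erps(small_epochs, by=("bin",), keep=["nonexistent"])


class TestAdjacency:
    def test_graph_properties(self):
        pos = synthdata.montage_positions(synthdata.SCALP_CHANNELS)
        adj = spatial_adjacency(pos)
        assert adj.shape == (31, 31)
        assert not adj.diagonal().any()
        assert (adj == adj.T).all()

    def test_disconnected_graph_rejected(self):
        pos = np.array([[0.0, 0.0], [5.0, 5.0]])
        with pytest.raises(ValueError, match="not connected"):
            spatial_adjacency(pos)


def exhaustive_signflip_p(diffs, cluster_alpha=0.05):
    """Independent oracle: exact sign-flip null for one channel by full
    enumeration (2^n assignments), using scipy primitives only."""
    from itertools import product

    from scipy import ndimage, stats

    n = diffs.shape[0]
    thr = stats.t.ppf(1 - cluster_alpha / 2, n - 1)

    def max_stat(d):
        t = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(n))
        best = 0.0
        for sign in (1, -1):
            lab, k = ndimage.label(sign * t > thr)
            for i in range(1, k + 1):
                best = max(best, abs(t[lab == i].sum()))
        return best

    obs = max_stat(diffs)
    null = [
        max_stat(diffs * np.array(s)[:, None])
        for s in product([1, -1], repeat=n)
    ]
    return obs, float(np.mean([v >= obs for v in null]))


class TestClusterTest:
    def test_identical_conditions_give_no_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 2, 20))
        res = cluster_permutation_test(
            a, a.copy(), adjacency=np.array([[False, True], [True, False]]),
            n_perm=100, seed=1, compute_bf=False,
        )
        assert res == []

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """n=5 participants, one channel: the Monte Carlo p of the largest
        cluster must match full 2^5 sign-flip enumeration within binomial
        error."""
        rng = np.random.default_rng(4)
        diffs = rng.normal(0.8, 1.0, size=(5, 12))
        obs, p_exact = exhaustive_signflip_p(diffs)
        assert p_exact < 1.0  # the fixture produces a cluster

        zeros = np.zeros_like(diffs)
        n_perm = 4000
        res = cluster_permutation_test(
            diffs, zeros, n_perm=n_perm, seed=5, compute_bf=False
        )
        p_mc = min(c.p for c in res)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < 3 * se + 2 / n_perm

    def test_injected_effect_detected_in_correct_window(self):
        """A +1.5 uV bump at 450-550 ms across participants yields the
        smallest-p positive cluster overlapping that window."""
        rng = np.random.default_rng(6)
        n_subj, n_t = 14, 128
        times = np.linspace(0, 1000, n_t)
        bump = 1.5 * np.exp(-((times - 500.0) ** 2) / (2 * 40.0**2))
        a = rng.normal(0, 1.0, size=(n_subj, n_t)) + bump
        b = rng.normal(0, 1.0, size=(n_subj, n_t))
        res = cluster_permutation_test(a, b, times=times, n_perm=1000, seed=7,
                                       compute_bf=False)
        best = res[0]
        assert best.p < 0.05
        assert best.polarity == "positive"
        lo, hi = best.window_ms
        assert lo <= 550 and hi >= 450

    def test_mismatched_participants_rejected(self):
        a = np.zeros((6, 10))
        b = np.zeros((5, 10))
        with pytest.raises(ValueError, match="identical shapes"):
            cluster_permutation_test(a, b, n_perm=10)

    def test_too_few_participants_rejected(self):
        a = np.zeros((3, 10))
        with pytest.raises(ValueError, match="at least 5"):
            cluster_permutation_test(a, a, n_perm=10)

    def test_spatial_adjacency_merges_channels(self):
        """With both channels suprathreshold and adjacent, one cluster spans
        them; with no adjacency they stay separate."""
        rng = np.random.default_rng(8)
        base = rng.normal(2.0, 0.5, size=(10, 1, 6))
        d = np.concatenate([base, base], axis=1)
        adj = np.array([[False, True], [True, False]])
        res = cluster_permutation_test(d, np.zeros_like(d), adjacency=adj,
                                       n_perm=50, seed=9, compute_bf=False)
        assert len(res) == 1
        assert len({c for c, _ in res[0].members}) == 2
        no_adj = np.array([[False, False], [False, False]])
        res2 = cluster_permutation_test(d, np.zeros_like(d), adjacency=no_adj,
                                        n_perm=50, seed=9, compute_bf=False)
        assert len(res2) == 2


class TestEffectSize:
    def test_hand_computed_value(self):
        assert cluster_effect_size([1.0, 2.0, 3.0]) == pytest.approx(2.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(cluster_effect_size([2.0, 2.0, 2.0]))

    def test_sign_matches_direction(self):
        assert cluster_effect_size([-1.0, -2.0, -3.0]) < 0


class TestRoiPipeline:
    @pytest.fixture(scope="class")
    def avgs(self):
        from facesd import pipeline
        from facesd.config import RunConfig
        from facesd.synthdata import DesignSpec

        cfg = RunConfig(
            design=DesignSpec(n_participants=20, n_blocks=6),
            erp_model=small_erp_model(),
            seed=77,
        )
        trials = pipeline.simulate_trials(cfg)
        return pipeline.simulate_condition_averages(cfg, trials)

    def test_lpp_far_contrast_detected_and_localized(self, avgs):
        avgs_bin, _ = avgs
        res = erp.roi_cluster_tests(avgs_bin, None, n_perm=500, seed=1)
        far = res[("LPP", "far_vs_middle")]
        assert far and far[0].p < 0.05 and far[0].polarity == "positive"
        lo, hi = far[0].window_ms
        assert lo <= 600 and hi >= 400
        close = res[("LPP", "close_vs_middle")]
        assert close and close[0].polarity == "negative"

    def test_roi_average_mode_agrees_qualitatively(self, avgs):
        avgs_bin, _ = avgs
        res = erp.roi_cluster_tests(avgs_bin, None, n_perm=500, seed=2,
                                    roi_mode="average")
        far = res[("LPP", "far_vs_middle")]
        assert far and far[0].p < 0.05

    def test_exploratory_windows_partition_epoch(self):
        w = erp.EXPLORATORY_WINDOWS
        assert w[0][0] == 0.0 and w[-1][1] == 1200.0
        for (a, b), (c, d) in zip(w[:-1], w[1:]):
            assert b == c
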