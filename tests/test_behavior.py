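"""Exclusions, bias statistic, bootstrap, and aligned-rank-transform ANOVA."""

import warnings

import numpy as np
import pandas as pd
import pytest

from facesd import behavior
from facesd.behavior import (
    add_derived_columns,
    anova_bf,
    art_anova,
    bias_measure,
    bootstrap_ci,
    filter_trials,
    within_anova,
)


def make_table(deltas, errors, participant=1, visibility="low", rt=2.0):
    """Build a minimal derived trial table from signed distances and errors."""
    face2 = np.full(len(deltas), 70)
    face1 = (face2 + np.asarray(deltas)) % 141
    response = (face2 + np.asarray(errors)) % 141
    df = pd.DataFrame(
        {
            "participant": participant,
            "block": 1,
            "trial": np.arange(len(deltas)) + 1,
            "visibility": visibility,
            "face1": face1,
            "face2": face2,
            "response": response,
            "rt": rt,
        }
    )
    return add_derived_columns(df)


class TestFilter:
    def test_rt_rule_strict(self):
        t = make_table([10] * 5, [0] * 5)
        t["rt"] = [3.0, 16.0, 2.0, 15.0, 2.0]  # 15.0 is not "more than 15 s"
        out, rep = filter_trials(t)
        assert rep["per_reason"]["rt_gt_15s"]["n"] == 1
        assert out["excluded"].sum() == 1
        assert out.loc[out["excluded"], "exclusion_reason"].iloc[0] == "rt_gt_15s"

    def test_error_rule_strict_at_60(self):
        t = make_table([10, 10], [61, 60])
        out, _ = filter_trials(t)
        assert out["excluded"].tolist() == [True, False]

    def test_delta_rule_at_70(self):
        t = make_table([70, 69, -70, 0], [0, 0, 0, 0])
        out, _ = filter_trials(t)
        assert out["excluded"].tolist() == [True, False, True, True]
        assert out["exclusion_reason"].tolist() == [
            "abs_delta_ge_70", "", "abs_delta_ge_70", "delta_eq_0",
        ]

    def test_idempotent_and_preserves_rows(self):
        t = make_table([10, 70, 5], [0, 0, 61])
        once, rep1 = filter_trials(t)
        twice, rep2 = filter_trials(once)
        assert len(once) == 3
        pd.testing.assert_frame_equal(once, twice)
        assert rep1 == rep2

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="rt"):
            filter_trials(pd.DataFrame({"error": [1], "delta": [1]}))


class TestBiasMeasure:
    def test_pure_attraction_positive(self):
        t = make_table([5, 6, 7, -5, -6, -7], [2, 3, 4, -2, -3, -4])
        m = bias_measure(filter_trials(t)[0])
        assert m["m"].iloc[0] == pytest.approx(6.0)  # 3 - (-3)

    def test_pure_repulsion_negative(self):
        t = make_table([5, 6, -5, -6], [-2, -2, 2, 2])
        m = bias_measure(filter_trials(t)[0])
        assert m["m"].iloc[0] == pytest.approx(-4.0)

    def test_symmetric_errors_give_zero(self):
        t = make_table([5, 6, 7, -5, -6, -7], [-1, 0, 1, -1, 0, 1])
        m = bias_measure(filter_trials(t)[0])
        assert m["m"].iloc[0] == pytest.approx(0.0)

    def test_sign_convention_flip(self):
        t = make_table([5, -5], [2, -2])
        a = bias_measure(filter_trials(t)[0])
        b = bias_measure(filter_trials(t)[0], sign_convention="ccw_minus_cw")
        assert a["m"].iloc[0] == -b["m"].iloc[0] != 0

    def test_shift_invariance(self):
        """Adding a constant to every error leaves the CW-CCW difference
        unchanged."""
        base = make_table([5, 6, 7, -5, -6, -7], [2, 5, 3, -4, -1, -2])
        shifted = make_table([5, 6, 7, -5, -6, -7], [5, 8, 6, -1, 2, 1])
        ma = bias_measure(filter_trials(base)[0])["m"].iloc[0]
        mb = bias_measure(filter_trials(shifted)[0])["m"].iloc[0]
        assert ma == pytest.approx(mb)

    def test_reflection_invariance(self):
        """Mirroring the wheel (delta -> -delta, error -> -error) leaves m
        unchanged: attraction toward the inducer does not depend on which
        direction is called clockwise."""
        t = make_table([5, 6, 7, -5, -6, -7], [2, 5, 3, -4, -1, -2])
        r = make_table([-5, -6, -7, 5, 6, 7], [-2, -5, -3, 4, 1, 2])
        ma = bias_measure(filter_trials(t)[0])["m"].iloc[0]
        mb = bias_measure(filter_trials(r)[0])["m"].iloc[0]
        assert ma == pytest.approx(mb)

    def test_one_sided_cell_undefined(self):
        t = make_table([5, 6], [1, 2])  # no counterclockwise trials
        with pytest.warns(UserWarning, match="lack clockwise"):
            m = bias_measure(filter_trials(t)[0])
        assert np.isnan(m["m"].iloc[0])
        assert m["n_ccw"].iloc[0] == 0


class TestBootstrap:
    def test_degenerate_constant_values(self):
        mean, lo, hi = bootstrap_ci([3.0] * 10, n_iter=200, seed=0)
        assert mean == lo == hi == 3.0

    def test_determinism(self):
        vals = np.random.default_rng(0).normal(size=28)
        a = bootstrap_ci(vals, seed=7)
        b = bootstrap_ci(vals, seed=7)
        assert a == b

    def test_interval_brackets_mean_for_wellbehaved_sample(self):
        vals = np.random.default_rng(1).normal(size=100)
        mean, lo, hi = bootstrap_ci(vals, seed=2)
        assert lo < mean < hi

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0])


class TestWithinAnova:
    def test_matches_pingouin_two_way(self):
        import pingouin as pg

        rng = np.random.default_rng(3)
        idx = pd.MultiIndex.from_product(
            [range(10), ["a", "b"], ["x", "y", "z"]],
            names=["participant", "f1", "f2"],
        )
        df = pd.DataFrame({"y": rng.normal(size=60)}, index=idx).reset_index()
        mine = within_anova(df, "y", ["f1", "f2"], "participant")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.rm_anova(
                data=df, dv="y", within=["f1", "f2"], subject="participant",
                detailed=True,
            )
        for eff, src in [("f1", "f1"), ("f2", "f2"), ("f1 * f2", "f1 * f2")]:
            row = mine[mine["effect"] == eff].iloc[0]
            r = ref[ref["Source"] == src].iloc[0]
            assert row["F"] == pytest.approx(r["F"], rel=1e-8)
            assert (row["df1"], row["df2"]) == (r["ddof1"], r["ddof2"])
            assert row["p"] == pytest.approx(r["p_unc"], rel=1e-8)

    def test_incomplete_design_rejected(self):
        df = pd.DataFrame(
            {"participant": [1, 1, 2], "f": ["a", "b", "a"], "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="incomplete"):
            within_anova(df, "y", ["f"], "participant")


class TestArtAnova:
    def _toy(self, effect_on="f1", noise=0.0, n=6, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            for i, a in enumerate(["a1", "a2"]):
                for j, b in enumerate(["b1", "b2"]):
                    y = rng.normal(0, noise) if noise else 0.0
                    if effect_on == "f1":
                        y += 10.0 * i
                    elif effect_on == "interaction":
                        y += 10.0 * (i == j)
                    rows.append({"participant": s, "f1": a, "f2": b, "y": y})
        return pd.DataFrame(rows)

    def test_pure_main_effect_separates_perfectly(self):
        df = self._toy("f1", noise=0.05, n=10)
        out = art_anova(df, "y", ["f1", "f2"], "participant")
        f1 = out[out["effect"] == "f1"].iloc[0]
        others = out[out["effect"] != "f1"]
        assert f1["p"] < 1e-3
        assert f1["p"] < others["p"].min()
        assert (others["p"] > 0.05).all()

    def test_interaction_only(self):
        df = self._toy("interaction", noise=0.05, n=10)
        out = art_anova(df, "y", ["f1", "f2"], "participant")
        inter = out[out["effect"] == "f1 * f2"].iloc[0]
        mains = out[~out["effect"].str.contains("\\*")]
        assert inter["p"] < 1e-3
        assert (mains["p"] > 0.05).all()

    def test_constant_responses_degenerate(self):
        df = self._toy("none", noise=0.0)
        df["y"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            art_anova(df, "y", ["f1", "f2"], "participant")

    def test_three_factor_design_runs(self):
        rng = np.random.default_rng(5)
        idx = pd.MultiIndex.from_product(
            [range(8), ["a", "b"], ["x", "y"], ["p", "q", "r"]],
            names=["participant", "f1", "f2", "f3"],
        )
        df = pd.DataFrame({"y": rng.normal(size=8 * 12)}, index=idx).reset_index()
        out = art_anova(df, "y", ["f1", "f2", "f3"], "participant")
        assert len(out) == 7  # 3 mains + 3 two-way + 1 three-way
        assert out["p"].between(0, 1).all()


class TestAnovaBF:
    def _cells(self, effect_size, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(28):
            base = rng.normal(0, 1)
            for v in ["low", "high"]:
                for k, b in enumerate(["close", "middle", "far"]):
                    rows.append(
                        {
                            "participant": s,
                            "visibility": v,
                            "bin": b,
                            "m": base + effect_size * k + rng.normal(0, 1),
                        }
                    )
        return pd.DataFrame(rows)

    def test_strong_effect_supported(self):
        bf = anova_bf(self._cells(2.0), "m", ["visibility", "bin"],
                      "participant", "bin")
        assert bf > 3.0

    def test_null_effect_disfavored(self):
        bf = anova_bf(self._cells(0.0), "m", ["visibility", "bin"],
                      "participant", "bin")
        assert bf < 1.0

    def test_interaction_bf_computable(self):
        bf = anova_bf(self._cells(1.0), "m", ["visibility", "bin"],
                      "participant", "visibility * bin")
        assert np.isfinite(bf) and bf > 0


class TestPipelineContract:
    def test_attractive_generator_gives_positive_group_bias(self):
        import facesd

        trials = facesd.generate_trials(facesd.DesignSpec(n_participants=8, seed=2))
        model = facesd.ResponseModel(
            bin_pulls={"close": 2.0, "middle": 2.0, "far": 2.0}, participant_sd=0.0
        )
        trials = facesd.simulate_responses(trials, model, seed=3)
        bias = bias_measure(filter_trials(trials)[0])
        assert bias.dropna(subset=["m"])["m"].mean() > 0

    def test_repulsive_generator_gives_negative_group_bias(self):
        import facesd

        trials = facesd.generate_trials(facesd.DesignSpec(n_participants=8, seed=2))
        model = facesd.ResponseModel(
            bin_pulls={"close": -2.0, "middle": -2.0, "far": -2.0},
            participant_sd=0.0,
        )
        trials = facesd.simulate_responses(trials, model, seed=3)
        bias = bias_measure(filter_trials(trials)[0])
        assert bias.dropna(subset=["m"])["m"].mean() < 0
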