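"""Split-plot ANOVA engine checked against pingouin and its own symmetries."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from grapholearn.mixed_anova import MixedAnova, factorial_effects


def simulate_2x2_mixed(rng, n1=8, n2=10, effects=None):
    eff = {"condition": 0.0, "group": 0.0, "condition:group": 0.0, **(effects or {})}
    rows = []
    for i in range(n1 + n2):
        grp = "blind" if i < n1 else "sighted"
        g = 1.0 if grp == "blind" else -1.0
        u = rng.normal(0, 1.0)
        for cond, c in (("writing", 1.0), ("no-writing", -1.0)):
            y = (
                u
                + eff["condition"] * c
                + eff["group"] * g
                + eff["condition:group"] * c * g
                + rng.normal(0, 1.0)
            )
            rows.append(
                {"participant": f"p{i:02d}", "group": grp, "condition": cond, "y": y}
            )
    return pd.DataFrame(rows)


def simulate_2x2x2(rng, n1=6, n2=8):
    rows = []
    for i in range(n1 + n2):
        grp = "blind" if i < n1 else "sighted"
        u = rng.normal(0, 1.0)
        for cond in ("writing", "no-writing"):
            for timing in ("immediate", "delayed"):
                rows.append(
                    {
                        "participant": f"p{i:02d}",
                        "group": grp,
                        "condition": cond,
                        "timing": timing,
                        "y": u + rng.normal(0, 1.0),
                    }
                )
    return pd.DataFrame(rows)


class TestAgainstPingouin:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_2x2_mixed_matches_reference(self, seed):
        # balanced groups: the unweighted (Type III) and classical sums of
        # squares coincide, so every effect must match the reference exactly
        rng = np.random.default_rng(seed)
        df = simulate_2x2_mixed(
            rng, n1=9, n2=9, effects={"condition": 0.4, "condition:group": 0.3}
        )
        ours = MixedAnova(df, dv="y", within=["condition"], between="group").fit()
        ref = pg.mixed_anova(
            df, dv="y", within="condition", between="group", subject="participant"
        )
        assert ours.effect("condition")["F"] == pytest.approx(
            float(ref.loc[ref["Source"] == "condition", "F"].iloc[0]), rel=1e-6
        )
        assert ours.effect("group")["F"] == pytest.approx(
            float(ref.loc[ref["Source"] == "group", "F"].iloc[0]), rel=1e-6
        )
        assert ours.effect("condition:group")["F"] == pytest.approx(
            float(ref.loc[ref["Source"] == "Interaction", "F"].iloc[0]), rel=1e-6
        )

    def test_unbalanced_groups_match_reference_on_between_effects(self):
        # with unequal group sizes the group and interaction tests still agree
        # with the reference implementation (the within main effect differs by
        # design: this engine uses unweighted Type-III means)
        rng = np.random.default_rng(12)
        df = simulate_2x2_mixed(rng, n1=8, n2=12)
        ours = MixedAnova(df, dv="y", within=["condition"], between="group").fit()
        ref = pg.mixed_anova(
            df, dv="y", within="condition", between="group", subject="participant"
        )
        assert ours.effect("group")["F"] == pytest.approx(
            float(ref.loc[ref["Source"] == "group", "F"].iloc[0]), rel=1e-6
        )
        assert ours.effect("condition:group")["F"] == pytest.approx(
            float(ref.loc[ref["Source"] == "Interaction", "F"].iloc[0]), rel=1e-6
        )

    def test_three_way_reduces_to_collapsed_two_way(self):
        # the timing main effect and timing x group interaction of the 2x2x2
        # equal the 2x2 mixed ANOVA on condition-averaged data
        rng = np.random.default_rng(7)
        df = simulate_2x2x2(rng)
        full = MixedAnova(
            df, dv="y", within=["condition", "timing"], between="group"
        ).fit()
        collapsed = (
            df.groupby(["participant", "group", "timing"], as_index=False)["y"].mean()
        )
        two = MixedAnova(collapsed, dv="y", within=["timing"], between="group").fit()
        assert full.effect("timing")["F"] == pytest.approx(two.effect("timing")["F"], rel=1e-9)
        assert full.effect("timing:group")["F"] == pytest.approx(
            two.effect("timing:group")["F"], rel=1e-9
        )

    def test_three_way_interaction_via_difference_scores(self):
        # condition x timing x group equals the timing x group interaction of
        # the per-participant condition-difference scores
        rng = np.random.default_rng(8)
        df = simulate_2x2x2(rng)
        full = MixedAnova(df, dv="y", within=["condition", "timing"], between="group").fit()
        wide = df.pivot_table(
            index=["participant", "group", "timing"], columns="condition", values="y"
        ).reset_index()
        wide["diff"] = (wide["no-writing"] - wide["writing"]) / 2.0
        two = MixedAnova(wide, dv="diff", within=["timing"], between="group").fit()
        assert full.effect("condition:timing:group")["F"] == pytest.approx(
            two.effect("timing:group")["F"], rel=1e-9
        )


class TestSymmetries:
    def test_location_shift_changes_only_intercept(self):
        rng = np.random.default_rng(3)
        df = simulate_2x2_mixed(rng)
        a = MixedAnova(df, dv="y", within=["condition"], between="group").fit(
            include_intercept=True
        )
        df2 = df.assign(y=df["y"] + 5.0)
        b = MixedAnova(df2, dv="y", within=["condition"], between="group").fit(
            include_intercept=True
        )
        for eff in ("condition", "group", "condition:group"):
            assert a.effect(eff)["F"] == pytest.approx(b.effect(eff)["F"], rel=1e-9)
        assert a.effect("intercept")["F"] != pytest.approx(b.effect("intercept")["F"])

    def test_participant_relabelling_invariance(self):
        rng = np.random.default_rng(4)
        df = simulate_2x2_mixed(rng)
        relabel = {p: f"q{int(p[1:]) + 50}" for p in df["participant"].unique()}
        df2 = df.assign(participant=df["participant"].map(relabel))
        a = MixedAnova(df, dv="y", within=["condition"], between="group").fit()
        b = MixedAnova(df2, dv="y", within=["condition"], between="group").fit()
        assert np.allclose(a.table["F"], b.table["F"])

    def test_group_sign_flip_preserves_interaction_F(self):
        rng = np.random.default_rng(5)
        df = simulate_2x2_mixed(rng, effects={"condition:group": 0.5})
        flipped = df.assign(
            group=df["group"].map({"blind": "sighted", "sighted": "blind"})
        )
        a = MixedAnova(df, dv="y", within=["condition"], between="group").fit()
        b = MixedAnova(flipped, dv="y", within=["condition"], between="group").fit()
        assert a.effect("condition:group")["F"] == pytest.approx(
            b.effect("condition:group")["F"], rel=1e-9
        )


class TestValidation:
    def test_missing_cell_raises(self):
        rng = np.random.default_rng(6)
        df = simulate_2x2_mixed(rng)
        broken = df.drop(index=df.index[0])
        with pytest.raises(ValueError, match="missing cell"):
            MixedAnova(broken, dv="y", within=["condition"], between="group").fit()

    def test_voxelwise_matches_scalar_path(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(12, 2, 2, 5))
        g = np.array([0] * 5 + [1] * 7)
        eff = factorial_effects(y, ["condition", "timing"], groups=g)
        for v in range(5):
            single = factorial_effects(y[..., v], ["condition", "timing"], groups=g)
            for name in eff:
                assert eff[name]["F"][v] == pytest.approx(float(single[name]["F"]), rel=1e-9)
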