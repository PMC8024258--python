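"""Inverse transform, aligned-rank-transform ANOVA, assumption checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from grapholearn.art import (
    ArtAnova,
    art_anova,
    assumption_checks,
    inverse_transform,
    posthoc_by_group,
)
from grapholearn.mixed_anova import MixedAnova
from grapholearn.synth import generate_behavior


class TestInverseTransform:
    def test_documented_convention(self):
        assert inverse_transform(np.array([99.0]))[0] == pytest.approx(0.01)
        assert inverse_transform(np.array([0.0]))[0] == pytest.approx(1.0)

    @given(st.lists(st.integers(min_value=0, max_value=400), min_size=2, max_size=30, unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_monotone_decreasing(self, values):
        y = np.sort(np.array(values, dtype=float)) / 4.0  # quarter-point accuracies
        t = inverse_transform(y)
        assert np.all(np.diff(t) < 0)

    def test_rank_order_exactly_reversed(self, rng):
        y = rng.uniform(0, 100, 40)
        ranks_before = stats.rankdata(y)
        ranks_after = stats.rankdata(inverse_transform(y))
        assert np.allclose(ranks_before + ranks_after, len(y) + 1)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            inverse_transform(np.array([-1.0]))


def _behavior(seed, **kw):
    return generate_behavior(n_blind=kw.pop("n_blind", 6), n_sighted=kw.pop("n_sighted", 6),
                             seed=seed, **kw)


class TestArtAnova:
    def test_single_within_factor_reduces_to_rank_anova(self, rng):
        # balanced single-factor ART: aligned response is y - grand mean, so
        # the ART F equals the rank ANOVA F computed independently
        rows = []
        for i in range(6):
            for cond in ("writing", "no-writing"):
                rows.append(
                    {"participant": f"p{i}", "condition": cond, "y": rng.normal()}
                )
        df = pd.DataFrame(rows)
        art = ArtAnova(df, dv="y", within=("condition",), between=None).fit()
        ranked = df.assign(y=stats.rankdata(df["y"] - df["y"].mean()))
        direct = MixedAnova(ranked, dv="y", within=["condition"], between=None).fit()
        assert art.effect("condition")["F"] == pytest.approx(
            direct.effect("condition")["F"], rel=1e-9
        )

    def test_affine_response_transform_leaves_every_F(self):
        table = _behavior(3)
        a = art_anova(table)
        b = art_anova(table.assign(accuracy=2.0 * table["accuracy"] + 8.0))
        # invariance is exact in real arithmetic; float rounding can resolve
        # exact ties in the aligned responses differently, hence the atol
        assert np.allclose(a.table["F"], b.table["F"], rtol=1e-6, atol=1e-4)

    def test_condition_relabelling_symmetry(self):
        table = _behavior(4)
        swapped = table.assign(
            condition=table["condition"].map({"writing": "no-writing", "no-writing": "writing"})
        )
        a = art_anova(table)
        b = art_anova(swapped)
        assert np.allclose(np.sort(a.table["F"]), np.sort(b.table["F"]))

    def test_expected_effects_present_with_correct_df(self):
        res = art_anova(generate_behavior(n_blind=12, n_sighted=18, seed=5))
        assert set(res.table["effect"]) == {
            "condition", "timing", "group", "condition:timing", "condition:group",
            "timing:group", "condition:timing:group",
        }
        assert (res.table["df2"] == 28).all()
        assert (res.table["df1"] == 1).all()

    def test_missing_cell_rejected(self):
        table = _behavior(6).iloc[1:]
        with pytest.raises(ValueError):
            art_anova(table)

    def test_alignment_diagnostic_sums(self):
        res = art_anova(_behavior(7))
        sums = [v for k, v in res.diagnostics.items() if k.endswith("_aligned_sum")]
        assert np.allclose(sums, 0.0, atol=1e-8)


class TestAssumptionChecks:
    def test_normal_residuals_calibrated(self):
        rejections = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            table = _behavior(s).assign(accuracy=rng.normal(50, 10, 48))
            rejections += assumption_checks(table)["shapiro_p"] < 0.05
        assert 0.01 < rejections / 200 < 0.12

    def test_ceiling_binomial_data_flagged(self):
        # ceiling-compressed accuracies: normality should be rejected often
        rejections = 0
        for s in range(50):
            table = generate_behavior(
                n_blind=15, n_sighted=15,
                effects={"intercept": 2.2, "timing": 1.2}, seed=s,
            )
            rejections += assumption_checks(table)["shapiro_p"] < 0.05
        assert rejections / 50 > 0.5

    def test_constant_data_degenerate(self):
        table = _behavior(8).assign(accuracy=50.0)
        with pytest.raises(ValueError):
            assumption_checks(table)


class TestPosthoc:
    def test_posthoc_invariant_to_other_group(self):
        table = generate_behavior(n_blind=6, n_sighted=6, seed=9)
        out1 = posthoc_by_group(table)
        # perturb the sighted group only
        perturbed = table.copy()
        mask = perturbed["group"] == "sighted"
        perturbed.loc[mask, "accuracy"] = (
            100 - perturbed.loc[mask, "accuracy"]
        )
        out2 = posthoc_by_group(perturbed)
        assert np.allclose(
            out1["blind"]["anova"].table["F"], out2["blind"]["anova"].table["F"]
        )

    def test_planted_condition_effect_found_in_one_group(self):
        hits = 0
        for s in range(30):
            rng = np.random.default_rng(500 + s)
            rows = []
            for i in range(12):
                grp = "blind" if i < 6 else "sighted"
                for cond, c in (("writing", 1.0), ("no-writing", -1.0)):
                    for timing in ("immediate", "delayed"):
                        delta = 1.0 * c if grp == "blind" else 0.0
                        rows.append(
                            {
                                "participant": f"p{i}",
                                "group": grp,
                                "condition": cond,
                                "timing": timing,
                                "accuracy": delta + rng.normal(0, 1.0),
                            }
                        )
            out = posthoc_by_group(pd.DataFrame(rows))
            hits += out["blind"]["anova"].effect("condition")["p"] < 0.05
        assert hits >= 27
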