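"""Mixed factorial ANOVA for two-level designs via within-subject contrasts.

The designs in this package are all 2x2(x2) factorials with two-level factors:
one or two within-participant factors (learning condition, period/timing) and
at most one two-level between-participant factor (group).  For such designs
the classical split-plot ANOVA decomposes exactly into independent one-degree-
of-freedom tests on per-participant contrast scores:

* for a subset S of within factors, the score is the mean of the cell values
  signed by the product of the S factors' +/-1 codes (S empty: the plain cell
  mean);
* the within effect S is the test of the scores' (unweighted-across-groups)
  grand mean against zero, the S x group interaction is the two-sample
  comparison of the scores between groups, and the group main effect is the
  two-sample comparison of the plain means.

With groups of sizes n1 and n2 every test is F(1, n1 + n2 - 2); without a
between factor, F(1, n - 1).  Unequal group sizes are handled with unweighted
(Type-III-style) marginal means.  The same arithmetic runs unchanged over a
trailing voxel axis, which is how the voxelwise second-level maps are built.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def _subset_scores(y_cells: np.ndarray, n_within: int, subset: tuple[int, ...]) -> np.ndarray:
    """Signed cell means for a subset of within factors.

    ``y_cells`` has shape (n_subj, 2, ..., 2[, extra]); within factor axes
    start at 1.  Level 0 of each factor is coded +1 and level 1 is coded -1,
    and the score is averaged (not summed) over cells, so a main-effect score
    is half the level-0-minus-level-1 difference.
    """
    y = np.asarray(y_cells, dtype=float)
    for f in subset:
        code_shape = [1] * y.ndim
        code_shape[1 + f] = 2
        y = y * np.array([1.0, -1.0]).reshape(code_shape)
    return y.mean(axis=tuple(range(1, 1 + n_within)))


def _one_group(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n = scores.shape[0]
    est = scores.mean(axis=0)
    se = scores.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (est / se) ** 2
    return est, f, n - 1


def _two_group(scores: np.ndarray, g: np.ndarray) -> tuple:
    """(est_mean, F_mean, est_diff, F_diff, df2) for a two-group comparison.

    est_mean is the unweighted mean of the two group means (Type III
    intercept), est_diff is half their difference (group-1 minus group-2).
    """
    s1, s2 = scores[g == 0], scores[g == 1]
    n1, n2 = s1.shape[0], s2.shape[0]
    m1, m2 = s1.mean(axis=0), s2.mean(axis=0)
    ss = ((s1 - m1) ** 2).sum(axis=0) + ((s2 - m2) ** 2).sum(axis=0)
    df2 = n1 + n2 - 2
    pooled = ss / df2
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f_mean = (((m1 + m2) / 2.0) / se) ** 2
        f_diff = (((m1 - m2) / 2.0) / se) ** 2
    return (m1 + m2) / 2.0, f_mean, (m1 - m2) / 2.0, f_diff, df2


def factorial_effects(
    y_cells: np.ndarray,
    within_names: list[str],
    groups: np.ndarray | None = None,
    between_name: str = "group",
    include_intercept: bool = False,
) -> dict[str, dict]:
    """All main effects and interactions of a 2^k mixed factorial.

    ``y_cells``: (n_subj, 2, ..., 2[, extra]) with one axis of length 2 per
    within factor; ``groups``: 0/1 label per subject or None for a pure
    within design.  Returns {effect: {estimate, F, df1, df2, p[, z]}} where
    every F has one numerator degree of freedom; estimates follow the +1/-1
    coding of ``_subset_scores``.  ``include_intercept`` adds the test of the
    grand mean against zero (the one-sample test on collapsed scores).
    """
    n_within = len(within_names)
    g = None if groups is None else np.asarray(groups)
    out: dict[str, dict] = {}

    def pack(name, est, f, df2):
        f = np.asarray(f, dtype=float)
        p = stats.f.sf(f, 1, df2)
        out[name] = {
            "estimate": est,
            "F": f if f.ndim else float(f),
            "df1": 1,
            "df2": int(df2),
            "p": p if np.ndim(p) else float(p),
        }

    subsets = [s for r in range(0, n_within + 1) for s in combinations(range(n_within), r)]
    for subset in subsets:
        scores = _subset_scores(y_cells, n_within, subset)
        label = ":".join(within_names[f] for f in subset)
        if g is None:
            if subset or include_intercept:
                est, f, df2 = _one_group(scores)
                pack(label if subset else "intercept", est, f, df2)
            continue
        est_m, f_m, est_d, f_d, df2 = _two_group(scores, g)
        if subset:
            pack(label, est_m, f_m, df2)
            pack(f"{label}:{between_name}", est_d, f_d, df2)
        else:
            if include_intercept:
                pack("intercept", est_m, f_m, df2)
            pack(between_name, est_d, f_d, df2)
    return out


def effects_to_zmaps(effects: dict[str, dict]) -> dict[str, np.ndarray]:
    """Signed standard-normal equivalents of the one-df F maps."""
    out = {}
    for name, eff in effects.items():
        p = np.clip(np.asarray(eff["p"], dtype=float), 1e-300, 1.0)
        z = stats.norm.isf(p / 2.0) * np.sign(np.asarray(eff["estimate"]))
        out[name] = z
    return out


class MixedAnova:
    """Mixed two-level factorial ANOVA on a long-form table.

    Parameters
    ----------
    data : long-form DataFrame with one row per participant x cell.
    dv : response column.
    within : one or two two-level within-participant factor columns.
    between : optional two-level between-participant factor column.
    subject : participant identifier column.

    Factor levels are ordered alphabetically; the first level is coded +1.
    ``fit()`` returns a :class:`MixedAnovaResults` with one row per effect.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        within: list[str],
        between: str | None = None,
        subject: str = "participant",
    ):
        self.data = data
        self.dv = dv
        self.within = list(within)
        self.between = between
        self.subject = subject
        if not 1 <= len(self.within) <= 2:
            raise ValueError("one or two within factors are supported")

    def _pivot(self) -> tuple[np.ndarray, np.ndarray | None, list]:
        df = self.data
        levels = {}
        for f in self.within:
            lv = sorted(df[f].astype(str).unique())
            if len(lv) != 2:
                raise ValueError(f"within factor {f!r} must have exactly 2 levels")
            levels[f] = lv
        subjects = sorted(df[self.subject].unique())
        shape = (len(subjects),) + (2,) * len(self.within)
        y = np.full(shape, np.nan)
        pivot = df.set_index([self.subject] + self.within)[self.dv]
        for si, s in enumerate(subjects):
            for idx in np.ndindex(*(2,) * len(self.within)):
                key = (s,) + tuple(levels[f][i] for f, i in zip(self.within, idx))
                try:
                    val = pivot.loc[key]
                except KeyError:
                    raise ValueError(f"missing cell {key} for participant {s!r}") from None
                if np.ndim(val) > 0:
                    val = np.mean(np.asarray(val, dtype=float))
                y[(si,) + idx] = val
        g = None
        if self.between is not None:
            lab = df.groupby(self.subject)[self.between].first()
            glevels = sorted(lab.astype(str).unique())
            if len(glevels) != 2:
                raise ValueError(f"between factor {self.between!r} must have 2 levels")
            g = np.array([glevels.index(str(lab.loc[s])) for s in subjects])
            if min((g == 0).sum(), (g == 1).sum()) < 2:
                raise ValueError("each group needs at least 2 participants")
        return y, g, subjects

    def fit(self, include_intercept: bool = False) -> "MixedAnovaResults":
        y, g, subjects = self._pivot()
        effects = factorial_effects(
            y,
            self.within,
            groups=g,
            between_name=self.between or "group",
            include_intercept=include_intercept,
        )
        rows = []
        for name, eff in effects.items():
            f = float(eff["F"])
            rows.append(
                {
                    "effect": name,
                    "estimate": float(eff["estimate"]),
                    "F": f,
                    "df1": eff["df1"],
                    "df2": eff["df2"],
                    "p": float(eff["p"]),
                    "partial_eta_sq": f / (f + eff["df2"]) if np.isfinite(f) else np.nan,
                }
            )
        return MixedAnovaResults(pd.DataFrame(rows), n_subjects=len(subjects))


class MixedAnovaResults:
    def __init__(self, table: pd.DataFrame, n_subjects: int):
        self.table = table
        self.n_subjects = n_subjects

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.table['effect'])}")
        return hit.iloc[0]

    def summary(self) -> str:
        lines = [f"Mixed factorial ANOVA ({self.n_subjects} participants)"]
        for r in self.table.itertuples():
            lines.append(
                f"  {r.effect:<28s} F({r.df1},{r.df2}) = {r.F:8.3f}  "
                f"p = {r.p:.4g}  partial eta^2 = {r.partial_eta_sq:.3f}"
            )
        return "\n".join(lines)
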