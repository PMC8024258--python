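"""Aligned-rank-transform (ART) nonparametric factorial ANOVA of recall accuracy.

Recall accuracies are bounded percentages with strong ceiling compression, so
the factorial analysis is run nonparametrically: for each effect the data are
*aligned* (every estimated effect except the one of interest is subtracted),
the aligned responses are ranked (average ranks for ties), and a parametric
mixed factorial ANOVA is run on the ranks — keeping only the F of the effect
the data were aligned for.  An optional inverse transform 1/(y + c) is applied
first to reduce variance heterogeneity.

The design is the study's 2x2x2: learning condition (writing vs no-writing)
and test timing (immediate vs delayed) within participants, group (blind vs
sighted) between.  Alignment uses observed (raw) marginal means, so the
aligned responses sum to zero exactly; the rank-stage ANOVA uses the
unweighted split-plot engine of :mod:`grapholearn.mixed_anova`.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_anova import factorial_effects


def inverse_transform(values: np.ndarray, offset: float = 1.0) -> np.ndarray:
    """Reciprocal transform y -> 1/(y + offset); strictly decreasing on [0, 100].

    The offset (default 1) guards against division by zero at accuracy 0 and
    is a configuration knob: offset 0 gives the plain reciprocal.
    """
    y = np.asarray(values, dtype=float)
    if np.any(y < 0):
        raise ValueError("accuracies must be non-negative")
    if np.any(y + offset <= 0):
        raise ValueError("offset too small: y + offset must be positive")
    return 1.0 / (y + offset)


def _marginal_means(y: np.ndarray, levels: list[np.ndarray], subset: tuple[int, ...]) -> np.ndarray:
    """Per-observation marginal mean over the factors in ``subset`` (raw means)."""
    if not subset:
        return np.full(y.shape, y.mean())
    key = np.zeros(len(y), dtype=int)
    for f in subset:
        key = key * 2 + levels[f]
    sums = np.bincount(key, weights=y, minlength=2 ** len(subset))
    counts = np.bincount(key, minlength=2 ** len(subset))
    return (sums / np.maximum(counts, 1))[key]


def art_effects_array(
    y_cells: np.ndarray,
    within_names: list[str],
    groups: np.ndarray | None = None,
    between_name: str = "group",
) -> tuple[dict[str, dict], dict[str, float]]:
    """ART on a (n_subj, 2[, 2]) cell array; returns (effects, diagnostics).

    For each effect: residuals (observation minus its full-factorial cell
    mean) plus the inclusion-exclusion estimate of that effect are ranked and
    submitted to the mixed factorial ANOVA on ranks; only that effect's row is
    kept.  Diagnostics hold, per effect, the maximum absolute F of the
    stripped effects in an ANOVA on the *aligned* (unranked) responses — all
    should be ~0 if the alignment is correct — and the mean aligned response.
    """
    y = np.asarray(y_cells, dtype=float)
    n_within = len(within_names)
    n_subj = y.shape[0]
    cell_shape = (2,) * n_within
    # flat observation layout with factor level arrays
    y_flat = y.reshape(n_subj, -1).ravel()
    level_arrays: list[np.ndarray] = []
    names: list[str] = []
    for ax, name in enumerate(within_names):
        idx = np.indices(cell_shape)[ax].ravel()
        level_arrays.append(np.tile(idx, n_subj))
        names.append(name)
    if groups is not None:
        g = np.asarray(groups, dtype=int)
        level_arrays.append(np.repeat(g, int(np.prod(cell_shape))))
        names.append(between_name)
    else:
        g = None
    n_factors = len(names)
    all_factors = tuple(range(n_factors))
    cell_mean = _marginal_means(y_flat, level_arrays, all_factors)
    residual = y_flat - cell_mean

    effects: dict[str, dict] = {}
    diagnostics: dict[str, float] = {}
    for r in range(1, n_factors + 1):
        for subset in combinations(all_factors, r):
            est = np.zeros_like(y_flat)
            for t in range(len(subset) + 1):
                for sub in combinations(subset, t):
                    sign = (-1.0) ** (len(subset) - t)
                    est += sign * _marginal_means(y_flat, level_arrays, sub)
            aligned = residual + est
            ranked = stats.rankdata(aligned).reshape(y.shape)
            res = factorial_effects(
                ranked, within_names, groups=g, between_name=between_name
            )
            label = ":".join(names[f] for f in subset)
            effects[label] = res[label]
            # stripped-effect check on the aligned (unranked) responses
            res_al = factorial_effects(
                aligned.reshape(y.shape), within_names, groups=g, between_name=between_name
            )
            others = [
                float(res_al[k]["F"]) for k in res_al if k != label and np.isfinite(res_al[k]["F"])
            ]
            diagnostics[label] = max(others) if others else 0.0
            diagnostics[f"{label}_aligned_sum"] = float(aligned.sum())
    return effects, diagnostics


class ArtAnova:
    """ART factorial ANOVA on a long-form behavioral table.

    Parameters follow the study design: ``within`` holds one or two two-level
    within-participant factor columns, ``between`` an optional two-level
    between-participant factor column.  ``fit()`` returns an
    :class:`ArtAnovaResults`; partial eta squared is F*df1 / (F*df1 + df2).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str = "accuracy",
        within: tuple[str, ...] = ("condition", "timing"),
        between: str | None = "group",
        subject: str = "participant",
    ):
        self.data = data
        self.dv = dv
        self.within = list(within)
        self.between = between
        self.subject = subject

    def _pivot(self) -> tuple[np.ndarray, np.ndarray | None, list]:
        df = self.data
        levels = {f: sorted(df[f].astype(str).unique()) for f in self.within}
        for f, lv in levels.items():
            if len(lv) != 2:
                raise ValueError(f"factor {f!r} must have exactly 2 levels")
        subjects = sorted(df[self.subject].unique())
        y = np.full((len(subjects),) + (2,) * len(self.within), np.nan)
        sub_idx = {s: i for i, s in enumerate(subjects)}
        lvl_idx = [{l: i for i, l in enumerate(levels[f])} for f in self.within]
        for row in df.itertuples():
            pos = (sub_idx[getattr(row, self.subject)],) + tuple(
                lvl_idx[k][str(getattr(row, f))] for k, f in enumerate(self.within)
            )
            y[pos] = getattr(row, self.dv)
        if np.isnan(y).any():
            raise ValueError("incomplete within-participant cells")
        g = None
        if self.between is not None:
            lab = df.groupby(self.subject)[self.between].first().astype(str)
            glevels = sorted(lab.unique())
            if len(glevels) != 2:
                raise ValueError(f"between factor {self.between!r} must have 2 levels")
            g = np.array([glevels.index(lab.loc[s]) for s in subjects])
            if min((g == 0).sum(), (g == 1).sum()) < 2:
                raise ValueError("each group needs at least 2 participants")
        return y, g, subjects

    def fit(self) -> "ArtAnovaResults":
        y, g, subjects = self._pivot()
        effects, diagnostics = art_effects_array(
            y, self.within, groups=g, between_name=self.between or "group"
        )
        rows = []
        for name, eff in effects.items():
            f = float(eff["F"])
            rows.append(
                {
                    "effect": name,
                    "F": f,
                    "df1": eff["df1"],
                    "df2": eff["df2"],
                    "partial_eta_sq": f / (f + eff["df2"]) if np.isfinite(f) else np.nan,
                    "p": float(eff["p"]),
                }
            )
        return ArtAnovaResults(pd.DataFrame(rows), diagnostics, n_subjects=len(subjects))


class ArtAnovaResults:
    def __init__(self, table: pd.DataFrame, diagnostics: dict, n_subjects: int):
        self.table = table
        self.diagnostics = diagnostics
        self.n_subjects = n_subjects

    def effect(self, name: str) -> pd.Series:
        hit = self.table[self.table["effect"] == name]
        if hit.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.table['effect'])}")
        return hit.iloc[0]

    def summary(self) -> str:
        lines = [f"Aligned-rank-transform ANOVA ({self.n_subjects} participants)"]
        for r in self.table.itertuples():
            lines.append(
                f"  {r.effect:<28s} F({r.df1},{r.df2}) = {r.F:8.2f}  "
                f"eta^2 = {r.partial_eta_sq:.2f}  p = {r.p:.3g}"
            )
        worst = max(
            (v for k, v in self.diagnostics.items() if not k.endswith("_aligned_sum")),
            default=0.0,
        )
        lines.append(f"  alignment check: max stripped-effect F = {worst:.2e}")
        return "\n".join(lines)


def art_anova(
    table: pd.DataFrame,
    dv: str = "accuracy",
    within: tuple[str, ...] = ("condition", "timing"),
    between: str | None = "group",
    subject: str = "participant",
) -> ArtAnovaResults:
    """Functional wrapper: ``ArtAnova(...).fit()``."""
    return ArtAnova(table, dv=dv, within=within, between=between, subject=subject).fit()


def assumption_checks(
    table: pd.DataFrame,
    dv: str = "accuracy",
    factors: tuple[str, ...] = ("group", "condition", "timing"),
) -> dict[str, float]:
    """Shapiro–Wilk on cell residuals and Brown–Forsythe Levene across cells."""
    vals = table[dv].to_numpy(dtype=float)
    if len(vals) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(vals) == 0:
        raise ValueError("constant data: assumption checks are degenerate")
    cells = table.groupby(list(factors))[dv]
    resid = vals - cells.transform("mean").to_numpy(dtype=float)
    shapiro_p = float(stats.shapiro(resid).pvalue)
    groups = [g.to_numpy(dtype=float) for _, g in cells]
    levene_p = float(stats.levene(*groups, center="median").pvalue)
    return {"shapiro_p": shapiro_p, "levene_p": levene_p}


def posthoc_by_group(
    table: pd.DataFrame,
    dv: str = "accuracy",
    within: tuple[str, str] = ("condition", "timing"),
    between: str = "group",
    subject: str = "participant",
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Per-group two-way within-participant ART, then per-timing condition tests.

    For each level of ``between``: a condition x timing ART ANOVA on that
    group alone; if the interaction is significant at ``alpha``, the effect
    of the first within factor is re-tested separately at each level of the
    second (single-factor ART).
    """
    cond, timing = within
    out: dict[str, dict] = {}
    for glevel, sub in table.groupby(between):
        res = ArtAnova(sub, dv=dv, within=within, between=None, subject=subject).fit()
        entry: dict = {"anova": res, "per_timing": {}}
        inter = res.effect(f"{cond}:{timing}")
        if inter["p"] < alpha:
            for tlevel, tsub in sub.groupby(timing):
                entry["per_timing"][tlevel] = ArtAnova(
                    tsub, dv=dv, within=(cond,), between=None, subject=subject
                ).fit()
        out[str(glevel)] = entry
    return out
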