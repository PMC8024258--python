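"""Representational similarity analysis: neural RDMs, ROI RSA, searchlight.

A neural RDM is one minus the Spearman rank correlation between every pair of
word patterns.  Its lower triangle is then rank-correlated with a theoretical
RDM's triangle, and the Fisher-z of that correlation becomes the unit of
second-level analysis: a 2x2 mixed ANOVA (learning condition within, group
between) per ROI and RDM, with Benjamini–Hochberg correction across ROIs, or
a whole-brain searchlight map fed into the same factorial machinery.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import fisher_z, lower_triangle
from .core import RDM, PatternMatrix
from .mixed_anova import MixedAnova
from .rois import sphere_offsets


def neural_rdm(patterns: PatternMatrix | np.ndarray, word_ids: list[str] | None = None) -> RDM:
    """1 - Spearman correlation of every pair of word patterns."""
    if isinstance(patterns, PatternMatrix):
        values, word_ids = patterns.values, patterns.word_ids
    else:
        values = np.asarray(patterns, dtype=float)
        if word_ids is None:
            word_ids = [f"w{i}" for i in range(values.shape[0])]
    if values.shape[1] < 2:
        raise ValueError("need at least 2 voxels for a neural RDM")
    const = np.all(values == values[:, :1], axis=1)
    if const.any():
        bad = [word_ids[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant pattern rows (correlation undefined) for words: {bad}")
    ranks = stats.rankdata(values, axis=1)
    rho = np.corrcoef(ranks)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return RDM(list(word_ids), d, "neural")


def rdm_similarity(
    neural: RDM, theoretical: RDM, method: str = "spearman"
) -> tuple[float, float]:
    """(rho, Fisher z) between the two RDMs' lower-triangle vectors."""
    if neural.labels != theoretical.labels:
        raise ValueError("RDMs must share the same labels in the same order")
    a = lower_triangle(neural.values)
    b = lower_triangle(theoretical.values)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance RDM triangle; correlation undefined")
    if method == "spearman":
        rho = float(stats.spearmanr(a, b).statistic)
    elif method == "pearson":
        rho = float(np.corrcoef(a, b)[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return rho, float(fisher_z(rho))


def roi_rsa(
    betas: dict[tuple[str, str, str], np.ndarray],
    groups: dict[str, str],
    roi_masks: dict[str, np.ndarray],
    rdms: dict[str, RDM],
    word_ids: list[str],
    min_voxels: int = 10,
    selection_map: np.ndarray | None = None,
    selection_threshold: float | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Long-form RSA table over participants x conditions x periods x ROIs x RDMs.

    ``betas`` maps (participant, condition, period) to a 4D array of
    word-level beta images with shape (n_words, x, y, z).  Within each ROI
    (optionally intersected with ``selection_map > selection_threshold``,
    mirroring the voxel-selection-at-a-lenient-threshold step) the word
    patterns are extracted, turned into a neural RDM, and correlated with
    every theoretical RDM; Fisher z values are returned one row per cell.
    ROIs below ``min_voxels`` are skipped with a warning.
    """
    rows = []
    for roi_name, roi in roi_masks.items():
        mask = np.asarray(roi).astype(bool)
        if selection_map is not None and selection_threshold is not None:
            mask = mask & (np.asarray(selection_map) > selection_threshold)
        n_vox = int(mask.sum())
        if n_vox < min_voxels:
            warnings.warn(
                f"ROI {roi_name!r} has {n_vox} voxels (< {min_voxels}); skipped",
                stacklevel=2,
            )
            continue
        for (participant, condition, period), vols in betas.items():
            pat = PatternMatrix(
                word_ids,
                np.asarray(vols, dtype=float)[:, mask],
                participant=participant,
                group=groups[participant],
                condition=condition,
                period=period,
                roi=roi_name,
            )
            nrdm = neural_rdm(pat)
            for level, theo in rdms.items():
                rho, z = rdm_similarity(nrdm, theo, method=method)
                rows.append(
                    {
                        "participant": participant,
                        "group": groups[participant],
                        "condition": condition,
                        "period": period,
                        "roi": roi_name,
                        "rdm_level": level,
                        "rho": rho,
                        "z": z,
                    }
                )
    return pd.DataFrame(rows)


def rsa_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Second-level tests on the Fisher-z RSA table.

    Per (period, rdm_level, roi): a mixed 2x2 ANOVA with learning condition
    within and group between, plus the test of the grand mean z against zero
    ('intercept', the one-sample question of whether the ROI carries the RDM
    at all).  p values are Benjamini–Hochberg corrected across ROIs within
    each (period, rdm_level, effect) family.
    """
    rows = []
    for (period, level, roi), sub in table.groupby(["period", "rdm_level", "roi"]):
        res = MixedAnova(
            sub, dv="z", within=["condition"], between="group", subject="participant"
        ).fit(include_intercept=True)
        for r in res.table.itertuples():
            rows.append(
                {
                    "period": period,
                    "rdm_level": level,
                    "roi": roi,
                    "effect": r.effect,
                    "estimate": r.estimate,
                    "F": r.F,
                    "df1": r.df1,
                    "df2": r.df2,
                    "p": r.p,
                    "partial_eta_sq": r.partial_eta_sq,
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for _, idx in out.groupby(["period", "rdm_level", "effect"]).groups.items():
        p = out.loc[idx, "p"].to_numpy()
        out.loc[idx, "p_fdr"] = multipletests(p, method="fdr_bh")[1]
    return out


def searchlight_rsa(
    betas: np.ndarray,
    gm_probability: np.ndarray,
    rdm: RDM,
    radius_voxels: float = 2.0,
    gm_threshold: float = 0.33,
    min_voxels: int = 10,
    method: str = "spearman",
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-brain searchlight correlation map for one theoretical RDM.

    For every centre voxel whose gray-matter probability exceeds the
    threshold, the word patterns of the sphere (centre-to-centre Euclidean
    distance <= ``radius_voxels``, intersected with the gray-matter mask) are
    turned into a neural RDM and correlated with ``rdm``.  Returns (r map,
    Fisher-z map); centres whose sphere is smaller than ``min_voxels`` and
    sub-threshold voxels are NaN.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 4 or betas.shape[0] != len(rdm):
        raise ValueError("betas must be (n_words, x, y, z) matching the RDM")
    gm = np.asarray(gm_probability, dtype=float)
    if gm.shape != betas.shape[1:]:
        raise ValueError("gray-matter map must be on the same grid as the betas")
    gm_mask = gm > gm_threshold
    centers = np.argwhere(gm_mask)
    if len(centers) == 0:
        raise ValueError(
            f"gray-matter threshold {gm_threshold} leaves no searchlight centres "
            f"(map maximum {gm.max():.3f})"
        )
    offsets = sphere_offsets(radius_voxels)
    shape = np.array(betas.shape[1:])
    theo_vec = lower_triangle(rdm.values)
    theo = stats.rankdata(theo_vec) if method == "spearman" else theo_vec
    theo = (theo - theo.mean()) / theo.std()
    tri = np.tril_indices(len(rdm), k=-1)
    r_map = np.full(betas.shape[1:], np.nan)
    flat = betas.reshape(betas.shape[0], -1)
    gm_flat = gm_mask.ravel()
    strides = np.array([shape[1] * shape[2], shape[2], 1])

    # split centres into the batched fast path (complete in-bounds, all-GM
    # spheres) and a per-centre loop for edge/partial spheres
    vox_all = centers[:, None, :] + offsets[None, :, :]  # (C, m, 3)
    inbounds = np.all((vox_all >= 0) & (vox_all < shape[None, None, :]), axis=(1, 2))
    lin_all = np.clip(vox_all, 0, shape - 1) @ strides
    full = inbounds & gm_flat[lin_all].all(axis=1)

    def _sphere_r(pat: np.ndarray) -> float:
        if np.any(np.all(pat == pat[:, :1], axis=1)):
            return np.nan
        ranks = stats.rankdata(pat, axis=1)
        d = 1.0 - np.corrcoef(ranks)
        vec = d[tri]
        x = stats.rankdata(vec) if method == "spearman" else vec
        sx = x.std()
        if sx == 0:
            return np.nan
        return float(np.mean((x - x.mean()) / sx * theo))

    if full.any():
        lin = lin_all[full]  # (C, m)
        pats = flat[:, lin.ravel()].reshape(flat.shape[0], len(lin), -1)
        pats = np.moveaxis(pats, 0, 1)  # (C, words, m)
        const = np.all(pats == pats[:, :, :1], axis=2).any(axis=1)
        ranks = stats.rankdata(pats, axis=2)
        ranks = ranks - ranks.mean(axis=2, keepdims=True)
        norm = np.sqrt(np.sum(ranks**2, axis=2))
        norm[norm == 0] = np.nan
        corr = np.einsum("cwm,cum->cwu", ranks, ranks) / (
            norm[:, :, None] * norm[:, None, :]
        )
        d = 1.0 - corr[:, tri[0], tri[1]]  # (C, pairs)
        x = stats.rankdata(d, axis=1) if method == "spearman" else d
        x = x - x.mean(axis=1, keepdims=True)
        sx = x.std(axis=1)
        sx[sx == 0] = np.nan
        r = (x / sx[:, None]) @ theo / len(theo)
        r[const] = np.nan
        cf = centers[full]
        r_map[cf[:, 0], cf[:, 1], cf[:, 2]] = r

    for c in centers[~full]:
        vox = c[None, :] + offsets
        ok = np.all((vox >= 0) & (vox < shape[None, :]), axis=1)
        lin = vox[ok] @ strides
        lin = lin[gm_flat[lin]]
        if len(lin) < min_voxels:
            continue
        r_map[tuple(c)] = _sphere_r(flat[:, lin])
    z_map = np.where(np.isnan(r_map), np.nan, fisher_z(np.nan_to_num(r_map)))
    return r_map, z_map
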