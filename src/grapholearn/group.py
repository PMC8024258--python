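"""Second-level inference: voxelwise factorial maps and permutation FWE.

``factorial_anova`` runs the mixed two-level factorial (period x condition
within, group between) at every voxel of a stack of first-level contrast
images.  Family-wise error control is permutation-based throughout: cluster
extent against the permutation distribution of the maximum suprathreshold
cluster (``cluster_correct``), and peak height restricted to an ROI for
small-volume correction (``roi_svc``).  Because the observed labelling is a
member of its own permutation distribution, the resulting p-values are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._utils import rng_for
from .mixed_anova import effects_to_zmaps, factorial_effects
from .rois import voxel_to_mm

#: 26-connectivity for cluster formation.
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass
class StatMap:
    """A statistic volume with its degrees of freedom and provenance."""

    values: np.ndarray
    kind: str  # "t" | "F" | "z"
    df: tuple[int, int] | int
    contrast: str
    affine: np.ndarray
    estimate: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def factorial_anova(
    images: np.ndarray,
    within_names: list[str],
    affine: np.ndarray,
    groups: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    between_name: str = "group",
) -> dict[str, StatMap]:
    """Voxelwise mixed factorial ANOVA over stacked contrast images.

    ``images`` has shape (n_subjects, 2, ..., 2, x, y, z) with one axis of
    length 2 per within factor, in the order of ``within_names``; ``groups``
    is an optional 0/1 label per subject.  Returns one F StatMap per main
    effect / interaction, each carrying a signed z-equivalent in ``meta``.
    """
    images = np.asarray(images, dtype=float)
    n_within = len(within_names)
    expected_ndim = 1 + n_within + 3
    if images.ndim != expected_ndim:
        raise ValueError(f"expected {expected_ndim}D image stack, got {images.ndim}D")
    if np.isnan(images).any():
        raise ValueError("missing cells in the image stack (NaNs present)")
    if groups is not None:
        groups = np.asarray(groups)
        if min((groups == 0).sum(), (groups == 1).sum()) < 2:
            raise ValueError("each group needs at least 2 participants")
    shape = images.shape[-3:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    flat = images[..., mask]  # (n_subj, 2.., n_vox)
    effects = factorial_effects(flat, within_names, groups=groups, between_name=between_name)
    zmaps = effects_to_zmaps(effects)
    out = {}
    for name, eff in effects.items():
        vol = np.zeros(shape)
        vol[mask] = eff["F"]
        zvol = np.zeros(shape)
        zvol[mask] = zmaps[name]
        est = np.zeros(shape)
        est[mask] = eff["estimate"]
        out[name] = StatMap(
            values=vol,
            kind="F",
            df=(eff["df1"], eff["df2"]),
            contrast=name,
            affine=np.asarray(affine),
            estimate=est,
            meta={"z": zvol, "mask": mask},
        )
    return out


def _t_map(contrasts: np.ndarray, groups: np.ndarray | None) -> tuple[np.ndarray, int]:
    """One-sample (sign-flippable) or two-group-difference t over axis 0."""
    if groups is None:
        n = contrasts.shape[0]
        m = contrasts.mean(axis=0)
        se = contrasts.std(axis=0, ddof=1) / np.sqrt(n)
        df = n - 1
    else:
        a, b = contrasts[groups == 0], contrasts[groups == 1]
        n1, n2 = a.shape[0], b.shape[0]
        m = a.mean(axis=0) - b.mean(axis=0)
        ss = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + ((b - b.mean(axis=0)) ** 2).sum(axis=0)
        df = n1 + n2 - 2
        se = np.sqrt(ss / df * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, m / se, 0.0)
    return t, df


def _max_cluster_extent(t_flat, thr, mask, two_sided):
    stat = np.abs(t_flat) if two_sided else t_flat
    vol = np.zeros(mask.shape)
    vol[mask] = stat
    labels, n = ndimage.label(vol > thr, structure=_STRUCTURE)
    if n == 0:
        return 0, labels, n
    sizes = ndimage.sum_labels(np.ones_like(vol), labels, index=np.arange(1, n + 1))
    return int(sizes.max()), labels, n


def cluster_correct(
    contrasts: np.ndarray,
    affine: np.ndarray,
    voxel_p: float = 0.001,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    mask: np.ndarray | None = None,
    groups: np.ndarray | None = None,
    two_sided: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster-extent FWE by permutation of the maximum cluster size.

    ``contrasts``: (n_subjects, x, y, z) per-participant contrast images.
    With ``groups=None`` the statistic is a one-sample t and the null is
    generated by sign flipping; with a 0/1 ``groups`` vector it is the group
    difference and the null permutes group labels.  Returns a table with one
    row per suprathreshold cluster: peak mm coordinates, peak t and
    z-equivalent, extent in voxels, and the FWE-corrected p.
    """
    if n_permutations < int(np.ceil(1.0 / alpha)) - 1:
        raise ValueError(f"need at least {int(np.ceil(1 / alpha)) - 1} permutations for alpha={alpha}")
    contrasts = np.asarray(contrasts, dtype=float)
    shape = contrasts.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    flat = contrasts[:, mask]
    t, df = _t_map(flat, groups)
    thr = stats.t.isf(voxel_p / 2 if two_sided else voxel_p, df)
    _, labels, n_clusters = _max_cluster_extent(t, thr, mask, two_sided)

    rng = rng_for(seed, "cluster_correct")
    null_max = np.zeros(n_permutations, dtype=int)
    n_subj = flat.shape[0]
    for b in range(n_permutations):
        if groups is None:
            signs = rng.choice([-1.0, 1.0], size=n_subj)[:, None]
            tp, _ = _t_map(flat * signs, None)
        else:
            perm = rng.permutation(n_subj)
            tp, _ = _t_map(flat, np.asarray(groups)[perm])
        null_max[b], _, _ = _max_cluster_extent(tp, thr, mask, two_sided)

    rows = []
    tvol = np.zeros(shape)
    tvol[mask] = t
    for c in range(1, n_clusters + 1):
        in_c = labels == c
        extent = int(in_c.sum())
        # observed labelling is part of its own null distribution
        p_fwe = (1 + int(np.sum(null_max >= extent))) / (1 + n_permutations)
        peak_idx = np.unravel_index(np.argmax(np.abs(tvol) * in_c), shape)
        peak_t = float(tvol[peak_idx])
        peak_mm = voxel_to_mm(affine, np.array(peak_idx))[0]
        p_unc = 2 * stats.t.sf(abs(peak_t), df) if two_sided else stats.t.sf(peak_t, df)
        z = float(np.sign(peak_t) * stats.norm.isf(max(p_unc, 1e-300) / 2))
        rows.append(
            {
                "x_mm": peak_mm[0],
                "y_mm": peak_mm[1],
                "z_mm": peak_mm[2],
                "peak_t": peak_t,
                "peak_z": z,
                "extent_voxels": extent,
                "p_fwe": p_fwe,
            }
        )
    table = pd.DataFrame(
        rows, columns=["x_mm", "y_mm", "z_mm", "peak_t", "peak_z", "extent_voxels", "p_fwe"]
    )
    return table.sort_values("extent_voxels", ascending=False).reset_index(drop=True)


def roi_svc(
    contrasts: np.ndarray,
    roi_mask: np.ndarray,
    affine: np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    groups: np.ndarray | None = None,
    two_sided: bool = True,
    seed: int = 0,
) -> dict:
    """Small-volume FWE on the peak statistic within an ROI, by permutation.

    The max-|t| statistic over the ROI voxels is compared with its
    permutation distribution (sign flips for a one-sample contrast, group
    relabelling for a two-group difference).  For a single-voxel ROI this
    reduces to the uncorrected permutation p of that voxel.
    """
    roi_mask = np.asarray(roi_mask).astype(bool)
    if not roi_mask.any():
        raise ValueError("ROI does not intersect the analysis mask")
    contrasts = np.asarray(contrasts, dtype=float)
    flat = contrasts[:, roi_mask]
    t, df = _t_map(flat, groups)
    stat = np.abs(t) if two_sided else t
    obs = float(stat.max())
    rng = rng_for(seed, "roi_svc")
    count = 0
    n_subj = flat.shape[0]
    for _ in range(n_permutations):
        if groups is None:
            signs = rng.choice([-1.0, 1.0], size=n_subj)[:, None]
            tp, _ = _t_map(flat * signs, None)
        else:
            perm = rng.permutation(n_subj)
            tp, _ = _t_map(flat, np.asarray(groups)[perm])
        mx = float((np.abs(tp) if two_sided else tp).max())
        if mx >= obs - 1e-12:
            count += 1
    p_fwe = (1 + count) / (1 + n_permutations)
    peak_flat = int(np.argmax(stat))
    peak_idx = tuple(np.argwhere(roi_mask)[peak_flat])
    return {
        "peak_voxel": peak_idx,
        "peak_mm": tuple(voxel_to_mm(affine, np.array(peak_idx))[0]),
        "peak_t": float(t[peak_flat]),
        "df": df,
        "p_fwe_svc": p_fwe,
        "significant": p_fwe <= alpha,
    }
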