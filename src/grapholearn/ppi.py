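"""Psychophysiological interaction (PPI) connectivity analysis.

A seed region's time course (its principal eigenvariate) is multiplied
element-by-element with a centred psychological contrast vector (here the
period x condition coding); the product's regression coefficient at each
target voxel indexes how strongly seed-target coupling changes with the
psychological context.  No hemodynamic deconvolution is applied: the product
is formed directly on the BOLD-level seed signal.  Second-level inference on
the per-participant interaction beta maps uses the mixed 2x2 ANOVA (condition
within, group between) plus permutation small-volume tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .group import StatMap, cluster_correct, factorial_anova, roi_svc


def eigenvariate(seed_timeseries: np.ndarray) -> np.ndarray:
    """Principal eigenvariate of a (time x voxels) seed matrix.

    The first left singular vector of the column-centred matrix, scaled to
    the mean per-voxel standard deviation and sign-fixed so it correlates
    positively with the mean seed series.
    """
    ts = np.asarray(seed_timeseries, dtype=float)
    if ts.ndim == 1:
        ts = ts[:, None]
    t, v = ts.shape
    if t < 2:
        raise ValueError("need at least 2 time points")
    centered = ts - ts.mean(axis=0)
    stds = centered.std(axis=0)
    if np.all(stds == 0):
        raise ValueError("degenerate seed: all voxel series are constant")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    ev = u[:, 0]
    mean_series = centered.mean(axis=1)
    if np.dot(ev, mean_series) < 0:
        ev = -ev
    return ev / ev.std() * stds.mean()


@dataclass
class PPIDesign:
    """Physiological, psychological and interaction regressors for one run."""

    physiological: np.ndarray
    psychological: np.ndarray
    interaction: np.ndarray
    nuisance: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def build_ppi(
    seed: np.ndarray,
    psych_labels: np.ndarray,
    contrast_weights: dict[str, float],
    nuisance: np.ndarray | None = None,
) -> PPIDesign:
    """Form the PPI regressors from a seed series and a per-volume labelling.

    ``contrast_weights`` maps each psychological label to its contrast
    weight; the weights must sum to zero (an interaction contrast must be
    centred across contexts).  Both the seed and the mapped psychological
    vector are mean-centred before multiplication, and the interaction column
    is standardised to unit variance so its beta is invariant to the seed's
    scale.
    """
    seed = np.asarray(seed, dtype=float)
    labels = np.asarray(psych_labels)
    if labels.shape[0] != seed.shape[0]:
        raise ValueError("psychological labels must cover all volumes")
    if abs(sum(contrast_weights.values())) > 1e-9:
        raise ValueError("contrast weights must sum to zero")
    missing = set(np.unique(labels).astype(str)) - set(map(str, contrast_weights))
    if missing:
        raise ValueError(f"labels without contrast weights: {sorted(missing)}")
    psych = np.array([contrast_weights[str(l)] for l in labels], dtype=float)
    psych = psych - psych.mean()
    phys = seed - seed.mean()
    inter = phys * psych
    inter = inter - inter.mean()
    sd = inter.std()
    if sd > 0:
        inter = inter / sd
    return PPIDesign(
        physiological=phys,
        psychological=psych,
        interaction=inter,
        nuisance=nuisance,
        meta={"weights": dict(contrast_weights)},
    )


def ppi_first_level(
    data: np.ndarray, design: PPIDesign, mask: np.ndarray | None = None
) -> np.ndarray:
    """Interaction beta at every voxel of a (x, y, z, t) or (t, v) array.

    The model contains the interaction term plus the physiological and
    psychological main effects (which renders the interaction estimate
    orthogonal to planted main effects in expectation), any nuisance columns,
    and an intercept.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 4:
        m = np.ones(arr.shape[:3], dtype=bool) if mask is None else mask.astype(bool)
        y = arr[m].T
    elif arr.ndim == 2:
        m = None
        y = arr
    else:
        raise ValueError("data must be (x, y, z, t) or (t, voxels)")
    cols = [design.interaction, design.physiological, design.psychological]
    if design.nuisance is not None:
        cols.append(np.asarray(design.nuisance, dtype=float))
    cols.append(np.ones(len(design.interaction)))
    x = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    inter_beta = beta[0]
    if m is None:
        return inter_beta
    vol = np.zeros(arr.shape[:3])
    vol[m] = inter_beta
    return vol


def ppi_group_test(
    interaction_betas: np.ndarray,
    groups: np.ndarray,
    affine: np.ndarray,
    mask: np.ndarray | None = None,
    roi_masks: dict[str, np.ndarray] | None = None,
    voxel_p: float = 0.001,
    min_extent: int = 10,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Condition x group inference on per-participant interaction beta maps.

    ``interaction_betas``: (n_subjects, 2 conditions, x, y, z); ``groups``:
    0/1 per subject (both groups must be present).  Returns the voxelwise
    interaction StatMap, a lenient whole-brain screen (voxel p below
    ``voxel_p``, extent above ``min_extent``), and a permutation
    small-volume test per supplied ROI.
    """
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("both groups must be present")
    betas = np.asarray(interaction_betas, dtype=float)
    if betas.ndim != 5 or betas.shape[1] != 2:
        raise ValueError("expected (n_subjects, 2, x, y, z) interaction betas")
    effects = factorial_anova(betas, ["condition"], affine, groups=groups, mask=mask)
    inter = effects["condition:group"]
    # per-subject condition-difference score: the unit the group test permutes
    diff = (betas[:, 0] - betas[:, 1]) / 2.0
    screen = cluster_correct(
        diff,
        affine,
        voxel_p=voxel_p,
        n_permutations=n_permutations,
        mask=mask,
        groups=groups,
        seed=seed,
    )
    screen = screen[screen["extent_voxels"] > min_extent].reset_index(drop=True)
    roi_results = {}
    for name, roi in (roi_masks or {}).items():
        roi_results[name] = roi_svc(
            diff,
            roi,
            affine,
            groups=groups,
            n_permutations=n_permutations,
            seed=seed,
        )
    return {"interaction": inter, "screen": screen, "roi": roi_results, "effects": effects}
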