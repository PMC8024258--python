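"""Generate 4D BOLD-like runs with planted patterns and connectivity.

Each run is one (participant, learning condition) acquisition containing a
study period followed by a test period: every word's events add an
HRF-convolved response scaled by that word's planted multivoxel pattern
inside its ROI; a seed and a target ROI share a smooth latent signal whose
coupling is multiplied by (1 + connectivity_gain) during the test period of
the designated (group, condition) cell; white + AR(1) noise and a constant
baseline are added, and six smooth motion nuisance series are generated.

The event-to-regressor convolution reuses the first-level design machinery,
so a noiseless run is an exact linear model of the fitted design and the GLM
recovers planted amplitudes to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from .._utils import rng_for
from ..core import BoldRun, PatternMatrix, StimulusSet
from ..design import convolve_events
from ..hrf import HRFSpec


@dataclass
class GroundTruth:
    """Everything the generator plants; fully determines the data given a seed."""

    planted_rdm: dict[str, str] = field(default_factory=dict)  # roi -> rdm level
    connectivity_gain: float = 0.0
    connectivity_cell: tuple[str, str] = ("blind", "writing")
    behavior_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def default_grid() -> tuple[tuple[int, int, int], np.ndarray]:
    """40 x 48 x 40 grid at 2 mm isotropic, origin at the volume centre."""
    shape = (40, 48, 40)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -(np.array(shape) - 1) / 2.0 * 2.0
    return shape, affine


def box_roi(
    shape: tuple[int, int, int], corner: tuple[int, int, int], size: tuple[int, int, int]
) -> np.ndarray:
    """Rectangular ROI mask; raises if the box leaves the grid."""
    corner = np.asarray(corner)
    size = np.asarray(size)
    if np.any(corner < 0) or np.any(corner + size > np.asarray(shape)):
        raise ValueError("ROI box extends outside the grid")
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    mask[sl] = True
    return mask


def gray_matter_map(shape: tuple[int, int, int]) -> np.ndarray:
    """Smooth ellipsoidal gray-matter probability map in [0, 1]."""
    axes = [np.linspace(-1.0, 1.0, s) for s in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    return np.clip(0.9 * (1.1 - r), 0.0, 1.0)


def make_events(
    stimuli: StimulusSet,
    tr_seconds: float = 3.5,
    n_reps: int = 3,
    condition: str = "writing",
    periods: tuple[str, ...] = ("study", "test"),
    gap_volumes: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Event table: each word presented ``n_reps`` times per period at SOA = TR."""
    rng = rng_for(seed, "events", condition)
    rows = []
    t = 0.0
    for period in periods:
        order = rng.permutation(len(stimuli))
        for idx in order:
            for _ in range(n_reps):
                rows.append(
                    {
                        "onset_s": t,
                        "duration_s": 0.0,
                        "word_id": stimuli[int(idx)].word_id,
                        "condition": condition,
                        "period": period,
                    }
                )
                t += tr_seconds
        t += gap_volumes * tr_seconds
    return pd.DataFrame(rows)


def _ar1_noise(rng: np.random.Generator, shape: tuple, sd: float, phi: float) -> np.ndarray:
    """AR(1) noise along the last axis with stationary standard deviation sd."""
    eps = rng.standard_normal(shape)
    if phi != 0.0:
        eps = lfilter([1.0], [1.0, -phi], eps, axis=-1)
        eps = eps * np.sqrt(1.0 - phi**2)
    return sd * eps


def generate_bold(
    stimuli: StimulusSet,
    patterns: dict[str, PatternMatrix],
    roi_masks: dict[str, np.ndarray],
    affine: np.ndarray,
    hrf: HRFSpec | None = None,
    tr_seconds: float = 3.5,
    events: pd.DataFrame | None = None,
    n_reps: int = 3,
    condition: str = "writing",
    group: str = "blind",
    amplitude: float = 1.0,
    noise_sd: float = 1.0,
    ar_phi: float = 0.3,
    baseline: float = 100.0,
    connectivity: GroundTruth | None = None,
    seed_roi: str | None = None,
    target_roi: str | None = None,
    coupling: float = 1.0,
    pad_volumes: int = 9,
    seed: int = 0,
) -> BoldRun:
    """One synthetic run for (participant-seed, group, condition).

    ``patterns`` maps ROI names (keys of ``roi_masks``) to the word pattern
    planted there; pattern voxel counts must match the mask sizes.  If
    ``connectivity`` is given with ``seed_roi``/``target_roi``, the two ROIs
    share a latent signal whose target coupling is multiplied by
    (1 + connectivity_gain) during the test period when (group, condition)
    equals the designated cell.
    """
    hrf = hrf or HRFSpec()
    shapes = {m.shape for m in roi_masks.values()}
    if len(shapes) > 1:
        raise ValueError("all ROI masks must share one grid shape")
    shape = shapes.pop()
    for name, pat in patterns.items():
        if name not in roi_masks:
            raise ValueError(f"patterns given for unknown ROI {name!r}")
        if pat.n_voxels != int(roi_masks[name].sum()):
            raise ValueError(f"pattern for ROI {name!r} does not match the mask size")

    if events is None:
        events = make_events(
            stimuli, tr_seconds, n_reps=n_reps, condition=condition, seed=seed
        )
    n_volumes = int(np.ceil((events["onset_s"].max() + events["duration_s"].max()) / tr_seconds)) + pad_volumes
    frame_times = np.arange(n_volumes) * tr_seconds

    rng = rng_for(seed, "bold", group, condition)
    data = np.zeros(shape + (n_volumes,), dtype=float)
    data += baseline

    task = convolve_events(events, "word_id", tr_seconds, n_volumes, hrf)
    word_order = sorted(stimuli.word_ids)
    # words without events contribute a zero regressor
    x_task = task.reindex(columns=word_order, fill_value=0.0).to_numpy()  # (t, n_words)
    for name, pat in patterns.items():
        order = [pat.word_ids.index(w) for w in word_order]
        data[roi_masks[name].astype(bool)] += (x_task @ (amplitude * pat.values[order])).T

    # period labelling per volume (study until the first test onset)
    test_onsets = events.loc[events["period"] == "test", "onset_s"]
    test_start = float(test_onsets.min()) if len(test_onsets) else np.inf
    period_labels = np.where(frame_times < test_start, "study", "test")

    if connectivity is not None and seed_roi is not None and target_roi is not None:
        latent = gaussian_filter1d(rng.standard_normal(n_volumes), sigma=1.5, mode="nearest")
        latent = (latent - latent.mean()) / latent.std()
        gain = (
            connectivity.connectivity_gain
            if (group, condition) == tuple(connectivity.connectivity_cell)
            else 0.0
        )
        modulation = 1.0 + gain * (period_labels == "test").astype(float)
        data[roi_masks[seed_roi].astype(bool)] += coupling * latent
        data[roi_masks[target_roi].astype(bool)] += coupling * modulation * latent

    if noise_sd > 0:
        data += _ar1_noise(rng, shape + (n_volumes,), noise_sd, ar_phi)

    motion = gaussian_filter1d(
        np.cumsum(rng.normal(0.0, 0.02, size=(n_volumes, 6)), axis=0), sigma=3, axis=0
    )

    return BoldRun(
        data=data,
        affine=np.asarray(affine, dtype=float),
        tr_seconds=tr_seconds,
        events=events,
        motion=motion,
        meta={
            "group": group,
            "condition": condition,
            "period_labels": period_labels,
            "amplitude": amplitude,
            "word_order": word_order,
            "hrf": hrf,
        },
    )
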