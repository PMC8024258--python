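"""First-level design matrices: event convolution, drift basis, nuisance.

The design holds one HRF-convolved regressor per condition or per word,
optional temporal-derivative columns, the six motion parameters, a
discrete-cosine drift set modelling fluctuations slower than the high-pass
cutoff, and an intercept.  A Gaussian temporal smoothing kernel (default FWHM
4 s) is applied to the task and motion columns here and to the data at fit
time, so data and model pass through matched filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .hrf import HRFSpec, hrf_derivative, hrf_kernel

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class CollinearityError(ValueError):
    """Raised when the design is rank deficient; names the offending columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"design matrix is rank deficient; collinear columns: {columns}")


@dataclass
class DesignMatrix:
    frame: pd.DataFrame
    frame_times_s: np.ndarray
    task_columns: list[str]
    tr_seconds: float
    temporal_smooth_s: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def drift_basis(n_volumes: int, tr_seconds: float, high_pass_s: float) -> np.ndarray:
    """Discrete-cosine drift set up to 1/(2*high_pass_s) Hz, constant included.

    With run duration T = n_volumes * tr, the basis holds
    floor(2*T/high_pass_s) + 1 columns: cosines of order k = 0..K with
    frequency k/(2T), the order-0 term being the constant.
    """
    if high_pass_s <= 0:
        raise ValueError("high-pass period must be positive")
    duration = n_volumes * tr_seconds
    order = int(np.floor(2.0 * duration / high_pass_s))
    t = (np.arange(n_volumes) + 0.5) / n_volumes
    cols = [np.cos(np.pi * k * t) for k in range(order + 1)]
    basis = np.column_stack(cols)
    basis[:, 0] = 1.0
    return basis


def temporal_smooth(series: np.ndarray, fwhm_s: float, tr_seconds: float) -> np.ndarray:
    """Gaussian smoothing along the time axis (axis 0); FWHM in seconds."""
    if fwhm_s <= 0:
        return series
    sigma = fwhm_s * FWHM_TO_SIGMA / tr_seconds
    return gaussian_filter1d(np.asarray(series, dtype=float), sigma, axis=0, mode="nearest")


def convolve_events(
    events: pd.DataFrame,
    groupby: str,
    tr_seconds: float,
    n_volumes: int,
    hrf: HRFSpec,
    oversampling: int = 16,
) -> pd.DataFrame:
    """One HRF-convolved regressor per unique value of ``events[groupby]``.

    Events are laid out as boxcars (sticks for zero durations) on a grid of
    step TR/oversampling, convolved with the canonical kernel, and sampled at
    the volume acquisition times.
    """
    dt = tr_seconds / oversampling
    n_hi = n_volumes * oversampling
    _, kernel = hrf_kernel(hrf, dt)
    frame_idx = np.arange(n_volumes) * oversampling
    out = {}
    for name, grp in events.groupby(groupby, sort=True):
        box = np.zeros(n_hi)
        for ev in grp.itertuples():
            start = int(round(ev.onset_s / dt))
            stop = max(start + 1, int(round((ev.onset_s + ev.duration_s) / dt)))
            box[start : min(stop, n_hi)] = 1.0
        reg = np.convolve(box, kernel)[:n_hi]
        out[str(name)] = reg[frame_idx]
    return pd.DataFrame(out)


def _find_collinear(matrix: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose residual norm after QR on the preceding columns vanishes."""
    scale = np.linalg.norm(matrix, axis=0)
    scale[scale == 0] = 1.0
    _, r = np.linalg.qr(matrix / scale)
    bad = np.abs(np.diag(r)) < 1e-8
    return [n for n, b in zip(names, bad) if b]


def build_design(
    events: pd.DataFrame,
    tr_seconds: float,
    n_volumes: int,
    hrf: HRFSpec,
    motion: np.ndarray | None = None,
    high_pass_s: float = 120.0,
    temporal_smooth_s: float = 4.0,
    per: str = "condition",
    oversampling: int = 16,
) -> DesignMatrix:
    """Assemble the full first-level design.

    ``per`` selects the task-regressor granularity: ``"condition"`` for the
    condition-level model (one regressor per condition, derivative columns if
    the HRF spec asks for them) or ``"word_id"`` for the 40-regressor
    word-level model used to build pattern matrices.
    """
    frame_times = np.arange(n_volumes) * tr_seconds
    duration = n_volumes * tr_seconds
    if len(events) and events["onset_s"].max() >= duration:
        raise ValueError("events extend beyond the run")

    blocks: list[pd.DataFrame] = []
    task_columns: list[str] = []
    if len(events):
        task = convolve_events(events, per, tr_seconds, n_volumes, hrf, oversampling)
        task_columns = list(task.columns)
        blocks.append(task)
        if hrf.with_temporal_derivative:
            dt = tr_seconds / oversampling
            _, kernel = hrf_kernel(hrf, dt)
            _, dkernel = hrf_derivative(hrf, dt)
            deriv = task.copy()
            n_hi = n_volumes * oversampling
            frame_idx = np.arange(n_volumes) * oversampling
            for name in task.columns:
                box = np.zeros(n_hi)
                for ev in events[events[per].astype(str) == name].itertuples():
                    start = int(round(ev.onset_s / dt))
                    stop = max(start + 1, int(round((ev.onset_s + ev.duration_s) / dt)))
                    box[start : min(stop, n_hi)] = 1.0
                deriv[name] = np.convolve(box, dkernel)[:n_hi][frame_idx]
            deriv.columns = [f"{c}_derivative" for c in task.columns]
            blocks.append(deriv)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_volumes:
            raise ValueError("motion rows must match the number of volumes")
        blocks.append(
            pd.DataFrame(motion, columns=[f"motion_{i + 1}" for i in range(motion.shape[1])])
        )

    frame = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=range(n_volumes))
    if temporal_smooth_s > 0 and len(frame.columns):
        frame.iloc[:, :] = temporal_smooth(frame.to_numpy(float), temporal_smooth_s, tr_seconds)

    drift = drift_basis(n_volumes, tr_seconds, high_pass_s)
    drift_names = ["intercept"] + [f"drift_{k}" for k in range(1, drift.shape[1])]
    frame = pd.concat(
        [frame.reset_index(drop=True), pd.DataFrame(drift, columns=drift_names)], axis=1
    )

    matrix = frame.to_numpy(dtype=float)
    if np.linalg.matrix_rank(matrix) < matrix.shape[1]:
        raise CollinearityError(_find_collinear(matrix, list(frame.columns)))

    return DesignMatrix(
        frame=frame,
        frame_times_s=frame_times,
        task_columns=task_columns,
        tr_seconds=tr_seconds,
        temporal_smooth_s=temporal_smooth_s,
        meta={"high_pass_s": high_pass_s, "per": per},
    )
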