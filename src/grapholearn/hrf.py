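"""Canonical double-gamma hemodynamic response function.

The kernel is a difference of two gamma densities (dispersion 1 s): a positive
lobe peaking at ``peak_delay_s`` and an undershoot peaking at
``undershoot_delay_s``, scaled down by ``peak_undershoot_ratio``.  Shapes are
``delay + 1`` so the mode of each gamma density falls exactly at its stated
delay.  The sampled kernel is normalised to a peak amplitude of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HRFSpec:
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_undershoot_ratio: float = 6.0
    duration_s: float = 32.0
    with_temporal_derivative: bool = False

    def __post_init__(self) -> None:
        if self.peak_delay_s <= 0 or self.undershoot_delay_s <= 0:
            raise ValueError("HRF delays must be positive")
        if self.peak_undershoot_ratio <= 0:
            raise ValueError("peak/undershoot ratio must be positive")


def hrf_kernel(spec: HRFSpec, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample the double-gamma kernel on a grid of step ``dt`` seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, spec.duration_s + dt / 2, dt)
    peak = stats.gamma.pdf(t, a=spec.peak_delay_s + 1.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=spec.undershoot_delay_s + 1.0, scale=1.0)
    h = peak - undershoot / spec.peak_undershoot_ratio
    h = h / np.max(np.abs(h))
    return t, h


def canonical_hrf(
    spec: HRFSpec, tr_seconds: float, oversampling: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel sampled at ``tr_seconds / oversampling`` resolution."""
    if tr_seconds <= 0:
        raise ValueError("TR must be positive")
    if oversampling < 1:
        raise ValueError("oversampling must be >= 1")
    return hrf_kernel(spec, tr_seconds / oversampling)


def hrf_derivative(spec: HRFSpec, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Temporal derivative of the kernel by central finite differences."""
    t, h = hrf_kernel(spec, dt)
    return t, np.gradient(h, dt)
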