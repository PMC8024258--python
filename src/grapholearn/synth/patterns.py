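"""Plant multivoxel patterns whose pairwise geometry follows a target RDM.

This is the inverse problem of the neural-RDM computation: given a target
dissimilarity matrix, draw word patterns whose expected neural RDM approaches
the target as fidelity goes to 1 and noise to 0.  The similarity matrix
1 - RDM is double-centred into a Gram (covariance across words) matrix,
negative eigenvalues are clipped to zero, patterns are drawn with that
covariance, and white noise is mixed in by (1 - fidelity).
"""

from __future__ import annotations

import numpy as np

from .._utils import rng_for
from ..core import RDM, PatternMatrix


def gram_from_rdm(rdm: RDM) -> np.ndarray:
    """Double-centred 1 - RDM with negative eigenvalues clipped to zero (PSD)."""
    n = len(rdm)
    s = 1.0 - rdm.values
    h = np.eye(n) - np.ones((n, n)) / n
    g = h @ s @ h
    w, v = np.linalg.eigh((g + g.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return (v * w) @ v.T


def plant_patterns(
    target_rdm: RDM,
    n_voxels: int,
    fidelity: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PatternMatrix:
    """Draw (n_words, n_voxels) patterns encoding ``target_rdm``.

    ``fidelity`` in [0, 1] mixes the structured draw with an independent
    white pattern (fidelity 1: pure structure, fidelity 0: no structure);
    ``noise_sd`` adds white measurement noise on top.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    n = len(target_rdm)
    g = gram_from_rdm(target_rdm)
    w, v = np.linalg.eigh(g)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    rng = rng_for(seed, "plant_patterns")
    signal = root @ rng.standard_normal((n, n_voxels))
    # normalise the structured part to unit average voxel variance so the
    # fidelity mixing weight is comparable across target RDMs
    scale = np.sqrt(np.mean(np.diag(g)))
    if scale > 0:
        signal = signal / scale
    white = rng.standard_normal((n, n_voxels))
    values = fidelity * signal + (1.0 - fidelity) * white
    if noise_sd > 0:
        values = values + noise_sd * rng.standard_normal((n, n_voxels))
    return PatternMatrix(list(target_rdm.labels), values)
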