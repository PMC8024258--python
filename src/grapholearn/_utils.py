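"""Shared numerical helpers: seeding, Fisher transforms, triangle extraction."""

from __future__ import annotations

import hashlib

import numpy as np

#: |rho| = 1 maps to atanh(1 - FISHER_EPS); keeps z finite for group statistics.
FISHER_EPS = 1e-12


def rng_for(seed: int, *stage: object) -> np.random.Generator:
    """Derive an independent generator for a named stage from one top-level seed.

    Every source of randomness in the package flows through this function so
    that a single integer seed fixes the whole experiment.  Stage labels are
    hashed into a ``SeedSequence`` spawn key, so distinct stages get
    independent streams and the same (seed, stage) pair always returns an
    identically-initialised generator.
    """
    key = [
        int.from_bytes(hashlib.sha256(str(s).encode()).digest()[:4], "little")
        for s in stage
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def fisher_z(rho: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilising atanh transform, guarded at |rho| = 1."""
    r = np.clip(rho, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS)
    return np.arctanh(r)


def lower_triangle(matrix: np.ndarray) -> np.ndarray:
    """Off-diagonal lower-triangle entries as a flat vector (n(n-1)/2 values)."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def check_symmetric(matrix: np.ndarray, tol: float = 1e-10) -> None:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite entries")
    if np.max(np.abs(m - m.T)) > tol:
        raise ValueError("matrix is not symmetric")
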