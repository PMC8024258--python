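"""Theoretical dissimilarity matrices over a word list, and the Mantel test.

Three stimulus-level geometries are built from the word list alone:

* **motor** — dissimilarity in handwriting effort, ``|s_i - s_j| / (s_i + s_j)``
  for total stroke counts ``s``;
* **syllabic** — one minus the proportion of shared syllables relative to the
  summed syllable counts of the pair.  Shared syllables are matched as a
  multiset (position-independent) and each matched syllable is counted in both
  words, so a word is at distance 0 from itself;
* **semantic** — one minus a taxonomy similarity (Wu–Palmer by default) of the
  words' concepts.

The simple Mantel test checks whether two such matrices share structure, by
permuting the labels of one matrix and recomputing the correlation of their
lower triangles.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from ._utils import lower_triangle, rng_for
from .core import RDM, StimulusSet, Taxonomy


def motor_rdm(stimuli: StimulusSet) -> RDM:
    """Stroke-count dissimilarity |s_i - s_j| / (s_i + s_j)."""
    s = stimuli.stroke_counts
    if np.any(s < 1):
        raise ValueError("stroke counts must be >= 1")
    diff = np.abs(s[:, None] - s[None, :])
    total = s[:, None] + s[None, :]
    return RDM(stimuli.word_ids, diff / total, "motor")


def _shared_syllables(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    """Matched syllables counted once per word (hence twice per matched pair)."""
    ca, cb = Counter(a), Counter(b)
    return 2 * sum(min(ca[k], cb[k]) for k in ca.keys() & cb.keys())


def syllabic_rdm(stimuli: StimulusSet) -> RDM:
    """1 - shared syllables over the pair's total syllable count."""
    words = stimuli.words
    n = len(words)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            shared = _shared_syllables(words[i].syllables, words[j].syllables)
            total = len(words[i].syllables) + len(words[j].syllables)
            values[i, j] = values[j, i] = 1.0 - shared / total
    return RDM(stimuli.word_ids, values, "syllabic")


def semantic_rdm(
    stimuli: StimulusSet, taxonomy: Taxonomy, measure: str = "wu_palmer"
) -> RDM:
    """1 - taxonomy similarity of the words' concepts (Wu–Palmer or path)."""
    if measure == "wu_palmer":
        sim = taxonomy.wu_palmer
    elif measure == "path":
        sim = taxonomy.path_similarity
    else:
        raise ValueError(f"unknown semantic measure {measure!r}")
    words = stimuli.words
    n = len(words)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            if words[i].concept_id == words[j].concept_id:
                d = 0.0
            else:
                d = 1.0 - sim(words[i].concept_id, words[j].concept_id)
            values[i, j] = values[j, i] = d
    return RDM(stimuli.word_ids, values, "semantic")


def mantel_test(
    a: RDM, b: RDM, n_permutations: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Simple two-sided Mantel test between two dissimilarity matrices.

    The statistic is the Pearson correlation of the lower-triangle
    off-diagonal vectors.  The null distribution is obtained by jointly
    permuting the rows and columns of ``b``; the p-value uses the
    +1-smoothed estimator (1 + #{|r_perm| >= |r_obs|}) / (1 + n_permutations),
    so p is never exactly zero.
    """
    if a.labels != b.labels:
        raise ValueError("RDMs must share the same labels in the same order")
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    va = lower_triangle(a.values)
    vb = lower_triangle(b.values)
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("a constant RDM triangle has no defined correlation")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = rng_for(seed, "mantel")
    n = len(a)
    za = (va - va.mean()) / va.std()
    count = 0
    tri = np.tril_indices(n, k=-1)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        vp = b.values[np.ix_(perm, perm)][tri]
        r_perm = float(np.mean(za * (vp - vp.mean()) / vp.std()))
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return r_obs, p
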