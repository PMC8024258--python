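"""Domain containers: stimuli, taxonomy, dissimilarity matrices, BOLD runs.

These are the objects every stage of the pipeline exchanges.  A word list
(:class:`StimulusSet`) carries the syllable sequence, handwriting stroke count
and taxonomy concept of each to-be-learned word; a :class:`Taxonomy` is the
single-rooted concept tree used for semantic distance; an :class:`RDM` is a
symmetric representational dissimilarity matrix over the word list; a
:class:`BoldRun` bundles one 4D acquisition with its event table and motion
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import check_symmetric, lower_triangle

#: Dissimilarity-level tags and their admissible value ranges.
RDM_RANGES = {
    "motor": (0.0, 1.0),
    "syllabic": (0.0, 1.0),
    "semantic": (0.0, 1.0),
    "neural": (0.0, 2.0),
}


@dataclass(frozen=True)
class Word:
    """One stimulus word: identifier, syllables, stroke count, concept, list."""

    word_id: str
    syllables: tuple[str, ...]
    stroke_count: int
    concept_id: str
    list_id: int = 1

    def __post_init__(self) -> None:
        if len(self.syllables) == 0:
            raise ValueError(f"word {self.word_id!r} has an empty syllable list")
        if self.stroke_count < 1:
            raise ValueError(f"word {self.word_id!r} has stroke_count < 1")
        if self.list_id not in (1, 2):
            raise ValueError("list_id must be 1 or 2")


class StimulusSet:
    """An ordered list of unique words with their writing/phonology/semantics."""

    def __init__(self, words: list[Word]):
        ids = [w.word_id for w in words]
        if len(set(ids)) != len(ids):
            raise ValueError("word_ids must be unique")
        if len(words) < 2:
            raise ValueError("a stimulus set needs at least 2 words")
        self.words = list(words)

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    def __getitem__(self, i: int) -> Word:
        return self.words[i]

    @property
    def word_ids(self) -> list[str]:
        return [w.word_id for w in self.words]

    @property
    def stroke_counts(self) -> np.ndarray:
        return np.array([w.stroke_count for w in self.words], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word_id": self.word_ids,
                "syllables": ["-".join(w.syllables) for w in self.words],
                "stroke_count": [w.stroke_count for w in self.words],
                "concept_id": [w.concept_id for w in self.words],
                "list_id": [w.list_id for w in self.words],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StimulusSet":
        words = [
            Word(
                word_id=str(r.word_id),
                syllables=tuple(str(r.syllables).split("-")),
                stroke_count=int(r.stroke_count),
                concept_id=str(r.concept_id),
                list_id=int(r.list_id),
            )
            for r in frame.itertuples()
        ]
        return cls(words)

    def reorder(self, order: list[int]) -> "StimulusSet":
        return StimulusSet([self.words[i] for i in order])


class Taxonomy:
    """Single-rooted concept tree with the root at depth 1.

    Rooting the tree at depth 1 (rather than 0) keeps Wu–Palmer similarity
    well defined even when the lowest common subsumer of two concepts is the
    root itself: 2*depth(root) / (depth(a) + depth(b)) is then positive.
    """

    def __init__(self, parent: dict[str, str]):
        nodes = set(parent) | set(parent.values())
        roots = [n for n in nodes if n not in parent]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.parent = dict(parent)
        # depth by walking to the root; also detects cycles
        self._depth: dict[str, int] = {self.root: 1}
        for n in nodes:
            chain = []
            cur = n
            while cur not in self._depth:
                chain.append(cur)
                cur = self.parent[cur]
                if len(chain) > len(nodes):
                    raise ValueError("taxonomy contains a cycle")
            d = self._depth[cur]
            for c in reversed(chain):
                d += 1
                self._depth[c] = d
        self.nodes = nodes

    def depth(self, node: str) -> int:
        try:
            return self._depth[node]
        except KeyError:
            raise KeyError(f"concept {node!r} is not in the taxonomy") from None

    def ancestors(self, node: str) -> list[str]:
        """Node itself plus all its ancestors, ordered leaf-to-root."""
        self.depth(node)
        out = [node]
        while node != self.root:
            node = self.parent[node]
            out.append(node)
        return out

    def leaves(self) -> list[str]:
        parents = set(self.parent.values())
        return sorted(n for n in self.nodes if n not in parents)

    def lowest_common_subsumer(self, a: str, b: str) -> str:
        anc_a = self.ancestors(a)
        anc_b = set(self.ancestors(b))
        for n in anc_a:
            if n in anc_b:
                return n
        return self.root

    def wu_palmer(self, a: str, b: str) -> float:
        """Wu–Palmer similarity 2*depth(LCS) / (depth(a) + depth(b))."""
        lcs = self.lowest_common_subsumer(a, b)
        return 2.0 * self.depth(lcs) / (self.depth(a) + self.depth(b))

    def path_similarity(self, a: str, b: str) -> float:
        """1 / (1 + number of edges on the path joining a and b)."""
        lcs = self.lowest_common_subsumer(a, b)
        edges = (self.depth(a) - self.depth(lcs)) + (self.depth(b) - self.depth(lcs))
        return 1.0 / (1.0 + edges)

    def to_edges(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.parent.items()), columns=["child", "parent"]
        )[["parent", "child"]]

    @classmethod
    def from_edges(cls, frame: pd.DataFrame) -> "Taxonomy":
        return cls({str(r.child): str(r.parent) for r in frame.itertuples()})


class RDM:
    """Representational dissimilarity matrix: symmetric, zero-diagonal.

    ``level`` records what the dissimilarity measures (motor / syllabic /
    semantic for theoretical matrices, neural for 1 - Spearman matrices) and
    fixes the admissible value range ([0, 1] theoretical, [0, 2] neural).
    """

    def __init__(self, labels: list[str], values: np.ndarray, level: str):
        if level not in RDM_RANGES:
            raise ValueError(f"unknown RDM level {level!r}")
        values = np.asarray(values, dtype=float)
        check_symmetric(values)
        if values.shape[0] != len(labels):
            raise ValueError("label count must match matrix dimension")
        if np.max(np.abs(np.diag(values))) > 1e-10:
            raise ValueError("RDM diagonal must be zero")
        lo, hi = RDM_RANGES[level]
        if values.min() < lo - 1e-9 or values.max() > hi + 1e-9:
            raise ValueError(f"{level} RDM entries must lie in [{lo}, {hi}]")
        self.labels = list(labels)
        self.values = values
        self.level = level

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def triangle(self) -> np.ndarray:
        return lower_triangle(self.values)

    def reorder(self, order: list[int]) -> "RDM":
        idx = np.asarray(order)
        return RDM(
            [self.labels[i] for i in order], self.values[np.ix_(idx, idx)], self.level
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long(self) -> pd.DataFrame:
        i, j = np.tril_indices(len(self), k=-1)
        return pd.DataFrame(
            {
                "word_i": [self.labels[a] for a in i],
                "word_j": [self.labels[b] for b in j],
                "value": self.values[i, j],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, level: str) -> "RDM":
        return cls(list(frame.columns), frame.to_numpy(dtype=float), level)


@dataclass
class PatternMatrix:
    """Words x voxels response-pattern matrix for one ROI or sphere.

    ``values[i]`` is word i's multivoxel pattern; optional metadata records
    where the patterns came from (participant, condition, period, ROI).
    """

    word_ids: list[str]
    values: np.ndarray
    participant: str | None = None
    group: str | None = None
    condition: str | None = None
    period: str | None = None
    roi: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.word_ids):
            raise ValueError("values must be (n_words, n_voxels)")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class BoldRun:
    """One 4D BOLD-like acquisition with its events and motion parameters.

    data has shape (x, y, z, t); events columns are onset_s, duration_s,
    word_id, condition, period; motion is a t x 6 nuisance matrix.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    events: pd.DataFrame
    motion: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        if abs(np.linalg.det(np.asarray(self.affine))) < 1e-12:
            raise ValueError("affine must be invertible")
        duration = self.n_volumes * self.tr_seconds
        if len(self.events) and (self.events["onset_s"].max() >= duration):
            raise ValueError("event onsets must fall within the run")
        if self.motion.shape != (self.n_volumes, 6):
            raise ValueError("motion must be a (n_volumes, 6) matrix")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_seconds
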