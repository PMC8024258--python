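import numpy as np
import pytest

from grapholearn.core import StimulusSet, Taxonomy, Word
from grapholearn.synth import generate_stimuli


@pytest.fixture(scope="session")
def small_stimuli() -> tuple[StimulusSet, Taxonomy]:
    return generate_stimuli(n_words=10, seed=11)


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    """root(1) -> a,b(2); a -> a1,a2(3); b -> b1,b2(3)."""
    return Taxonomy(
        {"a": "root", "b": "root", "a1": "a", "a2": "a", "b1": "b", "b2": "b"}
    )


def make_words(specs, taxonomy_nodes=("a1", "a2", "b1", "b2")) -> StimulusSet:
    """Build a StimulusSet from (syllables, stroke_count) pairs."""
    words = []
    for i, (syll, strokes) in enumerate(specs):
        words.append(
            Word(
                word_id=f"w{i + 1:02d}",
                syllables=tuple(syll),
                stroke_count=strokes,
                concept_id=taxonomy_nodes[i % len(taxonomy_nodes)],
                list_id=1 + (i % 2),
            )
        )
    return StimulusSet(words)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
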