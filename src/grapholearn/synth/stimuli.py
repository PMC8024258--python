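"""Generate stimulus word lists and the concept taxonomy.

The real experiment used 40 unknown foreign words written in kana (2–5
syllabic characters each), split into two lists of 20, with a handwriting
stroke count per word and a WordNet concept per meaning.  The generator
emulates that structure: syllable sequences drawn from a syllabary-sized
alphabet, stroke counts uniform on a plausible hand-writing range, and
concepts placed on the leaves of a synthetic single-rooted taxonomy.
"""

from __future__ import annotations

from .._utils import rng_for
from ..core import StimulusSet, Taxonomy, Word


def generate_taxonomy(branching: int = 4, depth: int = 4, seed: int = 0) -> Taxonomy:
    """Complete ``branching``-ary concept tree; root at depth 1, leaves at ``depth``."""
    if branching < 2 or depth < 2:
        raise ValueError("taxonomy needs branching >= 2 and depth >= 2")
    parent: dict[str, str] = {}
    level = ["root"]
    for d in range(2, depth + 1):
        nxt = []
        for node in level:
            for b in range(branching):
                child = f"{node}.{b}" if node != "root" else f"c{b}"
                parent[child] = node
                nxt.append(child)
        level = nxt
    return Taxonomy(parent)


def generate_stimuli(
    n_words: int = 40,
    syllable_alphabet_size: int = 48,
    branching: int = 4,
    depth: int = 4,
    stroke_range: tuple[int, int] = (2, 20),
    syllable_range: tuple[int, int] = (2, 5),
    seed: int = 0,
) -> tuple[StimulusSet, Taxonomy]:
    """Deterministically generate ``n_words`` unique words plus their taxonomy.

    Words get 2–5 syllables (uniform) from a 48-token syllabary by default,
    stroke counts uniform on [2, 20], concepts sampled from the taxonomy
    leaves (without replacement while leaves last), and alternating list
    membership so each of the two lists holds half the words.
    """
    if n_words < 2:
        raise ValueError("need at least 2 words")
    if syllable_alphabet_size < 2:
        raise ValueError("syllable alphabet needs at least 2 tokens")
    lo, hi = syllable_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid syllable_range")
    rng = rng_for(seed, "stimuli")
    taxonomy = generate_taxonomy(branching=branching, depth=depth, seed=seed)
    leaves = taxonomy.leaves()
    if n_words <= len(leaves):
        concepts = rng.choice(leaves, size=n_words, replace=False)
    else:
        concepts = rng.choice(leaves, size=n_words, replace=True)
    alphabet = [f"sy{i:02d}" for i in range(syllable_alphabet_size)]
    seen: set[tuple[str, ...]] = set()
    words = []
    for i in range(n_words):
        for _ in range(1000):
            length = int(rng.integers(lo, hi + 1))
            syll = tuple(alphabet[j] for j in rng.integers(0, syllable_alphabet_size, length))
            if syll not in seen:
                seen.add(syll)
                break
        else:  # pragma: no cover - only reachable with a tiny alphabet
            raise ValueError("could not generate enough unique syllable sequences")
        words.append(
            Word(
                word_id=f"w{i + 1:02d}",
                syllables=syll,
                stroke_count=int(rng.integers(stroke_range[0], stroke_range[1] + 1)),
                concept_id=str(concepts[i]),
                list_id=1 + (i % 2),
            )
        )
    return StimulusSet(words), taxonomy
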