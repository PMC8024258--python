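"""Generate recall-accuracy tables with planted factorial effects.

Accuracy is modelled as binomial on the 20 test items of a word list, with a
logistic model on the success probability: effect-coded main effects of test
timing (immediate +1), learning condition (writing +1) and group (blind +1),
all their interactions, and a participant random intercept.  The binomial
floor/ceiling behaviour reproduces the variance heterogeneity and ceiling
compression that motivates the nonparametric (ART) analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .._utils import rng_for

#: Planted effects on the logit scale, mirroring the study's qualitative
#: pattern: a dominant timing effect, small overall writing and group
#: advantages, a condition x group crossover, and timing x group /
#: three-way structure.
DEFAULT_BEHAVIOR_EFFECTS: dict[str, float] = {
    "intercept": 1.3,
    "timing": 0.9,
    "condition": 0.05,
    "group": 0.15,
    "timing:condition": 0.05,
    "condition:group": 0.30,
    "timing:group": 0.15,
    "timing:condition:group": 0.15,
}


def generate_behavior(
    n_blind: int = 12,
    n_sighted: int = 18,
    effects: dict[str, float] | None = None,
    n_items: int = 20,
    subject_sd: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-form accuracy table over participants x condition x timing.

    Returns one row per participant and within cell with columns participant,
    group (blind/sighted), condition (writing/no-writing), timing
    (immediate/delayed) and accuracy in [0, 100] (percentage of ``n_items``
    recalled, binomially distributed).
    """
    if n_blind < 2 or n_sighted < 2:
        raise ValueError("each group needs at least 2 participants")
    if n_items < 1:
        raise ValueError("n_items must be positive")
    eff = dict(DEFAULT_BEHAVIOR_EFFECTS if effects is None else effects)
    b = {k: eff.get(k, 0.0) for k in DEFAULT_BEHAVIOR_EFFECTS}
    rng = rng_for(seed, "behavior")
    rows = []
    groups = ["blind"] * n_blind + ["sighted"] * n_sighted
    intercepts = rng.normal(0.0, subject_sd, size=len(groups))
    for i, (grp, u) in enumerate(zip(groups, intercepts)):
        g = 1.0 if grp == "blind" else -1.0
        for cond, c in (("writing", 1.0), ("no-writing", -1.0)):
            for timing, t in (("immediate", 1.0), ("delayed", -1.0)):
                logit = (
                    b["intercept"]
                    + u
                    + b["timing"] * t
                    + b["condition"] * c
                    + b["group"] * g
                    + b["timing:condition"] * t * c
                    + b["condition:group"] * c * g
                    + b["timing:group"] * t * g
                    + b["timing:condition:group"] * t * c * g
                )
                k = rng.binomial(n_items, expit(logit))
                rows.append(
                    {
                        "participant": f"p{i + 1:02d}",
                        "group": grp,
                        "condition": cond,
                        "timing": timing,
                        "accuracy": 100.0 * k / n_items,
                    }
                )
    return pd.DataFrame(rows)
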