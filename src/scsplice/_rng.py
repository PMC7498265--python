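"""Named random substreams.

All randomness in the package flows from a single top-level integer seed.
Each simulation stage draws from its own substream, derived deterministically
from the top seed and a stage name, so stages can be re-run or swapped
independently without perturbing the draws of the others.
"""

from __future__ import annotations

import numpy as np

#: Fixed registry of stage names; the index of a name is part of its
#: substream identity, so the order here must never change.
STAGES = (
    "exons",
    "kinetics",
    "expression",
    "psi",
    "capture",
    "reads",
    "junctions",
    "constitutive",
    "permutation",
    "misc",
)


def stage_rng(seed: int, stage: str, replicate: int = 0) -> np.random.Generator:
    """Return the Generator for one named stage under a top-level seed."""
    try:
        idx = STAGES.index(stage)
    except ValueError:
        raise ValueError(f"unknown RNG stage {stage!r}; known: {STAGES}") from None
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(idx, int(replicate)))
    return np.random.default_rng(ss)
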