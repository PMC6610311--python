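"""Seed plumbing.

All randomness in the package flows from one user-supplied integer seed.
Each stage derives its own independent stream from that seed plus a fixed
stage tag, so adding reps to one stage never perturbs another.
"""

from __future__ import annotations

import numpy as np

# Fixed per-stage tags; order is part of the reproducibility contract.
STAGE_TAGS = {
    "rarefy": 1,
    "ses_mntd": 2,
    "beta_nti": 3,
    "rc_bray": 4,
    "simulate_tree": 5,
    "evolve_trait": 6,
    "simulate_communities": 7,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for one named pipeline stage.

    The stream is ``PCG64`` seeded from ``SeedSequence([seed, tag])`` where
    ``tag`` is the fixed integer registered for the stage.
    """
    try:
        tag = STAGE_TAGS[stage]
    except KeyError:  # pragma: no cover - programming error
        raise ValueError(f"unknown rng stage {stage!r}") from None
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([int(seed), tag])))


def stage_seed_for_dendropy(seed: int, stage: str) -> int:
    """Derive a plain integer (< 2**31) for libraries taking int seeds."""
    return int(stage_rng(seed, stage).integers(0, 2**31 - 1))
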