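"""Bray-Curtis dissimilarity and the abundance-based Raup-Crick null (RC_bray).

The null asks: how dissimilar would two communities be if they were
assembled at random from the regional species pool, holding each community's
observed richness and total abundance fixed? Each null community is built in
two stages: taxa are drawn without replacement with probability proportional
to their occupancy across samples (how many samples they occur in), each
drawn taxon gets one individual, and the remaining individuals are allocated
multinomially in proportion to the taxa's total abundances in the pool.
The observed Bray-Curtis value is then ranked within the null distribution
and rescaled to [-1, +1]: values near -1 mean the two communities are far
more similar than chance assembly predicts, near +1 far less similar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .io import CommunityTable, SampleMetadata
from .nullmodels import select_pairs

__all__ = [
    "bray_curtis",
    "MetacommunityProfile",
    "metacommunity_profile",
    "null_pair_bray",
    "rc_bray",
]

# relative tolerance for observed-equals-null ties in the rank statistic
TIE_RTOL = 1e-12


def bray_curtis(abund_a: np.ndarray, abund_b: np.ndarray) -> float:
    """Bray-Curtis dissimilarity: sum |x_i - y_i| / sum (x_i + y_i)."""
    x = np.asarray(abund_a, dtype=float)
    y = np.asarray(abund_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors differ in length")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("Bray-Curtis requires both communities non-empty")
    return float(np.abs(x - y).sum() / (x + y).sum())


@dataclass
class MetacommunityProfile:
    """Regional-pool weights for the Raup-Crick null.

    ``occupancy[i]``: number of samples in which taxon i occurs;
    ``totals[i]``: taxon i's summed abundance across samples. Both are
    derived deterministically from a community table.
    """

    taxa: list[str]
    occupancy: np.ndarray
    totals: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        if np.any(self.occupancy < 0) or np.any(self.occupancy > self.n_samples):
            raise ValueError("occupancy out of range")
        if np.any(self.totals < 0):
            raise ValueError("negative abundance total")


def metacommunity_profile(table: CommunityTable) -> MetacommunityProfile:
    """Occupancy and total abundance per taxon over the table's samples."""
    counts = table.counts
    return MetacommunityProfile(
        taxa=table.taxa,
        occupancy=(counts > 0).sum(axis=1),
        totals=counts.sum(axis=1),
        n_samples=counts.shape[1],
    )


def _draw_taxa(profile: MetacommunityProfile, richness: int, reps: int, rng) -> np.ndarray:
    """Occupancy-weighted sampling of taxa without replacement, reps rows.

    Uses exponential sort keys (smallest ``Exp(1)/w`` win), which realizes
    successive draws proportional to weight without replacement.
    """
    w = profile.occupancy.astype(float)
    available = int((w > 0).sum())
    if richness > available:
        raise ValueError(
            f"requested richness {richness} exceeds {available} taxa with occupancy > 0"
        )
    keys = rng.exponential(size=(reps, w.size))
    with np.errstate(divide="ignore"):
        keys = np.where(w > 0, keys / w, np.inf)
    return np.argpartition(keys, richness - 1, axis=1)[:, :richness]


def _null_communities(
    profile: MetacommunityProfile, richness: int, total: int, reps: int, rng
) -> np.ndarray:
    """Assemble ``reps`` null communities (rows: reps x n_taxa counts)."""
    if richness < 1:
        raise ValueError("richness must be >= 1")
    if total < richness:
        raise ValueError("total abundance must be >= richness")
    chosen = _draw_taxa(profile, richness, reps, rng)
    out = np.zeros((reps, len(profile.taxa)), dtype=np.int64)
    rows = np.arange(reps)[:, None]
    out[rows, chosen] = 1
    remaining = total - richness
    if remaining > 0:
        totals = profile.totals.astype(float)
        for r in range(reps):
            p = totals[chosen[r]]
            if p.sum() <= 0:  # degenerate pool: spread evenly
                p = np.ones_like(p)
            out[r, chosen[r]] += rng.multinomial(remaining, p / p.sum())
    return out


def null_pair_bray(
    profile: MetacommunityProfile,
    richness_a: int,
    richness_b: int,
    n_a: int,
    n_b: int,
    rng: np.random.Generator,
    *,
    reps: int = 1,
    return_communities: bool = False,
):
    """Bray-Curtis between null communities with the given richness/abundance.

    Draws ``reps`` independent null community pairs and returns the
    Bray-Curtis value of each (scalar when ``reps == 1``). With
    ``return_communities`` the two (reps x n_taxa) count arrays are also
    returned, so callers can verify richness/abundance conservation.
    """
    null_a = _null_communities(profile, richness_a, n_a, reps, rng)
    null_b = _null_communities(profile, richness_b, n_b, reps, rng)
    bc = np.abs(null_a - null_b).sum(axis=1) / (null_a + null_b).sum(axis=1)
    result = float(bc[0]) if reps == 1 else bc
    if return_communities:
        return result, null_a, null_b
    return result


def rc_bray(
    table: CommunityTable,
    *,
    reps: int = 999,
    seed: int = 0,
    pairs: str = "within",
    metadata: SampleMetadata | None = None,
    group_field: str = "group",
    profile: MetacommunityProfile | None = None,
) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis for the selected sample pairs.

    Per pair, with ``obs`` the observed Bray-Curtis and ``reps`` null
    values: p = (#{null < obs} + 0.5 #{null = obs}) / reps and
    RC_bray = 2 (p - 0.5), in [-1, +1]. Ties use relative tolerance
    :data:`TIE_RTOL`. The pool (``profile``) defaults to all samples in the
    table; pass a per-group profile to scope the null regionally.

    Returns a DataFrame with columns ``sample_a, sample_b, bray_curtis,
    rc_bray, reps``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sel = select_pairs(table.samples, pairs=pairs, metadata=metadata, group_field=group_field)
    if len(sel) == 0:
        raise ValueError("no sample pairs selected")
    counts = table.counts
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("RC_bray requires every sample total > 0")
    if profile is None:
        profile = metacommunity_profile(table)
    rng = stage_rng(seed, "rc_bray")
    sample_index = {s: i for i, s in enumerate(table.samples)}
    richness = (counts > 0).sum(axis=0)

    rows = []
    for a, b in sel:
        i, j = sample_index[a], sample_index[b]
        obs = bray_curtis(counts[:, i], counts[:, j])
        null = null_pair_bray(
            profile,
            int(richness[i]),
            int(richness[j]),
            int(totals[i]),
            int(totals[j]),
            rng,
            reps=reps,
        )
        null = np.atleast_1d(null)
        tol = TIE_RTOL * max(abs(obs), 1.0)
        n_below = int((null < obs - tol).sum())
        n_tied = int((np.abs(null - obs) <= tol).sum())
        p = (n_below + 0.5 * n_tied) / reps
        rows.append((a, b, obs, 2.0 * (p - 0.5), reps))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "bray_curtis", "rc_bray", "reps"]
    )
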