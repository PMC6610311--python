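"""Nearest-taxon phylogenetic metrics and their taxa-label permutation nulls.

Implements MNTD (within one community), its standardized effect size
SES.MNTD, the between-community analogue betaMNTD, and the beta nearest
taxon index betaNTI = (observed betaMNTD - null mean) / null sd. The null
("taxa labels") shuffles taxon identities on the cached patristic distance
matrix; one permutation per randomization is shared across every sample and
sample pair so that values within a randomization remain comparable.

Sign conventions: negative SES.MNTD / betaNTI mean taxa (or turnover) are
phylogenetically closer than expected — clustering, or homogeneous
selection between communities; positive values mean overdispersion /
variable selection.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .io import CommunityTable, SampleMetadata
from .phylo import PairwiseDistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedMetricError",
    "mntd",
    "ses_mntd",
    "beta_mntd",
    "beta_nti",
    "shuffle_labels",
    "select_pairs",
]


class UndefinedMetricError(ValueError):
    """A metric has no defined value (richness < 2 or zero null spread)."""


def _check_aligned(table: CommunityTable, dist: PairwiseDistanceMatrix) -> None:
    if list(table.taxa) != list(dist.labels):
        raise ValueError(
            "community table taxa and distance-matrix labels differ; "
            "align them first (align_tree_table / reorder)"
        )


def mntd(abundances: np.ndarray, dist: PairwiseDistanceMatrix, *, weighted: bool = False) -> float:
    """Mean nearest taxon distance of one community.

    For every taxon present, the distance to its closest relative also
    present (self excluded), averaged — uniformly, or weighted by relative
    abundance.

    Raises
    ------
    UndefinedMetricError
        If fewer than two taxa are present (no nearest taxon exists).
    """
    x = np.asarray(abundances, dtype=float)
    if x.shape != (len(dist.labels),):
        raise ValueError("abundance vector length does not match distance matrix")
    present = np.flatnonzero(x > 0)
    if present.size < 2:
        raise UndefinedMetricError("MNTD undefined: fewer than 2 taxa present")
    sub = dist.d[np.ix_(present, present)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    if weighted:
        w = x[present] / x[present].sum()
        return float(nearest @ w)
    return float(nearest.mean())


def beta_mntd(
    abund_a: np.ndarray,
    abund_b: np.ndarray,
    dist: PairwiseDistanceMatrix,
    *,
    weighted: bool = False,
) -> float:
    """Between-community mean nearest taxon distance.

    0.5 * [ sum_i w_ia min_j d(i, j) + sum_j w_jb min_i d(i, j) ] over taxa
    i present in community a and j present in community b. A taxon present
    in both communities contributes 0 (its nearest taxon in the other
    community is itself). Weights are relative abundances when ``weighted``,
    else 1/richness.
    """
    xa = np.asarray(abund_a, dtype=float)
    xb = np.asarray(abund_b, dtype=float)
    n = len(dist.labels)
    if xa.shape != (n,) or xb.shape != (n,):
        raise ValueError("abundance vector length does not match distance matrix")
    ia = np.flatnonzero(xa > 0)
    ib = np.flatnonzero(xb > 0)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("betaMNTD requires both communities non-empty")
    sub = dist.d[np.ix_(ia, ib)]
    near_a = sub.min(axis=1)  # per taxon in a, nearest in b
    near_b = sub.min(axis=0)
    if weighted:
        wa = xa[ia] / xa[ia].sum()
        wb = xb[ib] / xb[ib].sum()
    else:
        wa = np.full(ia.size, 1.0 / ia.size)
        wb = np.full(ib.size, 1.0 / ib.size)
    return float(0.5 * (near_a @ wa + near_b @ wb))


def shuffle_labels(dist: PairwiseDistanceMatrix, rng: np.random.Generator) -> PairwiseDistanceMatrix:
    """One "taxa labels" randomization: jointly permute rows and columns.

    The multiset of distances is unchanged; only which taxon carries which
    distances is randomized.
    """
    p = rng.permutation(len(dist.labels))
    return PairwiseDistanceMatrix(list(dist.labels), dist.d[np.ix_(p, p)])


def select_pairs(
    samples: list[str],
    *,
    pairs: str = "within",
    metadata: SampleMetadata | None = None,
    group_field: str = "group",
) -> list[tuple[str, str]]:
    """Unordered sample pairs to analyze: all, or within each group only."""
    if pairs == "all":
        return list(itertools.combinations(samples, 2))
    if pairs == "within":
        if metadata is None:
            raise ValueError("pairs='within' requires sample metadata")
        groups = metadata.groups(group_field)
        return [
            (a, b)
            for a, b in itertools.combinations(samples, 2)
            if groups[a] == groups[b]
        ]
    raise ValueError(f"unknown pair selector {pairs!r} (expected 'within' or 'all')")


# ---------------------------------------------------------------------------
# vectorized internals shared by SES.MNTD and betaNTI


def _present_indices(counts: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(counts[:, j] > 0) for j in range(counts.shape[1])]


def _weights_matrix(counts: np.ndarray, weighted: bool) -> np.ndarray:
    """Per-sample taxon weights: relative abundance, or 1/richness over present taxa."""
    x = counts.astype(float)
    if weighted:
        return x / x.sum(axis=0, keepdims=True)
    present = (x > 0).astype(float)
    return present / present.sum(axis=0, keepdims=True)

def _mntd_all_samples(d: np.ndarray, present: list[np.ndarray], w: np.ndarray) -> np.ndarray:
    """MNTD of every sample against one distance matrix; NaN when richness < 2."""
    out = np.full(len(present), np.nan)
    for j, idx in enumerate(present):
        if idx.size < 2:
            continue
        sub = d[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        out[j] = sub.min(axis=1) @ (w[idx, j] / w[idx, j].sum())
    return out


def _beta_mntd_all_pairs(d: np.ndarray, present: list[np.ndarray], w: np.ndarray) -> np.ndarray:
    """Symmetric matrix of betaMNTD over all sample pairs for one distance matrix.

    M[i, s] = distance from taxon i to its nearest taxon present in sample s;
    then beta[a, b] = 0.5 * ((W.T M)[a, b] + (W.T M)[b, a]).
    """
    n_samp = len(present)
    m = np.empty((d.shape[0], n_samp))
    for s, idx in enumerate(present):
        m[:, s] = d[:, idx].min(axis=1)
    half = w.T @ m
    return 0.5 * (half + half.T)


def ses_mntd(
    table: CommunityTable,
    dist: PairwiseDistanceMatrix,
    *,
    reps: int = 999,
    weighted: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Standardized effect size of MNTD per sample under the taxa-label null.

    SES.MNTD = (observed MNTD - null mean) / null sd with ``reps``
    randomizations; one label permutation per randomization is shared across
    all samples. Samples with richness < 2, or whose null distribution has
    zero spread, are flagged undefined (``ses_mntd`` NaN).

    Returns a DataFrame with columns ``sample_id, mntd_obs, ses_mntd,
    null_mean, null_sd, reps, weighted, undefined``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    _check_aligned(table, dist)
    rng = stage_rng(seed, "ses_mntd")
    counts = table.counts
    present = _present_indices(counts)
    w = _weights_matrix(counts, weighted)
    obs = _mntd_all_samples(dist.d, present, w)

    n = len(dist.labels)
    null = np.empty((reps, len(present)))
    for r in range(reps):
        p = rng.permutation(n)
        dp = dist.d[np.ix_(p, p)]
        null[r] = _mntd_all_samples(dp, present, w)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1) if reps > 1 else np.zeros(len(present))

    with np.errstate(invalid="ignore", divide="ignore"):
        ses = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)
    undefined = np.isnan(obs) | ~(null_sd > 0)
    ses = np.where(undefined, np.nan, ses)
    n_undef = int(undefined.sum())
    if n_undef:
        msg = f"SES.MNTD undefined for {n_undef} of {len(present)} samples"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return pd.DataFrame(
        {
            "sample_id": table.samples,
            "mntd_obs": obs,
            "ses_mntd": ses,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "reps": reps,
            "weighted": weighted,
            "undefined": undefined,
        }
    )


def beta_nti(
    table: CommunityTable,
    dist: PairwiseDistanceMatrix,
    *,
    reps: int = 999,
    weighted: bool = False,
    seed: int = 0,
    pairs: str = "within",
    metadata: SampleMetadata | None = None,
    group_field: str = "group",
) -> pd.DataFrame:
    """betaNTI for the selected sample pairs under the taxa-label null.

    For each unordered pair, betaNTI = (observed betaMNTD - null mean
    betaMNTD) / null sd, where each of the ``reps`` randomizations applies a
    single label permutation of the distance matrix shared by every pair.
    Pairs whose null sd is 0 are flagged undefined.

    Returns a DataFrame with columns ``sample_a, sample_b, beta_mntd,
    null_mean, null_sd, beta_nti, reps, weighted, undefined``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    _check_aligned(table, dist)
    sel = select_pairs(table.samples, pairs=pairs, metadata=metadata, group_field=group_field)
    if len(sel) == 0:
        raise ValueError("no sample pairs selected")
    rng = stage_rng(seed, "beta_nti")
    counts = table.counts
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("betaNTI requires every sample non-empty")
    present = _present_indices(counts)
    w = _weights_matrix(counts, weighted)
    obs = _beta_mntd_all_pairs(dist.d, present, w)

    n = len(dist.labels)
    s1 = np.zeros_like(obs)
    s2 = np.zeros_like(obs)
    for _ in range(reps):
        p = rng.permutation(n)
        dp = dist.d[np.ix_(p, p)]
        b = _beta_mntd_all_pairs(dp, present, w)
        s1 += b
        s2 += b * b
    null_mean = s1 / reps
    null_var = (s2 - reps * null_mean**2) / (reps - 1) if reps > 1 else np.zeros_like(obs)
    null_sd = np.sqrt(np.clip(null_var, 0.0, None))

    sample_index = {s: i for i, s in enumerate(table.samples)}
    rows = []
    n_undef = 0
    for a, b in sel:
        i, j = sample_index[a], sample_index[b]
        sd = null_sd[i, j]
        undefined = not sd > 1e-15
        value = np.nan if undefined else (obs[i, j] - null_mean[i, j]) / sd
        n_undef += undefined
        rows.append((a, b, obs[i, j], null_mean[i, j], sd, value, reps, weighted, undefined))
    if n_undef:
        msg = f"betaNTI undefined for {n_undef} of {len(sel)} pairs (null sd = 0)"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=[
            "sample_a",
            "sample_b",
            "beta_mntd",
            "null_mean",
            "null_sd",
            "beta_nti",
            "reps",
            "weighted",
            "undefined",
        ],
    )
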