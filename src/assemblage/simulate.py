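"""Synthetic communities with known assembly processes.

Generates the three artifacts the pipeline consumes — a phylogeny, a count
table, and sample metadata — under controlled scenarios, so that process
inference can be validated against a known truth:

* a pure-birth (Yule) ultrametric tree scaled to root depth 1;
* a niche trait evolving by Brownian motion along the tree, which makes
  niches phylogenetically conserved;
* per-sample communities assembled by scenario: Gaussian environmental
  filtering on the trait (homogeneous selection: one shared environment;
  variable selection: well-separated environments per group), neutral
  multinomial sampling from one shared log-normal pool, founder-pool
  subsampling (strong drift / dispersal limitation), or mass-effect mixing
  toward the pooled mean community (homogenizing dispersal).

Nearest-taxon indices can only detect selection when the niche is
phylogenetically conserved at the clade level, and with a regional pool of
~10^2 taxa a single Brownian trait realizes such clade-level structure only
sometimes. The selection scenarios therefore (i) act on a finite *guild* —
the ``guild_size`` taxa whose traits lie closest to the environmental
optimum, with the Gaussian filter width tied to the guild's trait spread —
and (ii) condition the trait realization on the guild being phylogenetically
compact (its mean nearest-taxon distance at most ``conservatism_ratio``
times that of random taxon sets), redrawing the Brownian trait
deterministically until the precondition holds. Without that precondition
the scenario would not represent selection that these metrics are, even in
principle, able to see.

Counts are multinomial with a fixed per-sample depth, mirroring a table
already rarefied to even depth.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._rng import stage_rng, stage_seed_for_dendropy
from .io import CommunityTable, PhyloTree, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "simulate_tree",
    "evolve_trait",
    "guild_conservatism",
    "simulate_communities",
    "simulate_dataset",
    "write_dataset",
]

SCENARIOS = [
    "homogeneous_selection",
    "variable_selection",
    "drift",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "neutral",
]

_SELECTION = {"homogeneous_selection", "variable_selection"}

# group labels mirroring soil-horizon naming when four or fewer groups are used
_HORIZON_NAMES = ["Oi", "Oe", "OA", "A"]

# per-sample log-abundance noise (ecological drift) by scenario when not set
_DEFAULT_NOISE = {
    "homogeneous_selection": 2.5,
    "variable_selection": 2.5,
    "homogenizing_dispersal": 2.5,
    "neutral": 0.2,
    "drift": 0.0,
    "dispersal_limitation": 0.75,
}


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic-community scenario.

    Defaults mirror the structure of a horizon-resolved soil 16S survey:
    128 OTUs, 4 groups x 6 samples, every sample at depth 1,073 reads.

    Parameters
    ----------
    filter_width
        sigma_f of the Gaussian environmental filter, in trait units. Used
        directly when ``guild_size`` is None; in guild mode the realized
        width is instead tied to the guild's trait spread (radius / 2).
    trait_sigma
        sigma of Brownian trait evolution, in trait units per unit branch
        length (the tree has root depth 1, so tip trait sd ~ trait_sigma).
    migration_rate
        Fraction of each sample drawn from the pooled mean community;
        ``None`` selects the scenario default (0.95 for homogenizing
        dispersal, 0 elsewhere).
    env_separation
        Spacing of group environments for non-guild variable selection, in
        units of ``filter_width``.
    pool_sigma
        Log-sd of the shared log-normal regional pool abundances.
    founder_size
        Individuals in the per-sample founder pool for the drift and
        dispersal-limitation scenarios (smaller = stronger drift).
    noise_sigma
        Log-sd of per-sample abundance fluctuations (demographic noise /
        drift acting alongside the scenario's deterministic structure);
        ``None`` selects the scenario default.
    guild_size
        Number of taxa in a selection scenario's niche guild; ``None``
        disables guild mode (pure Gaussian filter of ``filter_width``).
    conservatism_ratio
        Maximum allowed guild mean nearest-taxon distance relative to
        random taxon sets; the Brownian trait is redrawn (deterministically,
        at most ``max_trait_draws`` times) until the best guild satisfies
        it. ``None`` disables the conditioning.
    """

    scenario: str = "neutral"
    n_taxa: int = 128
    n_samples_per_group: int = 6
    n_groups: int = 4
    depth: int = 1073
    filter_width: float = 0.3
    trait_sigma: float = 1.0
    migration_rate: float | None = None
    seed: int = 0
    env_separation: float = 4.0
    pool_sigma: float = 1.0
    founder_size: int = 64
    noise_sigma: float | None = None
    guild_size: int | None = 16
    conservatism_ratio: float | None = 0.30
    max_trait_draws: int = 50

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        for name in ("n_taxa", "n_samples_per_group", "n_groups", "depth", "founder_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.filter_width <= 0:
            raise ValueError("filter_width must be > 0")
        if self.trait_sigma < 0:
            raise ValueError("trait_sigma must be >= 0")
        if self.migration_rate is not None and not 0 <= self.migration_rate <= 1:
            raise ValueError("migration_rate must be in [0, 1]")
        if self.guild_size is not None and not 2 <= self.guild_size <= self.n_taxa:
            raise ValueError("guild_size must be in [2, n_taxa]")

    @property
    def effective_migration(self) -> float:
        if self.migration_rate is not None:
            return self.migration_rate
        return 0.95 if self.scenario == "homogenizing_dispersal" else 0.0

    @property
    def effective_noise(self) -> float:
        if self.noise_sigma is not None:
            return self.noise_sigma
        return _DEFAULT_NOISE[self.scenario]

    def group_names(self) -> list[str]:
        if self.n_groups <= len(_HORIZON_NAMES):
            return _HORIZON_NAMES[: self.n_groups]
        return [f"G{k + 1}" for k in range(self.n_groups)]


def simulate_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with ``n_taxa`` tips, root depth 1.

    Tips are labeled ``OTU_0001 ...``; branch lengths are rescaled so every
    root-to-tip path has length exactly 1.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    from dendropy.model import birthdeath

    rnd = random.Random(stage_seed_for_dendropy(seed, "simulate_tree"))
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rnd,
    )
    # the generator stops at the n-th birth, leaving the newest sister pair
    # with zero-length tips; extend every tip by the waiting time to the
    # next (unrealized) speciation so the tree is sampled between events
    extra = rnd.expovariate(n_taxa * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    # time before the first split lives on the root edge and contributes no
    # divergence between tips; drop it before depth normalization
    tree.seed_node.edge.length = 0.0
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.tail_node is not None:
            edge.length = edge.length / depth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU_{i + 1:04d}"
    return PhyloTree(tree)


def _brownian(tree: PhyloTree, trait_sigma: float, rng: np.random.Generator) -> pd.Series:
    values: dict[int, float] = {}
    out = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = 0.0
        else:
            bl = node.edge.length or 0.0
            step = rng.normal(0.0, trait_sigma * np.sqrt(bl)) if bl > 0 else 0.0
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out, name="trait")


def evolve_trait(tree: PhyloTree, trait_sigma: float, seed: int) -> pd.Series:
    """Evolve one trait by Brownian motion from a root value of 0.

    Along each branch the trait takes an independent Normal(0,
    trait_sigma^2 * branch_length) step, so tip trait variance equals
    trait_sigma^2 times root-to-tip path length and covariance between tips
    equals trait_sigma^2 times their shared path length.
    """
    if trait_sigma < 0:
        raise ValueError("trait_sigma must be >= 0")
    return _brownian(tree, trait_sigma, stage_rng(seed, "evolve_trait"))


def _mean_nn_distance(d: np.ndarray, idx: np.ndarray) -> float:
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def guild_conservatism(
    trait_values: np.ndarray, d: np.ndarray, guild_size: int
) -> tuple[float, float]:
    """Best environmental optimum and its guild's phylogenetic compactness.

    Scans candidate optima over trait quantiles; for each, the guild is the
    ``guild_size`` taxa with traits closest to the optimum. Returns the
    optimum minimizing the guild's mean nearest-taxon distance, and that
    distance divided by the average over random taxon sets of the same size
    (ratio 1 = no conservatism; well below 1 = clade-like guild).
    """
    n = len(trait_values)
    if not 2 <= guild_size <= n:
        raise ValueError("guild_size out of range")
    base_rng = np.random.default_rng(12345)  # fixed: diagnostic baseline only
    baseline = np.mean(
        [_mean_nn_distance(d, base_rng.choice(n, guild_size, replace=False)) for _ in range(200)]
    )
    best, best_env = np.inf, 0.0
    for env in np.quantile(trait_values, np.linspace(0.05, 0.95, 31)):
        idx = np.argsort(np.abs(trait_values - env))[:guild_size]
        m = _mean_nn_distance(d, idx)
        if m < best:
            best, best_env = m, env
    return best_env, best / baseline


def _conserved_trait(
    tree: PhyloTree, config: ScenarioConfig, d: np.ndarray
) -> pd.Series:
    """Brownian trait conditioned on guild-level phylogenetic conservatism.

    Redraws the trait with a deterministic per-attempt stream until the best
    guild's compactness ratio is at or below ``conservatism_ratio``; if no
    draw within ``max_trait_draws`` qualifies, the most conserved draw is
    used (with a logged note).
    """
    best_traits, best_ratio = None, np.inf
    for attempt in range(config.max_trait_draws):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([int(config.seed), 6, attempt]))
        )
        traits = _brownian(tree, config.trait_sigma, rng)
        tv = traits.loc[tree.tip_labels].to_numpy()
        _, ratio = guild_conservatism(tv, d, config.guild_size)
        if ratio < best_ratio:
            best_traits, best_ratio = traits, ratio
        if ratio <= config.conservatism_ratio:
            return traits
    logger.info(
        "no trait draw reached conservatism ratio %.2f within %d attempts; "
        "using best (%.2f)",
        config.conservatism_ratio,
        config.max_trait_draws,
        best_ratio,
    )
    return best_traits


def _tip_distance_matrix(tree: PhyloTree) -> np.ndarray:
    from .phylo import cophenetic_matrix

    return cophenetic_matrix(tree, labels=tree.tip_labels).d


def _guild_filter(tv: np.ndarray, env: float, guild_size: int) -> np.ndarray:
    """Gaussian filter restricted to the guild_size trait-nearest taxa.

    The guild radius (trait distance of the guild's outermost member) sets
    the realized niche width: sigma = radius / 2, and weight is zero beyond
    the radius (a hard physiological tolerance limit).
    """
    dist = np.abs(tv - env)
    radius = np.sort(dist)[guild_size - 1]
    if radius <= 0:
        return (dist <= 0).astype(float)
    sigma = radius / 2.0
    w = np.where(dist <= radius, np.exp(-0.5 * (dist / sigma) ** 2), 0.0)
    return w


def _gaussian_filter(tv: np.ndarray, env: float, sigma_f: float) -> np.ndarray:
    z = (tv - env) / sigma_f
    w = np.exp(-0.5 * z * z)
    if w.sum() <= 0:  # environment far outside the trait range
        w = np.ones_like(w)
    return w


def _group_envs(config: ScenarioConfig, tv: np.ndarray) -> np.ndarray:
    """Environment optimum per group for variable selection."""
    if config.guild_size is not None:
        qs = np.linspace(0.1, 0.9, config.n_groups)
        return np.quantile(tv, qs)
    step = config.env_separation * config.filter_width
    offsets = np.arange(config.n_groups) - (config.n_groups - 1) / 2.0
    return offsets * step


def simulate_communities(
    config: ScenarioConfig, tree: PhyloTree, traits: pd.Series
) -> tuple[CommunityTable, SampleMetadata]:
    """Assemble per-sample communities under the configured scenario.

    Returns a count table (taxa in tree tip order, one column per sample)
    and metadata mapping each sample to its group. Sample IDs are
    ``<group>_<replicate>``; every column sums exactly to ``config.depth``.
    """
    missing = [t for t in tree.tip_labels if t not in traits.index]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:5]}...")
    rng = stage_rng(config.seed, "simulate_communities")
    taxa = tree.tip_labels
    tv = traits.loc[taxa].to_numpy(dtype=float)
    n = len(taxa)
    noise = config.effective_noise
    m = config.effective_migration

    pool = np.exp(rng.normal(0.0, config.pool_sigma, size=n))
    pool /= pool.sum()

    # deterministic per-scenario structure shared by all samples
    if config.scenario == "homogeneous_selection":
        if config.guild_size is not None:
            env, _ = guild_conservatism(tv, _tip_distance_matrix(tree), config.guild_size)
            base = _guild_filter(tv, env, config.guild_size)
        else:
            base = _gaussian_filter(tv, 0.0, config.filter_width)
    elif config.scenario == "variable_selection":
        envs = _group_envs(config, tv)
        if config.guild_size is not None:
            group_base = [_guild_filter(tv, e, config.guild_size) for e in envs]
        else:
            group_base = [_gaussian_filter(tv, e, config.filter_width) for e in envs]

    columns = {}
    meta_rows = []
    for g, group in enumerate(config.group_names()):
        for k in range(config.n_samples_per_group):
            sample = f"{group}_{k + 1}"
            if config.scenario == "homogeneous_selection":
                expected = base * np.exp(rng.normal(0.0, noise, size=n)) if noise else base
            elif config.scenario == "variable_selection":
                expected = (
                    group_base[g] * np.exp(rng.normal(0.0, noise, size=n))
                    if noise
                    else group_base[g]
                )
            elif config.scenario == "neutral":
                expected = pool * np.exp(rng.normal(0.0, noise, size=n)) if noise else pool
            elif config.scenario == "homogenizing_dispersal":
                local = pool * np.exp(rng.normal(0.0, noise, size=n))
                local /= local.sum()
                expected = (1 - m) * local + m * pool
            elif config.scenario == "dispersal_limitation":
                # each sample assembles from its own dispersal neighborhood:
                # a strongly perturbed view of the regional pool, so samples
                # diverge compositionally more than chance assembly allows
                local = pool * np.exp(rng.normal(0.0, noise, size=n))
                local /= local.sum()
                expected = (1 - m) * local + m * pool
            else:  # drift: founder subsampling from the common pool
                founders = rng.multinomial(config.founder_size, pool)
                local = founders / config.founder_size
                expected = (1 - m) * local + m * pool
            columns[sample] = rng.multinomial(config.depth, expected / expected.sum())
            meta_rows.append((sample, group))

    table = CommunityTable(
        pd.DataFrame(columns, index=pd.Index(taxa, name="taxon"), dtype=np.int64)
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {"group": [g for _, g in meta_rows]},
            index=pd.Index([s for s, _ in meta_rows], name="sample_id"),
        )
    )
    return table, meta


def simulate_dataset(config: ScenarioConfig):
    """Tree + traits + communities in one call.

    For selection scenarios with guild mode and a conservatism threshold the
    trait is the conditioned draw (see module docstring); other scenarios
    use the plain Brownian draw. Returns ``(tree, traits, table, metadata,
    truth)`` where ``truth`` records the generating scenario and parameters.
    """
    tree = simulate_tree(config.n_taxa, config.seed)
    if (
        config.scenario in _SELECTION
        and config.guild_size is not None
        and config.conservatism_ratio is not None
    ):
        traits = _conserved_trait(tree, config, _tip_distance_matrix(tree))
    else:
        traits = evolve_trait(tree, config.trait_sigma, config.seed)
    table, metadata = simulate_communities(config, tree, traits)
    truth = {"scenario": config.scenario, "parameters": asdict(config)}
    return tree, traits, table, metadata, truth


def write_dataset(config: ScenarioConfig, outdir) -> dict:
    """Simulate and write tree.nwk, table.tsv, metadata.tsv and truth.json."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, traits, table, metadata, truth = simulate_dataset(config)
    _io.write_newick(tree, outdir / "tree.nwk")
    _io.write_community_table(table, outdir / "table.tsv")
    _io.write_metadata(metadata, outdir / "metadata.tsv")
    traits.rename_axis("taxon").to_csv(outdir / "traits.tsv", sep="\t")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
    return truth
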