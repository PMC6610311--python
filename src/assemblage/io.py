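"""Input/output and preprocessing for trees, OTU tables and metadata.

The contract formats are plain text: Newick for trees (rooted, branch
lengths required), tab-separated tables for counts / metadata / pairwise
results, and JSON for process summaries. Rarefaction (random subsampling of
each sample to a common depth, without replacement) lives here because it is
the one preprocessing step the downstream null models assume has happened.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._rng import stage_rng

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "CommunityTable",
    "SampleMetadata",
    "read_newick",
    "write_newick",
    "read_community_table",
    "write_community_table",
    "read_metadata",
    "write_metadata",
    "align_tree_table",
    "rarefy",
    "write_turnover_results",
    "read_turnover_results",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violate a structural invariant."""


@dataclass
class PhyloTree:
    """A rooted phylogeny with branch lengths, over unique tip labels.

    Thin wrapper around a :class:`dendropy.Tree`; construction validates the
    invariants every downstream null model relies on (>= 2 tips, unique tip
    labels, finite non-negative branch lengths on every non-root edge).
    """

    tree: dendropy.Tree
    tip_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.tree.is_rooted = True
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) < 2:
            raise ValidationError("tree must have at least 2 tips")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge; length optional
                continue
            bl = edge.length
            if bl is None:
                raise ValidationError(
                    f"missing branch length on edge above "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else 'an internal node'}"
                )
            if not np.isfinite(bl) or bl < 0:
                raise ValidationError(f"invalid branch length {bl!r}")
        self.tip_labels = labels

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def pruned_to(self, labels) -> "PhyloTree":
        """Return a copy retaining only the given tip labels."""
        keep = set(labels)
        clone = self.tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        return PhyloTree(clone)

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


@dataclass
class CommunityTable:
    """Taxa x samples matrix of non-negative integer counts.

    ``data`` is a pandas DataFrame with taxon IDs as the index and sample
    IDs as columns; row/column order is preserved through every operation.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.size == 0:
            raise ValidationError("community table is empty")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValidationError("duplicate taxon or sample IDs")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class SampleMetadata:
    """Maps each sample ID to a group label (e.g. soil horizon)."""

    data: pd.DataFrame  # index: sample_id; columns include at least one group field

    def group_of(self, sample: str, group_field: str = "group") -> str:
        return str(self.data.loc[sample, group_field])

    def groups(self, group_field: str = "group") -> pd.Series:
        return self.data[group_field].astype(str)

    def check_covers(self, table: CommunityTable, group_field: str = "group") -> None:
        missing = [s for s in table.samples if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")
        if group_field not in self.data.columns:
            raise ValidationError(f"metadata lacks group field {group_field!r}")


# ---------------------------------------------------------------------------
# readers / writers


def read_newick(path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    path = Path(path)
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        if "DuplicateTaxon" in type(exc).__name__:
            raise ValidationError(f"{path}: duplicate tip labels: {exc}") from exc
        raise FormatError(f"cannot parse {path} as Newick: {exc}") from exc
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.as_newick() + "\n")


def read_community_table(path, *, samples_as_rows: bool = False) -> CommunityTable:
    """Read a TSV count table (taxa as rows by default).

    Parameters
    ----------
    samples_as_rows
        Accept the transposed layout (samples as rows, taxa as columns),
        as exported by some pipelines; the table is transposed back.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    if df.size == 0:
        raise ValidationError(f"{path}: empty table")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    frac = numeric.to_numpy() % 1
    if (frac != 0).any():
        r, c = np.argwhere(frac != 0)[0]
        raise ValidationError(
            f"{path}: non-integer count {numeric.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r}"
        )
    counts = numeric.astype(np.int64)
    if samples_as_rows:
        counts = counts.T
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CommunityTable(counts)


def write_community_table(table: CommunityTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="taxon")


def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata TSV (first column: sample ID)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample IDs")
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# preprocessing


def align_tree_table(
    tree: PhyloTree, table: CommunityTable
) -> tuple[PhyloTree, CommunityTable]:
    """Prune tree and table to their shared taxa.

    Retained taxa keep the table's row order; names dropped from either side
    are logged as warnings. Fails if fewer than two taxa are shared.
    """
    tips = set(tree.tip_labels)
    rows = set(table.taxa)
    shared = tips & rows
    if len(shared) < 2:
        raise ValidationError(
            f"tree and table share only {len(shared)} taxa; need at least 2"
        )
    dropped_tips = sorted(tips - rows)
    dropped_rows = sorted(rows - tips)
    if dropped_tips:
        msg = f"dropping {len(dropped_tips)} tree tips absent from table: {dropped_tips}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if dropped_rows:
        msg = f"dropping {len(dropped_rows)} table taxa absent from tree: {dropped_rows}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if not dropped_tips and not dropped_rows:
        return tree, table
    keep_order = [t for t in table.taxa if t in shared]
    new_table = CommunityTable(table.data.loc[keep_order])
    new_tree = tree.pruned_to(shared) if dropped_tips else tree
    return new_tree, new_table


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` reads, without replacement.

    Each column is a multivariate-hypergeometric draw from its own counts, so
    retained columns sum to ``depth`` exactly. Samples with fewer than
    ``depth`` reads are dropped with a warning; identical seeds give
    identical output.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = stage_rng(seed, "rarefy")
    counts = table.counts
    totals = counts.sum(axis=0)
    kept_cols = []
    out = {}
    for j, sample in enumerate(table.samples):
        if totals[j] < depth:
            msg = (
                f"sample {sample!r} has {totals[j]} reads < depth {depth}; dropped"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        out[sample] = rng.multivariate_hypergeometric(counts[:, j], depth)
        kept_cols.append(sample)
    if not kept_cols:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    df = pd.DataFrame(out, index=table.data.index, columns=kept_cols, dtype=np.int64)
    return CommunityTable(df)


# ---------------------------------------------------------------------------
# pairwise results

RESULT_COLUMNS = [
    "sample_a",
    "sample_b",
    "group_a",
    "group_b",
    "beta_mntd",
    "beta_nti",
    "bray_curtis",
    "rc_bray",
    "process_label",
]


def write_turnover_results(results: pd.DataFrame, path) -> None:
    """Write per-pair turnover results as a long-format TSV.

    One row per unordered sample pair, in lexicographic (sample_a, sample_b)
    order; columns are fixed by :data:`RESULT_COLUMNS`.
    """
    if results is None or len(results) == 0:
        raise ValidationError("no turnover results to write")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValidationError(f"results missing columns: {missing}")
    out = results[RESULT_COLUMNS].copy()
    swap = out["sample_a"] > out["sample_b"]
    if swap.any():
        cols_a = ["sample_a", "group_a"]
        cols_b = ["sample_b", "group_b"]
        a_vals = out.loc[swap, cols_a].to_numpy()
        out.loc[swap, cols_a] = out.loc[swap, cols_b].to_numpy()
        out.loc[swap, cols_b] = a_vals
    out = out.sort_values(["sample_a", "sample_b"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_turnover_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_a": str, "sample_b": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df
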