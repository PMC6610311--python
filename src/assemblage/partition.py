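"""Partition pairwise community turnover into ecological assembly processes.

Joint thresholds on betaNTI and RC_bray assign each sample pair to one of
five processes: deterministic selection when phylogenetic turnover deviates
from the null (betaNTI < -2: homogeneous selection; betaNTI > +2: variable
selection), otherwise compositional turnover decides among the stochastic
processes (RC_bray > +0.95: dispersal limitation; RC_bray < -0.95:
homogenizing dispersal; |RC_bray| <= 0.95: undominated, i.e. no single
dominant process). Group-level summaries report the fraction of pairs per
process — the per-horizon stacked-bar view of assembly.
"""

from __future__ import annotations

import json
import logging
import math
import warnings

import pandas as pd

from .io import SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "PROCESS_LABELS",
    "classify_pair",
    "classify_results",
    "partition_fractions",
    "summary_to_tidy",
    "write_summary_json",
]

PROCESS_LABELS = [
    "homogeneous_selection",
    "variable_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "undominated",
]

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


def classify_pair(beta_nti: float, rc_bray: float) -> str:
    """Assign one sample pair to an assembly process.

    Strict inequalities at the thresholds: exactly |betaNTI| = 2 is not
    selection and exactly |RC_bray| = 0.95 is undominated. Non-finite
    inputs yield ``"undefined"``.
    """
    if beta_nti is None or rc_bray is None:
        return "undefined"
    if not (math.isfinite(beta_nti) and math.isfinite(rc_bray)):
        return "undefined"
    if beta_nti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if beta_nti > BNTI_THRESHOLD:
        return "variable_selection"
    if rc_bray > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_bray < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def classify_results(results: pd.DataFrame) -> pd.DataFrame:
    """Add a ``process_label`` column from ``beta_nti`` and ``rc_bray``."""
    out = results.copy()
    out["process_label"] = [
        classify_pair(b, r) for b, r in zip(out["beta_nti"], out["rc_bray"])
    ]
    return out


def partition_fractions(
    results: pd.DataFrame,
    metadata: SampleMetadata,
    *,
    group_field: str = "group",
) -> dict:
    """Per-group fractions of the five assembly processes.

    Only within-group pairs enter a group's summary. Pairs labeled
    ``undefined`` are counted (``n_undefined``) but excluded from the
    denominator, so the five fractions sum to 1 over defined pairs. Groups
    with fewer than two samples are omitted with a warning.

    Returns ``{group: {"fractions": {process: f}, "n_pairs": int,
    "n_undefined": int}}``.
    """
    groups = metadata.groups(group_field)
    missing = sorted(
        {s for s in pd.concat([results["sample_a"], results["sample_b"]]) if s not in groups.index}
    )
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    labels = results["process_label"] if "process_label" in results else None
    if labels is None:
        results = classify_results(results)

    summary: dict = {}
    for group in sorted(groups.unique()):
        members = set(groups.index[groups == group])
        if len(members) < 2:
            msg = f"group {group!r} has < 2 samples; omitted from summary"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        mask = results["sample_a"].isin(members) & results["sample_b"].isin(members)
        sub = results.loc[mask]
        defined = sub.loc[sub["process_label"] != "undefined"]
        n_def = len(defined)
        counts = defined["process_label"].value_counts()
        fractions = {
            label: (float(counts.get(label, 0)) / n_def if n_def else 0.0)
            for label in PROCESS_LABELS
        }
        summary[group] = {
            "fractions": fractions,
            "n_pairs": n_def,
            "n_undefined": int(len(sub) - n_def),
        }
    return summary


def summary_to_tidy(summary: dict) -> pd.DataFrame:
    """Flatten a process summary into a tidy (group, process, fraction) table."""
    rows = [
        (group, process, entry["fractions"][process], entry["n_pairs"])
        for group, entry in summary.items()
        for process in PROCESS_LABELS
    ]
    return pd.DataFrame(rows, columns=["group", "process", "fraction", "n_pairs"])


def write_summary_json(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
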