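"""End-to-end orchestration: rarefy -> align -> distances -> nulls -> partition.

A run is fully described by a :class:`RunConfig` (paths, rarefaction depth,
null-model settings, seed, output directory); identical configs and seeds
produce byte-identical numeric outputs. Each run writes:

* ``ses_mntd.tsv`` — per-sample MNTD and SES.MNTD;
* ``turnover.tsv`` — per-pair betaMNTD, betaNTI, Bray-Curtis, RC_bray and
  the assigned assembly process;
* ``process_summary.json`` — per-group process fractions;
* ``provenance.json`` — config echo, seed, package versions and every
  warning emitted during the run.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, nullmodels, partition, phylo, raupcrick

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "PipelineError", "validate_config", "run_pipeline"]

_DEFAULTS = {
    "depth": 1073,
    "weighted": False,
    "reps_bnti": 999,
    "reps_rc": 999,
    "pairs": "within",
    "group_field": "group",
    "seed": 0,
}


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    tree: str
    table: str
    metadata: str
    outdir: str
    depth: int = _DEFAULTS["depth"]
    weighted: bool = _DEFAULTS["weighted"]
    reps_bnti: int = _DEFAULTS["reps_bnti"]
    reps_rc: int = _DEFAULTS["reps_rc"]
    pairs: str = _DEFAULTS["pairs"]
    group_field: str = _DEFAULTS["group_field"]
    seed: int = _DEFAULTS["seed"]
    config_warnings: list[str] = field(default_factory=list, repr=False)

    def validate(self) -> list[str]:
        errors = []
        for name in ("tree", "table", "metadata"):
            p = getattr(self, name)
            if not p:
                errors.append(f"{name}: path required")
            elif not Path(p).is_file():
                errors.append(f"{name}: file not found: {p}")
        if self.depth < 1:
            errors.append(f"depth: must be >= 1, got {self.depth}")
        if self.reps_bnti < 1:
            errors.append(f"reps_bnti: must be >= 1, got {self.reps_bnti}")
        if self.reps_rc < 1:
            errors.append(f"reps_rc: must be >= 1, got {self.reps_rc}")
        if self.pairs not in ("within", "all"):
            errors.append(f"pairs: must be 'within' or 'all', got {self.pairs!r}")
        return errors


def validate_config(path, overrides: dict | None = None) -> RunConfig:
    """Load and validate a TOML run configuration.

    Unknown keys produce warnings and are ignored; every invariant
    violation is collected and reported together in a :class:`ConfigError`
    rather than failing at the first problem. ``overrides`` (e.g. CLI
    flags) take precedence over file values.
    """
    import tomllib

    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigError([f"config file not found: {path}"]) from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError([f"cannot parse {path}: {exc}"]) from exc

    known = {f for f in RunConfig.__dataclass_fields__ if f != "config_warnings"}
    config_warnings = []
    for key in sorted(set(raw) - known):
        msg = f"unknown config key {key!r} ignored"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        config_warnings.append(msg)
        raw.pop(key)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    errors = [f"{name}: required" for name in ("tree", "table", "metadata", "outdir") if name not in raw]
    if errors:
        raise ConfigError(errors)
    cfg = RunConfig(**raw)
    cfg.config_warnings = config_warnings
    errors = cfg.validate()
    if errors:
        raise ConfigError(errors)
    return cfg


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""

    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    return _Guard()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full assembly-process analysis described by ``config``.

    Returns a dict of output paths plus the in-memory process summary.
    """
    errors = config.validate()
    if errors:
        raise ConfigError(errors)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    captured: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        with _stage("read_inputs"):
            tree = io.read_newick(config.tree)
            table = io.read_community_table(config.table)
            metadata = io.read_metadata(config.metadata)
        with _stage("rarefy"):
            table = io.rarefy(table, config.depth, config.seed)
            metadata.check_covers(table, config.group_field)
        with _stage("align"):
            tree, table = io.align_tree_table(tree, table)
        with _stage("cophenetic"):
            dist = phylo.cophenetic_matrix(tree, labels=table.taxa)
        with _stage("ses_mntd"):
            ses = nullmodels.ses_mntd(
                table, dist, reps=config.reps_bnti, weighted=False, seed=config.seed
            )
            ses.to_csv(outdir / "ses_mntd.tsv", sep="\t", index=False, float_format="%.10g")
        with _stage("beta_nti"):
            bnti = nullmodels.beta_nti(
                table,
                dist,
                reps=config.reps_bnti,
                weighted=config.weighted,
                seed=config.seed,
                pairs=config.pairs,
                metadata=metadata,
                group_field=config.group_field,
            )
        with _stage("rc_bray"):
            rc = raupcrick.rc_bray(
                table,
                reps=config.reps_rc,
                seed=config.seed,
                pairs=config.pairs,
                metadata=metadata,
                group_field=config.group_field,
            )
        with _stage("partition"):
            merged = bnti.merge(rc, on=["sample_a", "sample_b"], validate="one_to_one")
            groups = metadata.groups(config.group_field)
            merged["group_a"] = merged["sample_a"].map(groups)
            merged["group_b"] = merged["sample_b"].map(groups)
            merged = partition.classify_results(merged)
            io.write_turnover_results(merged, outdir / "turnover.tsv")
            summary = partition.partition_fractions(
                merged, metadata, group_field=config.group_field
            )
            partition.write_summary_json(summary, outdir / "process_summary.json")

        captured = [str(w.message) for w in wrec]
    for msg in captured:
        logger.warning(msg)

    provenance = {
        "config": {k: v for k, v in asdict(config).items() if k != "config_warnings"},
        "seed": config.seed,
        "versions": {
            "assemblage": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "warnings": config.config_warnings + captured,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "outdir": str(outdir),
        "ses_mntd": str(outdir / "ses_mntd.tsv"),
        "turnover": str(outdir / "turnover.tsv"),
        "process_summary": str(outdir / "process_summary.json"),
        "provenance": str(outdir / "provenance.json"),
        "summary": summary,
    }
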