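"""End-to-end assembly-process partitioning on a simulated survey.

Writes a dataset to disk, runs the full pipeline (rarefaction, alignment,
SES.MNTD, betaNTI, RC_bray, classification), and prints the per-group
process fractions — the stacked-bar view of community assembly.
"""

import json
import tempfile
from pathlib import Path

from assemblage import RunConfig, ScenarioConfig, run_pipeline
from assemblage.simulate import write_dataset

workdir = Path(tempfile.mkdtemp())
data = workdir / "data"
write_dataset(
    ScenarioConfig(scenario="homogeneous_selection", n_taxa=128, seed=1), data
)

paths = run_pipeline(
    RunConfig(
        tree=str(data / "tree.nwk"),
        table=str(data / "table.tsv"),
        metadata=str(data / "metadata.tsv"),
        outdir=str(workdir / "out"),
        depth=1073,
        reps_bnti=299,   # 999 for publication-grade nulls
        reps_rc=299,
        seed=5,
    )
)

summary = json.loads(Path(paths["process_summary"]).read_text())
print("per-group assembly process fractions (within-group pairs):")
for group, entry in summary.items():
    top = max(entry["fractions"], key=entry["fractions"].get)
    print(f"  {group}: modal = {top} "
          f"({entry['fractions'][top]:.2f} of {entry['n_pairs']} pairs)")
print("\nThe generating process was homogeneous selection in every group, so")
print("the modal label should be homogeneous_selection throughout.")
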