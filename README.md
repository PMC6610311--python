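# assemblage

Phylogenetic null models and ecological assembly-process partitioning for
microbial community tables.

## The problem

Microbial surveys (e.g. 16S rRNA OTU tables from soil horizons) routinely ask
*why* communities differ from place to place: is turnover driven by
deterministic selection imposed by the environment, or by stochastic processes
— dispersal and drift? A widely used answer combines two null models computed
on every pair of samples:

* **βMNTD / βNTI.** The between-community mean nearest taxon distance,

  βMNTD(a, b) = ½ [ Σᵢ∈a wᵢₐ · minⱼ∈b d(i, j) + Σⱼ∈b wⱼᵦ · minᵢ∈a d(i, j) ],

  where d is the patristic (cophenetic) distance on the OTU phylogeny and w
  are per-community taxon weights (1/richness, or relative abundances). The
  *taxa labels* null shuffles taxon identities on the distance matrix; with
  999 randomizations,

  βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null.

  βNTI < −2 marks less phylogenetic turnover than chance (homogeneous
  selection), βNTI > +2 more (variable selection). The within-community
  analogue SES.MNTD standardizes MNTD the same way.

* **RC_bray.** For pairs without a selection signal (|βNTI| < 2), the observed
  Bray-Curtis dissimilarity is ranked against communities reassembled at
  random from the regional pool — taxa drawn without replacement in proportion
  to occupancy, then individuals allocated in proportion to pooled abundance,
  holding each sample's richness and total count fixed. The rank is rescaled
  to RC_bray ∈ [−1, +1]: RC_bray > +0.95 indicates dispersal limitation,
  RC_bray < −0.95 homogenizing dispersal, |RC_bray| ≤ 0.95 "undominated"
  turnover.

Jointly the thresholds assign every sample pair to one of five processes, and
per-group fractions summarize how assembly differs between groups (e.g. soil
horizons). The package implements the whole chain — rarefaction, tree/table
alignment, cophenetic distances, both null models, classification, group
summaries — plus a synthetic-data generator that produces trees, Brownian
niche traits and communities under *known* assembly processes, so the
inference can be validated end to end.

## Worked example

```python
from assemblage import ScenarioConfig, beta_nti, rc_bray, simulate_dataset
from assemblage.partition import classify_results
from assemblage.phylo import cophenetic_matrix

config = ScenarioConfig(scenario="homogeneous_selection", seed=1)
tree, traits, table, metadata, truth = simulate_dataset(config)
dist = cophenetic_matrix(tree, labels=table.taxa)
bnti = beta_nti(table, dist, reps=999, seed=1, pairs="within", metadata=metadata)
rc = rc_bray(table, reps=999, seed=1, pairs="within", metadata=metadata)
labels = classify_results(bnti.merge(rc, on=["sample_a", "sample_b"]))
print(labels["process_label"].value_counts(normalize=True).round(2))
```

```
process_label
homogeneous_selection    0.78
dispersal_limitation     0.20
undefined                0.02
```

78% of within-group pairs show βNTI < −2 — the communities were indeed
assembled by a shared environmental filter, and the pipeline recovers it as
the modal process. Running `examples/04_full_pipeline.py` does the same
through the on-disk pipeline and prints per-group fractions:

```
per-group assembly process fractions (within-group pairs):
  A: modal = homogeneous_selection (0.64 of 14 pairs)
  OA: modal = homogeneous_selection (0.53 of 15 pairs)
  Oe: modal = homogeneous_selection (0.93 of 15 pairs)
  Oi: modal = homogeneous_selection (0.93 of 15 pairs)
```

The `examples/` directory holds one short script per capability (simulation,
nearest-taxon nulls, Raup-Crick, full pipeline). A thin CLI mirrors the
pipeline stages:

```sh
assemblage simulate --scenario drift --out data/
assemblage run --tree data/tree.nwk --table data/table.tsv \
    --metadata data/metadata.tsv --depth 1073 --seed 1 --out results/
```

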