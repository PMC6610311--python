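# Methods

## Metrics and null models

**Patristic distances.** The phylogeny is reduced once to the tip-to-tip
patristic distance matrix (sum of branch lengths along the connecting path),
computed in a single postorder pass and cached. All null models act on this
matrix; the tree itself is never revisited. Zero-length terminal branches are
legal, so nearest-taxon distances may tie at 0.

**MNTD / SES.MNTD.** For each community, every present taxon contributes its
distance to the closest other present taxon; the mean is unweighted
(1/richness) by default or relative-abundance weighted. SES.MNTD standardizes
the observed value against `reps` (default 999) randomizations of the *taxa
labels* null: rows and columns of the distance matrix are jointly permuted,
one permutation per randomization shared by every sample, so values within a
randomization remain comparable. Communities with richness < 2, and any case
whose null distribution has zero spread, are flagged `undefined` and carried
as explicit flags (never silent NaNs); downstream summaries count them
separately.

**βMNTD / βNTI.** βMNTD symmetrizes the mean distance from each taxon in one
community to its nearest taxon in the other; a taxon present in both
contributes 0. βNTI standardizes βMNTD against the same shared-permutation
null. A structural consequence of the shared-taxon convention: a pair of
*identical* communities has a null distribution identically zero (the
diagonal survives every permutation), so such pairs are flagged undefined
rather than scored — turnover of zero carries no rankable information.

**Weighting default.** βMNTD/βNTI default to the unweighted (presence-based)
form, matching picante's `comdistnt` default; abundance weighting is
available everywhere via `weighted=True`. At the regional-pool sizes this
package targets for validation (~10² taxa) the abundance-weighted null
concentrates weight on few dominant taxa and its coefficient of variation
grows to ~0.3–0.5, which compresses attainable |βNTI| toward the ±2
thresholds and makes selection detection unreliable; the unweighted null is
markedly better behaved. With thousands of taxa both modes are serviceable,
and the flag is recorded in every output. Note the unweighted convention here
is the symmetric half-sum of per-community means; picante's unweighted
`comdistnt` instead averages the pooled nearest-distance vector over
n_a + n_b taxa (the two agree at equal richness, and the abundance-weighted
forms agree exactly — the test suite cross-checks both against picante).

**RC_bray.** Each of `reps` (default 999) null community pairs is assembled
independently per community: taxa drawn without replacement with probability
proportional to occupancy (via exponential sort keys, which realize
successive weighted draws), each drawn taxon seeded with one individual, and
the remaining individuals allocated multinomially in proportion to pooled
abundances — holding observed richness and total abundance fixed. With
`obs` the observed Bray-Curtis, p = (#{null < obs} + ½·#{null = obs}) / reps
and RC = 2(p − ½). Ties use relative tolerance 1e−12. The pool defaults to
all samples in the run; a per-group (or any custom) pool can be passed
explicitly, and the choice is recorded.

**Classification.** Strict inequalities at the printed thresholds: βNTI < −2
homogeneous selection, > +2 variable selection; otherwise RC > +0.95
dispersal limitation, RC < −0.95 homogenizing dispersal, else undominated.
Exactly ±2 / ±0.95 therefore fall to the non-selection / undominated branch —
a measure-zero convention in practice. Non-finite inputs map to `undefined`.
Group summaries use within-group pairs, exclude undefined pairs from the
denominator and report their count; the five fractions sum to 1 over defined
pairs.

## Pipeline

`run_pipeline` executes rarefy → align → cophenetic → SES.MNTD → βNTI →
RC_bray → classify → summarize, writing per-sample and per-pair TSVs, a JSON
process summary, and a provenance record (config echo, seed, versions, every
warning raised during the run). Rarefaction subsamples each column to a fixed
depth without replacement (multivariate hypergeometric); samples below depth
are dropped with a warning. All randomness derives from one user seed: each
stage draws from `SeedSequence([seed, stage_tag])` with fixed per-stage tags,
so adding randomizations to one stage never perturbs another, and identical
config + seed reproduces outputs byte for byte.

## Synthetic-data generator

The generator emulates the structure of a horizon-resolved soil 16S survey:
a pure-birth (Yule) tree scaled to root depth 1 (the waiting time before the
first split is dropped from the root edge, and tips are extended by the
waiting time to the next unrealized speciation so the newest sister pair does
not sit at zero branch length); one niche trait evolved by Brownian motion
(tip variance σ_BM² × depth); and per-sample multinomial counts at fixed
depth, mirroring an already rarefied table. Default scale: 128 OTUs, 4
groups ("Oi", "Oe", "OA", "A") × 6 samples, depth 1,073.

Scenarios and their defaults:

| scenario | mechanism | key defaults |
|---|---|---|
| neutral | every sample drawn from one shared log-normal pool (log-sd 1.0) with mild per-sample log-normal noise | noise σ = 0.2 |
| homogeneous_selection | Gaussian filter on the trait toward one shared optimum, strong per-sample demographic noise | guild 16, noise σ = 2.5 |
| variable_selection | same filter, group optima at evenly spaced trait quantiles (0.1–0.9) | guild 16, noise σ = 2.5 |
| drift | per-sample founder subsampling (64 founders) from the common pool | founder 64 |
| dispersal_limitation | each sample assembles from its own log-normally perturbed neighborhood pool | noise σ = 0.75 |
| homogenizing_dispersal | per-sample noisy pool mixed with fraction m of the pooled mean | m = 0.95 |

**Guild mode and trait conditioning.** Nearest-taxon indices detect selection
only when the niche is phylogenetically conserved at clade level. A single
Brownian trait on a 128-tip Yule tree realizes such structure only in some
draws, so the selection scenarios (i) restrict the filter's support to the
`guild_size` (16) taxa trait-closest to the optimum, with the Gaussian width
tied to the guild's trait radius (σ = radius/2; a hard tolerance limit beyond
it), and (ii) redraw the trait — deterministically, attempt-indexed streams —
until the most compact candidate guild has mean nearest-taxon distance at
most 0.30× that of random same-sized taxon sets (at most 50 draws, then the
best draw is used). The homogeneous-selection optimum is the candidate (over
trait quantiles) minimizing that guild spread. This conditions the scenario
on the biological precondition it claims — selection on a conserved niche —
not on any downstream test statistic. Setting `guild_size=None` recovers the
pure Gaussian filter of width `filter_width` (in that mode the σ_f → ∞ limit
is a vanishing filter and uniform expected abundances). The calibration
(guild 16, ratio 0.30, noise 2.5) was fixed once against the βNTI
sensitivity analysis and is not a per-dataset tuning.

**Demographic noise.** Per-sample log-normal abundance fluctuations represent
ecological drift acting alongside each scenario's deterministic structure;
under selection they generate the taxon turnover (within the guild) that the
pairwise metrics need, and for the neutral scenario σ = 0.2 places observed
Bray-Curtis mid-null (smaller values make samples more similar than the
Raup-Crick null's forced-singleton assembly, pushing RC toward −1; larger
values push it toward +1).

**What passing recovery tests does and does not show.** The generator
produces even-depth multinomial counts with log-normal abundance structure;
it does not simulate sequencing error, chimeras, compositional biases,
variable read depth, or spatially explicit dispersal. Recovery of the
generating process under these conditions demonstrates internal consistency
of the inference chain, not field performance. Two known limits at the
128-taxon validation scale: homogenizing dispersal produces communities
statistically close to the Raup-Crick null's own assembly process, so
RC < −0.95 is reached only sporadically and the scenario mostly scores
undominated; and founder subsampling from the common pool (the drift
scenario) is likewise near-indistinguishable from the null, which is exactly
why drift is expected to land in dispersal_limitation + undominated rather
than any single dominant label.

## Problem sizes and numerical choices

Tests validate MNTD/βMNTD against naive double-loop oracles on ~1,000 small
cases (trees ≤ 8 tips) at 1e−12; null calibration uses 150 communities /
150 disjoint pairs on a 32-tip tree at 999 randomizations (|mean| < 0.15);
recovery tests pool three replicate datasets per scenario at the full
default scale (128 taxa, 24 samples, depth 1,073, 999 randomizations).
Observed MNTD/βMNTD values are additionally cross-checked against
picante (R) on a small dataset. Floating-point ties in the RC rank use
relative tolerance 1e−12; null standard deviations below 1e−15 are treated
as zero (undefined). Distance matrices are validated for symmetry, zero
diagonal and non-negativity on construction.
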