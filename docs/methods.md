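# Methods

This note documents the model implemented by `vtod`, the choices made where
the design was genuinely open, what the synthetic benchmark does and does not
emulate, and the numerical conventions.

## The model

The pipeline integrates three evidence channels over a set of seed genes
S = DE ∪ SA:

* **Data-driven:** for a gene pair, the maximum absolute Pearson correlation
  over the available channels (GE–GE, CNA–GE in both orientations, CNA–CNA),
  called MaxRel. CNA–CNA is excluded for genes sharing a cytoband or focal
  aberrant region, because physically proximal genes are amplified or
  deleted together regardless of function.
* **Topological:** normalized PPI connectivity NC(g) = deg(g)/max-degree and
  shortest-path lengths, both from the undirected interactome.
* **Hybrid (indirect relationships):** a pair without a direct relationship
  may be linked through a short PPI path whose chain of MaxRel values has a
  significant geometric mean against a null in which node labels are
  permuted while topology is conserved.

Modules are grown by voting (each gene nominates its strongest associates as
representatives), pre-module formation around representatives, and greedy
merging under a permutation-calibrated stopping threshold δ. Modules may
overlap — a gene can vote in one pre-module and be a representative in
another — reflecting genes that participate in several pathways.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `de_alpha` | 0.05 | Bonferroni-corrected level for DE seed selection |
| `top_fraction_direct` | 0.10 | per-channel quantile for direct-relationship thresholds |
| `path_length_limit` (L) | 2 | maximum simple-path length (edges) for indirect search |
| `n_random_ppi` | 50 | label permutations for path significance |
| `path_alpha` | 0.05 | empirical-p admission threshold for indirect pairs |
| `vote_spl_limit` (L_max) | 2 | shortest-path cutoff in the vote's topological term |
| `local_rank_limit` (P) | 1 | local vote rank required of a representative |
| `global_top_percent` (q) | 0.1 | global vote percentile required of a representative |
| `n_random_merge` | 100 | relationship shuffles calibrating δ |
| `merge_alpha` | 0.05 | empirical-p threshold for merge steps |
| `expr_change_top_fraction` | 0.10 | tail fraction defining per-sample expression change |
| `go_min_size`, `go_max_size` | 5, 250 | gene-set size bounds (boundary-inclusive) |
| `enrichment_fdr` | 0.05 | BH q-value threshold |

All empirical p-values use the (+1)/(n+1) pseudo-count convention, so no
permutation p is ever exactly zero and the per-step false-merge rate under
an exchangeable null is slightly below the nominal level.

### Choosing q at small scale

q controls the global vote budget: floor(q/100 · N(N−1)) ordered votes are
eligible. The default q = 0.1 (percent) matches cohort-scale seed sets
(thousands of genes), where it amounts to roughly five eligible votes per
seed gene. For desk-scale datasets (a few hundred seeds) the same
*votes-per-gene* ratio, q ≈ 100 · 5/(N−1), is the recommended operating
point and is what the test suite and acceptance script use; holding q itself
fixed while N shrinks by a factor of 30 would starve the budget below one
vote per gene and no module could be covered.

## Design choices at open points

* **Vote formula.** vote(i→j) = Rel(i,j) + NC(j)/SPL(i,j) for 1 ≤ SPL ≤
  L_max, else Rel alone. This is the reconstruction forced by three
  constraints: two terms each in [0,1] summing to at most 2, hub preference
  through the receiver's connectivity, and damping "by the length of the
  shortest path".
* **Indirect weight.** An admitted indirect pair is stored with its path's
  geometric-mean statistic — the quantity whose significance justified
  inclusion. The alternative (the pair's own sub-threshold MaxRel) is
  available via `PipelineConfig.indirect_weight = "maxrel"`; note that the
  geometric mean lets one strong link inflate the weight of a pair whose own
  correlation is null, which at small scale measurably feeds votes across
  module boundaries.
* **Indirect paths have ≥ 1 intermediate.** A bare PPI edge carries no chain
  statistic; paths of 2..L edges through data-bearing genes are searched.
  Intermediates need data but not seed membership
  (`strict_seed_paths = True` restricts to seeds).
* **Null model for paths.** A uniform node-label permutation of the whole
  PPI graph: topology exactly conserved, labels detached. Degree-preserving
  edge rewiring is deliberately not used. The path search is re-run in each
  permuted network, not merely re-scored. Replicates with no admissible path
  contribute a null statistic of 0.
* **Local rank.** P = 1 is read as "top-1 ranked vote"; a cumulative-mass
  reading is implemented behind `local_rank_mode = "cumulative"` but not
  default. Zero votes never select a representative.
* **Global rank.** Taken over ordered pairs (votes are asymmetric); ties at
  the cutoff value are admitted; the cutoff count uses floor so a vanishing
  q admits nobody.
* **IC convention.** Computed on the smaller module; at equal sizes both
  directions are evaluated and the maximum taken so MV stays symmetric.
  `ic_mode = "symmetric_max"` always takes the maximum.
* **Cross-pair mean.** Absent relationships count as 0 in MV's data term;
  averaging only existing relationships would inflate MV for sparsely
  related module pairs. Shared genes of overlapping modules stay in the
  cross-pair product set (union semantics); only self-pairs are excluded.
* **δ freezing and survival.** δ is computed once, from the first-merge
  maxima of `n_random_merge` shuffled networks: observed merging proceeds
  while the current maximum MV has empirical p ≤ `merge_alpha`, and δ is the
  smallest significant observed maximum. If not even the first observed
  merge clears the null, the pre-module structure is indistinguishable from
  a network with relationships detached from topology, and the pipeline
  reports no surviving modules. When at least one step is significant, all
  post-merge modules (merged and unmerged) are reported.
* **FDR scope.** Within each (module × collection) family, so q-values are
  comparable to per-module pathway screens; a global scope across modules is
  a one-line change at the call site (`fdr_correct` is scope-agnostic).
  Enrichment rows require overlap ≥ 1. The correlation of per-module
  relationship-type counts with cancer-gene enrichment uses −log10(p)
  (correlating raw p with counts is scale-degenerate).
* **Gene-to-region assignment.** Maximum-overlap with lexicographic
  region-id tie-break; cytoband by containment of the gene start; 0-based
  half-open coordinates throughout.

## The synthetic benchmark

`vtod.synthgen` writes a complete input bundle (tumor/control expression,
gene-level CNA with a few missing cells, PPI edge list, cytoband and focal
files, SA list, GMT gene sets, cancer-gene list) with planted ground truth.
Default geometry: five 20-gene modules, two genes shared between consecutive
modules, 120 background genes, 60 tumor and 10 control samples.

The generator reproduces the statistical couplings the method exploits, each
of which proved load-bearing:

* **Latent-factor expression with a loading spectrum.** Module genes follow
  x = shift + √ρ_g·f_m + √(1−ρ_g)·ε with per-gene loadings ρ_g jittered
  around `ge_latent_loading` (default 0.8 ± 0.15). The jitter emulates the
  eigengene (kME) spectrum of real co-expression modules; with exchangeable
  equal loadings every gene's best correlate is uniformly random among its
  module mates, votes never concentrate, and the two-gene pre-module filter
  discards a large fraction of genuine module genes.
* **Seeds outnumber module genes.** Background genes are not inert: one
  tranche is differentially expressed without co-expression, another
  consists of focal-region passengers sharing a per-region CNA profile
  (excluded from CNA–CNA pairing positionally, like real GISTIC
  passengers). The per-channel top-10% thresholds therefore operate on a
  mostly-null candidate distribution, as at cohort scale; when seeds equal
  module genes the quantile lands inside the signal peak.
* **Heavy-tailed PPI degrees.** Besides the planted partition (p_in = 0.5
  within modules, p_out = 0.01 elsewhere), a few data-less "sticky" hub
  proteins with high attachment give max-degree ≫ typical degree, so
  NC ≪ 1 for ordinary genes — as in real interactomes. Without them the
  topological vote term dominates and, critically, shuffled-relationship
  null runs still assemble pre-modules on the PPI communities, destroying
  the observed-vs-null separation the δ calibration measures.
* **Data–topology hub concordance.** Each module's top-loading gene is
  wired as its PPI hub (edges to ~80% of members): the method's premise is
  that representatives are hubs in both senses. The hub misses some members
  so modules split into a couple of pre-modules and the merge stage stays
  exercised, matching the published regime of roughly two pre-modules per
  final module.

The matched null dataset zeroes every effect (loading, CNA amplitude, DE
shift, planted PPI structure) while keeping the layout, formats and SA list.

**What passing these tests shows — and does not.** Recovery (mean best-match
Jaccard ≥ 0.8 over ten generator seeds) and null calibration (no surviving
modules on ≥ 95% of null seeds) demonstrate that the implementation
faithfully rewards the couplings the method was designed for, and nothing
else. The generator does not model microarray noise structure, dosage
coupling between CNA and expression of the same gene, arm-level events,
genome-scale gene counts, or correlated controls, so these results do not
certify performance on real cohorts — they certify the machinery.

## Numerical conventions and degenerate inputs

* Top-fraction thresholds: the k-th largest value with k = ceil(f·n);
  admission by ≥, so ties pass and at least a fraction f is admitted.
* Pearson correlations of constant vectors are undefined: the pair is
  skipped for that channel ("no value"), never coerced to 0.
* Zero pooled variance in the t-test: identical means give (t=0, p=1);
  different means give p=0 with a warning.
* Channel ties in MaxRel resolve in the order GE-GE, CNA-GE, CNA-CNA;
  best-path ties by lexicographic path; merge ties by lexicographic lineage;
  identical pre-module member sets keep the lexicographically smallest
  representative. All randomized stages consume child generators spawned
  from the single configured seed, so every output is bit-reproducible.
* CNA loading imputes missing cells with the row mean and errors on
  all-missing rows; duplicate gene symbols and malformed GMT/edge lines are
  format errors, not warnings.

## Known limitations

* The merge loop recomputes the maximum MV pair in O(k²) per step — fine
  for hundreds of pre-modules, not tuned for tens of thousands.
* The vectorized indirect-path search is specialized to L = 2 (the default);
  longer limits fall back to explicit path enumeration, which is intended
  for small graphs.
* δ calibration compares each observed step against the *first-step* maxima
  of the shuffled runs. At desk scale the null's first merges are its most
  favourable (near-duplicate pre-modules), so the test is conservative:
  late, marginal consolidation merges can be blocked. The aligned per-step
  comparison is available via `significance_curve`.
* Enrichment universes default to seed genes ∪ collection genes; with tiny
  universes the hypergeometric test is conservative.
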