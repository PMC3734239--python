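# vtod

Voting-based detection of overlapping cancer gene modules from paired tumor
gene-expression (GE) and copy-number-aberration (CNA) profiles combined with
a protein–protein interaction (PPI) network.

Cancer pathways are dysregulated through a mix of expression changes and DNA
copy-number changes, and the genes involved rarely belong to a single
pathway. `vtod` finds gene modules that are allowed to overlap, in which
members are tied together both by multi-omic correlation ("data-driven"
evidence) and by proximity in the interactome ("topological" evidence). It is
aimed at computational biologists working with matched tumor GE/CNA cohorts
(e.g. TCGA-style level-3 matrices) who want module calls that come with
enrichment-based evaluation and permutation-calibrated significance.

## Method

1. **Seed genes.** S = DE ∪ SA: differentially expressed genes (two-tailed
   pooled t-test against unmatched controls, Bonferroni ≤ 0.05) plus a list
   of significantly copy-number-altered genes from published focal
   aberration calls.
2. **Gene–gene relationship network** GGR = (S, R). For every seed pair the
   absolute Pearson correlations |PCC| of all available channels are taken —
   GE–GE, CNA–GE (both orientations), CNA–CNA — and the maximum (*MaxRel*)
   enters R as a **direct** relationship when it reaches its channel's
   top-10% threshold. CNA–CNA is suppressed for genes sharing a cytoband or
   focal aberrant region (co-amplification is positional, not functional).
   Pairs not in R gain an **indirect** relationship when a short PPI path
   (≤ 2 edges, intermediates carrying data, chosen to maximize mean
   normalized connectivity NC(g) = deg(g)/max-degree) has a significant
   geometric-mean MaxRel chain versus 50 node-label permutations of the PPI
   graph (empirical p ≤ 0.05).
3. **Voting.** Every ordered pair casts a vote

       vote(i→j) = Rel(i, j) + NC(j) / SPL(i, j),   SPL(i, j) ≤ L_max = 2

   (Rel = stored relationship weight, SPL = PPI shortest-path length; the
   topological term is dropped beyond the cutoff; votes lie in [0, 2]).
   Gene j is a *representative* of i when vote(i→j) is i's top-ranked vote
   **and** lies in the global top q% of all votes. Each representative with
   its voters forms a **pre-module**; subsets, two-gene pre-modules and
   single-focal-region artifacts are filtered out.
4. **Merging.** Pre-module pairs are scored by

       MV(M_i, M_j) = IC(M_i, M_j) + mean cross-pair Rel

   where IC is the fraction of the smaller module's genes with ≥ 1 PPI
   partner in the other. The maximum-MV pair is merged repeatedly while MV
   stays significant (empirical p ≤ 0.05) against the first-merge maxima of
   100 networks with uniformly re-drawn relationship pairs; the smallest
   significant MV is the stopping threshold δ. If not even the first merge
   clears the null, no module survives the calibration.
5. **Evaluation.** Hypergeometric enrichment of each module against gene-set
   collections (GMT) and cancer-gene lists with Benjamini–Hochberg FDR per
   (module × collection) family, the cancer-related subset of pathways, and
   per-module profiles of the three direct-relationship types.

A fully synthetic generator (`vtod.synthgen`) plants overlapping modules in
GE/CNA/PPI/gene-set files in exactly the formats the readers consume, so the
whole pipeline is testable without any external download.

## Worked example

Generate a synthetic cohort with five planted 20-gene modules (two genes
shared between consecutive modules) and run the pipeline:

```sh
vtod synth --seed 7 --out demo/data
vtod run \
  --ge demo/data/expression.tsv --controls demo/data/controls.tsv \
  --cna demo/data/cna.tsv --ppi demo/data/ppi.tsv \
  --cytoband demo/data/cytoband.txt --focal demo/data/focal_regions.bed \
  --gene-coords demo/data/gene_coords.tsv --sa-genes demo/data/sa_genes.txt \
  --gmt demo/data/gene_sets.gmt --cancer-genes demo/data/cancer_genes.txt \
  --q 2.7 --seed 7 --out demo/out
```

which prints

```json
{"n_seed_genes": 187, "n_direct": 4567, "n_indirect": 864,
 "n_premodules": 15, "delta": 1.6631432940053559, "n_modules": 5}
```

Reading: 187 seed genes (167 DE plus the listed SA genes) give 17,391 seed
pairs; 4,567 (26.3%) become direct relationships at the per-channel top-10%
thresholds (here 0.256 / 0.255 / 0.220 for GE–GE / CNA–GE / CNA–CNA) and 864
of the remaining pairs gain significant indirect PPI paths. Voting at the
global top q = 2.7% yields 15 pre-modules, merging stops at δ ≈ 1.66, and
the five surviving modules match the five planted ones. `demo/out/` holds
the modules (GMT + long TSV), pre-modules, the relationship table, the merge
trace with per-step empirical p, the enrichment table (the planted gene sets
are the top hits) and a JSON manifest echoing every count above.

## Layout

| module | contents |
| --- | --- |
| `vtod.datatypes` / `vtod.io` | domain containers and readers/writers (TSV matrices, SIF/TSV edge lists, GMT, cytoBand, BED-like focal regions) |
| `vtod.seeds` | DE testing, seed-set construction, expression-change annotation |
| `vtod.ggr` | direct + indirect relationship network |
| `vtod.voting` | votes, representative selection, pre-modules |
| `vtod.merging` | merging values, δ calibration, significance curves |
| `vtod.enrichment` | hypergeometric tests, FDR, cancer-related subset, profiles |
| `vtod.synthgen` | synthetic cohorts with planted ground truth |
| `vtod.pipeline` / `vtod.cli` | orchestration, manifest, `vtod` command |
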