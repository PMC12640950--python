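# immunohub

Immunophenotyping and hub-gene discovery for paired two-arm CAR-T cell
studies, with a synthetic-data generator that plants recoverable ground
truth.

The motivating design is a study comparing conventional CAR-T cells with
TCF-1–overexpressing (dual-transduced) CAR-T cells from the same donors:
multi-marker flow cytometry of the cell product across generation
timepoints, and paired RNA-seq of the final products. Two analysis
pipelines are implemented as a reusable library plus numbered analysis
drivers:

**Immunophenotyping** (`analysis/02_immunophenotype.py`):
cytometry events are arcsinh-transformed (`asinh(x/cofactor)`, cofactor
150), optionally gated, and clustered PhenoGraph-style — a k-nearest-
neighbour graph (Euclidean, k = 30) with edge weights equal to the Jaccard
index of the endpoints' kNN sets, partitioned by Louvain community
detection. Per-sample cluster frequencies (percent of parent, rows sum to
100) are standardised and decomposed by PCA per timepoint; the leading
principal components covering ≥ 70 % of cumulative variance are kept, and
each population's contribution

&nbsp;&nbsp;&nbsp;&nbsp;contrib<sub>i,j</sub> = 100 · ℓ<sub>ij</sub>² / Σ<sub>i</sub> ℓ<sub>ij</sub>²  (aggregated over retained PCs, eigenvalue-weighted)

is compared against the uniform expectation 100/p. Selected populations
are intersected across timepoints, populations with fewer than 300 pooled
cells are excluded (exactly 300 is kept), an optional manual merge map is
applied, and arm differences are tested per population and timepoint with
the paired t-test (t = mean(d)/(sd(d)/√n), df = n−1) plus
Benjamini–Hochberg adjustment. A per-sample cell bootstrap quantifies
selection stability.

**Hub-gene discovery** (`analysis/03_hub_genes.py`):
paired differential expression on log2(CPM+1) defines DEGs at
|log2FC| ≥ 1 and Q ≤ 0.05 (both inclusive); the DEG-induced
protein-interaction subnetwork is ranked by Maximal Clique Centrality
(MCC(v) = Σ over maximal cliques C ∋ v of (|C|−1)!) and mined for dense
modules with MCODE (core-based vertex weighting, greedy expansion at node
score cutoff 0.2, haircut, 2-core test, score = density × size); a random
forest classifying arm from DEG expression ranks genes by out-of-bag
permutation importance (mean decrease in accuracy) and impurity importance
(mean decrease in Gini). The hub set is the exact three-way intersection,
annotated up/down. GSEA uses the signal-to-noise ranking
(μ<sub>A</sub>−μ<sub>B</sub>)/(σ<sub>A</sub>+σ<sub>B</sub>) with the
canonical σ floor, the weighted running-sum enrichment score, gene-set
permutation nulls, NES and the standard FDR; over-representation is
upper-tail hypergeometric over user-supplied GMT sets.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 0 --out-dir results/data
python analysis/02_immunophenotype.py --seed 0 --data-dir results/data
python analysis/03_hub_genes.py      --seed 0 --data-dir results/data
```

The simulated cohort plants one population whose frequency drops from
~30 % to ~16 % of events in the TCF-1 arm, plus a 250-cell rare
population. The immunophenotyping driver prints (seed 0, 2,500
cells/sample):

```
clusters: 8 (modularity 0.791)
  day11: retained PCs 3, selected clusters [0, 1, 3, 5, 6]
  day14: retained PCs 3, selected clusters [0, 1, 3, 5, 6]
intersection: [0, 1, 3, 5, 6]; after <300-cell exclusion: [0, 1, 3, 5, 6]
final populations vs. planted truth:
  cluster 1: CD4_apoptotic (100% pure)
  ...
arm comparisons with raw p < 0.05 (6 of 10):
  cluster 1 @ day11: t=6.60 p=0.0012 q=0.006 **
  cluster 1 @ day14: t=10.19 p=0.00016 q=0.0016 ***
  ...
```

i.e. the planted apoptotic population is recovered as a pure cluster,
survives the PCA selection and count filter at both timepoints, and its
arm shift is highly significant under the paired test — while the planted
sub-300 population is excluded. (The co-selected clusters are the
compositional echo: a 14-point drop in one population necessarily raises
the others.) The hub-gene driver prints:

```
DEGs (|log2FC|>=1, Q<=0.05): 137 (104 down)
  137 of 150 planted recovered, 0 false positives
rankings: MCC set 35, MCODE set 10 (1 modules), RF set 36
hub genes (three-way intersection): ['G0460', 'G1075', 'G1863']
  G0460: log2FC=-2.92 (downregulated)
  ...
GSEA (gene-set permutation):
  PLANTED_SET: ES=0.776 NES=1.87 p=0.00101 FDR=0 *
```

— the planted dense module is recovered by MCODE, the hub intersection is
a downregulated subset of the planted truth, and only the planted gene
set reaches FDR < 0.05.

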