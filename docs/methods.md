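# Methods

## Scope and shape

The package reconstructs, as tested library code, the two bespoke analysis
procedures of a paired two-arm CAR-T characterisation study: (1)
unsupervised immunophenotyping of multi-marker cytometry with a
PCA-contribution population-selection rule, and (2) hub-gene discovery
from paired RNA-seq via three independent rankings of a DEG interaction
network. Raw study data are not redistributed; a synthetic-data generator
with planted ground truth stands in for them, which turns every pipeline
claim into a parameter-recovery statement that the test suite and
`scripts/acceptance.py` verify.

## Cytometry model

Events are simulated per (donor, arm, timepoint) sample. Each cell
population is a Gaussian on the arcsinh scale (the standard
variance-stabilising scale for fluorescence cytometry; raw intensities are
emitted as `cofactor·sinh(·)`, clipped at zero, and re-transformed by the
pipeline with the conventional cofactor 150). Population profiles are
hi/lo marker patterns (hi ≈ 3.5, lo ≈ 0.5, sd 0.4 on the arcsinh scale),
which mirrors cleanly gated major compartments. Per-sample population
frequencies follow a Dirichlet-multinomial: baseline frequencies are
perturbed per sample with concentration 200 (frequency sd ≈ 3 percentage
points for a 30 % population), modelling donor-to-donor variability; the
concentration can be set to `None` for exact multinomial sampling, which
is what the binomial-standard-error checks use. Arm effects are
multiplicative on the frequency vector with renormalisation; the default
study fixture shifts one apoptotic population from ~30 % to ~16 % of
events in the TCF-1 arm (> 10 percentage points, matching the magnitude
of effect the procedure is meant to detect) and plants one
marker-distinct rare population totalling 250 cells — deliberately below
the 300-cell exclusion threshold. Default design: 6 paired donors, two
arms, two timepoints, 10,000 cells per sample; per-sample event counts
are configurable because real instruments vary (these defaults are the
package's own choices, not measured values).

What the generator does **not** emulate: spillover/compensation artifacts,
doublets, debris, acquisition drift, heavy-tailed or skewed intensity
distributions, and continuous differentiation gradients between
populations. Passing recovery tests therefore demonstrates that the
procedure is correct and well-calibrated on well-separated populations
with realistic frequency noise — not that it is robust to every
instrument artifact.

## Clustering

PhenoGraph-style: exact k-nearest neighbours (Euclidean, k = 30, the
method's conventional default) via a KD-tree; edge weights are the
Jaccard index of the two endpoints' kNN sets computed only on the
symmetrised kNN edge list, with zero-Jaccard pairs dropped; Louvain
community detection on the weighted graph. Jaccard sets exclude the cell
itself (the convention fixed by the hand-enumerable 4-point example in
the test suite); a consequence worth knowing is that two mutual nearest
neighbours with disjoint remaining neighbour sets are *not* connected.

Louvain is implemented natively: a numba CSR local-move/aggregation pass
from singleton communities at any scale (local-move sweeps capped at 12
per level; on event-scale graphs the cap costs ≈ 0.3 % modularity and a
~4× speed-up), plus — on graphs of ≤ 512 nodes — seeded multistart from
random initial partitions with a dense numpy implementation, keeping the
highest-modularity partition (60 restarts for ≤ 64 nodes, 8 otherwise).
The multistart matters: greedy Louvain from singletons provably cannot
reach the maximum-modularity partition on some 8-node graphs, whereas
random-initial-partition restarts recover it; the acceptance suite checks
equality with exhaustive maximum-modularity search on 200 random small
graphs. Labels are relabelled by descending cluster size; all randomness
flows from an explicit seed. Louvain is order-dependent, so partitions
are guaranteed identical under cell-order permutation only when the
partition is unambiguous; the suite asserts this on well-separated data.

Samples are pooled across arms, donors and timepoints before clustering
("joint" mode, the default) so cluster identities are shared — the
cross-timepoint intersection of selections is only meaningful with a
shared label universe. A per-timepoint mode exists for exploration; it
reports the union of selections instead of an intersection.

t-SNE is display-only and delegated to scikit-learn (PCA initialisation,
seeded). Median-expression profiles order rows and columns by
average-linkage hierarchical clustering on Euclidean distances.

## Population selection

Frequencies (percent of the gated parent, rows summing to 100) are
centred and unit-scaled per cluster before PCA — rare and common clusters
live on very different scales. PCA is SVD-based with a deterministic sign
convention (largest-magnitude loading positive). Retention keeps the
smallest prefix of PCs whose *cumulative* variance fraction reaches 70 %;
the per-PC reading of "components contributing at least 70 %" is rejected
because single components rarely reach 70 % and the procedure retains
several. Variable contributions are 100·ℓ²/Σℓ² per PC, aggregated over
retained PCs by eigenvalue weighting (unweighted mean available); a
population is selected when its aggregate contribution strictly exceeds
the uniform reference 100/p — the standard expected-average-contribution
line, made explicit because the source procedure names no cut-off.
Selections are intersected across timepoints exactly; the count filter
excludes populations with **fewer than** 300 pooled cells (exactly 300 is
kept); a manual merge map (each population assigned to at most one merged
label) supports a posteriori grouping; the nesting invariant final ⊆
intersection ⊆ every per-timepoint selection is asserted on every run.

The robustness check — undefined in the source procedure — is defined
here as a per-sample cell bootstrap: resample cells with replacement
within each sample, re-run clustering and selection, and match bootstrap
clusters to reference clusters by nearest median marker profile; the
stability of a population is the fraction of resamples in which it is
re-selected.

## Statistics

Arm comparisons are two-sided paired t-tests per population and
timepoint; identical arms return (t = 0, p = 1) while constant non-zero
differences are rejected as degenerate. BH adjustment runs across the
whole population × timepoint grid; raw p is reported alongside because
figure-legend star conventions (*, **, ***, ****) traditionally use it.
Functional subsets are the 2³ Boolean combinations of CD107a/TNF-α/IFN-γ
positivity — an exact partition summing to 100 per sample; all eight
combinations are used (a "six subsets" phrasing in the source figure
caption lists eight combinations; the exhaustive partition is the only
self-consistent reading). Positivity thresholds default to the 99.5th
percentile of an unstimulated control (FMO-like placement).

## Expression model and differential expression

Counts are negative-binomial (gamma-Poisson) with log-normal baseline
abundances, uniform library sizes in a configurable range, and a
per-donor per-gene log-normal effect shared between the two arms of a
donor — exactly the nuisance a paired test removes. The DE stage is
deliberately simple: log2(CPM+1), per-gene paired t across donors, BH →
Q; a precomputed DE table can bypass it. With the study's 3 donors this
stage has df = 2, and per-gene t-tests at that depth only clear the BH
threshold when residual noise is small. The fixture therefore treats the
residual NB dispersion as within-product technical noise (0.002;
between-donor biology lives in the paired-cancelling donor effect) and
plants 150 well-expressed DEGs (CPM floor ≈ 2,000, |log2FC| uniform in
1–3, 70 % down) out of 2,000 genes — a planted fraction comparable, at
the scaled-down gene count, to the several hundred DEGs such studies
report. Under these conditions the stage recovers ~85–95 % of planted
DEGs with no false positives across seeds; at realistic biological
dispersions (≥ 0.1) a 3-donor per-gene t-test finds nothing, which is a
faithful property of the method, not a bug — real studies at this depth
use variance-moderated tools. The DEG filter is |log2FC| ≥ 1 AND Q ≤
0.05, both boundaries inclusive.

## Network rankings

MCC sums (|C|−1)! over a node's maximal cliques of size ≥ 2 (isolated
nodes score 0); ties break by degree then node id; cliques come from
networkx's Bron–Kerbosch enumeration. MCODE follows the published
defaults: vertex weight = (highest k-core of the closed neighbourhood) ×
(that core's density); greedy expansion from the highest-weight unvisited
seed admits unvisited neighbours with weight ≥ seed weight × (1 − 0.2);
haircut removes degree-1 members in a single pass; modules lacking a
2-core are discarded; score = density × size. The fluff stage is not
implemented (its default is off in the original tool; requesting it
raises). The random forest (scikit-learn, seeded, 2,000 trees by
default) yields mean decrease in Gini from impurity importances and mean
decrease in accuracy as per-tree out-of-bag permutation importance: one
seeded permutation per feature, each tree's accuracy on its own
out-of-bag samples before and after, averaged over trees — per-tree
granularity is essential, since forest-level majority votes are nearly
insensitive to any single feature when informative features are
redundant. The combined rank is the mean of the two rank positions. The
hub set is the exact intersection of the MCC top-n (default 154), the
union of MCODE module members, and the RF combined-rank top-n (default
46); the two defaults mirror the headline set sizes such analyses
present and are independently configurable (the fixture uses 30/30, in
proportion to its smaller gene universe).

## Gene-set analytics

Signal-to-noise = (μ_A − μ_B)/(σ_A + σ_B) with each class σ floored at
max(0.2·|μ|, 0.2) (the canonical implementation's floor); ties in the
metric break by gene id. The running sum increments hits by |metric|^p
normalised over hits (p = 1 default; an all-zero hit-weight degenerate
case falls back to uniform increments) and decrements misses by
1/(N−N_hits); ES is the extremum furthest from zero; the leading edge is
the members at or before the peak (positive ES) or at or after it
(negative). Significance uses random same-size gene sets by default —
with 3 samples per arm, phenotype permutation has only 10 distinct
relabellings and no resolution; phenotype mode exists for larger designs.
NES divides ES by the mean |null ES| of matching sign; nominal p is
one-sided on the matching sign with add-one smoothing; FDR q is the
standard pooled-NES ratio, clipped to [0, 1]. ORA is the upper-tail
hypergeometric with BH across sets; annotation retrieval is out of scope
(sets come from user GMT files).

## Determinism and manifests

Every stochastic step takes an explicit seed; a master seed fans out to
per-sample and per-stage streams through `numpy.random.SeedSequence`
spawning, so no two stages share a stream. Pipeline runs can write their
artifacts with a manifest recording all parameters and a SHA-256 digest
per output file; rerunning with the same seed reproduces every digest
(asserted in the suite), with floats serialised at fixed precision.

## Validation sizing

The acceptance experiments run at the study's design conditions — 6
paired donors, 10,000 events per sample, two timepoints, a > 10-point
planted shift — with Monte-Carlo replicate counts sized for a single-CPU
run of the whole suite (10 pipeline replicates in the suite, 8 in the
acceptance script; oracle suites at 100–200 graphs; 500 null gene sets;
50-cohort type-I calibration). `immunohub.benchmarks` exposes every
experiment with the replicate count as a parameter for larger runs.

## Known limitations

* The clustering stage assumes pooled samples fit in memory (~10⁶ events
  is comfortable); no subsampling or landmark strategy is provided.
* Louvain multistart (and hence small-graph global optimality) applies
  only up to 512 nodes; beyond that the single greedy pass is used.
* The per-gene paired t DE stage is underpowered at realistic biological
  dispersion with 3 donors (see above); it is a pluggable stage.
* Compositional effects are not modelled out: a large planted frequency
  shift necessarily anti-shifts other populations, so secondary
  populations can legitimately co-select.
* MCODE fluff is unimplemented; gate tie-break on exactly-threshold
  values is strict; kNN ties on duplicated points follow the KD-tree's
  deterministic but unspecified order.
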