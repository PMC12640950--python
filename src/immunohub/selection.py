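"""PCA-based selection of informative cell populations.

The procedure turns cluster assignments into per-sample frequency matrices
(percent of the parent compartment), standardises the frequencies, runs
PCA per timepoint, keeps the leading principal components that cumulatively
explain at least 70% of the variance, scores every population by its
eigenvalue-weighted contribution to those components, selects populations
contributing more than the uniform expectation (100/p percent), intersects
the per-timepoint selections, removes populations with fewer than 300
pooled cells, and optionally applies a manual merge map. A per-sample cell
bootstrap quantifies how stable the final selection is.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, build_knn_jaccard_graph, louvain_cluster
from .errors import ConfigError
from .events import EventTable

__all__ = [
    "PCAResult",
    "ContributionResult",
    "SelectionReport",
    "frequency_matrix",
    "pca_fit",
    "retain_pcs",
    "variable_contributions",
    "select_populations",
    "intersect_timepoints",
    "apply_count_filter",
    "merge_populations",
    "run_selection",
    "selection_robustness",
]

SAMPLE_INDEX = ("donor", "arm", "timepoint")


# ---------------------------------------------------------------------------
# frequency matrix
# ---------------------------------------------------------------------------
def frequency_matrix(
    table: EventTable,
    assignment: ClusterAssignment | np.ndarray,
    n_clusters: int | None = None,
    expected_samples: Sequence[tuple] | None = None,
) -> pd.DataFrame:
    """Samples x clusters matrix in percent of the parent compartment.

    The parent compartment is whatever the table was gated to before
    clustering. Rows are indexed by (donor, arm, timepoint) and each sums
    to 100; clusters absent from a sample contribute 0. ``n_clusters``
    fixes the cluster universe when the table is a slice of a jointly
    clustered pool. A sample expected but holding zero parent cells is an
    error naming the sample.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else np.asarray(assignment)
    if len(labels) != table.n_cells:
        raise ConfigError("assignment does not cover the event table")
    if n_clusters is None:
        n_clusters = int(labels.max()) + 1 if len(labels) else 0
    df = table.data[list(SAMPLE_INDEX)].copy()
    df["_cluster"] = labels
    counts = (
        df.groupby(list(SAMPLE_INDEX), observed=True)["_cluster"]
        .value_counts()
        .unstack(fill_value=0)
    )
    counts = counts.reindex(columns=range(n_clusters), fill_value=0)
    if expected_samples is not None:
        missing = [s for s in expected_samples if tuple(s) not in set(counts.index)]
        if missing:
            raise ConfigError(f"sample {missing[0]} has zero parent cells")
        counts = counts.loc[[tuple(s) for s in expected_samples]]
    freq = counts.div(counts.sum(axis=1), axis=0) * 100.0
    freq.columns.name = "cluster"
    return freq


def cluster_total_sizes(assignment: ClusterAssignment) -> dict:
    return {int(c): int(s) for c, s in enumerate(assignment.sizes)}


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------
@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending, >= 0
    variance_fractions: np.ndarray   # sums to 1
    loadings: pd.DataFrame           # variables x PCs
    scores: pd.DataFrame             # samples x PCs
    center: pd.Series
    scale: pd.Series


def pca_fit(freq: pd.DataFrame) -> PCAResult:
    """SVD-based PCA of the standardised frequency matrix.

    Columns are centred and scaled to unit variance (zero-variance columns
    are dropped with a warning — rare clusters can be identically absent).
    The sign convention makes the largest-magnitude loading of each PC
    positive, so results do not depend on the SVD implementation's sign
    choices.
    """
    if freq.shape[0] < 2:
        raise ConfigError("PCA needs at least 2 samples")
    X = freq.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 1e-12
    if keep.sum() < 2:
        raise ConfigError("PCA needs at least 2 non-constant variables")
    if not keep.all():
        dropped = list(freq.columns[~keep])
        warnings.warn(f"dropping zero-variance column(s): {dropped}", stacklevel=2)
    cols = freq.columns[keep]
    Xk = X[:, keep]
    center = Xk.mean(axis=0)
    scale = sd[keep]
    Z = (Xk - center) / scale
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    n = Z.shape[0]
    eig = (s**2) / (n - 1)
    # deterministic sign: largest-|loading| entry positive per PC
    for j in range(vt.shape[0]):
        i_star = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_star] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    pcs = [f"PC{j + 1}" for j in range(len(s))]
    return PCAResult(
        eigenvalues=eig,
        variance_fractions=eig / eig.sum(),
        loadings=pd.DataFrame(vt.T, index=cols, columns=pcs),
        scores=pd.DataFrame(u * s, index=freq.index, columns=pcs),
        center=pd.Series(center, index=cols),
        scale=pd.Series(scale, index=cols),
    )


def retain_pcs(pca: PCAResult, threshold: float = 0.70) -> list[int]:
    """Smallest prefix of PCs whose cumulative variance fraction reaches the threshold."""
    if not (0 < threshold <= 1):
        raise ConfigError("threshold must lie in (0, 1]")
    cum = np.cumsum(pca.variance_fractions)
    j = int(np.searchsorted(cum, threshold - 1e-12))
    return list(range(min(j + 1, len(cum))))


@dataclass
class ContributionResult:
    per_pc: pd.DataFrame      # variables x retained PCs, each column sums to 100
    aggregate: pd.Series      # eigenvalue-weighted mean over retained PCs
    retained: list = field(default_factory=list)


def variable_contributions(
    pca: PCAResult, retained: Sequence[int], eigenvalue_weighted: bool = True
) -> ContributionResult:
    """Percent contribution of each variable to the retained PCs.

    Per PC, the contribution of variable *i* is ``100 * loading(i)^2 /
    sum_i loading(i)^2``; the aggregate is the eigenvalue-weighted mean of
    the per-PC contributions over the retained components (unweighted mean
    available via ``eigenvalue_weighted=False``).
    """
    retained = list(retained)
    if not retained:
        raise ConfigError("retained PC list must be non-empty")
    L = pca.loadings.iloc[:, retained].to_numpy(dtype=float)
    per_pc = 100.0 * (L**2) / (L**2).sum(axis=0, keepdims=True)
    w = pca.eigenvalues[retained] if eigenvalue_weighted else np.ones(len(retained))
    aggregate = per_pc @ w / w.sum()
    cols = [pca.loadings.columns[j] for j in retained]
    return ContributionResult(
        per_pc=pd.DataFrame(per_pc, index=pca.loadings.index, columns=cols),
        aggregate=pd.Series(aggregate, index=pca.loadings.index),
        retained=retained,
    )


def select_populations(contribs: ContributionResult | pd.Series, rule: str = "above_uniform") -> set:
    """Populations contributing strictly more than the uniform expectation (100/p)."""
    if rule != "above_uniform":
        raise ConfigError(f"unknown selection rule {rule!r}")
    agg = contribs.aggregate if isinstance(contribs, ContributionResult) else contribs
    cutoff = 100.0 / len(agg)
    selected = {pop for pop, c in agg.items() if c > cutoff}
    if not selected:
        warnings.warn("no population contributes above the uniform expectation", stacklevel=2)
    return selected


def intersect_timepoints(selections: Mapping[str, set] | Sequence[set]) -> set:
    """Exact intersection of per-timepoint selections (order-invariant)."""
    sets = list(selections.values()) if isinstance(selections, Mapping) else list(selections)
    if len(sets) < 2:
        raise ConfigError("need selections from at least 2 timepoints")
    common = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    if not common:
        warnings.warn("timepoint selections have an empty intersection", stacklevel=2)
    return common


def apply_count_filter(populations: set, sizes: Mapping, min_total: int = 300) -> set:
    """Exclude populations with a pooled cell count below ``min_total``.

    The boundary is inclusive on the keep side: exactly ``min_total`` cells
    is retained ("less than 300" excluded).
    """
    unknown = [p for p in populations if p not in sizes]
    if unknown:
        raise ConfigError(f"unknown population id(s): {unknown[:5]}")
    return {p for p in populations if sizes[p] >= min_total}


def merge_populations(
    populations: set, merge_map: Mapping[str, Sequence], counts: Mapping | None = None
) -> tuple[set, dict]:
    """Apply a manual merge map ``{merged label: [member populations]}``.

    Members must be uniquely assigned; unmapped populations pass through
    unchanged. Returns the merged label set and, when ``counts`` is given,
    summed counts per merged label.
    """
    member_of: dict = {}
    for label, members in merge_map.items():
        for m in members:
            if m in member_of:
                raise ConfigError(f"population {m!r} mapped to two labels")
            member_of[m] = label
    merged: set = set()
    out_counts: dict = {}
    for p in populations:
        label = member_of.get(p, p)
        merged.add(label)
        if counts is not None:
            out_counts[label] = out_counts.get(label, 0) + counts[p]
    return merged, out_counts


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------
@dataclass
class SelectionReport:
    """Everything the selection procedure decided, stage by stage.

    The nesting invariant ``final (pre-merge) <= intersection <= every
    per-timepoint selection`` is asserted at construction.
    """

    per_timepoint: dict            # tp -> {"retained_pcs", "contributions", "selected"}
    intersection: set
    after_count_filter: set
    final: set
    cluster_sizes: dict
    merge_map: dict = field(default_factory=dict)
    merged_counts: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tp, entry in self.per_timepoint.items():
            if not self.intersection <= set(entry["selected"]):
                raise ConfigError(f"nesting violated: intersection not within {tp} selection")
        if not self.after_count_filter <= self.intersection:
            raise ConfigError("nesting violated: count-filtered set not within intersection")

    def to_dict(self) -> dict:
        return {
            "per_timepoint": {
                tp: {
                    "retained_pcs": list(entry["retained_pcs"]),
                    "contributions": {str(k): float(v) for k, v in entry["contributions"].aggregate.items()},
                    "selected": sorted(int(x) for x in entry["selected"]),
                }
                for tp, entry in self.per_timepoint.items()
            },
            "intersection": sorted(int(x) for x in self.intersection),
            "after_count_filter": sorted(int(x) for x in self.after_count_filter),
            "final": sorted(str(x) for x in self.final),
            "cluster_sizes": {str(k): int(v) for k, v in self.cluster_sizes.items()},
            "merge_map": {str(k): [int(x) for x in v] for k, v in self.merge_map.items()},
            "params": self.params,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def run_selection(
    pooled: EventTable,
    *,
    seed: int,
    k: int = 30,
    resolution: float = 1.0,
    variance_threshold: float = 0.70,
    min_count: int = 300,
    merge_map: Mapping[str, Sequence] | None = None,
    n_restarts: int | None = None,
    mode: str = "joint",
    assignment: ClusterAssignment | None = None,
) -> tuple[SelectionReport, ClusterAssignment]:
    """Cluster -> frequencies -> PCA selection -> intersection -> count filter.

    ``mode="joint"`` (default) clusters all samples and timepoints together
    so cluster identities are shared across timepoints, which is what makes
    the cross-timepoint intersection meaningful; ``mode="per_timepoint"``
    clusters each timepoint separately and skips the intersection (the
    union of timepoints is reported instead).
    """
    if mode not in ("joint", "per_timepoint"):
        raise ConfigError(f"unknown clustering mode {mode!r}")
    if not pooled.transformed:
        raise ConfigError("selection expects arcsinh-transformed events")
    timepoints = list(dict.fromkeys(pooled.data["timepoint"]))

    if mode == "joint":
        if assignment is None:
            graph = build_knn_jaccard_graph(pooled.marker_matrix(), k)
            assignment = louvain_cluster(graph, seed=seed, resolution=resolution, n_restarts=n_restarts)
        slices = {}
        for tp in timepoints:
            mask = (pooled.data["timepoint"] == tp).to_numpy()
            sub = EventTable(
                pooled.data.loc[mask],
                pooled.markers,
                transformed=True,
                cofactor=pooled.cofactor,
            )
            slices[tp] = (sub, assignment.labels[mask], assignment.n_clusters)
    else:
        slices = {}
        per_tp_assignments = {}
        for i, tp in enumerate(timepoints):
            mask = (pooled.data["timepoint"] == tp).to_numpy()
            sub = EventTable(
                pooled.data.loc[mask].reset_index(drop=True),
                pooled.markers,
                transformed=True,
                cofactor=pooled.cofactor,
            )
            graph = build_knn_jaccard_graph(sub.marker_matrix(), k)
            a = louvain_cluster(graph, seed=seed + i, resolution=resolution, n_restarts=n_restarts)
            slices[tp] = (sub, a.labels, a.n_clusters)
            per_tp_assignments[tp] = a
        assignment = per_tp_assignments[timepoints[0]]

    per_timepoint = {}
    for tp, (sub, labels, n_clusters) in slices.items():
        freq = frequency_matrix(sub, labels, n_clusters=n_clusters)
        pca = pca_fit(freq)
        retained = retain_pcs(pca, variance_threshold)
        contribs = variable_contributions(pca, retained)
        selected = select_populations(contribs)
        per_timepoint[tp] = {
            "frequencies": freq,
            "retained_pcs": retained,
            "contributions": contribs,
            "selected": selected,
        }

    if mode == "joint" and len(timepoints) >= 2:
        common = intersect_timepoints({tp: e["selected"] for tp, e in per_timepoint.items()})
    else:
        common = set().union(*(e["selected"] for e in per_timepoint.values()))

    if mode == "joint":
        sizes = cluster_total_sizes(assignment)
    else:
        sizes = _pooled_sizes({tp: ClusterAssignment(s[1]) for tp, s in slices.items()})
    filtered = apply_count_filter(common, sizes, min_total=min_count)
    if merge_map:
        final, merged_counts = merge_populations(filtered, merge_map, sizes)
    else:
        final, merged_counts = set(filtered), {}

    report = SelectionReport(
        per_timepoint=per_timepoint,
        intersection=common,
        after_count_filter=filtered,
        final=final,
        cluster_sizes=sizes,
        merge_map=dict(merge_map or {}),
        merged_counts=merged_counts,
        params={
            "k": k,
            "resolution": resolution,
            "variance_threshold": variance_threshold,
            "min_count": min_count,
            "mode": mode,
            "seed": int(seed),
        },
    )
    return report, assignment


def _pooled_sizes(assignments: Mapping[str, ClusterAssignment]) -> dict:
    sizes: dict = {}
    for a in assignments.values():
        for c, s in cluster_total_sizes(a).items():
            sizes[c] = sizes.get(c, 0) + s
    return sizes


def selection_robustness(
    pooled: EventTable,
    reference: SelectionReport,
    reference_assignment: ClusterAssignment,
    *,
    n_boot: int = 20,
    seed: int = 0,
    k: int = 30,
    resolution: float = 1.0,
    variance_threshold: float = 0.70,
    min_count: int = 300,
    n_restarts: int | None = None,
) -> pd.Series:
    """Per-population stability of the final selection under cell bootstrap.

    Cells are resampled with replacement within each sample, the clustering
    and selection rerun, and each reference final population counted as
    re-selected when some selected bootstrap cluster is nearest (Euclidean
    distance of median marker profiles) to that reference cluster. Returns
    the fraction of resamples re-selecting each reference population.
    """
    if n_boot < 10:
        raise ConfigError("n_boot must be >= 10")
    if not reference.after_count_filter:
        return pd.Series(dtype=float)
    ref_profiles = _cluster_medians(pooled, reference_assignment).loc[
        sorted(reference.after_count_filter)
    ]
    hits = {p: 0 for p in reference.after_count_filter}
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xB007]).spawn(n_boot)
    groups = pooled.data.groupby(list(SAMPLE_INDEX), observed=True).indices
    for b in range(n_boot):
        rng = np.random.default_rng(ss[b])
        take = np.concatenate(
            [rng.choice(idx, size=len(idx), replace=True) for idx in groups.values()]
        )
        boot = EventTable(
            pooled.data.iloc[np.sort(take)].reset_index(drop=True),
            pooled.markers,
            transformed=True,
            cofactor=pooled.cofactor,
        )
        report, assignment = run_selection(
            boot,
            seed=seed + 1 + b,
            k=k,
            resolution=resolution,
            variance_threshold=variance_threshold,
            min_count=min_count,
            n_restarts=n_restarts,
        )
        if not report.after_count_filter:
            continue
        boot_profiles = _cluster_medians(boot, assignment)
        for c in report.after_count_filter:
            d = ((ref_profiles - boot_profiles.loc[c]) ** 2).sum(axis=1)
            nearest = d.idxmin()
            if nearest in hits:
                hits[nearest] += 1
    stability = pd.Series({p: min(h, n_boot) / n_boot for p, h in hits.items()}, dtype=float)
    stability.index.name = "population"
    return stability.sort_index()


def _cluster_medians(table: EventTable, assignment: ClusterAssignment) -> pd.DataFrame:
    df = table.data[list(table.markers)].copy()
    df["_cluster"] = assignment.labels
    return df.groupby("_cluster").median()
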