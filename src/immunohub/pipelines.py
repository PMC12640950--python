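"""End-to-end pipelines, fixtures, and reproducibility manifests.

Two pipelines tie the stages together:

* :func:`run_immunophenotype_pipeline` — gate, cluster (PhenoGraph-style),
  frequency matrices, PCA population selection, cross-timepoint
  intersection, count filter, optional manual merge, paired statistics,
  median-expression profiles.
* :func:`run_hubgene_pipeline` — paired differential expression, DEG
  filter, MCC / MCODE / random-forest rankings over the DEG-induced
  interaction network, three-way hub intersection, GSEA and
  over-representation.

Each run can write its artifacts to a directory together with a manifest
recording every parameter, the seed fan-out and a SHA-256 digest of every
output file, so a rerun with the same master seed is checkable
byte-for-byte. The fixture builders generate the packaged synthetic study
at configurable size.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterAssignment, cluster_median_profile, tsne_embed
from .enrich import GeneSet, gsea_significance, ora_hypergeometric, signal_to_noise_rank
from .errors import ConfigError, PipelineError
from .events import EventTable, GateSpec, arcsinh_transform, concat_event_tables
from .graph import WeightedGraph
from .netrank import (
    HubReport,
    filter_degs,
    hub_intersection,
    mcc_rank,
    mcode_modules,
    rf_importance_rank,
    simple_paired_de,
)
from .selection import SelectionReport, run_selection
from .simulate import (
    SimCytoConfig,
    default_cyto_config,
    default_expr_config,
    default_net_config,
    expression_sample_info,
    simulate_cytometry,
    simulate_expression,
    simulate_gene_sets,
    simulate_ppi,
)
from .stats import longitudinal_compare

__all__ = [
    "ImmunoResult",
    "HubResult",
    "run_immunophenotype_pipeline",
    "run_hubgene_pipeline",
    "fixture_immuno_inputs",
    "fixture_hub_inputs",
    "final_frequency_table",
    "load_immuno_params",
]

_FLOAT_FMT = "%.10g"

#: keyword arguments a YAML parameter file may set for the immunophenotype
#: pipeline (anything else is rejected to catch typos early)
_IMMUNO_PARAM_KEYS = {
    "cofactor", "k", "resolution", "n_restarts", "variance_threshold",
    "min_count", "merge_map", "mode", "tsne_points",
}


def load_immuno_params(path: str | Path) -> dict:
    """Read pipeline parameters (including a merge map) from a YAML file.

    The file holds keyword arguments for
    :func:`run_immunophenotype_pipeline`, e.g.::

        k: 30
        variance_threshold: 0.70
        min_count: 300
        merge_map:
          apoptotic: [0, 2]
          resting: [1, 3]
    """
    params = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(params) - _IMMUNO_PARAM_KEYS
    if unknown:
        raise ConfigError(f"unknown pipeline parameter(s): {sorted(unknown)}")
    return params


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, params: dict, outputs: Sequence[Path]) -> Path:
    manifest = {
        "package_version": __version__,
        "params": params,
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


# ---------------------------------------------------------------------------
# immunophenotyping
# ---------------------------------------------------------------------------
@dataclass
class ImmunoResult:
    report: SelectionReport
    assignment: ClusterAssignment
    pooled: EventTable
    stats: pd.DataFrame
    median_profile: pd.DataFrame
    final_frequencies: pd.DataFrame
    manifest_path: Path | None = None


def final_frequency_table(report: SelectionReport) -> pd.DataFrame:
    """Per-sample frequencies of the final populations across all timepoints.

    Merged labels sum their member clusters; columns are the final
    population labels, rows all (donor, arm, timepoint) samples.
    """
    frames = [entry["frequencies"] for entry in report.per_timepoint.values()]
    freq = pd.concat(frames)
    member_of: dict = {}
    for label, members in report.merge_map.items():
        for m in members:
            member_of[m] = label
    out = {}
    for pop in sorted(report.final, key=str):
        members = [c for c in report.after_count_filter if member_of.get(c, c) == pop]
        if members:
            out[pop] = freq[members].sum(axis=1)
    return pd.DataFrame(out)


def run_immunophenotype_pipeline(
    tables: Mapping[tuple, EventTable] | EventTable,
    *,
    seed: int,
    out_dir: str | Path | None = None,
    cofactor: float = 150.0,
    gate: GateSpec | None = None,
    k: int = 30,
    resolution: float = 1.0,
    n_restarts: int | None = None,
    variance_threshold: float = 0.70,
    min_count: int = 300,
    merge_map: Mapping[str, Sequence] | None = None,
    mode: str = "joint",
    tsne_points: int = 0,
) -> ImmunoResult:
    """Gate -> cluster -> select -> compare, with optional artifact export.

    ``tables`` is either the per-sample dict from the generator/reader or
    an already pooled event table; raw tables are arcsinh-transformed with
    ``cofactor`` first. ``tsne_points`` > 0 additionally embeds a seeded
    subsample of cells for display export.
    """
    from .events import gate_events  # local import to keep module graph simple

    with _stage("pool"):
        pooled = tables if isinstance(tables, EventTable) else concat_event_tables(list(tables.values()))
    with _stage("transform"):
        if not pooled.transformed:
            pooled = arcsinh_transform(pooled, cofactor)
    if gate is not None:
        with _stage("gate"):
            pooled = gate_events(pooled, gate)
    with _stage("cluster+select"):
        report, assignment = run_selection(
            pooled,
            seed=seed,
            k=k,
            resolution=resolution,
            variance_threshold=variance_threshold,
            min_count=min_count,
            merge_map=merge_map,
            n_restarts=n_restarts,
            mode=mode,
        )
    with _stage("statistics"):
        final_freq = final_frequency_table(report)
        arms = tuple(dict.fromkeys(pooled.data["arm"]))
        if len(final_freq.columns) and len(arms) == 2:
            stats = longitudinal_compare(final_freq, arms)  # type: ignore[arg-type]
        else:
            stats = pd.DataFrame(
                columns=["population", "timepoint", "n_pairs", "t", "p", "untestable", "q", "stars"]
            )
            if not len(final_freq.columns):
                warnings.warn("empty final population set; no statistics computed", stacklevel=2)
    with _stage("profiles"):
        profile = cluster_median_profile(pooled, assignment)

    manifest_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs = []
        with _stage("export"):
            p = out_dir / "selection_report.json"
            report.to_json(p)
            outputs.append(p)
            p = out_dir / "final_frequencies.tsv"
            final_freq.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
            outputs.append(p)
            p = out_dir / "arm_comparison.tsv"
            stats.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
            outputs.append(p)
            p = out_dir / "median_profiles.tsv"
            profile.values.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
            outputs.append(p)
            p = out_dir / "cluster_assignments.csv"
            pd.DataFrame(
                {
                    "donor": pooled.data["donor"],
                    "arm": pooled.data["arm"],
                    "timepoint": pooled.data["timepoint"],
                    "cluster": assignment.labels,
                }
            ).to_csv(p, index=False)
            outputs.append(p)
            for tp, entry in report.per_timepoint.items():
                p = out_dir / f"frequency_matrix_{tp}.tsv"
                entry["frequencies"].to_csv(p, sep="\t", float_format=_FLOAT_FMT)
                outputs.append(p)
            if tsne_points > 0:
                rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x75E]))
                take = rng.choice(pooled.n_cells, size=min(tsne_points, pooled.n_cells), replace=False)
                take.sort()
                coords = tsne_embed(pooled.marker_matrix()[take], seed=seed)
                p = out_dir / "tsne_coordinates.csv"
                pd.DataFrame(
                    {"cell": take, "tsne1": coords[:, 0], "tsne2": coords[:, 1],
                     "cluster": assignment.labels[take]}
                ).to_csv(p, index=False, float_format=_FLOAT_FMT)
                outputs.append(p)
            params = {
                "seed": int(seed), "cofactor": cofactor, "k": k, "resolution": resolution,
                "variance_threshold": variance_threshold, "min_count": min_count,
                "mode": mode, "gated": gate is not None,
                "merge_map": {str(kk): list(map(int, v)) for kk, v in (merge_map or {}).items()},
            }
            manifest_path = _write_manifest(out_dir, params, outputs)

    return ImmunoResult(report, assignment, pooled, stats, profile.values, final_freq, manifest_path)


def fixture_immuno_inputs(
    seed: int = 0, cells_per_sample: int = 2500, n_donors: int = 6, rare_total: int = 250
) -> tuple[dict, "SimCytoConfig", object]:
    """Packaged synthetic immunophenotyping study (generated, not stored)."""
    cfg = default_cyto_config(
        seed, cells_per_sample=cells_per_sample, n_donors=n_donors, rare_total=rare_total
    )
    tables, truth = simulate_cytometry(cfg)
    return tables, cfg, truth


# ---------------------------------------------------------------------------
# hub genes
# ---------------------------------------------------------------------------
@dataclass
class HubResult:
    de_table: pd.DataFrame
    degs: pd.DataFrame
    hub_report: HubReport
    mcode: list
    rf_ranking: pd.DataFrame
    gsea: list
    ora: pd.DataFrame
    manifest_path: Path | None = None


def run_hubgene_pipeline(
    counts: pd.DataFrame,
    sample_info: pd.DataFrame,
    ppi: WeightedGraph,
    gene_sets: Sequence[GeneSet],
    *,
    seed: int,
    out_dir: str | Path | None = None,
    de_table: pd.DataFrame | None = None,
    lfc_min: float = 1.0,
    q_max: float = 0.05,
    mcc_top_n: int = 154,
    mcode_node_score_cutoff: float = 0.2,
    rf_top_n: int = 46,
    n_trees: int = 2000,
    gsea_n_perm: int = 1000,
    gsea_mode: str = "gene_set",
    gsea_weight_p: float = 1.0,
) -> HubResult:
    """DE -> DEG filter -> MCC/MCODE/RF -> intersection -> GSEA/ORA.

    A precomputed DE table (gene-indexed, columns log2fc and q) bypasses
    the built-in paired test. An empty DEG set downgrades the network and
    forest stages to empty results with a warning rather than failing.
    """
    with _stage("differential expression"):
        de = de_table if de_table is not None else simple_paired_de(counts, sample_info)
    with _stage("deg filter"):
        degs = filter_degs(de, lfc_min=lfc_min, q_max=q_max)
    arms = tuple(dict.fromkeys(sample_info["arm"]))

    if len(degs) == 0:
        warnings.warn("no genes pass the DEG filter; hub report is empty", stacklevel=2)
        hub_report = hub_intersection((), (), (), de)
        mcode: list = []
        rf_rank = pd.DataFrame(columns=["mda", "mdg", "rank_mda", "rank_mdg", "combined_rank"])
    else:
        with _stage("network restriction"):
            deg_in_graph = [g for g in degs.index if g in set(ppi.node_names)]
            subnet = ppi.subgraph(deg_in_graph) if deg_in_graph else ppi.subgraph([])
        with _stage("mcc"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mcc = mcc_rank(subnet, top_n=min(mcc_top_n, max(subnet.n_nodes, 1)))
            mcc_set = tuple(mcc.index[mcc["mcc"] > 0])
        with _stage("mcode"):
            mcode = mcode_modules(subnet, node_score_cutoff=mcode_node_score_cutoff)
            mcode_set = tuple(sorted({g for m in mcode for g in m.members}, key=str))
        with _stage("random forest"):
            cpm = counts / counts.sum(axis=0) * 1e6
            expr = np.log2(cpm + 1.0).loc[degs.index]
            rf_rank = rf_importance_rank(expr, sample_info["arm"].to_numpy(), n_trees=n_trees, seed=seed)
            rf_set = tuple(rf_rank.index[rf_rank["combined_rank"] <= rf_top_n])
        with _stage("hub intersection"):
            hub_report = hub_intersection(mcc_set, mcode_set, rf_set, de)

    with _stage("gsea"):
        cpm = counts / counts.sum(axis=0) * 1e6
        expr_all = np.log2(cpm + 1.0)
        ranked = signal_to_noise_rank(expr_all, sample_info["arm"].to_numpy(), arms[0], arms[1])
        usable = [s for s in gene_sets if any(g in set(ranked.genes) for g in s.members)]
        gsea = gsea_significance(
            ranked, usable, n_perm=gsea_n_perm, mode=gsea_mode, seed=seed,
            weight_p=gsea_weight_p, expr=expr_all,
            labels=sample_info["arm"].to_numpy(), classes=(arms[0], arms[1]),
        )
    with _stage("ora"):
        ora = ora_hypergeometric(list(degs.index), list(gene_sets), list(counts.index))

    manifest_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs = []
        with _stage("export"):
            p = out_dir / "de_table.tsv"
            de.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
            outputs.append(p)
            p = out_dir / "deg_table.tsv"
            degs.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
            outputs.append(p)
            p = out_dir / "hub_report.json"
            hub_report.to_json(p)
            outputs.append(p)
            p = out_dir / "venn_counts.csv"
            pd.Series(hub_report.venn_counts).rename("n_genes").to_csv(p)
            outputs.append(p)
            p = out_dir / "rf_ranking.tsv"
            rf_rank.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
            outputs.append(p)
            p = out_dir / "gsea_results.tsv"
            pd.DataFrame(
                [
                    {"set": r.name, "n_members": r.n_members, "es": r.es, "nes": r.nes,
                     "p": r.p, "fdr_q": r.fdr_q, "leading_edge": "|".join(map(str, r.leading_edge))}
                    for r in gsea
                ]
            ).to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
            outputs.append(p)
            for r in gsea:
                p = out_dir / f"running_sum_{r.name}.csv"
                pd.DataFrame({"rank": np.arange(1, len(r.running_sum) + 1),
                              "running_es": r.running_sum}).to_csv(
                    p, index=False, float_format=_FLOAT_FMT
                )
                outputs.append(p)
            p = out_dir / "ora_results.tsv"
            ora.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
            outputs.append(p)
            params = {
                "seed": int(seed), "lfc_min": lfc_min, "q_max": q_max,
                "mcc_top_n": mcc_top_n, "rf_top_n": rf_top_n, "n_trees": n_trees,
                "mcode_node_score_cutoff": mcode_node_score_cutoff,
                "gsea_n_perm": gsea_n_perm, "gsea_mode": gsea_mode,
                "gsea_weight_p": gsea_weight_p,
            }
            manifest_path = _write_manifest(out_dir, params, outputs)

    return HubResult(de, degs, hub_report, mcode, rf_rank, gsea, ora, manifest_path)


def fixture_hub_inputs(seed: int = 0, n_genes: int = 2000, n_deg: int = 150):
    """Packaged synthetic hub-gene study.

    Simulated paired counts with planted DEGs; a scale-free PPI whose
    planted dense module comprises the strongest downregulated planted
    genes; gene sets with one planted set made of planted DEGs. Returns
    ``(counts, sample_info, ppi, gene_sets, truth)``.
    """
    expr_cfg = default_expr_config(seed, n_genes=n_genes, n_deg=n_deg)
    counts, truth = simulate_expression(expr_cfg)
    sample_info = expression_sample_info(expr_cfg)
    planted = list(truth.index[truth["is_deg"]])
    down = sorted(
        (g for g in planted if truth.loc[g, "log2fc"] < 0),
        key=lambda g: truth.loc[g, "log2fc"],
    )
    module = (down or planted)[:10]
    net_cfg = default_net_config(module, seed=seed)
    ppi = simulate_ppi(net_cfg, list(counts.index))
    set_dict = simulate_gene_sets(list(counts.index), planted, n_null_sets=20, set_size=25, seed=seed)
    gene_sets = [GeneSet(name, tuple(members)) for name, members in set_dict.items()]
    return counts, sample_info, ppi, gene_sets, truth
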