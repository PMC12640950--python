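"""Synthetic data generators with planted ground truth.

Three generators emulate the statistical structure of a paired two-arm
CAR-T study so the analysis pipelines can be validated by parameter
recovery:

* :func:`simulate_cytometry` — multi-marker event tables for paired donors
  across two arms and several timepoints. Each cell population is a
  Gaussian on the arcsinh scale; per-sample population frequencies follow a
  Dirichlet-multinomial with configurable concentration (donor
  variability); selected populations carry planted arm-specific frequency
  shifts, and an optional rare population is planted below the pipeline's
  count-exclusion threshold.
* :func:`simulate_expression` — paired negative-binomial RNA-seq counts
  with planted differentially expressed genes at |log2FC| >= 1.
* :func:`simulate_ppi` — a scale-free (preferential-attachment) background
  network with one planted dense module among chosen genes.

Every generator is a pure function of its config (including the seed): the
master seed fans out to per-sample streams through
``numpy.random.SeedSequence`` spawning, so identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .events import EventTable
from .graph import WeightedGraph

__all__ = [
    "PopulationSpec",
    "SimCytoConfig",
    "SimCytoTruth",
    "simulate_cytometry",
    "SimExprConfig",
    "simulate_expression",
    "SimNetConfig",
    "simulate_ppi",
    "simulate_gene_sets",
    "default_cyto_config",
    "default_expr_config",
    "default_net_config",
]

_FREQ_TOL = 1e-9


# ---------------------------------------------------------------------------
# cytometry
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PopulationSpec:
    """One cell population: Gaussian marker profile on the arcsinh scale."""

    name: str
    means: tuple[float, ...]
    sds: tuple[float, ...]
    baseline_freq: float = 0.0

    def __post_init__(self) -> None:
        if len(self.means) != len(self.sds):
            raise ConfigError(f"population {self.name!r}: means/sds length mismatch")
        if any(s <= 0 for s in self.sds):
            raise ConfigError(f"population {self.name!r}: all sds must be > 0")


@dataclass(frozen=True)
class SimCytoConfig:
    markers: tuple[str, ...]
    populations: tuple[PopulationSpec, ...]
    n_donors: int = 6
    arms: tuple[str, str] = ("CAR", "DT.CAR")
    timepoints: tuple[str, ...] = ("day11", "day14")
    effect_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    cells_per_sample: int = 10_000
    donor_concentration: float | None = 200.0
    rare_population: PopulationSpec | None = None
    rare_population_total: int = 0
    panel_id: str = "panel1"
    cofactor: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ConfigError("at least one population is required")
        if len(self.arms) != 2:
            raise ConfigError("exactly two arms are required")
        if self.n_donors < 1:
            raise ConfigError("n_donors must be >= 1")
        if self.cells_per_sample < 1:
            raise ConfigError("cells_per_sample must be >= 1")
        total = sum(p.baseline_freq for p in self.populations)
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"baseline frequencies must sum to 1 (got {total:.6f})")
        for p in self.populations:
            if len(p.means) != len(self.markers):
                raise ConfigError(f"population {p.name!r}: wrong marker dimension")
        names = {p.name for p in self.populations}
        if len(names) != len(self.populations):
            raise ConfigError("population names must be unique")
        for pop in self.effect_map:
            if pop not in names:
                raise ConfigError(f"effect for unknown population {pop!r}")
        if self.rare_population is not None:
            if len(self.rare_population.means) != len(self.markers):
                raise ConfigError("rare population: wrong marker dimension")
            if self.rare_population_total <= 0:
                raise ConfigError("rare_population_total must be > 0 when a rare population is set")
        if self.donor_concentration is not None and self.donor_concentration <= 0:
            raise ConfigError("donor_concentration must be > 0 or None")


@dataclass
class SimCytoTruth:
    """Realized per-sample population frequencies plus per-population flags.

    Flags: ``planted_shift`` (population carries an arm-specific frequency
    multiplier), ``sub_threshold`` (the planted rare population) or
    ``null``.
    """

    frequencies: pd.DataFrame  # donor, arm, timepoint, population, frequency
    flags: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "flags": self.flags,
            "frequencies": self.frequencies.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _arm_weights(cfg: SimCytoConfig, arm: str) -> np.ndarray:
    w = np.array([p.baseline_freq for p in cfg.populations], dtype=float)
    for i, p in enumerate(cfg.populations):
        mult = cfg.effect_map.get(p.name, {}).get(arm, 1.0)
        w[i] *= mult
    return w / w.sum()


def simulate_cytometry(cfg: SimCytoConfig) -> tuple[dict, SimCytoTruth]:
    """Generate one raw-scale event table per (donor, arm, timepoint).

    Marker values are drawn per population as Gaussians on the arcsinh
    scale and emitted on the raw scale (``cofactor * sinh``, clipped at 0)
    so the tables enter the pipeline exactly like exported instrument data.
    Each table gains a ``true_population`` annotation column (synthetic
    provenance; ignored by the pipeline, used by recovery tests).
    """
    donors = tuple(f"D{i + 1}" for i in range(cfg.n_donors))
    keys = [(d, a, tp) for d in donors for a in cfg.arms for tp in cfg.timepoints]
    children = np.random.SeedSequence(cfg.seed).spawn(len(keys) + 1)

    # fixed allocation of the planted rare population across samples
    alloc_rng = np.random.default_rng(children[-1])
    if cfg.rare_population is not None:
        rare_alloc = alloc_rng.multinomial(
            cfg.rare_population_total, np.full(len(keys), 1.0 / len(keys))
        )
    else:
        rare_alloc = np.zeros(len(keys), dtype=int)

    pop_names = [p.name for p in cfg.populations]
    all_names = pop_names + ([cfg.rare_population.name] if cfg.rare_population else [])
    means = np.array([p.means for p in cfg.populations], dtype=float)
    sds = np.array([p.sds for p in cfg.populations], dtype=float)

    tables: dict[tuple[str, str, str], EventTable] = {}
    truth_rows = []
    for (key, child, n_rare) in zip(keys, children, rare_alloc):
        donor, arm, tp = key
        rng = np.random.default_rng(child)
        weights = _arm_weights(cfg, arm)
        if cfg.donor_concentration is not None:
            weights = rng.dirichlet(weights * cfg.donor_concentration)
        n_rare = min(int(n_rare), cfg.cells_per_sample - 1)
        n_main = cfg.cells_per_sample - n_rare
        counts = rng.multinomial(n_main, weights)

        blocks, labels = [], []
        for i, n_i in enumerate(counts):
            if n_i == 0:
                continue
            blocks.append(rng.normal(means[i], sds[i], size=(n_i, len(cfg.markers))))
            labels.extend([pop_names[i]] * n_i)
        if n_rare:
            rp = cfg.rare_population
            blocks.append(
                rng.normal(np.array(rp.means), np.array(rp.sds), size=(n_rare, len(cfg.markers)))
            )
            labels.extend([rp.name] * n_rare)
        asinh_values = np.vstack(blocks)
        raw = np.clip(cfg.cofactor * np.sinh(asinh_values), 0.0, None)

        order = rng.permutation(len(raw))
        df = pd.DataFrame(raw[order], columns=list(cfg.markers))
        df.insert(0, "donor", donor)
        df.insert(1, "arm", arm)
        df.insert(2, "timepoint", tp)
        df.insert(3, "panel", cfg.panel_id)
        df["true_population"] = np.asarray(labels, dtype=object)[order]
        tables[key] = EventTable(df, cfg.markers, transformed=False)

        full_counts = np.append(counts, n_rare) if cfg.rare_population else counts
        freqs = full_counts / cfg.cells_per_sample
        assert abs(freqs.sum() - 1.0) < _FREQ_TOL
        for name, f in zip(all_names, freqs):
            truth_rows.append(
                {"donor": donor, "arm": arm, "timepoint": tp, "population": name, "frequency": f}
            )

    flags = {}
    for p in cfg.populations:
        shifted = any(abs(m - 1.0) > 1e-12 for m in cfg.effect_map.get(p.name, {}).values())
        flags[p.name] = "planted_shift" if shifted else "null"
    if cfg.rare_population is not None:
        flags[cfg.rare_population.name] = "sub_threshold"
    return tables, SimCytoTruth(pd.DataFrame(truth_rows), flags)


def write_event_tables(tables: Mapping, out_dir: str | Path) -> list[Path]:
    """Write one CSV per sample (metadata columns first, then markers)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (donor, arm, tp), table in tables.items():
        safe_arm = arm.replace(".", "")
        p = out_dir / f"events_{donor}_{safe_arm}_{tp}.csv"
        table.data.to_csv(p, index=False, float_format="%.6g")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SimExprConfig:
    n_genes: int = 2000
    n_donors: int = 3
    arms: tuple[str, str] = ("CAR", "DT.CAR")
    planted_log2fc: Mapping[int, float] = field(default_factory=dict)
    # residual (within-donor technical) dispersion; between-donor biological
    # variation is modelled separately via donor_sd and cancels in pairing
    dispersion: float = 0.002
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    donor_sd: float = 0.15
    base_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ConfigError("paired testing requires n_donors >= 2")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        for idx, lfc in self.planted_log2fc.items():
            if not (0 <= idx < self.n_genes):
                raise ConfigError(f"planted gene index {idx} out of range")
            if abs(lfc) < 1.0:
                raise ConfigError(f"planted |log2FC| must be >= 1 (gene {idx}: {lfc})")
        if not (0 < self.lib_size_range[0] <= self.lib_size_range[1]):
            raise ConfigError("invalid library-size range")


def simulate_expression(cfg: SimExprConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired negative-binomial counts: genes x (2 * n_donors) samples.

    The second arm multiplies planted genes by ``2**log2FC``. A per-donor,
    per-gene log-normal effect is shared between the two arms of the same
    donor, which is exactly the nuisance structure a paired test removes.
    Returns ``(counts, truth)`` where truth lists each gene's planted
    log2FC (0 for nulls).
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    base = np.exp(rng.normal(0.0, cfg.base_log_sd, cfg.n_genes))
    # keep planted genes comfortably expressed so their fold change is measurable
    for idx in cfg.planted_log2fc:
        base[idx] = max(base[idx], float(np.exp(2.5)))
    lfc = np.zeros(cfg.n_genes)
    for idx, value in cfg.planted_log2fc.items():
        lfc[idx] = value

    donors = [f"D{i + 1}" for i in range(cfg.n_donors)]
    columns, data = [], []
    donor_effect = rng.normal(0.0, cfg.donor_sd, size=(cfg.n_donors, cfg.n_genes))
    for d, donor in enumerate(donors):
        for a, arm in enumerate(cfg.arms):
            lib = rng.uniform(*cfg.lib_size_range)
            log2_mean = np.log2(base) + donor_effect[d] + (lfc if a == 1 else 0.0)
            rel = np.exp2(log2_mean)
            mu = lib * rel / rel.sum()
            shape = 1.0 / cfg.dispersion
            lam = rng.gamma(shape, mu * cfg.dispersion)
            data.append(rng.poisson(lam))
            columns.append(f"{donor}_{arm}")
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    truth = pd.DataFrame(
        {"gene": genes, "log2fc": lfc, "is_deg": [i in cfg.planted_log2fc for i in range(cfg.n_genes)]}
    ).set_index("gene")
    return counts, truth


def expression_sample_info(cfg: SimExprConfig) -> pd.DataFrame:
    """Sample sheet (donor, arm) matching :func:`simulate_expression` columns."""
    rows = []
    for d in range(cfg.n_donors):
        for arm in cfg.arms:
            rows.append({"sample": f"D{d + 1}_{arm}", "donor": f"D{d + 1}", "arm": arm})
    return pd.DataFrame(rows).set_index("sample")


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SimNetConfig:
    attachment_m: int = 2
    module_genes: tuple[str, ...] = ()
    module_density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.module_density <= 1):
            raise ConfigError("module density must be in (0, 1]")
        if self.module_genes and len(self.module_genes) < 3:
            raise ConfigError("planted module needs >= 3 genes")
        if self.attachment_m < 1:
            raise ConfigError("attachment_m must be >= 1")


def simulate_ppi(cfg: SimNetConfig, gene_names: Sequence[str]) -> WeightedGraph:
    """Scale-free background (Barabasi-Albert) plus one planted dense module.

    The planted module adds ``round(density * C(s, 2))`` edges chosen
    uniformly among the module pairs; background edges inside the module
    can only raise its realized density. Node-to-gene assignment is
    shuffled so hub status is independent of input order.
    """
    gene_names = list(gene_names)
    n = len(gene_names)
    missing = [g for g in cfg.module_genes if g not in gene_names]
    if missing:
        raise ConfigError(f"module genes not in gene set: {missing[:5]}")
    if len(cfg.module_genes) > n:
        raise ConfigError("module larger than the gene universe")
    if n <= cfg.attachment_m:
        raise ConfigError("need more genes than the attachment parameter")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    bg = nx.barabasi_albert_graph(n, cfg.attachment_m, seed=int(rng.integers(2**31 - 1)))
    assignment = rng.permutation(n)  # node i -> gene_names[assignment[i]]
    pairs = {(min(u, v), max(u, v)) for u, v in ((assignment[a], assignment[b]) for a, b in bg.edges())}

    module_idx = [gene_names.index(g) for g in cfg.module_genes]
    module_pairs = [
        (min(a, b), max(a, b))
        for k, a in enumerate(module_idx)
        for b in module_idx[k + 1 :]
    ]
    n_add = int(round(cfg.module_density * len(module_pairs)))
    chosen = rng.choice(len(module_pairs), size=n_add, replace=False) if module_pairs else []
    pairs.update(module_pairs[i] for i in np.sort(np.asarray(chosen, dtype=int)))

    edges = np.array(sorted(pairs), dtype=np.int64) if pairs else np.empty((0, 2), np.int64)
    return WeightedGraph(tuple(gene_names), edges, np.ones(len(edges)))


def simulate_gene_sets(
    universe: Sequence[str],
    planted_genes: Sequence[str],
    n_null_sets: int = 20,
    set_size: int = 25,
    seed: int = 0,
) -> dict:
    """One planted (truly coherent) gene set plus random null sets.

    The planted set is the given gene list; null sets are uniform draws
    from the universe. Returned as ``{name: member list}`` ready for GMT
    export.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = list(universe)
    if not set(planted_genes) <= set(universe):
        raise ConfigError("planted genes must lie in the universe")
    sets = {"PLANTED_SET": list(planted_genes)}
    for i in range(n_null_sets):
        members = rng.choice(len(universe), size=min(set_size, len(universe)), replace=False)
        sets[f"NULL_SET_{i + 1:02d}"] = [universe[j] for j in np.sort(members)]
    return sets


# ---------------------------------------------------------------------------
# study-condition fixtures
# ---------------------------------------------------------------------------
_PANEL1 = ("CD3", "CD4", "Apotracker", "CD95", "CD253", "7AAD")

# Marker profiles on the arcsinh scale: hi ~= 3.5, lo ~= 0.5, as seen for
# cleanly separated compartments after arcsinh with cofactor 150.
_HI, _LO = 3.5, 0.5


def _pop(name: str, pattern: Sequence[int], freq: float, sd: float = 0.4) -> PopulationSpec:
    means = tuple(_HI if bit else _LO for bit in pattern)
    return PopulationSpec(name, means, tuple([sd] * len(pattern)), freq)


def default_cyto_config(
    seed: int = 0,
    cells_per_sample: int = 10_000,
    n_donors: int = 6,
    timepoints: tuple[str, ...] = ("day11", "day14"),
    rare_total: int = 250,
    shift_multiplier: float = 0.45,
) -> SimCytoConfig:
    """Study-condition cytometry fixture.

    Six paired donors, two arms, the apoptosis panel (CD3/CD4/Apotracker/
    CD95/CD253 plus 7AAD viability), five major populations, one planted
    arm shift — the CD4+ apoptotic population drops from ~30% to ~16% of
    events in the TCF-1 arm, a >10 percentage-point shift — and a planted
    rare population totalling fewer than 300 cells pooled.
    """
    # pattern over (CD3, CD4, Apotracker, CD95, CD253, 7AAD)
    populations = (
        _pop("CD4_apoptotic", (1, 1, 1, 1, 1, 0), 0.30),
        _pop("CD4_resting", (1, 1, 0, 0, 0, 0), 0.25),
        _pop("CD8_resting", (1, 0, 0, 0, 0, 0), 0.20),
        _pop("CD8_apoptotic", (1, 0, 1, 1, 0, 0), 0.15),
        _pop("CD4_primed", (1, 1, 0, 1, 0, 0), 0.10),
    )
    rare = _pop("rare_artifact", (0, 0, 0, 0, 1, 0), 0.0) if rare_total else None
    return SimCytoConfig(
        markers=_PANEL1,
        populations=populations,
        n_donors=n_donors,
        timepoints=tuple(timepoints),
        effect_map={"CD4_apoptotic": {"DT.CAR": shift_multiplier}},
        cells_per_sample=cells_per_sample,
        rare_population=rare,
        rare_population_total=rare_total,
        seed=seed,
    )


def cluster_truth_map(table: EventTable, labels: np.ndarray) -> pd.DataFrame:
    """Majority true population per cluster (synthetic tables only).

    Uses the generator's ``true_population`` annotation column to report,
    for each cluster, the dominant planted population and its purity.
    """
    if "true_population" not in table.data.columns:
        raise ConfigError("table has no true_population column (not a synthetic table?)")
    df = pd.DataFrame({"cluster": np.asarray(labels), "truth": table.data["true_population"].to_numpy()})
    rows = []
    for cluster, grp in df.groupby("cluster"):
        top = grp["truth"].value_counts()
        rows.append(
            {"cluster": int(cluster), "population": top.index[0],
             "purity": float(top.iloc[0] / len(grp)), "size": len(grp)}
        )
    return pd.DataFrame(rows).set_index("cluster")


def default_expr_config(seed: int = 0, n_genes: int = 2000, n_deg: int = 150) -> SimExprConfig:
    """Paired 3-donor RNA-seq fixture with planted DEGs, mostly downregulated."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 90210]))
    idx = rng.choice(n_genes, size=n_deg, replace=False)
    signs = np.where(rng.random(n_deg) < 0.7, -1.0, 1.0)  # downregulation dominates
    magnitudes = rng.uniform(1.0, 3.0, n_deg)
    planted = {int(i): float(s * m) for i, s, m in zip(idx, signs, magnitudes)}
    return SimExprConfig(n_genes=n_genes, n_donors=3, planted_log2fc=planted, seed=seed)


def default_net_config(module_genes: Sequence[str], seed: int = 0) -> SimNetConfig:
    return SimNetConfig(attachment_m=2, module_genes=tuple(module_genes), module_density=0.9, seed=seed)
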