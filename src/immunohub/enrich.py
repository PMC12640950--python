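"""Gene-set analytics: signal-to-noise ranking, GSEA, over-representation.

The GSEA statistic follows the canonical weighted Kolmogorov-Smirnov-like
running sum: genes are ranked by the signal-to-noise metric
``(mu_A - mu_B) / (sigma_A + sigma_B)`` (with the canonical standard-
deviation floor ``max(0.2 * |mu|, 0.2)`` per class); walking down the list,
set members increment the sum by ``|metric|^p`` normalised over hits and
non-members decrement it by ``1 / (N - N_hits)``. The enrichment score ES
is the extremum furthest from zero, the leading edge the members before
(positive ES) or after (negative ES) the peak. Significance comes from
random same-size gene sets (default, appropriate for tiny sample sizes) or
phenotype permutations; NES normalises by the mean same-sign null ES, and
FDR follows the standard NES-based procedure.

Over-representation is the upper-tail hypergeometric test with BH
adjustment across sets. Gene sets are read and written as GMT (tab-
separated: name, description, members).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ParseError

__all__ = [
    "GeneSet",
    "RankedGeneList",
    "EnrichmentScore",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "signal_to_noise_rank",
    "gsea_es",
    "gsea_significance",
    "ora_hypergeometric",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ConfigError(f"gene set {self.name!r} has duplicate members")


@dataclass
class RankedGeneList:
    """Genes in descending metric order with their metric values."""

    genes: tuple
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ConfigError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ConfigError("ranked list has duplicate genes")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ConfigError("scores must be in descending order")


@dataclass
class EnrichmentScore:
    es: float
    running_sum: np.ndarray
    peak_index: int
    leading_edge: tuple


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    p: float
    fdr_q: float
    leading_edge: tuple
    running_sum: np.ndarray
    n_members: int


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------
def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"GMT line {lineno}: need name, description and >= 1 member")
        members = tuple(dict.fromkeys(p for p in parts[2:] if p))
        sets.append(GeneSet(parts[0], members, parts[1]))
    return sets


def write_gmt(sets: Sequence[GeneSet] | Mapping[str, Sequence], path: str | Path) -> None:
    if isinstance(sets, Mapping):
        sets = [GeneSet(name, tuple(members)) for name, members in sets.items()]
    lines = ["\t".join([s.name, s.description or "na", *map(str, s.members)]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ranking metric
# ---------------------------------------------------------------------------
def _floored_sd(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(len(values))
    floor = np.maximum(0.2 * np.abs(mu), 0.2)
    return mu, np.maximum(sd, floor)


def signal_to_noise_rank(
    expr: pd.DataFrame, labels: Sequence[str], class_a: str, class_b: str
) -> RankedGeneList:
    """Per-gene signal-to-noise ranking, descending; ties break by gene id."""
    labels = np.asarray(labels)
    mask_a, mask_b = labels == class_a, labels == class_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ConfigError("each class needs >= 2 samples")
    values = expr.to_numpy(dtype=float)
    mu_a, sd_a = _floored_sd(values[:, mask_a])
    mu_b, sd_b = _floored_sd(values[:, mask_b])
    s2n = (mu_a - mu_b) / (sd_a + sd_b)
    order = np.lexsort((np.asarray(expr.index, dtype=object), -s2n))
    return RankedGeneList(tuple(expr.index[order]), s2n[order])


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------
def _running_sum(scores: np.ndarray, hit_mask: np.ndarray, weight_p: float) -> np.ndarray:
    n = len(scores)
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ConfigError("gene set must hit some but not all of the ranked list")
    w = np.abs(scores) ** weight_p
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total <= 0:  # all hit metrics are exactly zero: fall back to uniform steps
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    # ratio-of-cumsums form: exact +-1 at the boundary cases (a single member
    # at the top or bottom of the list), unlike a cumsum of signed steps
    return np.cumsum(hit_w) / total - np.cumsum(~hit_mask) / (n - n_hits)


def gsea_es(ranked: RankedGeneList, gene_set: GeneSet, weight_p: float = 1.0) -> EnrichmentScore:
    """Enrichment score: the running-sum extremum furthest from zero."""
    members = set(gene_set.members)
    hit_mask = np.fromiter((g in members for g in ranked.genes), bool, len(ranked.genes))
    running = _running_sum(ranked.scores, hit_mask, weight_p)
    peak = int(np.argmax(np.abs(running)))
    es = float(running[peak])
    hit_positions = np.flatnonzero(hit_mask)
    if es >= 0:
        leading = [ranked.genes[i] for i in hit_positions if i <= peak]
    else:
        leading = [ranked.genes[i] for i in hit_positions if i >= peak]
    return EnrichmentScore(es, running, peak, tuple(leading))


def _null_es_gene_set(
    scores: np.ndarray, set_size: int, n_perm: int, weight_p: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised ES for ``n_perm`` random same-size gene sets."""
    n = len(scores)
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, set_size, axis=1)[:, :set_size]
    w = np.abs(scores) ** weight_p
    hit_w = w[idx]
    totals = hit_w.sum(axis=1)
    degenerate = totals <= 0
    if degenerate.any():
        hit_w[degenerate] = 1.0
        totals = hit_w.sum(axis=1)
    hits_full = np.zeros((n_perm, n))
    np.put_along_axis(hits_full, idx, hit_w / totals[:, None], axis=1)
    miss_full = np.ones((n_perm, n)) / (n - set_size)
    np.put_along_axis(miss_full, idx, 0.0, axis=1)
    running = np.cumsum(hits_full, axis=1) - np.cumsum(miss_full, axis=1)
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), peaks]


def gsea_significance(
    ranked: RankedGeneList,
    sets: Sequence[GeneSet],
    n_perm: int = 1000,
    mode: str = "gene_set",
    seed: int = 0,
    weight_p: float = 1.0,
    expr: pd.DataFrame | None = None,
    labels: Sequence[str] | None = None,
    classes: tuple[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Permutation significance and FDR for a collection of gene sets.

    ``mode="gene_set"`` draws random same-size gene sets (the default; the
    study has too few samples per arm for phenotype permutation to have
    any resolution); ``mode="phenotype"`` permutes arm labels and re-ranks,
    requiring ``expr``, ``labels`` and ``classes``. NES divides ES by the
    mean absolute same-sign null ES; the nominal p is one-sided on the
    matching sign with add-one smoothing; FDR q follows the standard
    pooled-NES procedure. Deterministic given the seed.
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    if mode not in ("gene_set", "phenotype"):
        raise ConfigError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x65EA]))

    genes_in_list = set(ranked.genes)
    observed: list[EnrichmentScore] = []
    present_sizes: list[int] = []
    for s in sets:
        present = [g for g in s.members if g in genes_in_list]
        if not present:
            raise ConfigError(f"gene set {s.name!r} has no member in the ranked list")
        observed.append(gsea_es(ranked, GeneSet(s.name, tuple(present), s.description), weight_p))
        present_sizes.append(len(present))

    if mode == "gene_set":
        null_by_size: dict[int, np.ndarray] = {}
        for size in sorted(set(present_sizes)):
            null_by_size[size] = _null_es_gene_set(ranked.scores, size, n_perm, weight_p, rng)
        nulls = [null_by_size[size] for size in present_sizes]
    else:
        if expr is None or labels is None or classes is None:
            raise ConfigError("phenotype mode needs expr, labels and classes")
        labels = np.asarray(labels)
        for c in classes:
            if (labels == c).sum() < 2:
                raise ConfigError("phenotype mode needs >= 2 samples per arm")
        member_lists = [
            tuple(g for g in s.members if g in genes_in_list) for s in sets
        ]
        null_rows: list[list[float]] = [[] for _ in sets]
        for _ in range(n_perm):
            perm_labels = labels[rng.permutation(len(labels))]
            try:
                perm_ranked = signal_to_noise_rank(expr, perm_labels, *classes)
            except ConfigError:
                continue
            for i, members in enumerate(member_lists):
                score = gsea_es(perm_ranked, GeneSet(sets[i].name, members), weight_p)
                null_rows[i].append(score.es)
        nulls = [np.asarray(row) for row in null_rows]

    # normalise: ES / mean(|null ES| of matching sign)
    def _nes(es_values: np.ndarray, null: np.ndarray) -> np.ndarray:
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        out = np.where(es_values >= 0, es_values / pos_mean, es_values / neg_mean)
        return out

    nes_obs = np.array([_nes(np.array([o.es]), null)[0] for o, null in zip(observed, nulls)])
    null_nes_pooled = np.concatenate([_nes(null, null) for null in nulls])
    null_nes_pooled = null_nes_pooled[np.isfinite(null_nes_pooled)]

    results = []
    for i, (o, null) in enumerate(zip(observed, nulls)):
        same_sign = null[null >= 0] if o.es >= 0 else null[null < 0]
        more_extreme = (same_sign >= o.es).sum() if o.es >= 0 else (same_sign <= o.es).sum()
        p = (1.0 + more_extreme) / (1.0 + len(same_sign)) if len(same_sign) else 1.0
        nes = nes_obs[i]
        if np.isfinite(nes):
            if nes >= 0:
                n_null = (null_nes_pooled >= nes).mean() if len(null_nes_pooled) else 1.0
                n_obs = (nes_obs[np.isfinite(nes_obs)] >= nes).mean()
            else:
                n_null = (null_nes_pooled <= nes).mean() if len(null_nes_pooled) else 1.0
                n_obs = (nes_obs[np.isfinite(nes_obs)] <= nes).mean()
            q = float(np.clip(n_null / n_obs if n_obs > 0 else 1.0, 0.0, 1.0))
        else:
            q = 1.0
        results.append(
            EnrichmentResult(
                name=sets[i].name,
                es=o.es,
                nes=float(nes),
                p=float(p),
                fdr_q=q,
                leading_edge=o.leading_edge,
                running_sum=o.running_sum,
                n_members=present_sizes[i],
            )
        )
    return results


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------
def ora_hypergeometric(
    hits: Sequence, sets: Sequence[GeneSet] | GeneSet, universe: Sequence
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation, BH-adjusted across sets.

    ``P(X >= overlap)`` for drawing ``|hits|`` genes from a universe of
    size ``|universe|`` containing ``|set ∩ universe|`` successes.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ConfigError("empty universe")
    hit_set = set(hits)
    if not hit_set <= universe_set:
        raise ConfigError("hits must be a subset of the universe")
    if isinstance(sets, GeneSet):
        sets = [sets]
    rows = []
    for s in sets:
        members = set(s.members) & universe_set
        overlap = len(hit_set & members)
        p = float(sps.hypergeom.sf(overlap - 1, len(universe_set), len(members), len(hit_set)))
        rows.append({"set": s.name, "set_size": len(members), "n_hits": len(hit_set),
                     "overlap": overlap, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out
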