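"""Paired statistics for population frequencies and functional subsets.

The study design is paired: every donor contributes both a conventional
CAR-T arm and a TCF-1 (dual-transduced) arm, so arm comparisons use the
paired t-test on per-donor differences. Longitudinal tables run one test
per population and timepoint with Benjamini-Hochberg adjustment across the
whole grid (raw p is also reported, since figure-legend star conventions
use unadjusted p). Functional-subset decomposition assigns each stimulated
cell to one of the 2^3 Boolean combinations of three effector markers
(degranulation CD107a, TNF-a, IFN-g), an exact partition whose per-sample
percentages sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, SchemaError
from .events import EventTable

__all__ = [
    "PairedSamples",
    "paired_t_test",
    "significance_stars",
    "functional_subsets",
    "longitudinal_compare",
]


@dataclass(frozen=True)
class PairedSamples:
    """Per-donor value pairs for one readout (arm A vs arm B)."""

    donors: tuple[str, ...]
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.donors)
        if n < 2:
            raise ConfigError("paired test requires n >= 2 donors")
        if len(self.values_a) != n or len(self.values_b) != n:
            raise ConfigError("both arms must be present for every donor")


def paired_t_test(samples: PairedSamples) -> tuple[float, float, int]:
    """Classic paired t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1.

    Identical arms (all differences exactly zero) return (0, 1, n-1);
    constant non-zero differences have zero variance and are rejected as
    degenerate.
    """
    d = np.asarray(samples.values_a, dtype=float) - np.asarray(samples.values_b, dtype=float)
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0, n - 1
        raise ConfigError("degenerate pairs: differences are constant and non-zero")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p), n - 1


def significance_stars(p: float) -> str:
    """Figure-legend star convention: *P<0.05 **P<0.01 ***P<0.001 ****P<0.0001."""
    if np.isnan(p):
        return "na"
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def functional_subsets(
    table: EventTable,
    markers: Sequence[str] = ("CD107a", "TNFa", "IFNg"),
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample percentages of the 8 Boolean effector-marker combinations.

    Each cell is assigned to exactly one combination by strict thresholding
    on the transformed scale, so the 8 columns partition the sample and sum
    to 100. Column names spell the combination, e.g. ``CD107a+TNFa-IFNg+``.
    """
    if len(markers) != 3:
        raise ConfigError("functional subsets are defined over exactly 3 markers")
    for m in markers:
        if m not in table.markers:
            raise SchemaError(f"marker {m!r} not in panel")
    if thresholds is None:
        raise ConfigError("positivity thresholds are required")
    for m in markers:
        if m not in thresholds:
            raise ConfigError(f"missing threshold for {m!r}")

    bits = np.column_stack(
        [(table.data[m].to_numpy(dtype=float) > float(thresholds[m])).astype(int) for m in markers]
    )
    code = bits[:, 0] * 4 + bits[:, 1] * 2 + bits[:, 2]

    def _name(c: int) -> str:
        signs = [("+" if (c >> shift) & 1 else "-") for shift in (2, 1, 0)]
        return "".join(f"{m}{s}" for m, s in zip(markers, signs))

    df = table.data[["donor", "arm", "timepoint"]].copy()
    df["_code"] = code
    counts = (
        df.groupby(["donor", "arm", "timepoint"], observed=True)["_code"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=range(8), fill_value=0)
    )
    freq = counts.div(counts.sum(axis=1), axis=0) * 100.0
    freq.columns = [_name(c) for c in range(8)]
    return freq


def fmo_thresholds(
    control: EventTable, markers: Sequence[str], quantile: float = 0.995
) -> dict:
    """FMO-style positivity thresholds: a high quantile of unstimulated control cells."""
    out = {}
    for m in markers:
        if m not in control.markers:
            raise SchemaError(f"marker {m!r} not in control panel")
        out[m] = float(np.quantile(control.data[m].to_numpy(dtype=float), quantile))
    return out


def longitudinal_compare(
    freq: pd.DataFrame,
    arms: tuple[str, str],
    timepoints: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Arm comparison per (population, timepoint) with BH adjustment.

    ``freq`` is a samples x populations matrix indexed by (donor, arm,
    timepoint). Donors missing either arm at a timepoint are dropped;
    cells with fewer than two complete pairs are flagged untestable rather
    than raising. Output columns: population, timepoint, n_pairs, t, p, q,
    stars.
    """
    if timepoints is None:
        timepoints = list(dict.fromkeys(freq.index.get_level_values("timepoint")))
    rows = []
    for tp in timepoints:
        sub = freq.xs(tp, level="timepoint")
        by_arm = {arm: sub.xs(arm, level="arm") for arm in arms if arm in sub.index.get_level_values("arm")}
        if len(by_arm) < 2:
            donors_common: list = []
        else:
            donors_common = sorted(set(by_arm[arms[0]].index) & set(by_arm[arms[1]].index))
        for pop in freq.columns:
            if len(donors_common) < 2:
                rows.append(
                    {"population": pop, "timepoint": tp, "n_pairs": len(donors_common),
                     "t": np.nan, "p": np.nan, "untestable": True}
                )
                continue
            a = by_arm[arms[0]].loc[donors_common, pop].to_numpy(dtype=float)
            b = by_arm[arms[1]].loc[donors_common, pop].to_numpy(dtype=float)
            try:
                t, p, _ = paired_t_test(PairedSamples(tuple(donors_common), tuple(a), tuple(b)))
                rows.append(
                    {"population": pop, "timepoint": tp, "n_pairs": len(donors_common),
                     "t": t, "p": p, "untestable": False}
                )
            except ConfigError:
                rows.append(
                    {"population": pop, "timepoint": tp, "n_pairs": len(donors_common),
                     "t": np.nan, "p": np.nan, "untestable": True}
                )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    testable = ~out["untestable"]
    if testable.any():
        out.loc[testable, "q"] = multipletests(out.loc[testable, "p"], method="fdr_bh")[1]
    out["stars"] = [significance_stars(p) for p in out["p"]]
    return out
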