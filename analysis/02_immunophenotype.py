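#!/usr/bin/env python
"""Machine-learning immunophenotyping of the simulated cohort.

Reads the per-sample event tables written by 01_simulate_cohort.py, pools
them, arcsinh-transforms, clusters (kNN-Jaccard graph + Louvain), selects
informative populations by the PCA contribution rule (PCs to 70% cumulative
variance, contribution above 100/p), intersects the day11/day14 selections,
applies the sub-300-cell exclusion, and runs paired arm statistics on the
final populations. Reports which planted population was found.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from immunohub.errors import ImmunohubError
from immunohub.events import PanelDef, read_event_table
from immunohub.pipelines import load_immuno_params, run_immunophenotype_pipeline
from immunohub.simulate import cluster_truth_map

PANEL = PanelDef(
    "panel1",
    ("CD3", "CD4", "Apotracker", "CD95", "CD253", "7AAD"),
    {"7AAD": "viability", "CD3": "lineage"},
)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--data-dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/immunophenotype"))
    ap.add_argument("--k", type=int, default=30, help="kNN graph neighbourhood size")
    ap.add_argument("--config", type=Path, default=None,
                    help="optional YAML parameter file (overrides --k; may set a merge_map)")
    args = ap.parse_args()
    params = load_immuno_params(args.config) if args.config else {}
    params.setdefault("k", args.k)

    tables = {}
    for path in sorted((args.data_dir / "cytometry").glob("events_*.csv")):
        table = read_event_table(path, PANEL)
        key = (table.data["donor"].iloc[0], table.data["arm"].iloc[0],
               table.data["timepoint"].iloc[0])
        tables[key] = table
    if not tables:
        print("no event tables found; run 01_simulate_cohort.py first", file=sys.stderr)
        return 1
    print(f"loaded {len(tables)} samples")

    params.setdefault("tsne_points", 2000)
    res = run_immunophenotype_pipeline(tables, seed=args.seed, out_dir=args.out_dir, **params)
    report = res.report
    print(f"clusters: {res.assignment.n_clusters} "
          f"(modularity {res.assignment.modularity:.3f})")
    for tp, entry in report.per_timepoint.items():
        print(f"  {tp}: retained PCs {len(entry['retained_pcs'])}, "
              f"selected clusters {sorted(entry['selected'])}")
    print(f"intersection: {sorted(report.intersection)}; "
          f"after <300-cell exclusion: {sorted(report.after_count_filter)}")

    if "true_population" in res.pooled.data.columns:
        tmap = cluster_truth_map(res.pooled, res.assignment.labels)
        names = {c: f"{tmap.loc[c, 'population']} ({tmap.loc[c, 'purity']:.0%} pure)"
                 for c in report.after_count_filter}
        print("final populations vs. planted truth:")
        for c, desc in sorted(names.items()):
            print(f"  cluster {c}: {desc}")

    sig = res.stats[(~res.stats["untestable"]) & (res.stats["p"] < 0.05)]
    print(f"arm comparisons with raw p < 0.05 ({len(sig)} of {len(res.stats)}):")
    for _, row in sig.iterrows():
        print(f"  cluster {row['population']} @ {row['timepoint']}: "
              f"t={row['t']:.2f} p={row['p']:.2g} q={row['q']:.2g} {row['stars']}")
    print(f"artifacts in {args.out_dir} (manifest: {res.manifest_path})")
    return 0


if __name__ == "__main__":
    try:
        raise SystemExit(main())
    except ImmunohubError as exc:
        print(f"error: {exc}", file=sys.stderr)
        raise SystemExit(1)
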