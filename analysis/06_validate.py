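#!/usr/bin/env python
"""Robustness checks on the inferred networks (reduced scale).

Runs the four validation procedures against the early-stage network of the
simulated dataset: within-taxon randomization (false-positive rate),
richness-effect null simulations, taxon subsampling to a common model size,
and standardization of the successional-axis range.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from succnet import compositional, validate
from succnet.containers import concat_clr
from succnet.io import read_community_table, read_metadata
from succnet.simulate import simulate_probabilities

DEPTHS = {"bacteria": 7000, "fungi": 900, "small_eukaryote": 750,
          "microfauna": 600, "plant": 400}


def merged_stage_table(datadir, stages, stage, seed):
    """Rarefied counts of all groups side by side for one stage's samples."""
    ids = stages.loc[stages.stage == stage, "sample_id"].tolist()
    parts = []
    for g, depth in DEPTHS.items():
        t = read_community_table(datadir / f"counts_{g}.tsv",
                                 datadir / f"annotation_{g}.tsv")
        t = compositional.rarefy(t, depth, seed=seed)
        parts.append(t.select_samples([s for s in ids if s in t.sample_ids]))
    from succnet.containers import CommunityTable
    import numpy as np
    counts = np.hstack([p.counts for p in parts])
    return CommunityTable(parts[0].sample_ids,
                          [x for p in parts for x in p.taxon_ids], counts,
                          [g for p in parts for g in p.group],
                          [x for p in parts for x in p.trophic])


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--n-reps", type=int, default=3,
                    help="replicates per randomization/subsampling procedure")
    args = ap.parse_args()

    stages = pd.read_csv(args.outdir / "stages.tsv", sep="\t",
                         dtype={"sample_id": str})
    settings = validate.FitSettings(d=3, iterations=1500, burn_in=500, thin=2,
                                    cutoff=12)
    early = merged_stage_table(args.datadir, stages, "early", args.seed)
    summary = {}

    # 1. observed network, then within-taxon randomization
    edges, _, stats, n_taxa = validate.fit_edges_from_counts(
        early, settings, seed=args.seed)
    print(f"observed early network: {n_taxa} modelled taxa, "
          f"{len(edges)} edges, density {stats.linkage_density:.2f}")
    rep = validate.randomization_fp_report(early, max(len(edges), 1), settings,
                                           n_reps=args.n_reps, seed=args.seed)
    print(f"randomized data: {rep.summary['mean_randomized_edges']:.1f} "
          f"+/- {rep.summary['sd_randomized_edges']:.1f} edges "
          f"-> {rep.summary['percent']:.2f}% false positives")
    summary["false_positive"] = rep.summary

    # 2. richness non-effect
    scen = {"low": simulate_probabilities(30, seed=args.seed),
            "high": simulate_probabilities(60, seed=args.seed + 1)}
    rich = validate.richness_effect_simulation(
        scen, n_reps=args.n_reps, settings=settings, seed=args.seed + 2)
    reg = rich.summary["edges_vs_mean_richness"]
    print(f"richness regression: R2 {reg['r2']:.3f}, P {reg['p']:.2f} "
          f"({len(rich.replicates)} replicates)")
    summary["richness_effect"] = rich.summary

    # 3. taxon subsampling to a common model size
    sub = validate.subsample_taxa_rerun(
        early, max(2, int(0.8 * n_taxa)), settings, n_reps=args.n_reps,
        seed=args.seed + 3)
    print(f"subsampled to {int(0.8 * n_taxa)} taxa: "
          f"{sub.summary['edges']['mean']:.0f} +/- "
          f"{sub.summary['edges']['sd']:.0f} edges")
    summary["taxon_subsampling"] = sub.summary

    # 4. common successional-axis range
    stage_tables = {s: merged_stage_table(args.datadir, stages, s, args.seed)
                    for s in ("early", "mid", "late")}
    stage_scores = {}
    for s, t in stage_tables.items():
        sc = stages.set_index("sample_id").loc[t.sample_ids, "axis1_score"]
        stage_scores[s] = sc.to_numpy()
    # narrowest window that still holds 12 plots in every stage
    def min_feasible(v, k=12):
        s = sorted(v)
        return min(s[i + k - 1] - s[i] for i in range(len(s) - k + 1))
    width = max(min_feasible(v) for v in stage_scores.values()) * 1.01
    axis = validate.standardize_axis_range_rerun(
        stage_tables, stage_scores, settings, window_width=float(width),
        n_plots=12, seed=args.seed + 4)
    print("axis-range standardized edge counts:",
          axis.summary["edges_by_stage"])
    summary["axis_range"] = axis.summary

    with open(args.outdir / "validation.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=float)
        fh.write("\n")


if __name__ == "__main__":
    main()
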