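"""End-to-end orchestration: counts -> stages -> per-stage networks.

The pipeline is a pure function of (inputs, seed): rarefy each organism
group to its even depth, assign successional stages from the environmental
PCA, then per stage apply the core-taxon frequency filter, zero-replace and
clr-transform each group, fit the latent-variable JSDM, call edges from the
residual-correlation credible intervals, and assemble the networks with
their statistics and convergence diagnostics.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import compositional, jsdm, network, ordination
from .containers import concat_clr
from .io import RunConfig, write_network_outputs

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


def _child_seeds(seed, n):
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(2**31 - 1, size=n)]


def stage_clr(tables, stage_samples, cutoff):
    """Frequency-filter and clr-transform each group for one stage's samples.

    Filtering and the clr geometry are per organism group (each group was
    rarefied to its own depth, so their compositions are separate); the
    resulting blocks are column-concatenated. Returns (ClrMatrix, annotations
    DataFrame) or (None, None) when no taxon passes the filter.
    """
    blocks, anns = [], []
    for gname, table in tables.items():
        sub = table.select_samples([s for s in stage_samples
                                    if s in table.sample_ids])
        if sub.n_samples == 0:
            continue
        filt = compositional.frequency_filter(sub, cutoff)
        if filt.n_taxa == 0:
            continue
        blocks.append(compositional.clr_of_table(filt))
        anns.append(filt.annotation_frame())
    if not blocks:
        return None, None
    import pandas as pd
    return concat_clr(blocks), pd.concat(anns)


def run_pipeline(cfg: RunConfig, tables: dict, metadata, outdir=None) -> dict:
    """Run the full analysis; returns a dict with stages, networks and report.

    ``tables`` maps organism group -> CommunityTable (raw counts). All
    randomness derives from ``cfg.seed``; identical inputs and seed give
    identical outputs.
    """
    t0 = time.time()
    seeds = _child_seeds(cfg.seed, 2 + cfg.n_stages)
    report = {"seed": cfg.seed, "stages": {}, "selected_covariates": None}

    # --- rarefaction ---
    try:
        rarefied = {}
        rare_seeds = _child_seeds(seeds[0], len(tables))
        for (gname, table), s in zip(tables.items(), rare_seeds):
            depth = cfg.rarefaction_depths.get(gname)
            if depth is None:
                raise KeyError(f"no rarefaction depth configured for {gname!r}")
            rarefied[gname] = compositional.rarefy(table, depth, seed=s)
            logger.info("rarefy[%s]: %d samples x %d taxa at depth %d", gname,
                        rarefied[gname].n_samples, rarefied[gname].n_taxa, depth)
    except Exception as exc:
        raise PipelineError(f"rarefaction failed: {exc}") from exc

    # samples surviving rarefaction in every group
    shared = None
    for table in rarefied.values():
        ids = set(table.sample_ids)
        shared = ids if shared is None else shared & ids
    shared = [s for s in metadata.sample_ids if s in shared]
    if len(shared) < cfg.n_stages:
        raise PipelineError("stage assignment failed: too few shared samples")
    meta = metadata.select_samples(shared)
    rarefied = {g: t.select_samples(shared) for g, t in rarefied.items()}

    # --- successional stages from the environmental PCA ---
    try:
        stage_vars = cfg.stage_variables or list(meta.covariates.columns)
        scores = ordination.pca_stage_scores(meta, stage_vars)
        assignment = ordination.assign_stages(scores, cfg.n_stages)
    except Exception as exc:
        raise PipelineError(f"stage assignment failed: {exc}") from exc
    report["pca_axis1_fraction"] = float(scores.variance_fractions[0])

    # --- environmental covariates (configured or forward-selected) ---
    try:
        if cfg.covariates:
            selected = list(cfg.covariates)
        else:
            full_clr, _ = stage_clr(rarefied, shared, 1)
            candidates = meta.covariates
            selected = jsdm.forward_select_env(
                full_clr.values, candidates,
                min(cfg.n_covariates, candidates.shape[1]))
        report["selected_covariates"] = selected
    except Exception as exc:
        raise PipelineError(f"covariate selection failed: {exc}") from exc

    # --- per-stage JSDM fits and networks ---
    networks = {}
    seen = set(assignment["stage"])
    stage_names = [s for s in ordination.STAGE_NAMES if s in seen]
    stage_names += sorted(seen - set(stage_names))
    fit_seeds = _child_seeds(seeds[1], len(stage_names))
    for stage_name, fseed in zip(stage_names, fit_seeds):
        t_stage = time.time()
        samples = assignment.loc[assignment["stage"] == stage_name,
                                 "sample_id"].tolist()
        try:
            clr, ann = stage_clr(rarefied, samples, cfg.frequency_cutoff)
            if clr is None:
                raise ValueError("no taxa pass the frequency cutoff")
            sub_meta = meta.select_samples(samples)
            model = jsdm.JsdmModel(
                y=clr.values,
                x=sub_meta.covariate_matrix(selected),
                coords=sub_meta.coords,
                d=cfg.n_latent,
                taxon_ids=clr.taxon_ids,
                sample_ids=clr.sample_ids,
                covariate_names=selected,
            )
            post = jsdm.fit_jsdm(model, cfg.iterations, cfg.burn_in, cfg.thin,
                                 seed=fseed)
            rho = jsdm.residual_correlation_draws(post)
            summary = jsdm.summarize_residual_correlations(
                rho, clr.taxon_ids, cfg.credible_level)
            edges = jsdm.significant_edges(summary)
            g = network.build_network(edges, ann)
            stats = network.network_stats(g)
            _, qq = jsdm.quantile_residuals(model, post)
            diag = {"geweke": jsdm.geweke_report(post), **qq}
        except Exception as exc:
            raise PipelineError(f"stage {stage_name!r} failed: {exc}") from exc
        networks[stage_name] = {"graph": g, "stats": stats, "edges": edges,
                                "posterior": post, "summary": summary}
        report["stages"][stage_name] = {
            "n_samples": len(samples),
            "n_taxa_modeled": clr.n_taxa,
            "retained_draws": post.n_draws,
            "network": stats.to_dict(),
            "diagnostics": diag,
            "runtime_s": round(time.time() - t_stage, 2),
        }
        logger.info("stage %s: %d taxa, %d edges, linkage density %.2f",
                    stage_name, clr.n_taxa, stats.edges, stats.linkage_density)

    report["runtime_s"] = round(time.time() - t0, 2)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        assignment.to_csv(outdir / "stages.tsv", sep="\t", index=False)
        for stage_name, res in networks.items():
            write_network_outputs(res["graph"], res["stats"], outdir,
                                  prefix=f"network_{stage_name}")
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return {"assignment": assignment, "networks": networks, "report": report,
            "selected_covariates": selected}
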