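"""Robustness procedures for the inferred networks.

Four checks probe whether the successional decline in network complexity
could be a statistical artifact:

1. *Within-taxon randomization* — permute each taxon's abundances across
   samples (preserving its occurrence frequency and abundance multiset,
   destroying cross-taxon association), refit, and count surviving edges;
   their mean over replicates divided by the observed edge count is the
   false-positive percentage.
2. *Richness-effect simulation* — Dirichlet-multinomial null communities of
   varying richness, fit with latent variables only; regressions of edge
   count and linkage density on richness should be flat.
3. *Taxon subsampling* — refit on random subsets of the modelled taxa so all
   stages enter the model with the same number of taxa.
4. *Axis-range standardization* — refit each stage on plots spanning the
   same width of the successional (PCA axis 1) gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import compositional, jsdm, network
from .containers import CommunityTable
from .simulate import simulate_dirichlet_multinomial

logger = logging.getLogger(__name__)


@dataclass
class FitSettings:
    """MCMC and edge-calling settings for validation refits.

    Validation refits default to a shortened chain relative to the main
    analysis schedule; a warning is logged so reduced settings are explicit.
    """

    d: int = 3
    iterations: int = 3000
    burn_in: int = 1000
    thin: int = 4
    credible_level: float = 0.95
    covariates: list = None     # None -> latent variables only
    cutoff: int = 12
    spatial: bool = False


@dataclass
class ValidationReport:
    procedure: str
    replicates: pd.DataFrame
    summary: dict = field(default_factory=dict)


def randomize_within_taxa(table: CommunityTable, seed=0) -> CommunityTable:
    """Independently permute each taxon's abundances across samples.

    Preserves every taxon's abundance multiset (hence occurrence frequency
    and column sum) while destroying cross-taxon associations.
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(table.counts).copy()
    for j in range(counts.shape[1]):
        counts[:, j] = counts[rng.permutation(counts.shape[0]), j]
    return CommunityTable(list(table.sample_ids), list(table.taxon_ids),
                          counts, list(table.group), list(table.trophic))


def false_positive_rate(randomized_edge_counts, observed_edges: int) -> dict:
    """Percent of observed edges attributable to chance.

    100 x mean(edge counts under randomization) / observed edges, with the
    mean and SD of the randomized counts reported alongside.
    """
    counts = np.asarray(list(randomized_edge_counts), dtype=float)
    if observed_edges <= 0:
        raise ValueError("observed edge count must be positive")
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return {"percent": 100.0 * mean / observed_edges,
            "mean_randomized_edges": mean, "sd_randomized_edges": sd,
            "observed_edges": int(observed_edges), "n_replicates": int(counts.size)}


def fit_edges_from_counts(table: CommunityTable, settings: FitSettings,
                          seed=0, metadata=None):
    """Cutoff -> clr -> JSDM -> significant edges for one count table.

    Returns (edge DataFrame, graph, stats, n_taxa_modeled); the graph is None
    when no taxon passes the cutoff.
    """
    filt = compositional.frequency_filter(table, settings.cutoff)
    if filt.n_taxa < 2:
        return None, None, None, filt.n_taxa
    clr = compositional.clr_of_table(filt)
    if settings.covariates and metadata is not None:
        sub = metadata.select_samples(clr.sample_ids)
        x = sub.covariate_matrix(settings.covariates)
        coords = sub.coords
    else:
        x = np.zeros((clr.n_samples, 0))
        coords = (metadata.select_samples(clr.sample_ids).coords
                  if (metadata is not None and settings.spatial) else None)
    model = jsdm.JsdmModel(y=clr.values, x=x, coords=coords,
                           d=settings.d, taxon_ids=clr.taxon_ids,
                           sample_ids=clr.sample_ids, spatial=settings.spatial)
    post = jsdm.fit_jsdm(model, settings.iterations, settings.burn_in,
                         settings.thin, seed=seed)
    rho = jsdm.residual_correlation_draws(post)
    summary = jsdm.summarize_residual_correlations(rho, clr.taxon_ids,
                                                   settings.credible_level)
    edges = jsdm.significant_edges(summary)
    g = network.build_network(edges, filt.annotation_frame())
    stats = network.network_stats(g)
    return edges, g, stats, filt.n_taxa


def randomization_fp_report(table: CommunityTable, observed_edges: int,
                            settings: FitSettings, n_reps: int = 10,
                            seed=0) -> ValidationReport:
    """Full within-taxon randomization procedure for one stage."""
    if settings.iterations < 40000:
        logger.warning("validation refit uses a shortened MCMC schedule "
                       "(%d iterations)", settings.iterations)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        rand = randomize_within_taxa(table, seed=rng.integers(2**31 - 1))
        edges, _, stats, n_taxa = fit_edges_from_counts(
            rand, settings, seed=rng.integers(2**31 - 1))
        n_edges = 0 if edges is None else len(edges)
        rows.append({"replicate": rep, "edges": n_edges,
                     "n_taxa_modeled": n_taxa})
    reps = pd.DataFrame(rows)
    summary = false_positive_rate(reps["edges"], observed_edges)
    return ValidationReport("within_taxon_randomization", reps, summary)


def richness_effect_simulation(scenario_probabilities: dict, n_reps: int = 25,
                               n_samples: int = 25, depth: int = 2000,
                               concentration: float = 100.0,
                               settings: FitSettings = None,
                               seed=0) -> ValidationReport:
    """Does richness alone drive edge counts? Null simulation + regression.

    ``scenario_probabilities`` maps scenario name -> base relative-abundance
    vector (scenarios differ in richness). Per replicate: draw a
    Dirichlet-multinomial count table, apply the frequency cutoff, clr,
    fit a latent-only model, record edge count and linkage density. Edge
    count and complexity are each regressed on mean observed richness and on
    the number of modelled (post-cutoff) taxa; R^2 and p for the four
    regressions land in the summary.
    """
    if len(scenario_probabilities) < 2:
        raise ValueError("need at least two richness scenarios")
    settings = settings or FitSettings()
    rng = np.random.default_rng(seed)
    rows = []
    for name, probs in scenario_probabilities.items():
        probs = np.asarray(probs, dtype=float)
        for rep in range(n_reps):
            counts = simulate_dirichlet_multinomial(
                probs, n_samples, depth, concentration,
                seed=rng.integers(2**31 - 1))
            table = CommunityTable([f"s{i}" for i in range(n_samples)],
                                   [f"t{j}" for j in range(probs.size)], counts)
            edges, _, stats, n_taxa = fit_edges_from_counts(
                table, settings, seed=rng.integers(2**31 - 1))
            if edges is None:
                logger.warning("richness sim %s rep %d: all taxa filtered out",
                               name, rep)
                continue
            rows.append({
                "scenario": name, "replicate": rep,
                "mean_richness": float((counts > 0).sum(axis=1).mean()),
                "n_taxa_modeled": n_taxa,
                "edges": len(edges),
                "linkage_density": stats.linkage_density,
            })
    reps = pd.DataFrame(rows)
    summary = {}
    for resp in ("edges", "linkage_density"):
        for pred in ("mean_richness", "n_taxa_modeled"):
            if reps[pred].nunique() > 1:
                fit = sps.linregress(reps[pred], reps[resp])
                summary[f"{resp}_vs_{pred}"] = {
                    "slope": float(fit.slope), "r2": float(fit.rvalue**2),
                    "p": float(fit.pvalue)}
            else:
                summary[f"{resp}_vs_{pred}"] = {"slope": 0.0, "r2": 0.0,
                                                "p": 1.0}
    return ValidationReport("richness_effect_simulation", reps, summary)


def subsample_taxa_rerun(table: CommunityTable, n_taxa: int,
                         settings: FitSettings, n_reps: int = 10,
                         seed=0, metadata=None) -> ValidationReport:
    """Refit on random subsets of the modelled taxa (equal-size control).

    Taxa passing the frequency cutoff are subsampled to ``n_taxa`` before
    each refit; with ``n_taxa`` equal to all available taxa a single
    deterministic replicate is run.
    """
    filt = compositional.frequency_filter(table, settings.cutoff)
    if n_taxa > filt.n_taxa:
        raise ValueError(f"n_taxa={n_taxa} exceeds {filt.n_taxa} available taxa")
    rng = np.random.default_rng(seed)
    full = n_taxa == filt.n_taxa
    reps = 1 if full else n_reps
    no_cut = FitSettings(**{**settings.__dict__, "cutoff": 1})
    rows = []
    for rep in range(reps):
        if full:
            chosen = list(filt.taxon_ids)
        else:
            idx = sorted(rng.choice(filt.n_taxa, size=n_taxa, replace=False))
            chosen = [filt.taxon_ids[i] for i in idx]
        sub = filt.select_taxa(chosen)
        edges, _, stats, _ = fit_edges_from_counts(
            sub, no_cut, seed=rng.integers(2**31 - 1), metadata=metadata)
        rows.append({"replicate": rep, "edges": 0 if edges is None else len(edges),
                     "linkage_density": 0.0 if stats is None else stats.linkage_density,
                     "nodes": 0 if stats is None else stats.nodes})
    df = pd.DataFrame(rows)
    summary = {c: {"mean": float(df[c].mean()),
                   "sd": float(df[c].std(ddof=1)) if len(df) > 1 else 0.0}
               for c in ("edges", "linkage_density", "nodes")}
    return ValidationReport("taxon_subsampling", df, summary)


def select_axis_window(scores: np.ndarray, width: float, n_plots: int, seed=0):
    """Pick plots spanning at most ``width`` units of the successional axis.

    A window of the given width slides over the sorted scores; the placement
    containing the most plots wins (ties -> leftmost). ``n_plots`` plots are
    then sampled uniformly from within it. Returns sorted positional indices.
    """
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(scores)
    best_start, best_count = None, -1
    for s in range(scores.size):
        lo = scores[order[s]]
        count = int(np.sum((scores >= lo) & (scores <= lo + width)))
        if count > best_count:
            best_start, best_count = s, count
    if best_count < n_plots:
        raise ValueError(
            f"no window of width {width} contains {n_plots} plots")
    lo = scores[order[best_start]]
    inside = np.flatnonzero((scores >= lo) & (scores <= lo + width))
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(inside, size=n_plots, replace=False).tolist())


def standardize_axis_range_rerun(stage_tables: dict, stage_scores: dict,
                                 settings: FitSettings,
                                 window_width: float = 0.35, n_plots: int = 12,
                                 seed=0, metadata=None) -> ValidationReport:
    """Refit every stage on plots covering the same successional-axis span.

    ``stage_tables`` maps stage -> CommunityTable; ``stage_scores`` maps
    stage -> axis-1 scores aligned to that table's samples. Each stage is
    reduced to ``n_plots`` plots drawn from a best-filled window of
    ``window_width`` axis units before refitting.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for stage, table in stage_tables.items():
        scores = np.asarray(stage_scores[stage], dtype=float)
        if scores.size != table.n_samples:
            raise ValueError(f"scores misaligned for stage {stage!r}")
        try:
            idx = select_axis_window(scores, window_width, n_plots,
                                     seed=rng.integers(2**31 - 1))
        except ValueError as exc:
            raise ValueError(f"stage {stage!r}: {exc}") from exc
        chosen = [table.sample_ids[i] for i in idx]
        sub = table.select_samples(chosen)
        edges, _, stats, n_taxa = fit_edges_from_counts(
            sub, settings, seed=rng.integers(2**31 - 1), metadata=metadata)
        rows.append({
            "stage": stage, "n_plots": n_plots,
            "score_range": float(scores[idx].max() - scores[idx].min()),
            "edges": 0 if edges is None else len(edges),
            "linkage_density": 0.0 if stats is None else stats.linkage_density,
            "n_taxa_modeled": n_taxa,
        })
    df = pd.DataFrame(rows)
    return ValidationReport("axis_range_standardization", df,
                            {"edges_by_stage": dict(zip(df["stage"], df["edges"]))})
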