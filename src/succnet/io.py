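"""File formats and run configuration.

All tabular interchange is UTF-8 TSV with a header row (counts, metadata,
annotations, edge lists, diversity tables); networks are additionally written
as GraphML; statistics and diagnostics as JSON. Posterior draws persist as a
directory of TSV matrices plus a JSON manifest. The run configuration is a
flat YAML file whose defaults mirror the study settings (per-group
rarefaction depths, 12-plot core-taxon cutoff, three latent variables,
40,000/10,000/30 MCMC schedule, 95% credible level).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .containers import CommunityTable, SampleMetadata, ValidationError
from .jsdm import JsdmPosterior

logger = logging.getLogger(__name__)

DEFAULT_DEPTHS = {"bacteria": 7987, "fungi": 1023,
                  "small_eukaryote": 871, "microfauna": 700, "plant": 500}


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    rarefaction_depths: dict = field(default_factory=lambda: dict(DEFAULT_DEPTHS))
    frequency_cutoff: int = 12
    n_latent: int = 3
    iterations: int = 40000
    burn_in: int = 10000
    thin: int = 30
    credible_level: float = 0.95
    seed: int = 0
    n_covariates: int = 4
    covariates: list = None          # None -> forward selection picks them
    stage_variables: list = None     # None -> all metadata covariates
    n_stages: int = 3

    def __post_init__(self):
        if any(d <= 0 for d in self.rarefaction_depths.values()):
            raise ValidationError("rarefaction depths must be positive")
        if not (0 < self.burn_in < self.iterations):
            raise ValidationError("need 0 < burn_in < iterations")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if not (0 < self.credible_level < 1):
            raise ValidationError("credible level must be in (0, 1)")
        if self.n_latent < 0:
            raise ValidationError("n_latent must be >= 0")
        if self.frequency_cutoff < 1:
            raise ValidationError("frequency cutoff must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def read_community_table(path, annotation_path=None) -> CommunityTable:
    """Read a counts TSV (samples x taxa) and an optional annotation TSV.

    The counts file has taxon ids in the header and sample ids in the first
    column. The annotation file maps taxon id -> group, trophic; taxa missing
    from it get "unknown" labels with a logged warning.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    dupes = [h for h in header if h in seen or seen.add(h)]
    if dupes:  # pandas silently renames duplicates, so check the raw header
        raise ValidationError(f"duplicate taxon columns: {sorted(set(dupes))}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.duplicated().any():
        raise ValidationError("duplicate sample ids")
    try:
        counts = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric counts in {path}: {exc}") from exc
    if np.any(~np.isfinite(counts)):
        raise ValidationError(f"missing or non-finite counts in {path}")
    if np.any(counts < 0):
        raise ValidationError(f"negative counts in {path}")
    if np.any(counts != np.round(counts)):
        raise ValidationError(f"non-integer counts in {path}")
    taxa = [str(t) for t in df.columns]
    group = trophic = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype=str)
        missing = [t for t in taxa if t not in ann.index]
        if missing:
            logger.warning("annotation missing for %d taxa (set to unknown): %s",
                           len(missing), missing[:10])
        group = [str(ann.loc[t, "group"]) if t in ann.index else "unknown"
                 for t in taxa]
        trophic = [str(ann.loc[t, "trophic"]) if t in ann.index else "unknown"
                   for t in taxa]
    return CommunityTable([str(s) for s in df.index], taxa,
                          counts.astype(np.int64), group, trophic)


def write_community_table(table: CommunityTable, path, annotation_path=None):
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")
    if annotation_path is not None:
        table.annotation_frame().to_csv(annotation_path, sep="\t",
                                        index_label="taxon_id")


def read_metadata(path, sample_order=None) -> SampleMetadata:
    """Read a metadata TSV with covariate columns and coordinate columns x, y.

    If ``sample_order`` is given the rows are realigned to it by id (logged
    when the file order differs); ids absent from the file raise an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValidationError(f"metadata missing coordinate column {col!r}")
    if sample_order is not None:
        sample_order = [str(s) for s in sample_order]
        missing = [s for s in sample_order if s not in df.index]
        if missing:
            raise ValidationError(f"metadata missing samples: {missing}")
        if list(df.index[: len(sample_order)]) != sample_order or len(df) != len(sample_order):
            logger.info("read_metadata: realigning rows to declared sample order")
        df = df.loc[sample_order]
    coords = df[["x", "y"]].to_numpy(dtype=float)
    covars = df.drop(columns=["x", "y"])
    return SampleMetadata(list(df.index), covars, coords)


def write_metadata(metadata: SampleMetadata, path):
    df = metadata.covariates.copy()
    df["x"] = metadata.coords[:, 0]
    df["y"] = metadata.coords[:, 1]
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_network_outputs(g: nx.Graph, stats, outdir, prefix: str = "network"):
    """Emit edge-list TSV, GraphML and a JSON statistics block.

    Returns the three written paths. An empty network still produces valid
    files (zero edge rows, nodes=0 in the stats).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edge_path = outdir / f"{prefix}_edges.tsv"
    rows = [{"taxon_a": a, "taxon_b": b,
             "median_rho": d.get("weight"), "sign": d.get("sign")}
            for a, b, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "median_rho", "sign"]).to_csv(
        edge_path, sep="\t", index=False)
    graphml_path = outdir / f"{prefix}.graphml"
    nx.write_graphml(g, graphml_path)
    stats_path = outdir / f"{prefix}_stats.json"
    payload = stats.to_dict() if hasattr(stats, "to_dict") else dict(stats)
    with open(stats_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return edge_path, graphml_path, stats_path


def save_posterior(post: JsdmPosterior, outdir):
    """Persist posterior draws as TSV matrices plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = post.n_draws
    arrays = {
        "beta0": post.beta0,
        "beta": post.beta.reshape(m, -1),
        "loadings": post.loadings.reshape(m, -1),
        "scores": post.scores.reshape(m, -1),
        "sigma2": post.sigma2,
        "phi": post.phi.reshape(m, 1),
    }
    for name, arr in arrays.items():
        np.savetxt(outdir / f"{name}.tsv", arr, delimiter="\t")
    manifest = {
        "n_draws": m,
        "shapes": {"beta0": list(post.beta0.shape),
                   "beta": list(post.beta.shape),
                   "loadings": list(post.loadings.shape),
                   "scores": list(post.scores.shape),
                   "sigma2": list(post.sigma2.shape),
                   "phi": list(post.phi.shape)},
        "taxon_ids": post.taxon_ids,
        "settings": post.settings,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def load_posterior(outdir) -> JsdmPosterior:
    outdir = Path(outdir)
    with open(outdir / "manifest.json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    shapes = manifest["shapes"]

    def _load(name):
        arr = np.loadtxt(outdir / f"{name}.tsv", delimiter="\t", ndmin=2)
        return arr.reshape(shapes[name])

    return JsdmPosterior(
        beta0=_load("beta0"), beta=_load("beta"), loadings=_load("loadings"),
        scores=_load("scores"), sigma2=_load("sigma2"),
        phi=_load("phi").reshape(-1),
        taxon_ids=manifest["taxon_ids"], settings=manifest["settings"],
    )
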