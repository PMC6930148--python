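"""Synthetic community generator with known ("planted") structure.

Two generation paths mirror the two places simulated data are needed:

* a count-space path — lognormal species-abundance distributions sampled
  through a Dirichlet-multinomial, giving overdispersed count tables with no
  planted inter-taxon association (a null generator for calibration and
  richness experiments);
* a clr-space path — Gaussian responses drawn directly from the
  latent-variable model (intercepts + covariate effects + spatially
  correlated latent factors), giving data with a known residual-correlation
  structure for parameter-recovery tests.

The environment generator emulates the study layout: ~75 plots on a jittered
50 m grid with a handful of 5 m clusters, and environmental covariates driven
by one dominant shared gradient (so PCA axis 1 captures a majority of the
variance) plus independent noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ClrMatrix, CommunityTable, SampleMetadata
from .jsdm import spherical_corr_matrix

DEFAULT_COVARIATES = ("snow_depth", "pH", "soil_moisture", "cv_snow", "plant_cover")

# group-level defaults emulating the study: per-group taxon richness,
# rarefaction-scale read depths, and a rough trophic composition
DEFAULT_GROUPS = {
    "bacteria": {"richness": 60, "depth": 7987,
                 "trophic": {"heterotrophic": 0.8, "photosynthetic": 0.1,
                             "chemoautotrophic": 0.05, "unknown": 0.05}},
    "fungi": {"richness": 25, "depth": 1023,
              "trophic": {"heterotrophic": 0.9, "unknown": 0.1}},
    "small_eukaryote": {"richness": 20, "depth": 871,
                        "trophic": {"photosynthetic": 0.4,
                                    "heterotrophic": 0.5, "unknown": 0.1}},
    "microfauna": {"richness": 10, "depth": 700,
                   "trophic": {"heterotrophic": 1.0}},
    "plant": {"richness": 6, "depth": 500,
              "trophic": {"photosynthetic": 1.0}},
}


@dataclass
class SimTruth:
    """Ground truth of one simulated latent-variable community."""

    beta0_true: np.ndarray       # (p,)
    beta_true: np.ndarray        # (q, p)
    lambda_true: np.ndarray      # (p, d)
    sigma_true: np.ndarray       # (p,) residual SDs
    phi_true: float              # spatial range (m)
    base_probabilities: np.ndarray = None

    @property
    def rho_true(self) -> np.ndarray:
        """Implied residual correlation matrix (symmetric, unit diagonal, PSD)."""
        cov = self.lambda_true @ self.lambda_true.T + np.diag(self.sigma_true**2)
        sd = np.sqrt(np.diag(cov))
        rho = cov / np.outer(sd, sd)
        np.fill_diagonal(rho, 1.0)
        return rho

    def true_edges(self, threshold: float = 0.3):
        """Set of taxon index pairs with |rho_true| above the threshold."""
        rho = self.rho_true
        p = rho.shape[0]
        return {(j, k) for j in range(p) for k in range(j + 1, p)
                if abs(rho[j, k]) > threshold}


@dataclass
class SimConfig:
    """Study-scale defaults for the multi-group community simulation."""

    n_samples: int = 75
    groups: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_GROUPS.items()})
    concentration: float = 100.0      # Dirichlet concentration scale
    sad_sigma: float = 1.0            # lognormal SAD shape
    gradient_effect: float = 1.0      # per-taxon response scale to succession
    grid_spacing: float = 50.0        # m
    n_latent: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def simulate_probabilities(richness: int, sigma: float = 1.0, seed=0,
                           distribution: str = "lognormal") -> np.ndarray:
    """Relative-abundance vector from a lognormal species-abundance law.

    Larger ``sigma`` gives a more uneven community (fewer dominant taxa hold
    more of the total abundance).
    """
    if richness < 1:
        raise ValueError("richness must be >= 1")
    if distribution != "lognormal":
        raise ValueError(f"unknown SAD distribution {distribution!r}")
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.normal(0.0, sigma, size=richness))
    return raw / raw.sum()


def simulate_dirichlet_multinomial(p: np.ndarray, n_samples: int, depth: int,
                                   concentration: float, seed=0) -> np.ndarray:
    """Overdispersed count matrix: Dirichlet(concentration * p) then
    multinomial(depth) per sample. Every row sums to ``depth`` exactly.

    As concentration grows the per-sample proportions concentrate on ``p``
    and the counts approach plain multinomial sampling; finite concentration
    adds the between-sample variability real communities show.
    """
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8 or np.any(p < 0):
        raise ValueError("p must be a probability vector summing to 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    alpha = np.maximum(concentration * p, 1e-12)
    out = np.empty((n_samples, p.size), dtype=np.int64)
    for i in range(n_samples):
        theta = rng.dirichlet(alpha)
        out[i] = rng.multinomial(depth, theta)
    return out


def simulate_environment_spatial(n_samples: int = 75, grid_spacing: float = 50.0,
                                 covariate_names=DEFAULT_COVARIATES,
                                 gradient_weight: float = 0.7,
                                 n_clusters: int = 3, cluster_spread: float = 5.0,
                                 seed=0) -> SampleMetadata:
    """Plot layout and correlated environmental covariates.

    Plots sit on a square grid (10% positional jitter); the last plots are
    pulled into ``n_clusters`` tight clusters of ~``cluster_spread`` meters to
    emulate nested sampling. Each covariate is ``w * t + sqrt(1 - w^2) * e``
    with a shared standard-normal gradient t (the successional axis) and
    independent noise e, so with weight w the leading PCA axis explains about
    w^2 + (1 - w^2)/k of the variance. ``plant_cover`` always loads
    positively on the gradient, anchoring the early -> late orientation.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if not 0 <= gradient_weight <= 1:
        raise ValueError("gradient_weight must be in [0, 1]")
    rng = np.random.default_rng(seed)
    side = math.ceil(math.sqrt(n_samples))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    pts = np.column_stack([gx.ravel(), gy.ravel()])[:n_samples] * grid_spacing
    pts = pts + rng.uniform(-0.1, 0.1, size=pts.shape) * grid_spacing
    n_clustered = min(3 * n_clusters, n_samples // 3)
    if n_clusters > 0 and n_clustered >= n_clusters:
        per = n_clustered // n_clusters
        centers = pts[rng.choice(n_samples - n_clustered, size=n_clusters,
                                 replace=False)]
        row = n_samples - n_clustered
        for c in range(n_clusters):
            take = per if c < n_clusters - 1 else n_clustered - per * (n_clusters - 1)
            for _ in range(take):
                pts[row] = centers[c] + rng.uniform(-cluster_spread,
                                                    cluster_spread, size=2)
                row += 1
    gradient = rng.normal(size=n_samples)
    w = gradient_weight
    cov = {}
    for v, name in enumerate(covariate_names):
        sign = 1.0 if name == "plant_cover" else (1.0 if v % 2 == 0 else -1.0)
        noise = rng.normal(size=n_samples)
        cov[name] = sign * w * gradient + math.sqrt(1.0 - w**2) * noise
    sample_ids = [f"plot{i + 1:03d}" for i in range(n_samples)]
    return SampleMetadata(sample_ids, pd.DataFrame(cov), pts)


def planted_truth(n_taxa: int, n_covariates: int = 2, n_latent: int = 2,
                  n_modules: int = 2, module_size: int = 5,
                  loading: float = 2.0, sigma: float = 1.0,
                  beta_scale: float = 1.0, phi: float = 100.0,
                  seed=0) -> SimTruth:
    """Build a SimTruth with block-structured ("planted") residual modules.

    The first ``n_modules * module_size`` taxa are split into modules; taxa in
    module k load with strength ``loading`` (alternating sign within the
    module) on latent axis ``k mod n_latent``, giving strong within-module
    residual correlations (|rho| = loading^2 / (loading^2 + sigma^2)).
    Remaining taxa have zero loadings. Covariate coefficients are drawn
    N(0, beta_scale^2). All parameter columns are centered across taxa so the
    signal lives in the clr (zero-row-sum) subspace.
    """
    if n_modules * module_size > n_taxa:
        raise ValueError("modules exceed the number of taxa")
    rng = np.random.default_rng(seed)
    lam = np.zeros((n_taxa, n_latent))
    for m in range(n_modules):
        axis = m % n_latent
        for i in range(module_size):
            j = m * module_size + i
            lam[j, axis] = loading * (1.0 if i % 2 == 0 else -1.0)
    beta0 = rng.normal(0.0, 0.5, size=n_taxa)
    beta = rng.normal(0.0, beta_scale, size=(n_covariates, n_taxa))
    beta0 -= beta0.mean()
    beta -= beta.mean(axis=1, keepdims=True)
    lam -= lam.mean(axis=0, keepdims=True)
    sigma_vec = np.full(n_taxa, float(sigma))
    return SimTruth(beta0, beta, lam, sigma_vec, float(phi))


def simulate_jsdm_community(truth: SimTruth, metadata: SampleMetadata,
                            covariate_names=None, seed=0) -> ClrMatrix:
    """Draw clr-space responses from the latent-variable model.

    y_ij = beta0_j + x_i . beta_j + z_i . lambda_j + eps_ij, where the latent
    columns are spatially correlated across samples, z_.k ~ N(0, R(phi_true))
    under the spherical model on plot distances. Rows are re-centered to sum
    to zero so the output respects clr geometry.
    """
    q, p = truth.beta_true.shape
    d = truth.lambda_true.shape[1]
    if truth.lambda_true.shape[0] != p or truth.sigma_true.shape[0] != p:
        raise ValueError("inconsistent truth dimensions")
    if covariate_names is None:
        covariate_names = list(metadata.covariates.columns[:q])
    if len(covariate_names) != q:
        raise ValueError(f"need {q} covariates, got {len(covariate_names)}")
    rng = np.random.default_rng(seed)
    n = metadata.n_samples
    x = metadata.covariate_matrix(covariate_names)
    sd = x.std(axis=0, ddof=1)
    x = (x - x.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    if d > 0:
        from scipy.spatial.distance import pdist, squareform
        dists = squareform(pdist(metadata.coords))
        r = spherical_corr_matrix(dists, truth.phi_true)
        chol = np.linalg.cholesky(r)
        z = chol @ rng.standard_normal((n, d))
    else:
        z = np.zeros((n, 0))
    eps = rng.standard_normal((n, p)) * truth.sigma_true[None, :]
    y = truth.beta0_true[None, :] + x @ truth.beta_true + z @ truth.lambda_true.T + eps
    y = y - y.mean(axis=1, keepdims=True)
    return ClrMatrix(list(metadata.sample_ids),
                     [f"t{j}" for j in range(p)], y)


def _trophic_labels(rng, richness: int, weights: dict) -> list:
    modes = list(weights)
    probs = np.array([weights[m] for m in modes], dtype=float)
    probs = probs / probs.sum()
    return [modes[i] for i in rng.choice(len(modes), size=richness, p=probs)]


def simulate_dataset(cfg: SimConfig):
    """Multi-group count tables plus metadata for end-to-end pipeline runs.

    Per group: a lognormal base SAD, modulated along the shared environmental
    gradient (taxon j's expected share is ~ p_j * exp(b_j * gradient_i) with
    b_j ~ N(0, gradient_effect^2)), then Dirichlet-multinomial sampling at
    the group's read depth. The gradient response creates genuine
    compositional turnover across successional stages; no taxon-taxon
    interaction is planted.

    Returns (tables, metadata) with ``tables`` a dict group -> CommunityTable.
    """
    root = np.random.default_rng(cfg.seed)
    meta_seed, *group_seeds = root.integers(2**31 - 1, size=1 + len(cfg.groups))
    metadata = simulate_environment_spatial(cfg.n_samples, cfg.grid_spacing,
                                            seed=meta_seed)
    # recover the latent gradient as the mean of the oriented covariates
    grad = metadata.covariates["plant_cover"].to_numpy()
    grad = (grad - grad.mean()) / grad.std()
    tables = {}
    for (gname, spec), gseed in zip(cfg.groups.items(), group_seeds):
        rng = np.random.default_rng(gseed)
        richness = spec["richness"]
        base = simulate_probabilities(richness, cfg.sad_sigma,
                                      seed=rng.integers(2**31 - 1))
        resp = rng.normal(0.0, cfg.gradient_effect, size=richness)
        counts = np.empty((cfg.n_samples, richness), dtype=np.int64)
        for i in range(cfg.n_samples):
            wvec = base * np.exp(resp * grad[i])
            wvec = wvec / wvec.sum()
            theta = rng.dirichlet(np.maximum(cfg.concentration * wvec, 1e-12))
            counts[i] = rng.multinomial(spec["depth"], theta)
        taxon_ids = [f"{gname[:3]}_{j + 1:03d}" for j in range(richness)]
        trophic = _trophic_labels(rng, richness, spec["trophic"])
        tables[gname] = CommunityTable(metadata.sample_ids, taxon_ids, counts,
                                       [gname] * richness, trophic)
    return tables, metadata
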