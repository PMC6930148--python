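"""Hierarchical Bayesian latent-variable joint species distribution model.

The model is a Gaussian factor regression on clr-transformed abundances:

    y_ij = beta0_j + x_i . beta_j + z_i . lambda_j + eps_ij,
    eps_ij ~ N(0, sigma_j^2),

with n samples, p taxa, q environmental covariates and d latent variables.
Each latent column z_.k carries a spherical spatial correlation across
samples, z_.k ~ N(0, R(phi)) with R_ii' = 1 - 1.5 h/phi + 0.5 (h/phi)^3 for
pairwise distance h <= phi and 0 beyond the range phi, which absorbs
non-independence due to the spatial arrangement of plots.

The residual (environment-removed) covariance between taxa j and k is
Sigma_jk = lambda_j . lambda_k + 1{j=k} sigma_j^2; its correlation

    rho_jk = lambda_j . lambda_k
             / sqrt((|lambda_j|^2 + sigma_j^2)(|lambda_k|^2 + sigma_k^2))

is the model's proxy for a species-to-species association. Pairs whose
posterior credible interval for rho excludes zero become network edges.

Inference is Gibbs sampling: all conditionals are conjugate (normal for
intercepts, covariate coefficients, loadings and latent scores; inverse-gamma
for residual variances) except the spatial range phi, which gets a
random-walk Metropolis step under a uniform prior on the span of observed
pairwise distances. Identifiability of the factor part uses the standard
lower-triangular constraint: loadings above the diagonal of the first d
taxon rows are fixed at zero and the diagonal is positive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import ndtri
from scipy.stats import truncnorm

logger = logging.getLogger(__name__)

# vague defaults in the spirit of standard JSDM software
PRIOR_COEF_VAR = 100.0     # N(0, 10^2) for beta0, beta and free loadings
PRIOR_SIGMA_A = 0.01       # InvGamma(a, b) for sigma_j^2
PRIOR_SIGMA_B = 0.01
_CHOL_JITTER = 1e-8


def spherical_correlation(h, phi: float):
    """Spherical correlation 1 - 1.5(h/phi) + 0.5(h/phi)^3, zero beyond phi."""
    if phi <= 0:
        raise ValueError("spherical range phi must be positive")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be non-negative")
    u = np.minimum(h / phi, 1.0)
    out = 1.0 - 1.5 * u + 0.5 * u**3
    if out.ndim == 0:
        return float(out)
    return out


def spherical_corr_matrix(dists: np.ndarray, phi: float) -> np.ndarray:
    r = spherical_correlation(dists, phi)
    return np.asarray(r) + _CHOL_JITTER * np.eye(dists.shape[0])


@dataclass
class JsdmModel:
    """Data bundle for one fit: clr responses, covariates and coordinates."""

    y: np.ndarray                     # (n, p) clr values
    x: np.ndarray                     # (n, q) covariates, z-scored in fit
    coords: np.ndarray                # (n, 2) meters
    d: int = 3
    taxon_ids: list = None
    sample_ids: list = None
    covariate_names: list = None
    spatial: bool = True           # False: iid latent scores, no range parameter

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response matrix contains non-finite values")
        n, p = self.y.shape
        self.x = (np.zeros((n, 0)) if self.x is None
                  else np.asarray(self.x, dtype=float))
        if self.x.shape[0] != n:
            raise ValueError("covariate rows must match response rows")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("covariates contain non-finite values")
        self.coords = (np.zeros((n, 2)) if self.coords is None
                       else np.asarray(self.coords, dtype=float))
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n, 2)")
        if self.d < 0:
            raise ValueError("latent dimension d must be >= 0")
        if self.taxon_ids is None:
            self.taxon_ids = [f"t{j}" for j in range(p)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(n)]

    @property
    def n(self):
        return self.y.shape[0]

    @property
    def p(self):
        return self.y.shape[1]

    @property
    def q(self):
        return self.x.shape[1]

    def distances(self) -> np.ndarray:
        return squareform(pdist(self.coords))


@dataclass
class JsdmPosterior:
    """Retained MCMC draws. Arrays are indexed draw-first."""

    beta0: np.ndarray      # (m, p)
    beta: np.ndarray       # (m, q, p)
    loadings: np.ndarray   # (m, p, d)
    scores: np.ndarray     # (m, n, d)
    sigma2: np.ndarray     # (m, p)
    phi: np.ndarray        # (m,)
    taxon_ids: list
    settings: dict = field(default_factory=dict)

    @property
    def n_draws(self):
        return self.beta0.shape[0]

    @property
    def d(self):
        return self.loadings.shape[2]


@dataclass
class ResidualCorrelationSummary:
    """Posterior median and equal-tailed credible interval per taxon pair."""

    taxon_ids: list
    median: np.ndarray   # (p, p)
    lower: np.ndarray
    upper: np.ndarray
    level: float


def zscore_columns(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[1] == 0:
        return x
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def _mvn_sample(prec_chol: np.ndarray, lin: np.ndarray, rng) -> np.ndarray:
    """Draw from N(P^-1 lin, P^-1) given the Cholesky factor L of P = L L^T."""
    mean = np.linalg.solve(prec_chol.T, np.linalg.solve(prec_chol, lin))
    noise = np.linalg.solve(prec_chol.T, rng.standard_normal(lin.shape[0]))
    return mean + noise


def _init_state(model: JsdmModel, rng):
    n, p, q, d = model.n, model.p, model.q, model.d
    y = model.y
    g = np.column_stack([np.ones(n), model.x])
    coef, *_ = np.linalg.lstsq(g, y, rcond=None)
    beta0 = coef[0].copy()
    beta = coef[1:].copy() if q else np.zeros((0, p))
    resid = y - g @ coef
    if d > 0:
        u, s, vt = np.linalg.svd(resid, full_matrices=False)
        k = min(d, s.size)
        z = np.zeros((n, d))
        lam = np.zeros((p, d))
        z[:, :k] = u[:, :k] * math.sqrt(n)
        lam[:, :k] = (vt[:k].T * s[:k]) / math.sqrt(n)
        # enforce the lower-triangular identifiability constraint
        for j in range(min(d, p)):
            lam[j, j + 1:] = 0.0
            if lam[j, j] <= 0:
                lam[:, j] *= -1.0
                z[:, j] *= -1.0
            if lam[j, j] <= 0:
                lam[j, j] = 0.1
        resid = resid - z @ lam.T
    else:
        z = np.zeros((n, 0))
        lam = np.zeros((p, 0))
    sigma2 = np.maximum(resid.var(axis=0), 1e-4)
    return beta0, beta, lam, z, sigma2


def fit_jsdm(model: JsdmModel, iterations: int = 40000, burn_in: int = 10000,
             thin: int = 30, seed=0, phi_step_frac: float = 0.1) -> JsdmPosterior:
    """Gibbs sampler for the latent-variable JSDM.

    Retains ``(iterations - burn_in) / thin`` draws (the defaults give 1000)
    and is deterministic for a given seed. With ``d=0`` the model reduces to
    independent Bayesian linear regressions per taxon (no latent scores, no
    spatial range).
    """
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    rng = np.random.default_rng(seed)
    n, p, q, d = model.n, model.p, model.q, model.d
    y = model.y
    x = zscore_columns(model.x)
    tau2 = PRIOR_COEF_VAR

    beta0, beta, lam, z, sigma2 = _init_state(model, rng)

    # spatial prior support: span of observed pairwise distances
    use_spatial = False
    phi = float("nan")
    if d > 0:
        dists = model.distances()
        off = dists[np.triu_indices(n, 1)]
        positive = off[off > 0]
        use_spatial = bool(model.spatial and positive.size)
        if use_spatial:
            phi_lo, phi_hi = float(positive.min()), float(off.max())
            if phi_hi <= phi_lo:
                phi_hi = phi_lo * 1.5
            phi = 0.5 * (phi_lo + phi_hi)
            phi_step = phi_step_frac * (phi_hi - phi_lo)
            r = spherical_corr_matrix(dists, phi)
            r_eval, r_evec = np.linalg.eigh(r)
            r_chol = np.linalg.cholesky(r)
        else:  # iid latent scores: R = I
            r_eval = np.ones(n)
            r_evec = np.eye(n)

    n_keep = (iterations - burn_in) // thin
    out = JsdmPosterior(
        beta0=np.empty((n_keep, p)),
        beta=np.empty((n_keep, q, p)),
        loadings=np.empty((n_keep, p, d)),
        scores=np.empty((n_keep, n, d)),
        sigma2=np.empty((n_keep, p)),
        phi=np.empty(n_keep),
        taxon_ids=list(model.taxon_ids),
        settings={"iterations": iterations, "burn_in": burn_in, "thin": thin,
                  "seed": int(seed) if np.isscalar(seed) else None,
                  "d": d, "q": q, "n": n, "p": p},
    )

    ones = np.ones((n, 1))
    kept = 0
    for it in range(1, iterations + 1):
        # --- per-taxon coefficient updates (beta0_j, beta_j, lambda_j) ---
        # full design [1 | X | Z]; Gram matrices computed once per sweep
        g_full = np.hstack([ones, x, z]) if (q or d) else ones
        gtg = g_full.T @ g_full
        gty = g_full.T @ y
        m_full = g_full.shape[1]
        for j in range(p):
            s2 = sigma2[j]
            k_free = min(j, d)       # unconstrained latent columns for taxon j
            has_diag = j < d         # taxon j owns a positive diagonal loading
            if j >= d:
                idx = np.arange(m_full)
            else:
                idx = np.arange(1 + q + k_free)
            sub_gtg = gtg[np.ix_(idx, idx)]
            lin = gty[idx, j].copy()
            if has_diag:
                jcol = 1 + q + j
                lin -= gtg[idx, jcol] * lam[j, j]
            prec = sub_gtg / s2 + np.eye(idx.size) / tau2
            theta = _mvn_sample(np.linalg.cholesky(prec), lin / s2, rng)
            beta0[j] = theta[0]
            if q:
                beta[:, j] = theta[1:1 + q]
            if d > 0:
                if j >= d:
                    lam[j, :] = theta[1 + q:]
                else:
                    lam[j, :k_free] = theta[1 + q:]
                    lam[j, j + 1:] = 0.0
            if has_diag:
                # truncated-normal draw for the positive diagonal loading
                jcol = 1 + q + j
                prec_d = gtg[jcol, jcol] / s2 + 1.0 / tau2
                vr = gty[jcol, j] - gtg[jcol, idx] @ theta
                mean_d = (vr / s2) / prec_d
                sd_d = 1.0 / math.sqrt(prec_d)
                a = (0.0 - mean_d) / sd_d
                lam[j, j] = truncnorm.rvs(a, np.inf, loc=mean_d, scale=sd_d,
                                          random_state=rng)

        # --- residual variances ---
        fitted = ones @ beta0[None, :] + (x @ beta if q else 0.0)
        if d > 0:
            fitted = fitted + z @ lam.T
        resid = y - fitted
        ss = (resid**2).sum(axis=0)
        shape = PRIOR_SIGMA_A + 0.5 * n
        rate = PRIOR_SIGMA_B + 0.5 * ss
        sigma2 = rate / rng.gamma(shape, 1.0, size=p)
        sigma2 = np.maximum(sigma2, 1e-10)

        if d > 0:
            # --- latent scores: rows of Z, diagonalised through eig(R) ---
            dinv_lam = lam / sigma2[:, None]          # (p, d)
            a_mat = lam.T @ dinv_lam                  # (d, d)
            env_resid = y - ones @ beta0[None, :] - (x @ beta if q else 0.0)
            b = env_resid @ dinv_lam                  # (n, d)
            bt = r_evec.T @ b
            w = np.empty((n, d))
            for l in range(n):
                prec_l = a_mat + np.eye(d) / max(r_eval[l], 1e-10)
                w[l] = _mvn_sample(np.linalg.cholesky(prec_l), bt[l], rng)
            z = r_evec @ w

            # --- spatial range phi: random-walk Metropolis ---
            if use_spatial:
                log_target_cur = _phi_log_target(r_chol, z)
                phi_prop = phi + phi_step * rng.standard_normal()
                if phi_lo <= phi_prop <= phi_hi:
                    r_prop = spherical_corr_matrix(dists, phi_prop)
                    try:
                        chol_prop = np.linalg.cholesky(r_prop)
                    except np.linalg.LinAlgError:
                        chol_prop = None
                    if chol_prop is not None:
                        lt_prop = _phi_log_target(chol_prop, z)
                        if math.log(rng.uniform()) < lt_prop - log_target_cur:
                            phi = float(phi_prop)
                            r_chol = chol_prop
                            r_eval, r_evec = np.linalg.eigh(r_prop)

        if it > burn_in and (it - burn_in) % thin == 0:
            out.beta0[kept] = beta0
            out.beta[kept] = beta
            out.loadings[kept] = lam
            out.scores[kept] = z
            out.sigma2[kept] = sigma2
            out.phi[kept] = phi
            kept += 1

        if not np.all(np.isfinite(sigma2)) or not np.all(np.isfinite(beta0)):
            raise RuntimeError(f"sampler reached a non-finite state at iteration {it}")

    assert kept == n_keep
    return out


def _phi_log_target(r_chol: np.ndarray, z: np.ndarray) -> float:
    d = z.shape[1]
    logdet = 2.0 * float(np.log(np.diag(r_chol)).sum())
    quad = float((np.linalg.solve(r_chol, z) ** 2).sum())
    return -0.5 * d * logdet - 0.5 * quad


def residual_correlation_draws(post: JsdmPosterior):
    """Per-draw residual correlation matrices and their posterior summary.

    rho_jk = lambda_j . lambda_k / sqrt((|lambda_j|^2 + sigma_j^2)
    (|lambda_k|^2 + sigma_k^2)); each draw's matrix is symmetric, has unit
    diagonal and is positive semidefinite by construction.
    """
    if post.d == 0:
        raise ValueError("no latent structure to correlate (d = 0)")
    m, p, _ = post.loadings.shape
    rho = np.empty((m, p, p))
    for t in range(m):
        lam = post.loadings[t]
        cov = lam @ lam.T + np.diag(post.sigma2[t])
        sd = np.sqrt(np.diag(cov))
        rho[t] = cov / np.outer(sd, sd)
        np.fill_diagonal(rho[t], 1.0)
    return rho


def summarize_residual_correlations(rho_draws: np.ndarray, taxon_ids,
                                    level: float = 0.95) -> ResidualCorrelationSummary:
    if not 0 < level < 1:
        raise ValueError("credible level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    median = np.median(rho_draws, axis=0)
    lower = np.quantile(rho_draws, alpha, axis=0)
    upper = np.quantile(rho_draws, 1.0 - alpha, axis=0)
    return ResidualCorrelationSummary(list(taxon_ids), median, lower, upper, level)


def significant_edges(summary: ResidualCorrelationSummary) -> pd.DataFrame:
    """Taxon pairs whose credible interval for rho excludes zero.

    Positive edges have lower bound > 0, negative edges upper bound < 0; the
    edge weight is the posterior median correlation.
    """
    p = len(summary.taxon_ids)
    rows = []
    for j in range(p):
        for k in range(j + 1, p):
            lo, hi = summary.lower[j, k], summary.upper[j, k]
            if lo > 0 or hi < 0:
                rows.append({
                    "taxon_a": summary.taxon_ids[j],
                    "taxon_b": summary.taxon_ids[k],
                    "median_rho": summary.median[j, k],
                    "lower": lo,
                    "upper": hi,
                    "sign": "positive" if summary.median[j, k] >= 0 else "negative",
                })
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "median_rho",
                                       "lower", "upper", "sign"])


def forward_select_env(y: np.ndarray, candidates: pd.DataFrame, k: int):
    """Greedy forward selection of environmental covariates.

    At each step the candidate that maximises the mean per-taxon in-sample
    variance explained of the environment-only regression (d = 0) joins the
    selected set; candidates effectively collinear (|r| ~ 1) with an already
    selected covariate are skipped with a warning. Deterministic: ties keep
    column order.
    """
    if k > candidates.shape[1]:
        raise ValueError("k exceeds the number of candidate covariates")
    y = np.asarray(y, dtype=float)
    names = list(candidates.columns)
    selected: list = []
    for _ in range(k):
        best_name, best_r2 = None, -np.inf
        for name in names:
            if name in selected:
                continue
            cand = candidates[name].to_numpy(dtype=float)
            if selected:
                sel = candidates[selected].to_numpy(dtype=float)
                skip = False
                for c in range(sel.shape[1]):
                    r = np.corrcoef(cand, sel[:, c])[0, 1]
                    if abs(r) > 0.999:
                        logger.warning(
                            "forward_select_env: %r collinear with %r, skipped",
                            name, selected[c])
                        skip = True
                        break
                if skip:
                    continue
            r2 = _mean_r2(y, candidates[selected + [name]].to_numpy(dtype=float))
            if r2 > best_r2 + 1e-12:
                best_name, best_r2 = name, r2
        if best_name is None:
            break
        selected.append(best_name)
    return selected


def _mean_r2(y: np.ndarray, x: np.ndarray) -> float:
    n = y.shape[0]
    g = np.column_stack([np.ones(n), zscore_columns(x)])
    coef, *_ = np.linalg.lstsq(g, y, rcond=None)
    resid = y - g @ coef
    ss_res = (resid**2).sum(axis=0)
    yc = y - y.mean(axis=0)
    ss_tot = (yc**2).sum(axis=0)
    ok = ss_tot > 0
    return float(np.mean(1.0 - ss_res[ok] / ss_tot[ok]))


def env_variance_explained(model: JsdmModel, post: JsdmPosterior):
    """Per-taxon and mean R^2 of an environment-only (d = 0) fit.

    R^2_j = 1 - E[residual SS_j] / total SS_j, the expectation taken over
    posterior draws. Zero-variance taxon columns are excluded with a warning.
    """
    if post.d != 0:
        raise ValueError("env_variance_explained requires an environment-only fit")
    y = model.y
    x = zscore_columns(model.x)
    n, p = y.shape
    m = post.n_draws
    ss_res = np.zeros(p)
    for t in range(m):
        fitted = np.ones((n, 1)) @ post.beta0[t][None, :]
        if model.q:
            fitted = fitted + x @ post.beta[t]
        ss_res += ((y - fitted) ** 2).sum(axis=0)
    ss_res /= m
    yc = y - y.mean(axis=0)
    ss_tot = (yc**2).sum(axis=0)
    ok = ss_tot > 0
    if not ok.all():
        bad = [model.taxon_ids[j] for j in np.flatnonzero(~ok)]
        logger.warning("env_variance_explained: zero-variance taxa excluded: %s", bad)
    r2 = np.full(p, np.nan)
    r2[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    return r2, float(np.nanmean(r2))


def geweke_diagnostic(chain, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain windows.

    z = (mean of first 10% - mean of last 50%) / sqrt(S1(0)/n1 + S2(0)/n2),
    with S(0) the spectral density at frequency zero estimated from windowed
    autocovariances. |z| > ~2 flags disagreement between the windows, i.e. a
    chain that has not reached its stationary distribution. A constant chain
    has no variance and yields NaN with a warning.
    """
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 1:
        raise ValueError("chain must be 1-D")
    n = chain.size
    if n < 50:
        raise ValueError("need at least 50 draws for the Geweke diagnostic")
    w1 = chain[: int(first * n)]
    w2 = chain[n - int(last * n):]
    v1 = _spectral_var_at_zero(w1)
    v2 = _spectral_var_at_zero(w2)
    denom = v1 / w1.size + v2 / w2.size
    if denom <= 0:
        logger.warning("geweke_diagnostic: zero-variance windows, returning NaN")
        return float("nan")
    return float((w1.mean() - w2.mean()) / math.sqrt(denom))


def _spectral_var_at_zero(x: np.ndarray) -> float:
    """S(0) via autocovariances with a Bartlett window (lag ~ sqrt(n))."""
    n = x.size
    xc = x - x.mean()
    max_lag = max(1, int(math.sqrt(n)))
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for lag in range(1, max_lag + 1):
        g = float(xc[:-lag] @ xc[lag:]) / n
        s += 2.0 * (1.0 - lag / (max_lag + 1)) * g
    return max(s, 0.0)


def geweke_report(post: JsdmPosterior) -> dict:
    """Geweke z per parameter block (means across elements of |z| and max)."""
    blocks = {"beta0": post.beta0.reshape(post.n_draws, -1),
              "sigma2": post.sigma2.reshape(post.n_draws, -1)}
    if post.beta.shape[1]:
        blocks["beta"] = post.beta.reshape(post.n_draws, -1)
    if post.d:
        blocks["loadings"] = post.loadings.reshape(post.n_draws, -1)
        blocks["phi"] = post.phi.reshape(post.n_draws, -1)
    report = {}
    for name, arr in blocks.items():
        zs = []
        for c in range(arr.shape[1]):
            if np.ptp(arr[:, c]) == 0:
                continue  # structurally fixed (e.g. constrained loadings)
            try:
                z = geweke_diagnostic(arr[:, c])
            except ValueError:
                continue
            if np.isfinite(z):
                zs.append(abs(z))
        report[name] = {
            "mean_abs_z": float(np.mean(zs)) if zs else float("nan"),
            "max_abs_z": float(np.max(zs)) if zs else float("nan"),
            "n_parameters": len(zs),
        }
    return report


def quantile_residuals(model: JsdmModel, post: JsdmPosterior):
    """Dunn-Smyth (randomized quantile) residuals and a normal-QQ summary.

    For a Gaussian response the randomized quantile residual reduces to the
    standardized residual (y - mu_hat) / sigma_hat evaluated at the posterior
    means. Returns the (n, p) residual matrix and a dict with the slope and
    intercept of the least-squares line through the normal QQ plot; a
    well-specified model gives slope ~ 1 and intercept ~ 0.
    """
    x = zscore_columns(model.x)
    n = model.n
    mu = np.ones((n, 1)) @ post.beta0.mean(axis=0)[None, :]
    if model.q:
        mu = mu + x @ post.beta.mean(axis=0)
    if post.d:
        mu = mu + post.scores.mean(axis=0) @ post.loadings.mean(axis=0).T
    sd = np.sqrt(post.sigma2.mean(axis=0))
    resid = (model.y - mu) / sd[None, :]
    flat = np.sort(resid.ravel())
    m = flat.size
    theo = ndtri((np.arange(1, m + 1) - 0.375) / (m + 0.25))
    slope, intercept = np.polyfit(theo, flat, 1)
    return resid, {"qq_slope": float(slope), "qq_intercept": float(intercept)}
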