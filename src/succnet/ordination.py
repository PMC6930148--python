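"""Successional-stage assignment by PCA of environmental variables, and
redundancy analysis (RDA) of clr abundances on stage with a permutation test.

Succession is treated as a gradient summarised by the first principal
component of environmental and vegetation variables; plots are ranked along
axis 1 and split into equal-sized groups (early / mid / late). RDA on clr
values is equivalent to constrained ordination in Aitchison geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ClrMatrix, SampleMetadata

STAGE_NAMES = ("early", "mid", "late")


@dataclass
class PcaScores:
    sample_ids: list
    axis1: np.ndarray              # axis-1 score per sample
    variance_fractions: np.ndarray  # fraction of variance per axis, sums to 1
    loadings: pd.DataFrame          # variables x axes


def pca_stage_scores(metadata: SampleMetadata, variable_names,
                     orient_by: str = "plant_cover") -> PcaScores:
    """PCA of z-scored environmental variables.

    Variables are standardised (correlation-matrix PCA) because they carry
    heterogeneous units. Axis 1 is sign-oriented so that ``orient_by`` (plant
    cover by default, a late-succession indicator) loads positively; if that
    variable is absent, the variable with the largest absolute axis-1 loading
    is oriented positive instead.
    """
    variable_names = list(variable_names)
    if len(variable_names) < 2:
        raise ValueError("PCA needs at least two variables")
    x = metadata.covariate_matrix(variable_names)
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least three samples")
    sd = x.std(axis=0, ddof=1)
    zero_var = [v for v, s in zip(variable_names, sd) if s == 0]
    if zero_var:
        raise ValueError(f"zero-variance variables: {zero_var}")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    frac = s**2 / (s**2).sum()
    scores = u * s
    loadings = vt.T
    if orient_by in variable_names:
        ref = variable_names.index(orient_by)
    else:
        ref = int(np.argmax(np.abs(loadings[:, 0])))
    flip = np.where(loadings[ref, :] < 0, -1.0, 1.0)
    # keep the orientation rule on axis 1 only; other axes get a deterministic
    # largest-loading-positive convention
    for k in range(1, loadings.shape[1]):
        r = int(np.argmax(np.abs(loadings[:, k])))
        flip[k] = -1.0 if loadings[r, k] < 0 else 1.0
    scores = scores * flip
    loadings = loadings * flip
    return PcaScores(
        list(metadata.sample_ids),
        scores[:, 0],
        frac,
        pd.DataFrame(loadings, index=variable_names,
                     columns=[f"axis{k + 1}" for k in range(loadings.shape[1])]),
    )


def assign_stages(scores: PcaScores, n_groups: int = 3) -> pd.DataFrame:
    """Split samples into contiguous groups along axis 1 (ascending).

    Earlier groups receive the extra samples when n is not divisible by
    ``n_groups`` (e.g. 7 samples, 3 groups -> sizes 3/2/2). Ties in score are
    broken by sample id. Returns a DataFrame with sample_id, axis1_score and
    stage; with three groups the stages are named early/mid/late, otherwise
    stage1..stageK.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    n = len(scores.sample_ids)
    if n < n_groups:
        raise ValueError("fewer samples than groups")
    order = sorted(range(n), key=lambda i: (scores.axis1[i], scores.sample_ids[i]))
    base, extra = divmod(n, n_groups)
    sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]
    names = (list(STAGE_NAMES) if n_groups == 3
             else [f"stage{g + 1}" for g in range(n_groups)])
    stage = {}
    pos = 0
    for g, size in enumerate(sizes):
        for i in order[pos:pos + size]:
            stage[i] = names[g]
        pos += size
    return pd.DataFrame(
        {
            "sample_id": list(scores.sample_ids),
            "axis1_score": scores.axis1,
            "stage": [stage[i] for i in range(n)],
        }
    )


def rda_permutation(clr: ClrMatrix, stages, n_perm: int = 999, seed=0):
    """RDA of clr abundances on successional stage with a permutation test.

    The constrained variance is the squared norm of the least-squares
    projection of the column-centered clr matrix onto stage indicators.
    Returns (variance-explained fraction, pseudo-F, p-value); the p-value
    uses the add-one correction p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    stages = list(stages)
    if len(stages) != clr.n_samples:
        raise ValueError("stage labels must match clr samples")
    levels = sorted(set(stages))
    if len(levels) < 2:
        raise ValueError("RDA needs at least two stages")
    y = clr.values - clr.values.mean(axis=0, keepdims=True)
    g = np.array([levels.index(s) for s in stages])
    n = y.shape[0]
    df_c = len(levels) - 1
    df_r = n - len(levels)
    if df_r <= 0:
        raise ValueError("not enough samples for residual degrees of freedom")

    def f_stat(yy):
        total = (yy**2).sum()
        fitted = np.zeros_like(yy)
        for lv in range(len(levels)):
            m = g == lv
            fitted[m] = yy[m].mean(axis=0)
        constrained = (fitted**2).sum()
        resid = total - constrained
        f = (constrained / df_c) / (resid / df_r) if resid > 0 else np.inf
        frac = constrained / total if total > 0 else 0.0
        return frac, f

    frac_obs, f_obs = f_stat(y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, f_p = f_stat(y[perm])
        if f_p >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(frac_obs), float(f_obs), float(p)
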