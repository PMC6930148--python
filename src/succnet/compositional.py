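"""Compositional preprocessing: rarefaction, zero replacement, clr, filtering.

Marker-gene count tables are compositional — only relative information is
meaningful — so downstream modelling works on centered log-ratio (clr)
transformed abundances. The chain implemented here is the standard one:
subsample every sample to an even depth (hypergeometric rarefaction), replace
count zeros by a small positive value with a multiplicative adjustment of the
non-zero parts, take the clr, and restrict to "core" taxa that occur in a
minimum number of plots.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import ClrMatrix, CommunityTable, ValidationError

logger = logging.getLogger(__name__)


def rarefy(table: CommunityTable, depth: int, seed) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total count is below ``depth`` are dropped (with a log
    message). Each retained sample is drawn once from the multivariate
    hypergeometric distribution, so zeros stay zero and no count can exceed
    its original value.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    counts = np.asarray(table.counts, dtype=np.int64)
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropping %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    row = 0
    for i in np.flatnonzero(keep):
        if totals[i] == depth:
            out[row] = counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(counts[i], depth)
        row += 1
    return CommunityTable(
        [s for s, k in zip(table.sample_ids, keep) if k],
        list(table.taxon_ids),
        out,
        list(table.group),
        list(table.trophic),
    )


def impute_zeros(table: CommunityTable, frac: float = 0.65) -> np.ndarray:
    """Replace count zeros by small positive proportions (CZM-style).

    Count-zero multiplicative replacement: for a sample with total count
    ``n_i``, each zero becomes ``delta_i = frac / (n_i + 1)`` — a fraction of
    the Bayes-Laplace posterior share of one pseudo-count — and the non-zero
    parts are multiplicatively rescaled so the row remains a composition
    summing to one. The imputed value shrinks as sequencing depth grows,
    reflecting the stronger evidence that a taxon is genuinely rare.

    Returns a strictly positive (n_samples, n_taxa) proportion matrix.
    """
    counts = np.asarray(table.counts, dtype=float)
    totals = counts.sum(axis=1)
    zero_rows = np.flatnonzero(totals <= 0)
    if zero_rows.size:
        bad = [table.sample_ids[i] for i in zero_rows]
        raise ValidationError(f"all-zero samples cannot be imputed: {bad}")
    props = counts / totals[:, None]
    out = np.empty_like(props)
    for i in range(props.shape[0]):
        z = props[i] == 0
        if not z.any():
            out[i] = props[i]
            continue
        delta = frac / (totals[i] + 1.0)
        imputed_total = delta * z.sum()
        if imputed_total >= 1.0:
            raise ValidationError(
                f"sample {table.sample_ids[i]!r}: too many zeros at depth "
                f"{totals[i]:.0f} for multiplicative replacement"
            )
        out[i] = np.where(z, delta, props[i] * (1.0 - imputed_total))
    return out


def clr_transform(comp: np.ndarray, sample_ids=None, taxon_ids=None) -> ClrMatrix:
    """Centered log-ratio transform of a strictly positive composition matrix.

    clr_ij = ln(x_ij) - mean_j ln(x_ij). Rows of the result sum to zero and
    the transform is invariant to per-sample rescaling.
    """
    comp = np.asarray(comp, dtype=float)
    if np.any(comp <= 0):
        raise ValueError("clr requires strictly positive entries; impute zeros first")
    logx = np.log(comp)
    vals = logx - logx.mean(axis=1, keepdims=True)
    n, p = vals.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if taxon_ids is None:
        taxon_ids = [f"t{j}" for j in range(p)]
    return ClrMatrix(list(sample_ids), list(taxon_ids), vals)


def clr_of_table(table: CommunityTable, frac: float = 0.65) -> ClrMatrix:
    """Zero-replace then clr-transform a count table."""
    comp = impute_zeros(table, frac=frac)
    return clr_transform(comp, table.sample_ids, table.taxon_ids)


def frequency_filter(table: CommunityTable, min_plots: int) -> CommunityTable:
    """Keep taxa occurring (count > 0) in at least ``min_plots`` samples.

    Taxon order is preserved. Raising ``min_plots`` can only remove taxa.
    """
    if min_plots < 1:
        raise ValueError("min_plots must be >= 1")
    occ = (np.asarray(table.counts) > 0).sum(axis=0)
    keep = occ >= min_plots
    return CommunityTable(
        list(table.sample_ids),
        [t for t, k in zip(table.taxon_ids, keep) if k],
        table.counts[:, keep],
        [g for g, k in zip(table.group, keep) if k],
        [t for t, k in zip(table.trophic, keep) if k],
    )
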