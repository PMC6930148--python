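"""Alpha-diversity and occupancy metrics: Chao1, Shannon/Pielou, Faith's PD,
rarity, and per-taxon occurrence frequency."""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CommunityTable

logger = logging.getLogger(__name__)


def chao1(counts) -> float:
    """Chao1 richness estimate for one sample.

    Classic form S_obs + F1^2 / (2 F2) with F1 singletons and F2 doubletons;
    when no doubletons are observed the bias-corrected form
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)) is used instead. Always >= observed
    richness, with equality iff there are no singletons.
    """
    counts = np.asarray(counts)
    if counts.size == 0 or counts.sum() == 0:
        logger.warning("chao1: empty or all-zero sample, returning 0")
        return 0.0
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon_pielou(counts):
    """Shannon entropy (nats) and Pielou's evenness J = H / ln(S_obs).

    J is undefined for a single-taxon sample and returned as NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("shannon_pielou requires at least one positive count")
    p = counts[counts > 0]
    p = p / p.sum()
    h = float(-(p * np.log(p)).sum())
    s_obs = p.size
    j = h / math.log(s_obs) if s_obs > 1 else float("nan")
    return h, j


def faith_pd(tree: TreeNode, present_taxa, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a set of present tips.

    Sum of branch lengths of the minimal subtree spanning the present tips;
    by default the path up to the root is included (matching common
    implementations), otherwise branches above the most recent common
    ancestor of the present tips are excluded.
    """
    present = set(map(str, present_taxa))
    if not present:
        return 0.0
    tip_names = {t.name for t in tree.tips()}
    missing = sorted(present - tip_names)
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    marked = set()
    for tip in tree.tips():
        if tip.name not in present:
            continue
        node = tip
        while node.parent is not None:
            if id(node) in marked:
                break
            marked.add(id(node))
            node = node.parent
    node_by_id = {id(n): n for n in tree.traverse()}
    total = sum((node_by_id[i].length or 0.0) for i in marked)
    if not include_root:
        tips = [t for t in tree.tips() if t.name in present]
        lca = tree.lca(tips) if len(tips) > 1 else tips[0]
        node = lca
        while node.parent is not None:
            total -= node.length or 0.0
            node = node.parent
    return float(total)


def rarity(table: CommunityTable) -> pd.Series:
    """Per-sample proportion of present taxa rarer than 1/S.

    S is the mean observed richness across the table's samples (one
    successional stage); a taxon counts as rare in a sample when its relative
    abundance there is strictly below 1/S. The denominator is the number of
    taxa present in that sample.
    """
    counts = np.asarray(table.counts, dtype=float)
    if counts.shape[0] == 0:
        raise ValueError("rarity requires at least one sample")
    richness = (counts > 0).sum(axis=1)
    s_mean = richness.mean()
    if s_mean == 0:
        raise ValueError("rarity undefined for an all-empty stage")
    thresh = 1.0 / s_mean
    vals = []
    for i in range(counts.shape[0]):
        row = counts[i]
        present = row > 0
        n_present = int(present.sum())
        if n_present == 0:
            vals.append(float("nan"))
            continue
        rel = row[present] / row.sum()
        vals.append(float((rel < thresh).sum() / n_present))
    return pd.Series(vals, index=table.sample_ids, name="rarity")


def taxon_frequency(table: CommunityTable) -> pd.Series:
    """Number of samples (plots) in which each taxon occurs."""
    occ = (np.asarray(table.counts) > 0).sum(axis=0)
    return pd.Series(occ, index=table.taxon_ids, name="frequency")


def diversity_table(table: CommunityTable, tree: TreeNode = None) -> pd.DataFrame:
    """Long-format table of per-sample diversity metrics for one stage."""
    rows = []
    rar = rarity(table)
    for i, sid in enumerate(table.sample_ids):
        counts = table.counts[i]
        h, j = shannon_pielou(counts) if counts.sum() > 0 else (float("nan"),) * 2
        rows.append({"sample_id": sid, "metric": "chao1", "value": chao1(counts)})
        rows.append({"sample_id": sid, "metric": "shannon", "value": h})
        rows.append({"sample_id": sid, "metric": "pielou_evenness", "value": j})
        rows.append({"sample_id": sid, "metric": "rarity", "value": rar[sid]})
        if tree is not None:
            present = [t for t, c in zip(table.taxon_ids, counts) if c > 0]
            rows.append(
                {"sample_id": sid, "metric": "faith_pd",
                 "value": faith_pd(tree, present)}
            )
    return pd.DataFrame(rows)
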