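"""Core in-memory containers for community data.

Tables are oriented samples-as-rows throughout, the convention used by most
community-ecology software. ``CommunityTable`` holds raw or rarefied counts
together with per-taxon annotations (organism group and trophic mode);
``SampleMetadata`` holds environmental covariates plus plot coordinates; and
``ClrMatrix`` holds centered log-ratio transformed abundances, whose rows lie
in the zero-sum hyperplane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORGANISM_GROUPS = ("bacteria", "fungi", "small_eukaryote", "microfauna", "plant")
TROPHIC_MODES = ("photosynthetic", "heterotrophic", "chemoautotrophic", "unknown")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class CommunityTable:
    """Samples x taxa non-negative count matrix with taxon annotations.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``counts``.
    taxon_ids : list of str
        Unique taxon identifiers, one per column of ``counts``.
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integer counts.
    group : list of str
        Organism group per taxon (``bacteria``, ``fungi``, ``small_eukaryote``,
        ``microfauna``, ``plant`` or ``unknown``).
    trophic : list of str
        Trophic mode per taxon (``photosynthetic``, ``heterotrophic``,
        ``chemoautotrophic`` or ``unknown``).
    """

    sample_ids: list
    taxon_ids: list
    counts: np.ndarray
    group: list = field(default=None)
    trophic: list = field(default=None)

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        n, p = self.counts.shape
        if n != len(self.sample_ids) or p != len(self.taxon_ids):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(self.counts.astype(float))):
            raise ValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon ids")
        if self.group is None:
            self.group = ["unknown"] * p
        if self.trophic is None:
            self.trophic = ["unknown"] * p
        if len(self.group) != p or len(self.trophic) != p:
            raise ValidationError("group/trophic length must equal number of taxa")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def annotation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group, "trophic": self.trophic}, index=self.taxon_ids
        )

    def select_samples(self, sample_ids) -> "CommunityTable":
        """Subset (and reorder) to the given sample ids."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityTable(
            [self.sample_ids[i] for i in idx],
            list(self.taxon_ids),
            self.counts[idx, :],
            list(self.group),
            list(self.trophic),
        )

    def select_taxa(self, taxon_ids) -> "CommunityTable":
        """Subset (and reorder) to the given taxon ids."""
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CommunityTable(
            list(self.sample_ids),
            [self.taxon_ids[i] for i in idx],
            self.counts[:, idx],
            [self.group[i] for i in idx],
            [self.trophic[i] for i in idx],
        )


@dataclass
class SampleMetadata:
    """Per-sample environmental covariates and spatial coordinates.

    ``covariates`` is a samples x variables DataFrame; ``coords`` is an
    (n, 2) array of x, y positions in meters.
    """

    sample_ids: list
    covariates: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.coords = np.asarray(self.coords, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in metadata")
        if self.coords.shape != (len(self.sample_ids), 2):
            raise ValidationError("coords must be (n_samples, 2)")
        if len(self.covariates) != len(self.sample_ids):
            raise ValidationError("covariate rows must match sample ids")
        self.covariates = self.covariates.copy()
        self.covariates.index = self.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def covariate_matrix(self, names) -> np.ndarray:
        """Return the named covariates as a float matrix, refusing NAs."""
        missing = [c for c in names if c not in self.covariates.columns]
        if missing:
            raise ValidationError(f"unknown covariates: {missing}")
        sub = self.covariates[list(names)]
        for c in names:
            if sub[c].isna().any():
                raise ValidationError(f"covariate {c!r} contains missing values")
        return sub.to_numpy(dtype=float)

    def select_samples(self, sample_ids) -> "SampleMetadata":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return SampleMetadata(
            [self.sample_ids[i] for i in idx],
            self.covariates.iloc[idx],
            self.coords[idx, :],
        )


@dataclass
class ClrMatrix:
    """Samples x taxa matrix of centered log-ratio abundances.

    Every row sums to zero (within 1e-8): clr values live in the hyperplane
    orthogonal to the all-ones vector, so Euclidean distance between rows is
    the Aitchison distance between the underlying compositions.
    """

    sample_ids: list
    taxon_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError("values shape does not match ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("clr values must be finite")
        row_sums = self.values.sum(axis=1)
        if np.any(np.abs(row_sums) > 1e-8 * max(1, self.values.shape[1])):
            raise ValidationError("clr rows must sum to zero")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)


def concat_clr(matrices) -> ClrMatrix:
    """Column-concatenate ClrMatrix objects sharing the same sample order.

    Each block keeps its own clr geometry (rows of each block sum to zero);
    the concatenated rows therefore also sum to zero.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValidationError("no matrices to concatenate")
    ref = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != ref:
            raise ValidationError("sample ids differ between clr blocks")
    taxa = [t for m in matrices for t in m.taxon_ids]
    vals = np.hstack([m.values for m in matrices])
    return ClrMatrix(list(ref), taxa, vals)
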