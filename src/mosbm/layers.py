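"""Omics layers: feature-by-sample weight matrices and their preprocessing.

Each omics data type (bulk gene expression in FPKM, miRNA counts per million,
per-gene copy numbers, ...) enters the analysis as one :class:`OmicsLayer`:
a nonnegative feature-by-sample matrix with its own units and normalization.
Layers are filtered and transformed independently — branches of the
multipartite network never share a normalization — and only then joined on a
common sample set and discretized into a network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OmicsLayer",
    "select_highly_variable",
    "log_transform",
    "select_high_cnv",
    "intersect_samples",
    "read_layer",
    "write_layer",
]


@dataclass
class OmicsLayer:
    """One branch of the multipartite network.

    Parameters
    ----------
    branch_name:
        Short identifier for the branch ("genes", "mirna", "cnv", ...).
    data:
        Feature-by-sample matrix (rows = features, columns = samples) of
        nonnegative, finite weights in branch-specific units.
    units:
        Free-text description of the weight units (e.g. "FPKM").
    """

    branch_name: str
    data: pd.DataFrame
    units: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            raise ValueError(f"duplicate feature ids in branch {self.branch_name!r}")
        if self.data.columns.has_duplicates:
            raise ValueError(f"duplicate sample ids in branch {self.branch_name!r}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError(f"non-finite weights in branch {self.branch_name!r}")
        if (values < 0).any():
            raise ValueError(f"negative weights in branch {self.branch_name!r}")

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def restrict_features(self, feature_ids) -> "OmicsLayer":
        return OmicsLayer(self.branch_name, self.data.loc[list(feature_ids)], self.units)

    def restrict_samples(self, sample_ids) -> "OmicsLayer":
        return OmicsLayer(self.branch_name, self.data[list(sample_ids)], self.units)


def select_highly_variable(layer: OmicsLayer, n_top: int, n_bins: int = 20) -> OmicsLayer:
    """Keep the ``n_top`` features with highest mean-binned dispersion.

    Dispersion is variance over mean, the Fano-factor-style statistic used for
    highly-variable gene selection. Because dispersion scales with expression,
    features are first ranked by mean weight and split into ``n_bins``
    equal-count bins; within each bin the dispersion is z-scored, and the
    ``n_top`` features with the largest z-scores are kept. Features with zero
    mean carry no signal and are never candidates. Deterministic: ties are
    broken lexicographically by feature id.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    values = layer.data.to_numpy(dtype=float)
    means = values.mean(axis=1)
    variances = values.var(axis=1, ddof=1) if layer.n_samples > 1 else np.zeros_like(means)
    candidates = np.flatnonzero(means > 0)
    if candidates.size == 0 or np.all(variances[candidates] == 0):
        raise ValueError("no variable features")
    if n_top > candidates.size:
        raise ValueError(
            f"n_top={n_top} exceeds the {candidates.size} features with nonzero mean"
        )
    dispersion = variances[candidates] / means[candidates]

    # equal-count bins by mean-expression rank (stable: mean, then feature id)
    ids = np.asarray(layer.feature_ids, dtype=object)[candidates]
    rank_order = np.lexsort((ids, means[candidates]))
    z = np.empty(candidates.size, dtype=float)
    for binned in np.array_split(rank_order, min(n_bins, candidates.size)):
        d = dispersion[binned]
        sd = d.std(ddof=0)
        z[binned] = (d - d.mean()) / sd if sd > 0 else 0.0

    keep = np.lexsort((ids, -z))[:n_top]
    # preserve the original row order of the matrix for the surviving features
    chosen = set(ids[keep])
    ordered = [f for f in layer.feature_ids if f in chosen]
    return layer.restrict_features(ordered)


def log_transform(layer: OmicsLayer) -> OmicsLayer:
    """Apply ``x -> ln(x + 1)`` to every weight.

    Shrinks heavy-tailed expression values so that the discretized network has
    far fewer unit edges; monotone and zero-preserving.
    """
    return OmicsLayer(layer.branch_name, np.log1p(layer.data), layer.units)


def select_high_cnv(layer: OmicsLayer, threshold: float = 3.5) -> OmicsLayer:
    """Keep features whose mean weight over samples is strictly above ``threshold``.

    With copy-number weights the default 3.5 keeps genes carrying at least two
    extra copies on average (diploid baseline 2).
    """
    means = layer.data.mean(axis=1)
    keep = layer.data.index[means > threshold]
    return layer.restrict_features(keep)


def intersect_samples(layers: list[OmicsLayer]) -> list[OmicsLayer]:
    """Restrict all layers to their common samples, identically ordered.

    The common order is the sample order of the first layer.
    """
    if not layers:
        raise ValueError("no layers given")
    common = set(layers[0].sample_ids)
    for layer in layers[1:]:
        common &= set(layer.sample_ids)
    if not common:
        raise ValueError("empty sample intersection across layers")
    ordered = [s for s in layers[0].sample_ids if s in common]
    return [layer.restrict_samples(ordered) for layer in layers]


def read_layer(path, branch_name: str, units: str = "", sep: str = "\t") -> OmicsLayer:
    """Read a feature-by-sample matrix (first column feature ids, header samples)."""
    data = pd.read_csv(path, sep=sep, index_col=0)
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    return OmicsLayer(branch_name, data, units)


def write_layer(layer: OmicsLayer, path, sep: str = "\t") -> None:
    layer.data.to_csv(path, sep=sep, index_label="feature_id")
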