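"""Sliding-window extraction, per-window z-normalization and 2D PCA embedding.

Every length-``w_g`` subsequence of the series (step 1) is z-normalized to
zero mean and unit *population* standard deviation, so comparison is by
shape, not level. The normalized windows are then projected onto their top
two principal components, giving a temporally ordered 2D point set in which
similar waveforms land close together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.decomposition import PCA

from .io import TimeSeries

#: spread below which a window counts as constant and is zeroed out
DEGENERACY_EPS = 1e-12


@dataclass(frozen=True)
class SubseqMatrix:
    """All sliding windows of a series: row ``i`` is ``T[i : i + w_g]``."""

    data: np.ndarray  # (N, w_g)

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def w_g(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class NormalizedMatrix:
    """Row-wise z-normalized windows; constant rows become all-zero."""

    data: np.ndarray  # (N, w_g)
    degenerate_rows: frozenset[int]


@dataclass(frozen=True)
class Embedding2D:
    """Temporally ordered N x 2 projection plus explained-variance fractions."""

    points: np.ndarray  # (N, 2)
    explained: np.ndarray  # (2,)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


def extract_subsequences(series: TimeSeries, w_g: int) -> SubseqMatrix:
    """All contiguous windows of length ``w_g`` (sliding step 1).

    Requires ``2 <= w_g <= n - 1`` so that at least two windows exist.
    """
    n = series.n
    if not 2 <= w_g <= n - 1:
        raise ValueError(f"window length w_g={w_g} out of range [2, {n - 1}] for n={n}")
    return SubseqMatrix(sliding_window_view(series.values, w_g).copy())


def znormalize(Z: SubseqMatrix, eps: float = DEGENERACY_EPS) -> NormalizedMatrix:
    """Z-normalize each row with the population standard deviation.

    Rows with spread below ``eps`` (constant segments) become zero vectors
    and are recorded in ``degenerate_rows`` instead of raising.
    """
    X = Z.data
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population (divisor N) convention
    degenerate = sd[:, 0] < eps
    safe = np.where(degenerate[:, None], 1.0, sd)
    out = (X - mu) / safe
    out[degenerate] = 0.0
    return NormalizedMatrix(out, frozenset(np.flatnonzero(degenerate).tolist()))


def project_2d(Zn: NormalizedMatrix) -> Embedding2D:
    """Project normalized windows onto their top two principal components.

    The decomposition is exact (full SVD, no randomized solver) and a fixed
    sign convention is applied: within each component the loading with the
    largest absolute value is made positive, so the orientation of the
    embedding — and the grid binning downstream — is deterministic.

    A matrix with fewer than two distinct rows collapses to identical points;
    that is returned, not raised.
    """
    X = Zn.data
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(f"need at least a 2x2 matrix, got {X.shape}")
    centered = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(centered) > 1e-15):
        # all windows identical: every point at the origin, nothing explained
        return Embedding2D(np.zeros((X.shape[0], 2)), np.zeros(2))
    pca = PCA(n_components=2, svd_solver="full")
    pts = pca.fit_transform(X)
    comps = pca.components_
    for j in range(2):
        pivot = int(np.argmax(np.abs(comps[j])))
        if comps[j, pivot] < 0:
            pts[:, j] = -pts[:, j]
    explained = np.nan_to_num(pca.explained_variance_ratio_, nan=0.0)
    return Embedding2D(pts, explained)


def embed(series: TimeSeries, w_g: int, eps: float = DEGENERACY_EPS) -> Embedding2D:
    """Convenience: extraction → z-normalization → 2D projection."""
    return project_2d(znormalize(extract_subsequences(series, w_g), eps=eps))
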