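"""Model/Results interface for graph-based subsequence anomaly detection.

``GraphTS`` is built from a univariate series plus the two structural
parameters — the embedding window ``w_g`` (slightly below the normal-pattern
length, ``l_np - 20`` by convention) and the grid size ``n_cell`` (a perfect
square, default 100). ``fit()`` runs the deterministic three-stage pipeline

    windows → z-normalize → 2D PCA → grid → transition graph

and returns a :class:`GraphTSResults` holding the embedding, grid, node path
and weighted graph. Scoring, Top-K detection, variable-length scans,
summaries and debug plots all hang off the results object; every length is
scored against the one fitted graph without re-embedding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import embedding as _emb
from . import graph as _graph
from . import scoring as _scoring
from .io import AnomalyReport, TimeSeries
from .synthetic import estimate_period_hint


def _check_n_cells(n_cells: int) -> int:
    root = math.isqrt(n_cells)
    if n_cells < 4 or root * root != n_cells:
        raise ValueError(f"n_cells must be a perfect square >= 4, got {n_cells}")
    return root


class GraphTS:
    """Graph representation model of a univariate time series.

    Parameters
    ----------
    endog : TimeSeries | array-like
        The series to model.
    window : int, optional
        Embedding window ``w_g``. When omitted it is derived from an
        autocorrelation period estimate as ``period - 20``; an unreliable
        estimate raises, since ``w_g`` is structural.
    n_cells : int
        Total grid cells ``n_cell`` (perfect square), default 100.
    """

    def __init__(self, endog, window: int | None = None, n_cells: int = 100, name: str = "series"):
        self.series = endog if isinstance(endog, TimeSeries) else TimeSeries(
            np.asarray(endog, dtype=np.float64), name=name
        )
        self.n_c = _check_n_cells(n_cells)
        self.n_cells = n_cells
        if window is None:
            hint = estimate_period_hint(self.series)
            if not hint.reliable or hint.period is None:
                raise ValueError(
                    "no reliable period found to derive the window from; pass window= explicitly"
                )
            window = max(2, hint.period - 20)
        if not 2 <= window <= self.series.n - 1:
            raise ValueError(
                f"window {window} out of range [2, {self.series.n - 1}] for n={self.series.n}"
            )
        self.window = int(window)

    @classmethod
    def from_dataframe(cls, df, column=None, **kwargs) -> "GraphTS":
        """Build from a pandas DataFrame/Series column."""
        col = df.iloc[:, 0] if column is None and hasattr(df, "iloc") and df.ndim == 2 else (
            df[column] if column is not None else df
        )
        return cls(np.asarray(col, dtype=np.float64), name=str(getattr(col, "name", "series")), **kwargs)

    def fit(self) -> "GraphTSResults":
        """Run the embedding → grid → graph pipeline (deterministic)."""
        emb = _emb.project_2d(
            _emb.znormalize(_emb.extract_subsequences(self.series, self.window))
        )
        grid, path = _graph.grid_partition(emb, self.n_c)
        g = _graph.build_graph(path, grid)
        return GraphTSResults(self, emb, grid, path, g)


@dataclass
class GraphTSResults:
    """Fitted graph representation plus scoring/detection methods."""

    model: GraphTS
    embedding: _emb.Embedding2D
    grid: _graph.GridSpec
    path: _graph.NodePath
    graph: _graph.TSGraph

    def _params(self, **extra) -> dict:
        p = {"w_g": self.model.window, "n_cell": self.model.n_cells}
        p.update(extra)
        return p

    def score_profile(
        self, length: int | None = None, smooth: bool = True, smooth_window: int | None = None
    ) -> _scoring.ScoreProfile:
        """Mean-edge-weight score per start; smoothed with ``w_g`` by default."""
        length = length if length is not None else self.model.window
        prof = _scoring.score_profile(self.graph, self.path, length)
        if smooth:
            prof = _scoring.smooth_scores(prof, smooth_window or self.model.window)
        return prof

    def detect(
        self,
        length: int | None = None,
        k: int | None = None,
        smooth: bool = True,
        smooth_window: int | None = None,
    ) -> AnomalyReport:
        """Top-K lowest-score subsequences with exclusion zones.

        ``k=None`` returns the full ranked post-exclusion list.
        """
        length = length if length is not None else self.model.window
        prof = self.score_profile(length, smooth=smooth, smooth_window=smooth_window)
        return _scoring.detect_topk(prof, k=k, params=self._params(length=length, k=k))

    def scan(
        self,
        min_length: int,
        max_length: int,
        step: int = 1,
        k: int = 1,
        smooth: bool = True,
        smooth_window: int | None = None,
    ) -> _scoring.LengthScanResult:
        """Per-length Top-k over [min_length, max_length], one graph build."""
        return _scoring.scan_lengths(
            self.graph,
            self.path,
            min_length,
            max_length,
            step=step,
            k=k,
            smooth_window=(smooth_window or self.model.window) if smooth else None,
            params=self._params(),
        )

    def occupancy(self) -> dict:
        return _graph.occupancy_stats(self.graph)

    def summary(self) -> str:
        """Plain-text summary of the fitted representation."""
        st = self.occupancy()
        ev = self.embedding.explained
        rows = [
            ("No. observations", f"{self.series_n}"),
            ("Window (w_g)", f"{self.model.window}"),
            ("Windows embedded (N)", f"{len(self.path)}"),
            ("Grid", f"{self.model.n_c} x {self.model.n_c} ({self.model.n_cells} cells)"),
            ("Occupied nodes |V|", f"{st['node_count']}"),
            ("Distinct edges", f"{st['edge_count']}"),
            ("Total edge weight", f"{st['total_weight']}"),
            ("Self-loop weight frac.", f"{st['self_loop_fraction']:.3f}"),
            ("Explained variance", f"{ev[0]:.3f}, {ev[1]:.3f}"),
        ]
        width = max(len(k) for k, _ in rows) + 2
        line = "=" * 46
        body = "\n".join(f"{k + ':':<{width}}{v}" for k, v in rows)
        return f"{'GraphTS Results':^46}\n{line}\n{body}\n{line}"

    @property
    def series_n(self) -> int:
        return self.model.series.n

    # -- debug plots ---------------------------------------------------------

    def plot_embedding(self, ax=None):
        """Scatter of the 2D embedding colored by time order."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.embedding.points
        ax.scatter(pts[:, 0], pts[:, 1], c=np.arange(len(pts)), s=4, cmap="viridis")
        ax.set_xlabel("PC 1")
        ax.set_ylabel("PC 2")
        ax.set_title(f"2D embedding ({self.model.series.name})")
        return ax

    def plot_scores(self, length: int | None = None, ax=None):
        """Smoothed score curve; minima mark candidate anomalies."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.score_profile(length)
        ax.plot(prof.scores, lw=0.8)
        ax.set_xlabel("subsequence start")
        ax.set_ylabel("mean edge weight")
        ax.set_title(f"score profile (l={prof.length})")
        return ax
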