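"""Path-based subsequence scoring, smoothing, Top-K ranking and length scans.

A length-``l`` subsequence starting at ``i`` traverses the ``l`` edges
``(v^i, v^{i+1}) ... (v^{i+l-1}, v^{i+l})`` of the node path; its score is
the mean of those edge weights. Frequent (normal) trajectories ride on heavy
edges and score high; rare (anomalous) trajectories score low. A centered
moving average then flattens the near-duplicate scores of trivially
overlapping windows, and Top-K selection greedily takes score minima while
masking an exclusion zone of ``l`` on both sides so overlapping detections
are never reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import NodePath, TSGraph, edge_weight_sequence
from .io import AnomalyReport, ReportEntry


@dataclass(frozen=True)
class ScoreProfile:
    """Score per subsequence start; index i covers path nodes v^i .. v^{i+l}."""

    scores: np.ndarray
    length: int
    smoothed: bool = False

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass
class LengthScanResult:
    """Per-length Top-k reports plus a cross-length merged ranking."""

    per_length: dict[int, AnomalyReport] = field(default_factory=dict)
    merged: AnomalyReport = field(default_factory=AnomalyReport)


def subsequence_score(graph: TSGraph, path: NodePath, i: int, length: int) -> float:
    """Mean edge weight along the path segment of ``length`` edges from node i.

    This is the direct one-edge-at-a-time evaluation; use
    :func:`score_profile` for all starts at once.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    n = len(path)
    if not 0 <= i <= n - length - 1:
        raise ValueError(f"start {i} out of range [0, {n - length - 1}] for length {length}")
    ids = path.ids
    total = 0
    for k in range(i, i + length):
        total += graph.weight(int(ids[k]), int(ids[k + 1]))
    return total / length


def score_profile(graph: TSGraph, path: NodePath, length: int) -> ScoreProfile:
    """Scores for every valid start, via a cumulative sum over transition weights.

    The profile has ``len(path) - length`` entries (each needs ``length + 1``
    path nodes), computed in O(N).
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    n = len(path)
    if n < length + 1:
        raise ValueError(f"length {length} too large for path of {n} nodes")
    w = edge_weight_sequence(graph, path)
    cs = np.concatenate(([0.0], np.cumsum(w)))
    scores = (cs[length:] - cs[: n - length]) / length
    return ScoreProfile(scores, length=length, smoothed=False)


def smooth_scores(profile: ScoreProfile, window: int) -> ScoreProfile:
    """Centered moving average with window ``window``.

    At the boundaries the window shrinks to the available indices (no padding
    values are invented). Length is unchanged.
    """
    if window < 1:
        raise ValueError(f"smoothing window must be >= 1, got {window}")
    s = profile.scores
    m = s.size
    left = (window - 1) // 2
    right = window // 2
    cs = np.concatenate(([0.0], np.cumsum(s)))
    idx = np.arange(m)
    lo = np.clip(idx - left, 0, m)
    hi = np.clip(idx + right + 1, 0, m)
    out = (cs[hi] - cs[lo]) / (hi - lo)
    return ScoreProfile(out, length=profile.length, smoothed=True)


def detect_topk(
    profile: ScoreProfile,
    k: int | None = None,
    params: dict | None = None,
) -> AnomalyReport:
    """Greedy Top-K selection of score minima with exclusion zones.

    Repeatedly take the global minimum, emit it, and mask every index within
    ``length`` on either side, until ``k`` detections are found or the
    profile is exhausted. Ties break toward the smaller start index. With
    ``k=None`` the full ranked (post-exclusion) list is returned.
    """
    if k is not None and k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ell = profile.length
    scores = profile.scores.copy()
    m = scores.size
    alive = np.ones(m, dtype=bool)
    entries: list[ReportEntry] = []
    limit = k if k is not None else m
    while len(entries) < limit and alive.any():
        masked = np.where(alive, scores, np.inf)
        i = int(np.argmin(masked))  # argmin returns the first (smallest) index on ties
        entries.append(ReportEntry(len(entries) + 1, i, ell, float(scores[i])))
        alive[max(0, i - ell) : i + ell + 1] = False
    truncated = k is not None and len(entries) < k
    return AnomalyReport(entries=entries, params=dict(params or {}), truncated=truncated)


def scan_lengths(
    graph: TSGraph,
    path: NodePath,
    min_length: int,
    max_length: int,
    step: int = 1,
    k: int = 1,
    smooth_window: int | None = None,
    params: dict | None = None,
) -> LengthScanResult:
    """Top-k detection at every length in ``[min_length, max_length]``.

    All lengths reuse the SAME graph and node path — no re-embedding. The
    merged list pools every per-length detection, sorts by score ascending
    (raw per-edge means are comparable across lengths), and greedily keeps
    non-overlapping intervals.
    """
    if not 1 <= min_length <= max_length:
        raise ValueError(f"need 1 <= min_length <= max_length, got [{min_length}, {max_length}]")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if len(path) < max_length + 1:
        raise ValueError(f"max_length {max_length} too large for path of {len(path)} nodes")

    result = LengthScanResult()
    pool: list[ReportEntry] = []
    for ell in range(min_length, max_length + 1, step):
        prof = score_profile(graph, path, ell)
        if smooth_window is not None:
            prof = smooth_scores(prof, smooth_window)
        rep = detect_topk(prof, k=k, params={**(params or {}), "length": ell})
        result.per_length[ell] = rep
        pool.extend(rep.entries)

    pool.sort(key=lambda e: (e.score, e.start, e.length))
    kept: list[ReportEntry] = []
    for e in pool:
        s, t = e.start, e.start + e.length
        if all(t <= o.start or o.start + o.length <= s for o in kept):
            kept.append(ReportEntry(len(kept) + 1, e.start, e.length, e.score))
    result.merged = AnomalyReport(entries=kept, params=dict(params or {}))
    return result


def evaluate_topk(report: AnomalyReport, truth, k: int | None = None) -> float:
    """Top-K accuracy of a report against ground-truth anomaly intervals.

    A detection is a hit if ``[start, start + length)`` intersects a true
    interval not already claimed (one-to-one matching, greedy by rank).
    ``truth`` is a GroundTruth or an iterable of (start, end) half-open pairs.
    """
    intervals = list(getattr(truth, "intervals", truth))
    if k is None:
        k = len(report.entries)
    if k == 0:
        return 0.0
    claimed = [False] * len(intervals)
    hits = 0
    for e in report.entries[:k]:
        s, t = e.start, e.start + e.length
        for j, (a, b) in enumerate(intervals):
            if not claimed[j] and s < b and a < t:
                claimed[j] = True
                hits += 1
                break
    return hits / k
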