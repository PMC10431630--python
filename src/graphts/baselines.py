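"""Brute-force nearest-neighbor discord baseline.

The classic discord definition ranks each subsequence by the z-normalized
Euclidean distance to its nearest non-overlapping neighbor: the largest
distance marks the anomaly. It is bundled here as an exact (O(N^2))
reference for contrast experiments — in particular the recurrent-anomaly
("twin freak") failure mode, where each instance of a repeated abnormal
waveform finds a close twin and is never ranked as a discord.
"""

from __future__ import annotations

import numpy as np

from .embedding import extract_subsequences, znormalize
from .io import AnomalyReport, ReportEntry, TimeSeries


def nn_discord_distances(
    series: TimeSeries, length: int, exclusion: int | None = None
) -> np.ndarray:
    """Z-normalized Euclidean distance of each window to its nearest
    non-trivial (|i - j| > exclusion) neighbor. Exact, block-wise O(N^2)."""
    if exclusion is None:
        exclusion = length
    Z = znormalize(extract_subsequences(series, length)).data
    N = Z.shape[0]
    sq = np.einsum("ij,ij->i", Z, Z)
    nn = np.full(N, np.inf)
    block = 512
    for lo in range(0, N, block):
        hi = min(lo + block, N)
        d2 = sq[lo:hi, None] + sq[None, :] - 2.0 * (Z[lo:hi] @ Z.T)
        idx = np.arange(lo, hi)
        for r, i in enumerate(idx):
            a = max(0, i - exclusion)
            b = min(N, i + exclusion + 1)
            d2[r, a:b] = np.inf
        nn[lo:hi] = np.sqrt(np.maximum(d2.min(axis=1), 0.0))
    return nn


def nn_discord_topk(
    series: TimeSeries, length: int, k: int, exclusion: int | None = None
) -> AnomalyReport:
    """Top-k discords (largest NN distance first) with exclusion zones.

    Note the returned report ranks by *descending* distance — rank 1 is the
    strongest discord — unlike path-score reports where rank 1 is the lowest
    score.
    """
    if exclusion is None:
        exclusion = length
    nn = nn_discord_distances(series, length, exclusion=exclusion)
    scores = nn.copy()
    alive = np.isfinite(scores)
    entries = []
    while len(entries) < k and alive.any():
        masked = np.where(alive, scores, -np.inf)
        i = int(np.argmax(masked))
        entries.append(ReportEntry(len(entries) + 1, i, length, float(scores[i])))
        alive[max(0, i - exclusion) : i + exclusion + 1] = False
    return AnomalyReport(
        entries=entries,
        params={"method": "nn_discord", "length": length, "k": k},
        truncated=len(entries) < k,
    )
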