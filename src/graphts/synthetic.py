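"""Synthetic quasi-periodic signals with planted subsequence anomalies.

The generator emulates long biosignal-like recordings (ECG beats, tilt-table
arterial blood pressure): a repeating template cycle with beat-to-beat
variability — cycle-length jitter and a smoothly varying amplitude envelope —
plus i.i.d. Gaussian noise. Anomalies are spliced waveform distortions with
ground-truth intervals; when ``recurrent_shape_reuse`` is set, every planted
anomaly reuses one identical abnormal waveform (the recurrent, "twin"
anomaly case that defeats nearest-neighbor discord definitions).

Everything is a pure function of the spec, including its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import TimeSeries

TEMPLATES = ("sine", "pqrst_like", "square_smooth")
ANOMALY_SHAPES = ("damped_beat", "premature_beat", "widened_peak", "inverted_peak")

# pqrst_like: fixed piecewise Gaussian-bump cycle (phase fraction, amplitude,
# width as phase fraction). A schematic beat, not a physiological simulator.
PQRST_BUMPS = (
    (0.10, 0.16, 0.035),   # P
    (0.26, -0.14, 0.012),  # Q
    (0.30, 1.00, 0.014),   # R
    (0.34, -0.24, 0.013),  # S
    (0.52, 0.32, 0.055),   # T
)

# Anomalies fit a whole number of beats into their interval, so the waveform
# starts and ends at phase zero and hands off continuously to the surrounding
# rhythm — like ectopic beats displacing sinus beats, with no splice jump.
_WIDENED_TEMPO = 1.6


def _template_phase(name: str, phase: np.ndarray) -> np.ndarray:
    """Evaluate one normal cycle as a function of phase in [0, 1)."""
    if name == "sine":
        return np.sin(2 * np.pi * phase)
    if name == "square_smooth":
        return np.tanh(3.0 * np.sin(2 * np.pi * phase))
    if name == "pqrst_like":
        p = np.mod(phase, 1.0)
        out = np.zeros_like(p)
        for center, amp, width in PQRST_BUMPS:
            for shift in (-1.0, 0.0, 1.0):  # wrap bumps across cycle edges
                out += amp * np.exp(-0.5 * ((p - center + shift) / width) ** 2)
        return out
    raise ValueError(f"unknown template {name!r} (choose from {TEMPLATES})")


def template_cycle(name: str, period: int) -> np.ndarray:
    """One cycle of the normal template sampled at ``period`` points."""
    return _template_phase(name, np.arange(period) / period)


def anomaly_waveform(
    shape: str, length: int, period: int, template: str, amplitude: float = 1.0
) -> np.ndarray:
    """The distorted waveform spliced over an anomaly interval.

    ``premature_beat`` (default): a run of extra, faster beats squeezed into
    the middle of the interval by a smooth time warp — the outer quarters run
    at exactly normal tempo, so the distortion is confined mid-interval and
    the edges blend into the rhythm (a tachycardia-salvo-like event).
    ``damped_beat``: beats at roughly normal rate whose amplitude collapses
    mid-interval (low-voltage / fusion-beat morphology). ``widened_peak``:
    fewer, slower beats. ``inverted_peak``: negated beats at roughly normal
    rate. All fit a whole number of beats into ``length`` so the waveform is
    phase-continuous with its surroundings.
    """
    t = np.arange(length, dtype=np.float64)
    if shape == "premature_beat":
        m = length // period + 1  # one more beat than the interval would hold
        extra = m - length / period
        u = np.clip((t - length / 4.0) / (length / 2.0), 0.0, 1.0)
        ramp = u * u * (3.0 - 2.0 * u)  # smoothstep: all extra phase mid-interval
        wave = _template_phase(template, t / period + extra * ramp)
    elif shape == "damped_beat":
        m = max(1, round(length / period))
        notch = 1.0 - 0.7 * np.exp(-0.5 * ((t - length / 2.0) / (length / 6.0)) ** 2)
        wave = _template_phase(template, t * m / length) * notch
    elif shape == "widened_peak":
        m = max(1, round(length / (_WIDENED_TEMPO * period)))
        wave = _template_phase(template, t * m / length)
    elif shape == "inverted_peak":
        m = max(1, round(length / period))
        wave = -_template_phase(template, t * m / length)
    else:
        raise ValueError(f"unknown anomaly shape {shape!r} (choose from {ANOMALY_SHAPES})")
    return amplitude * wave


@dataclass(frozen=True)
class Anomaly:
    """One planted anomaly: spliced at the start of cycle ``position``."""

    position: int
    length: int
    shape: str = "premature_beat"
    amplitude: float = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic recording.

    period
        Nominal cycle length l_np in samples (>= 20).
    period_jitter, amp_jitter
        Beat-to-beat variability: relative sd of each cycle's length, and of
        the smoothly interpolated per-cycle amplitude envelope.
    recurrent_shape_reuse
        Force every anomaly to reuse the first anomaly's shape and amplitude.
    """

    period: int = 100
    n_cycles: int = 50
    normal_template: str = "sine"
    anomalies: tuple[Anomaly, ...] = ()
    recurrent_shape_reuse: bool = False
    noise_sd: float = 0.02
    period_jitter: float = 0.03
    amp_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.period < 20:
            raise ValueError(f"period must be >= 20, got {self.period}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "anomalies", tuple(self.anomalies))


@dataclass(frozen=True)
class GroundTruth:
    """Half-open anomaly intervals, sorted and non-overlapping, with shape labels."""

    intervals: tuple[tuple[int, int], ...]
    labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.intervals)


def generate(spec: SyntheticSpec) -> tuple[TimeSeries, GroundTruth]:
    """Render a spec into a series and its ground truth.

    Each anomaly replaces ``ceil(length / period)`` whole cycles on the
    timeline with its waveform, so the rhythm resumes at phase zero right
    after the splice — like an ectopic beat displacing sinus beats, with no
    artificial phase glitch at the boundaries. Anomaly intervals must end up
    pairwise separated by at least one nominal period; violations raise
    rather than silently overlapping.
    """
    rng = np.random.default_rng(spec.seed)

    # per-cycle beat-to-beat variability, drawn for all nominal cycles up
    # front so the realization is a pure function of the seed
    factors = 1.0 + rng.normal(0.0, spec.period_jitter, size=spec.n_cycles)
    cyc_len = np.maximum(4, np.rint(spec.period * factors)).astype(np.int64)
    amp = 1.0 + rng.normal(0.0, spec.amp_jitter, size=spec.n_cycles)

    anomalies = list(spec.anomalies)
    if spec.recurrent_shape_reuse and anomalies:
        first = anomalies[0]
        anomalies = [
            replace(a, shape=first.shape, amplitude=first.amplitude) for a in anomalies
        ]
    anom_at: dict[int, Anomaly] = {}
    for a in anomalies:
        if not 0 <= a.position < spec.n_cycles:
            raise ValueError(f"anomaly position {a.position} outside 0..{spec.n_cycles - 1}")
        if a.position in anom_at:
            raise ValueError(f"two anomalies at cycle {a.position}")
        anom_at[a.position] = a

    segments: list[np.ndarray] = []
    anom_spans: list[tuple[int, int, Anomaly]] = []  # sample interval + anomaly
    norm_centers: list[float] = []
    norm_amp: list[float] = []
    pos = 0
    c = 0
    while c < spec.n_cycles:
        a = anom_at.get(c)
        if a is not None:
            span = math.ceil(a.length / spec.period)
            if c + span > spec.n_cycles:
                raise ValueError(f"anomaly at cycle {c} runs past the series end")
            if any(p in anom_at for p in range(c + 1, c + span)):
                raise ValueError(f"anomalies overlap around cycle {c}")
            wave = anomaly_waveform(
                a.shape, a.length, spec.period, spec.normal_template, a.amplitude
            )
            segments.append(wave)
            anom_spans.append((pos, pos + a.length, a))
            pos += a.length
            c += span
        else:
            L = int(cyc_len[c])
            segments.append(_template_phase(spec.normal_template, np.arange(L) / L))
            norm_centers.append(pos + L / 2.0)
            norm_amp.append(float(amp[c]))
            pos += L
            c += 1

    series = np.concatenate(segments)
    n = series.size
    if norm_centers:
        # the slow multiplicative envelope (respiration/contact drift) acts on
        # the whole recording, spliced beats included; planted twins therefore
        # share one waveform up to local scale, which z-normalization removes
        series *= np.interp(np.arange(n), norm_centers, norm_amp)

    intervals = [(s, e) for s, e, _ in anom_spans]
    labels = [a.shape for _, _, a in anom_spans]
    for (a0, b0), (a1, b1) in zip(intervals, intervals[1:]):
        if a1 - b0 < spec.period:
            raise ValueError(
                f"anomaly intervals [{a0},{b0}) and [{a1},{b1}) closer than one period"
            )

    series = series + rng.normal(0.0, spec.noise_sd, size=n)
    ts = TimeSeries(series, name=f"synthetic-{spec.normal_template}")
    return ts, GroundTruth(tuple(intervals), tuple(labels))


def planted_spec(
    n_anomalies: int = 1,
    length: int = 110,
    shape: str = "premature_beat",
    recurrent: bool = False,
    seed: int = 0,
    lengths=None,
    amplitude: float = 1.0,
    **overrides,
) -> SyntheticSpec:
    """A spec with ``n_anomalies`` randomly placed, well-separated anomalies.

    ``lengths`` gives per-anomaly lengths (overrides ``length``). Placement
    is rejection-sampled from the seed: positions leave at least two clear
    cycles between anomalies and avoid the first/last cycle.
    """
    base = SyntheticSpec(seed=seed, **overrides)
    lens = list(lengths) if lengths is not None else [length] * n_anomalies
    if len(lens) != n_anomalies:
        raise ValueError("lengths must have n_anomalies entries")
    spans = [math.ceil(l / base.period) for l in lens]
    rng = np.random.default_rng(seed)
    hi = base.n_cycles - max(spans, default=1) - 2
    if hi < 1:
        raise ValueError("series too short for the requested anomalies")
    for _ in range(1000):
        pos = np.sort(rng.integers(1, hi + 1, size=n_anomalies))
        gaps_ok = all(
            pos[i + 1] - pos[i] >= spans[i] + 2 for i in range(n_anomalies - 1)
        )
        if gaps_ok:
            anomalies = tuple(
                Anomaly(int(p), int(l), shape=shape, amplitude=amplitude)
                for p, l in zip(pos, lens)
            )
            return replace(base, anomalies=anomalies, recurrent_shape_reuse=recurrent)
    raise ValueError("could not place anomalies without overlap; reduce count or lengths")


@dataclass(frozen=True)
class PeriodHint:
    """Advisory autocorrelation period estimate (used to suggest w_g = period - 20)."""

    period: int | None
    peak_corr: float
    reliable: bool


def estimate_period_hint(series: TimeSeries, max_lag: int | None = None) -> PeriodHint:
    """Dominant period from the first major autocorrelation peak.

    Scans lags 2..max_lag for the highest *local* maximum of the (biased)
    autocorrelation. A flat series, or one without periodic structure
    (peak correlation < 0.2), is flagged unreliable.
    """
    x = series.values - series.values.mean()
    n = series.n
    if max_lag is None:
        max_lag = n // 3
    if n <= 2 * max_lag:
        raise ValueError(f"need n > 2*max_lag, got n={n}, max_lag={max_lag}")
    if float(np.abs(x).max(initial=0.0)) < 1e-12:
        return PeriodHint(None, 0.0, False)
    f = np.fft.rfft(x, 2 * n)
    ac = np.fft.irfft(f * np.conj(f))[: max_lag + 2]
    ac = ac / ac[0]
    # local maxima over lags [2, max_lag]
    lags = np.arange(2, max_lag + 1)
    vals = ac[2 : max_lag + 1]
    is_peak = (vals >= ac[1 : max_lag]) & (vals >= ac[3 : max_lag + 2])
    if not is_peak.any():
        return PeriodHint(None, float(vals.max()), False)
    cand = lags[is_peak]
    best = cand[np.argmax(vals[is_peak])]
    peak = float(ac[best])
    return PeriodHint(int(best), peak, peak >= 0.2)
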