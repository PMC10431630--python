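# Methods

## Model

`graphts` treats a univariate series as a trajectory through a small set of
waveform states. All length-*w_g* sliding windows are z-normalized and
projected onto their top two principal components; the plane is cut into an
*n_c × n_c* grid; each occupied cell is a state (node) and each
consecutive-window transition increments a directed edge weight, self-loops
included. A length-ℓ subsequence is scored by the mean weight of the ℓ edges
its path traverses; low mean weight marks a rare trajectory. The working
assumptions are:

- the series is dominated by a repeating pattern of roughly stable length
  *l_np*, so normal windows concentrate on a heavily traversed loop;
- anomalies are rarer than normal patterns. Rarity is counted on graph
  edges, not by nearest-neighbor distances, so an abnormal waveform that
  recurs r times still scores about r — far below the per-cycle traffic of
  the normal loop — which is what defeats the "twin freak" failure of
  discord definitions;
- anomaly lengths need not be known: any ℓ can be scored against the one
  fitted graph, because scoring touches only the node path.

What the model does *not* do: score series other than the one it was built
from (no train/apply split), threshold scores into hard labels, or handle
multivariate signals.

## Parameters

| parameter | default | meaning and rationale |
| --- | --- | --- |
| `window` (*w_g*) | *l_np* − 20 | embedding window, samples. Slightly below the normal-pattern length so every window holds most of one pattern; derived from an autocorrelation period estimate when not given. |
| `n_cells` (*n_cell*) | 100 | grid cells (perfect square). Detection is stable from 100 up; larger grids refine states without growing past the cell bound. Node count ≤ *n_cell* regardless of series length. |
| `length` (ℓ) | *w_g* | scored subsequence length, samples. Accuracy is robust to mismatch with the true anomaly length. |
| smoothing window | *w_g* | centered moving average over the score curve; aligns score minima with anomaly centers and equalizes trivially overlapping windows. Shrinks at the profile boundaries rather than inventing padding. |
| `k` | none | number of detections. Optional: without it the full ranked, exclusion-filtered list is returned. |

## Numerical choices

- **Z-normalization** uses the population (divisor-*N*) standard deviation.
  Windows with spread below 1e-12 become zero vectors (recorded as
  degenerate) so constant segments flow through instead of raising.
- **PCA** is an exact full decomposition — no randomized solver — and the
  sign of each component is fixed by making its largest-magnitude loading
  positive. The projection is sign/rotation ambiguous in principle; any
  fixed convention works, but it must be deterministic because the grid
  binning downstream depends on orientation. Centering uses column means of
  the normalized window matrix.
- **Grid binning** clamps points on the right/top boundary into the last
  cell, and a degenerate axis (zero spread) maps everything to row/col 0.
  Node ids are row-major over the full grid for stable naming across runs.
- **Scoring convention**: the score of start *i* averages the ℓ edges over
  nodes v^i … v^{i+ℓ}, so the profile has `len(path) − ℓ` entries. The
  whole profile is a cumulative sum over per-transition weights, O(N), and
  is tested to 1e-12 against per-index recomputation.
- **Ties** in Top-K selection break toward the smaller start index; the
  pipeline contains no randomness, so identical inputs give bit-identical
  reports.
- **Cross-length merging** in a scan pools per-length detections, sorts by
  raw score (per-edge means are comparable across lengths) and keeps
  non-overlapping intervals greedily. This is a convention of this package;
  sensible alternatives exist.

## Synthetic data

The generator emulates long quasi-periodic biosignal recordings. One normal
template cycle (`sine`, schematic `pqrst_like`, or `square_smooth`) repeats
`n_cycles` times with beat-to-beat variability: each cycle's length is
jittered (relative sd `period_jitter`, default 3% — heart-rate-variability
scale) and a smooth amplitude envelope interpolated between cycle centers
(relative sd `amp_jitter`, default 5%) multiplies the whole recording, like
respiration or contact drift. I.i.d. Gaussian noise (`noise_sd`, default
0.02 of unit amplitude) is added last.

Anomalies replace a whole number of cycles on the timeline and fit an
integer number of distorted beats into their interval, so they are
phase-continuous with the surrounding rhythm — an ectopic beat displaces
sinus beats; it does not leave splice glitches. Shapes: `premature_beat`
(default — extra faster beats squeezed mid-interval by a smoothstep time
warp; the outer quarters run at exactly normal tempo), `widened_peak`
(fewer, slower beats), `inverted_peak` (negated beats), and `damped_beat`
(mid-interval amplitude collapse; note its embedding displacement is
deliberately subtle and it is the hardest shape for the detector). With
`recurrent_shape_reuse` every instance reuses one identical waveform — the
recurrent-anomaly case. Generation is a pure function of the spec's seed.

What the generator does **not** emulate: real ECG morphology and its
artifacts (electrode noise bursts, baseline wander, missing data),
heavy-tailed rhythm disturbances inside the "normal" background, or
multichannel structure. Passing tests therefore demonstrate the mechanism —
shape-based embedding, bounded graph, path scoring, twin-freak robustness —
under controlled variability, not clinical performance.

## Evaluation protocol

Top-K accuracy sets K to the number of planted anomalies; a detection is a
hit when its interval [start, start + ℓ) intersects a not-yet-claimed true
interval (greedy one-to-one matching by rank). The bundled contrast
baseline is an exact brute-force nearest-neighbor discord: z-normalized
Euclidean distance to the nearest neighbor outside an exclusion zone of ℓ,
largest distances reported first. Experiments in the tests and the
acceptance script use 20 seeded replicates of the standard conditions
(period 100, 50 cycles, noise sd 0.02, *w_g* = 80, *n_cell* = 100,
ℓ = 110); these sizes keep a full run in tens of seconds while leaving the
per-seed problem (~4 600 samples, ~4 500 windows) large enough for stable
statistics.

## Known limitations

- The embedding keeps only two principal components; signals whose
  discriminating structure lives in higher components (for example
  harmonic-only morphology changes at unchanged fundamental) can embed onto
  the normal trajectory and go undetected — `damped_beat` borders on this.
- A single fixed grid means detection sensitivity depends on where the
  normal loop sits relative to cell boundaries; *n_cell* ≥ 100 makes this
  negligible in practice but pathological alignments are possible.
- Scores are counts, so very short series (few cycles) leave little
  contrast between rare and normal edges.
- The period estimate used for the default *w_g* is a single global
  autocorrelation peak; series with strong sub-harmonics may need an
  explicit `window`.
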