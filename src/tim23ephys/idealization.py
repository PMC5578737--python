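"""Trace idealization: noisy current recording -> piecewise-constant levels.

The idealizer is a penalized least-squares change-point fit (PELT dynamic
program, exact on its candidate grid) followed by two merge passes:

1. **duration filter** — segments shorter than ``min_dwell_s`` are merged into
   the neighboring segment with the closer level (shortest first);
2. **amplitude filter** — adjacent segments whose levels differ by less than
   ``min_step_pA`` are merged.

The duration filter runs before the amplitude filter; the output depends on
this order, so it is fixed here.  Segment levels are the means of the raw
samples they cover, re-estimated after every merge, so the residual mean per
segment is ~0 by construction.

Penalty default is ``3 * sigma^2 * ln(n)`` — a BIC-like choice — with the
noise scale ``sigma`` estimated robustly from the median absolute deviation
of successive differences (divided by sqrt(2), scaled to Gaussian sd), so
that genuine gating steps do not inflate it.

For recordings up to 200k samples the change-point search is exact at every
sample; longer recordings use a candidate grid (0.2 ms stride up to 2M
samples, 1 ms beyond) and each detected change point is then refined locally
to single-sample resolution.  The very long recordings in this regime are
multi-minute quiet constant-voltage runs whose dwell times sit far above a
millisecond, so the gridded search costs no measurable accuracy there.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from ._pelt import pelt_changepoints, refine_changepoints
from .errors import MetadataError, Tim23EphysError
from .trace_io import IdealizedTrace, Trace

#: Sample count above which the change-point search uses a coarse candidate
#: grid with local refinement instead of testing every sample.
EXACT_SEARCH_MAX_SAMPLES = 200_000

#: Candidate stride (seconds) for medium recordings (< MEDIUM_MAX_SAMPLES).
MEDIUM_GRID_S = 2e-4
MEDIUM_MAX_SAMPLES = 2_000_000

#: Candidate stride (seconds) for very long recordings, whose dwells are
#: orders of magnitude above a millisecond.
COARSE_GRID_S = 1e-3


@dataclasses.dataclass(frozen=True)
class IdealizeParams:
    """Tuning parameters of the idealizer.

    penalty : per-change-point model-selection penalty (pA^2 units); ``None``
        selects ``3 * sigma_hat^2 * ln(n)`` automatically.
    min_dwell_s : shortest retained dwell (dead time), default 0.5 ms — five
        samples at the default 10 kHz digitization rate.
    min_step_pA : smallest level difference kept after merging, default 1.5 pA.
    grid : candidate stride in samples for the change-point search; ``None``
        selects 1 (exact) up to 200k samples, a 0.2 ms stride up to 2M
        samples and a 1 ms stride beyond.
    """

    penalty: Optional[float] = None
    min_dwell_s: float = 5e-4
    min_step_pA: float = 1.5
    grid: Optional[int] = None

    def __post_init__(self):
        if self.penalty is not None and self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if self.min_dwell_s <= 0 or self.min_step_pA <= 0:
            raise ValueError("min_dwell_s and min_step_pA must be positive")


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise sd estimate from the MAD of successive differences.

    Insensitive to the (sparse) true level steps; exact for iid Gaussian
    noise: sd = 1.4826 * MAD(diff x) / sqrt(2).
    """
    d = np.diff(np.asarray(x, dtype=float))
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def default_penalty(x: np.ndarray) -> float:
    """BIC-like penalty 3 * sigma_hat^2 * ln(n), floored so that noiseless
    (sigma ~ 0) traces still pay a positive price per change point."""
    n = len(x)
    sigma2 = robust_noise_sd(x) ** 2
    floor = 1e-8 * (1.0 + float(np.mean(np.square(x))))
    return 3.0 * max(sigma2, floor) * np.log(n)


def _merge_short_segments(bounds: np.ndarray, cs: np.ndarray, min_len: int) -> np.ndarray:
    """Merge segments shorter than min_len samples into the neighbor with the
    closer mean level, shortest segment first."""
    bounds = list(bounds)
    while len(bounds) > 2:
        lengths = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
        order = int(np.argmin(lengths))
        if lengths[order] >= min_len:
            break
        i = order
        if i == 0:
            del bounds[1]
            continue
        if i == len(lengths) - 1:
            del bounds[-2]
            continue
        mean = lambda a, b: (cs[b] - cs[a]) / (b - a)  # noqa: E731
        seg = mean(bounds[i], bounds[i + 1])
        left = mean(bounds[i - 1], bounds[i])
        right = mean(bounds[i + 1], bounds[i + 2])
        if abs(seg - left) <= abs(seg - right):
            del bounds[i]  # absorb into left neighbor
        else:
            del bounds[i + 1]  # absorb into right neighbor
    return np.asarray(bounds, dtype=np.int64)


def _merge_small_steps(bounds: np.ndarray, cs: np.ndarray, min_step: float) -> np.ndarray:
    """Merge adjacent segments whose mean levels differ by < min_step pA,
    smallest difference first."""
    bounds = list(bounds)
    while len(bounds) > 2:
        means = [
            (cs[bounds[i + 1]] - cs[bounds[i]]) / (bounds[i + 1] - bounds[i])
            for i in range(len(bounds) - 1)
        ]
        diffs = np.abs(np.diff(means))
        j = int(np.argmin(diffs))
        if diffs[j] >= min_step:
            break
        del bounds[j + 1]
    return np.asarray(bounds, dtype=np.int64)


def idealize(trace: Trace, params: IdealizeParams = IdealizeParams()) -> IdealizedTrace:
    """Fit a piecewise-constant idealization to a trace.

    Raises
    ------
    Tim23EphysError
        if the trace is shorter than 10 samples or than twice the minimum
        dwell.
    """
    x = trace.samples
    n = len(x)
    fs = trace.meta.sample_rate_Hz
    min_len = max(1, int(round(params.min_dwell_s * fs)))
    if n < 10:
        raise Tim23EphysError("trace too short to idealize (< 10 samples)")
    if n < 2 * min_len:
        raise Tim23EphysError(
            f"trace ({n} samples) shorter than twice the minimum dwell ({min_len} samples)"
        )

    penalty = params.penalty if params.penalty is not None else default_penalty(x)
    if params.grid is not None:
        grid = max(1, int(params.grid))
    elif n <= EXACT_SEARCH_MAX_SAMPLES:
        grid = 1
    elif n <= MEDIUM_MAX_SAMPLES:
        grid = max(1, int(round(MEDIUM_GRID_S * fs)))
    else:
        grid = max(1, int(round(COARSE_GRID_S * fs)))

    cps = pelt_changepoints(x, penalty, grid=grid)
    if grid > 1:
        cps = refine_changepoints(x, cps, radius=grid)

    cs = np.concatenate(([0.0], np.cumsum(x, dtype=np.float64)))
    bounds = np.concatenate(([0], cps, [n]))
    bounds = _merge_short_segments(bounds, cs, min_len)
    bounds = _merge_small_steps(bounds, cs, params.min_step_pA)

    starts = bounds[:-1]
    ends = bounds[1:]
    levels = (cs[ends] - cs[starts]) / (ends - starts)
    seg = pd.DataFrame(
        {
            "start_s": starts / fs,
            "duration_s": (ends - starts) / fs,
            "level_pA": levels,
        }
    )
    return IdealizedTrace(segments=seg, meta=trace.meta)


def residual_sd(trace: Trace, ideal: IdealizedTrace) -> float:
    """Standard deviation of (trace - idealized reconstruction).

    Raises :class:`MetadataError` if the idealization belongs to a different
    recording.
    """
    if ideal.meta != trace.meta:
        raise MetadataError("idealized trace metadata does not match trace")
    recon = ideal.reconstruct(len(trace.samples))
    return float(np.std(trace.samples - recon))
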