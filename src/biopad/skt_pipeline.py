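"""Skin-temperature processing.

Smoothing uses the weighted three-point moving average
y(n) = 0.8·x(n) + 0.1·x(n−1) + 0.1·x(n−2); unpleasant stimulation is
quantified by the temperature change across the stimulation window
(end-of-stimulus mean minus start-of-stimulus mean over 5 s edges) plus the
post-stimulus recovery slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SMOOTH_WEIGHTS = (0.8, 0.1, 0.1)
EDGE_MEAN_S = 5.0


@dataclass
class SKTResponse:
    baseline_mean_c: float
    stim_delta_c: float
    recovery_slope_c_per_s: float


def smooth_skt(x) -> np.ndarray:
    """Three-point weighted moving average; first two samples pass through."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    w0, w1, w2 = SMOOTH_WEIGHTS
    y = x.copy()
    y[2:] = w0 * x[2:] + w1 * x[1:-1] + w2 * x[:-2]
    return y


def stimulus_delta(x, fs: float, baseline_win, stim_win,
                   recovery_win) -> SKTResponse:
    """Baseline mean, stimulus-locked delta, and recovery slope.

    ``*_win`` are (start_s, end_s) pairs, ordered and non-overlapping.  The
    delta is the mean of the last 5 s of the stimulation window minus the
    mean of its first 5 s — robust to sample noise, unlike a point
    difference.
    """
    x = np.asarray(x, dtype=float)
    duration = len(x) / fs
    wins = [tuple(map(float, w)) for w in (baseline_win, stim_win, recovery_win)]
    for (t0, t1) in wins:
        if not (0 <= t0 < t1 <= duration + 1e-9):
            raise ValueError(f"window ({t0}, {t1}) outside record of {duration} s")
    for (_, a_end), (b_start, _) in zip(wins, wins[1:]):
        if b_start < a_end:
            raise ValueError("windows must be ordered and non-overlapping")

    def mean_over(t0, t1):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        return float(np.mean(x[i0:i1]))

    b0, b1 = wins[0]
    s0, s1 = wins[1]
    r0, r1 = wins[2]
    edge = min(EDGE_MEAN_S, (s1 - s0) / 2.0)
    baseline = mean_over(b0, b1)
    delta = mean_over(s1 - edge, s1) - mean_over(s0, s0 + edge)
    i0, i1 = int(round(r0 * fs)), int(round(r1 * fs))
    t = np.arange(i0, i1) / fs
    slope = float(np.polyfit(t, x[i0:i1], 1)[0]) if i1 - i0 >= 2 else 0.0
    return SKTResponse(baseline_mean_c=baseline, stim_delta_c=delta,
                       recovery_slope_c_per_s=slope)
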