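"""EEG analysis: Welch PSD, alpha-band (8–13 Hz) dominance for the
eyes-open/eyes-closed comparison, cross-device PSD correlation, and
blink-transient detection.

The alpha-dominance statistic compares relative (8, 13] Hz band power
between an eyes-closed and an eyes-open epoch; a ratio well above 1 is the
classic signature of alpha blocking on eye opening.  Epochs of 15 s of
clean signal are the intended input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

ALPHA_BAND = (8.0, 13.0)
DEFAULT_EPOCH_S = 15.0


@dataclass
class PSDResult:
    freqs: np.ndarray        # Hz
    power: np.ndarray        # μV²/Hz
    segment_len_s: float
    overlap_frac: float


@dataclass
class BandPower:
    band: tuple
    absolute: float          # μV²
    relative: float          # fraction of total power


def welch_psd(x, fs: float, segment_len_s: float = 2.0,
              overlap_frac: float = 0.5) -> PSDResult:
    """Welch estimate with Hann windows (default 2 s segments, 50% overlap)."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_len_s * fs))
    if len(x) < nperseg:
        raise ValueError(
            f"input of {len(x)} samples shorter than one {nperseg}-sample segment"
        )
    freqs, power = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap_frac),
    )
    return PSDResult(freqs=freqs, power=power,
                     segment_len_s=segment_len_s, overlap_frac=overlap_frac)


def band_power(psd: PSDResult, lo: float, hi: float) -> BandPower:
    """Trapezoidal band integral over (lo, hi] and its share of total power."""
    if not 0 <= lo < hi:
        raise ValueError(f"invalid band ({lo}, {hi}]")
    if hi > psd.freqs[-1] + 1e-9:
        raise ValueError(f"band edge {hi} Hz beyond PSD grid")
    absolute = _trapz_band(psd.freqs, psd.power, lo, hi)
    total = _trapz_band(psd.freqs, psd.power, 0.0, psd.freqs[-1])
    relative = absolute / total if total > 0 else 0.0
    return BandPower(band=(lo, hi), absolute=absolute, relative=relative)


def _trapz_band(freqs, power, lo, hi):
    # integrate with interpolated band edges so narrow bands are exact
    grid = np.unique(np.concatenate([freqs, [lo, hi]]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    if len(grid) < 2:
        return 0.0
    p = np.interp(grid, freqs, power)
    return float(np.trapezoid(p, grid))


def alpha_dominance(eeg_closed, eeg_open, fs: float) -> float:
    """Ratio of relative alpha power, eyes-closed over eyes-open."""
    ratios = []
    for x in (eeg_closed, eeg_open):
        x = np.asarray(x, dtype=float)
        if np.allclose(x, 0) or np.var(x) == 0:
            raise ValueError("degenerate (zero-power) EEG segment")
        psd = welch_psd(x, fs)
        bp = band_power(psd, *ALPHA_BAND)
        ratios.append(bp.relative)
    if ratios[1] == 0:
        raise ValueError("eyes-open segment has zero alpha-band power")
    return ratios[0] / ratios[1]


def dominant_frequency(psd: PSDResult, lo: float = 1.0,
                       hi: float | None = None) -> float:
    """Frequency of the largest PSD value within (lo, hi]."""
    hi = hi if hi is not None else psd.freqs[-1]
    mask = (psd.freqs > lo) & (psd.freqs <= hi)
    return float(psd.freqs[mask][np.argmax(psd.power[mask])])


def psd_pearson(psd_a: PSDResult, psd_b: PSDResult) -> float:
    """Pearson correlation between two PSDs on the same grid."""
    if len(psd_a.freqs) != len(psd_b.freqs) or not np.allclose(
            psd_a.freqs, psd_b.freqs):
        raise ValueError("PSDs are on different frequency grids")
    if np.var(psd_a.power) == 0 or np.var(psd_b.power) == 0:
        raise ValueError("correlation undefined for constant PSD")
    r, _ = stats.pearsonr(psd_a.power, psd_b.power)
    return float(r)


def detect_blinks(x, fs: float, lowpass_hz: float = 5.0,
                  k: float = 6.0, refractory_s: float = 0.5) -> np.ndarray:
    """Blink-transient times from frontal EEG.

    Low-passes below ``lowpass_hz``, thresholds at median + k·MAD of the
    absolute deviation, and enforces a refractory spacing.  This detector is
    fixture-validation plumbing, not a published algorithm.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0 or np.allclose(x, 0):
        return np.zeros(0)
    b, a = signal.butter(4, lowpass_hz, btype="low", fs=fs)
    lf = signal.filtfilt(b, a, x)
    dev = np.abs(lf - np.median(lf))
    mad = np.median(dev)
    if mad == 0:
        return np.zeros(0)
    above = dev > k * mad
    times = []
    refractory = int(refractory_s * fs)
    i = 0
    n = len(x)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            peak = i + int(np.argmax(dev[i:j]))
            times.append(peak / fs)
            i = max(j, peak + refractory)
        else:
            i += 1
    return np.asarray(times)


def zscore(x) -> np.ndarray:
    """Per-segment normalization used before cross-device comparison."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant segment")
    return (x - x.mean()) / sd
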