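"""Electrodermal-activity analysis.

Two instruments:

* a band-split SNR statistic — the (0, 5] Hz band (where all useful EDA
  content lives) over the (5, fs/2] Hz remainder, in dB, computed on 10 s
  segments with 50% overlap;
* the skin-conductance-response (SCR) extraction chain — downsample to
  20 Hz, differentiate, convolve with a 20-point Bartlett window — followed
  by threshold event detection with stimulus matching.  A stimulus-locked
  SCR typically peaks 1–5 s after the triggering event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

SCR_FS = 20.0            # Hz after downsampling
BARTLETT_POINTS = 20     # smoothing window (1 s of support at 20 Hz)
SNR_BAND_EDGE_HZ = 5.0


@dataclass
class SNRResult:
    snr_db: float
    fs: float
    band_edge: float = SNR_BAND_EDGE_HZ


@dataclass
class SCREvent:
    onset_s: float
    peak_s: float
    amplitude: float                  # μS/s (derivative units)
    stimulus_latency_s: float | None = None


def eda_snr(x, fs: float, band_edge: float = SNR_BAND_EDGE_HZ) -> SNRResult:
    """Band-split SNR: 10·log10(ΣPSD(0, 5] / ΣPSD(5, fs/2]).

    Periodogram with rectangular window; the DC bin is excluded.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * band_edge:
        raise ValueError("sampling rate too low for the band split")
    freqs, psd = signal.periodogram(x, fs=fs, window="boxcar")
    in_band = (freqs > 0) & (freqs <= band_edge)
    out_band = freqs > band_edge
    p_sig = float(psd[in_band].sum())
    p_noise = float(psd[out_band].sum())
    if p_noise == 0.0:
        warnings.warn("zero noise power; SNR is infinite", RuntimeWarning,
                      stacklevel=2)
        return SNRResult(snr_db=np.inf, fs=fs, band_edge=band_edge)
    return SNRResult(snr_db=10.0 * np.log10(p_sig / p_noise), fs=fs,
                     band_edge=band_edge)


def segment_snr(x, fs: float, seg_s: float = 10.0,
                overlap: float = 0.5):
    """Per-segment SNR over a sliding window; returns (mean dB, sd dB, n).

    A 150 s record at 10 s segments with 50% overlap yields 29 segments.
    """
    x = np.asarray(x, dtype=float)
    nseg = int(round(seg_s * fs))
    if len(x) < nseg:
        raise ValueError("recording shorter than one segment")
    step = int(round(nseg * (1.0 - overlap)))
    snrs = []
    for start in range(0, len(x) - nseg + 1, step):
        snrs.append(eda_snr(x[start:start + nseg], fs).snr_db)
    snrs = np.asarray(snrs)
    return float(snrs.mean()), float(snrs.std(ddof=0)), len(snrs)


def extract_scr(x, fs: float) -> np.ndarray:
    """SCR signal: anti-alias → decimate to 20 Hz → differentiate → Bartlett.

    The first difference is scaled by the 20 Hz rate so the output is in
    μS/s; the 20-point Bartlett window is normalized to unit sum, leaving
    amplitudes in derivative units.  Output sampling rate is 20 Hz and the
    length matches the decimated signal.
    """
    x = np.asarray(x, dtype=float)
    if fs < 2 * SCR_FS:
        raise ValueError(f"input rate {fs} Hz too low to resample to {SCR_FS} Hz")
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of EDA signal")
    factor = fs / SCR_FS
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("input rate must be an integer multiple of 20 Hz")
    factor = int(round(factor))
    if factor > 1:
        b, a = signal.butter(8, 8.0, btype="low", fs=fs)
        x = signal.filtfilt(b, a, x)
        x = x[::factor]
    d = np.empty_like(x)
    d[1:] = np.diff(x) * SCR_FS
    d[0] = d[1] if len(d) > 1 else 0.0
    window = signal.windows.bartlett(BARTLETT_POINTS)
    window = window / window.sum()
    return np.convolve(d, window, mode="same")


def detect_scr_events(scr, stimuli=None, threshold_k: float = 4.0,
                      min_duration_s: float = 0.25,
                      max_latency_s: float = 10.0,
                      fs: float = SCR_FS) -> list[SCREvent]:
    """Threshold detection on the SCR signal with stimulus matching.

    An event is a run of samples exceeding median + k·MAD of the SCR signal
    that lasts at least ``min_duration_s``.  Each event is matched to the
    latest stimulus no more than ``max_latency_s`` before its onset.
    """
    scr = np.asarray(scr, dtype=float)
    stimuli = np.sort(np.asarray(stimuli, dtype=float)) if stimuli is not None \
        else np.zeros(0)
    med = np.median(scr)
    mad = np.median(np.abs(scr - med))
    if mad == 0:
        return []
    thresh = med + threshold_k * mad
    above = scr > thresh
    min_run = max(1, int(round(min_duration_s * fs)))
    events: list[SCREvent] = []
    i = 0
    n = len(scr)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                peak = i + int(np.argmax(scr[i:j]))
                onset_s = i / fs
                latency = None
                prior = stimuli[stimuli <= onset_s]
                if len(prior) and onset_s - prior[-1] <= max_latency_s:
                    latency = float(onset_s - prior[-1])
                events.append(SCREvent(
                    onset_s=onset_s, peak_s=peak / fs,
                    amplitude=float(scr[peak]),
                    stimulus_latency_s=latency,
                ))
            i = j
        else:
            i += 1
    return events
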