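"""Pulse-rate estimation from motion-corrupted PPG.

Head and body movement changes the optical path of a reflective PPG sensor,
adding acceleration-correlated motion artifact (MA).  The chain here:

1. :func:`rls_cancel` — recursive-least-squares adaptive FIR prediction of
   the artifact from the tri-axial accelerometer, subtracted from the PPG;
   by default the three axes are applied as a cascade of single-reference
   stages (x → y → z), with a joint multi-reference ("parallel") option.
2. :func:`estimate_pr` — windowed FFT spectral-peak tracking with
   verification: 8 s windows stepped by 2 s, search band 0.7–3.5 Hz,
   each new estimate constrained to ±12 BPM of the previous one, with a
   guard against locking onto the second harmonic.
3. Agreement metrics against a ground-truth series: average absolute error
   (AAE), Bland-Altman bias and limits of agreement, Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

PR_BAND_HZ = (0.7, 3.5)          # 42–210 BPM
PR_WINDOW_S = 8.0
PR_STEP_S = 2.0
TRACK_COLLAR_BPM = 12.0
FFT_RESOLUTION_HZ = 0.02


@dataclass
class RLSConfig:
    """RLS stage parameters (chosen here; the source method's are unpublished)."""

    order: int = 10
    lam: float = 0.999           # forgetting factor
    delta: float = 0.01          # P(0) = I / delta
    topology: str = "cascade"    # "cascade" or "parallel"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.lam <= 1:
            raise ValueError(f"forgetting factor must be in (0, 1], got {self.lam}")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class PRSeries:
    window_starts_s: np.ndarray
    pr_est: np.ndarray                     # BPM per window
    pr_true: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return len(self.pr_est)


@dataclass
class AgreementStats:
    aae_bpm: float
    bias_bpm: float
    loa_low_bpm: float
    loa_high_bpm: float
    pearson_r: float


def _rls_single(desired: np.ndarray, reference: np.ndarray,
                cfg: RLSConfig) -> np.ndarray:
    """One exponentially-weighted RLS stage; returns the a-priori error
    (input minus predicted artifact)."""
    m = cfg.order
    n = len(desired)
    w = np.zeros(m)
    p = np.eye(m) / cfg.delta
    u = np.zeros(m)
    out = np.empty(n)
    inv_lam = 1.0 / cfg.lam
    for i in range(n):
        u[1:] = u[:-1]
        u[0] = reference[i]
        pu = p @ u
        k = pu / (cfg.lam + u @ pu)
        e = desired[i] - w @ u
        out[i] = e
        w += k * e
        p = (p - np.outer(k, pu)) * inv_lam
        p = 0.5 * (p + p.T)     # keep symmetric against roundoff
    return out


def rls_cancel(ppg, accel, cfg: RLSConfig | None = None) -> np.ndarray:
    """Remove accelerometer-correlated artifact from a PPG channel.

    ``accel`` is an (n, 3) array of reference signals at the same rate.
    Cascade topology runs one single-reference stage per axis in order;
    parallel topology runs a single joint stage whose regressor stacks all
    three axes.  A zero reference predicts zero artifact, so the signal
    passes through unchanged.
    """
    cfg = cfg or RLSConfig()
    ppg = np.asarray(ppg, dtype=float)
    accel = np.asarray(accel, dtype=float).reshape(-1, 3)
    if len(accel) != len(ppg):
        raise ValueError("PPG and acceleration lengths differ")
    if not (np.all(np.isfinite(ppg)) and np.all(np.isfinite(accel))):
        raise ValueError("non-finite samples")
    if cfg.topology == "cascade":
        out = ppg
        for axis in range(3):
            out = _rls_single(out, accel[:, axis], cfg)
        return out
    if cfg.topology == "parallel":
        joint = RLSConfig(order=cfg.order * 3, lam=cfg.lam, delta=cfg.delta)
        return _rls_joint(ppg, accel, joint)
    raise ValueError(f"unknown topology {cfg.topology!r}")


def _rls_joint(desired: np.ndarray, refs: np.ndarray,
               cfg: RLSConfig) -> np.ndarray:
    m = cfg.order           # total taps (multiple of 3)
    per_axis = m // 3
    n = len(desired)
    w = np.zeros(m)
    p = np.eye(m) / cfg.delta
    hist = np.zeros((per_axis, 3))
    out = np.empty(n)
    inv_lam = 1.0 / cfg.lam
    for i in range(n):
        hist[1:] = hist[:-1]
        hist[0] = refs[i]
        u = hist.reshape(-1)
        pu = p @ u
        k = pu / (cfg.lam + u @ pu)
        e = desired[i] - w @ u
        out[i] = e
        w += k * e
        p = (p - np.outer(k, pu)) * inv_lam
        p = 0.5 * (p + p.T)
    return out


def estimate_pr(ppg, fs: float, win_s: float = PR_WINDOW_S,
                step_s: float = PR_STEP_S,
                pr_true_track=None) -> PRSeries:
    """Windowed spectral-peak pulse-rate tracking.

    Per window: detrend, Hann window, zero-padded FFT to ≤ 0.02 Hz
    resolution, search 0.7–3.5 Hz.  The first window takes the global
    in-band maximum; later windows take the spectral peak nearest the
    previous estimate within ±12 BPM, falling back (after a harmonic guard
    that halves a peak sitting at twice the previous rate) to the global
    maximum.  Estimates are amplitude-invariant.

    If ``pr_true_track`` (BPM sampled at ``fs``) is given, each window's
    mean true rate is attached for evaluation.
    """
    ppg = np.asarray(ppg, dtype=float)
    nwin = int(round(win_s * fs))
    step = int(round(step_s * fs))
    if len(ppg) < nwin:
        raise ValueError("recording shorter than one analysis window")
    nfft = 1
    while nfft < fs / FFT_RESOLUTION_HZ:
        nfft *= 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    band = (freqs >= PR_BAND_HZ[0]) & (freqs <= PR_BAND_HZ[1])
    window = np.hanning(nwin)

    starts, ests, trues = [], [], []
    prev_f = None
    for s0 in range(0, len(ppg) - nwin + 1, step):
        seg = signal.detrend(ppg[s0:s0 + nwin]) * window
        spec = np.abs(np.fft.rfft(seg, n=nfft))
        f_est = _pick_peak(freqs[band], spec[band], prev_f)
        prev_f = f_est
        starts.append(s0 / fs)
        ests.append(60.0 * f_est)
        if pr_true_track is not None:
            trues.append(float(np.mean(pr_true_track[s0:s0 + nwin])))
    return PRSeries(
        window_starts_s=np.asarray(starts),
        pr_est=np.asarray(ests),
        pr_true=np.asarray(trues) if pr_true_track is not None else None,
    )


def _pick_peak(freqs: np.ndarray, spec: np.ndarray,
               prev_f: float | None,
               min_rel_height: float = 0.25) -> float:
    # only spectrally significant peaks are tracking candidates; otherwise
    # a noise ripple inside the collar would pin the tracker forever
    peak_idx, _ = signal.find_peaks(spec, height=min_rel_height * spec.max())
    if len(peak_idx) == 0:
        peak_idx = np.array([int(np.argmax(spec))])
    peak_f = freqs[peak_idx]
    global_f = float(freqs[int(np.argmax(spec))])
    if prev_f is None:
        return global_f
    collar_hz = TRACK_COLLAR_BPM / 60.0
    near = np.abs(peak_f - prev_f) <= collar_hz
    if np.any(near):
        cand_f = peak_f[near]
        return float(cand_f[np.argmin(np.abs(cand_f - prev_f))])
    # harmonic guard: a dominant peak at ~2x the previous rate is the
    # waveform's second harmonic, not a doubled pulse rate
    if abs(global_f / 2.0 - prev_f) <= collar_hz:
        return global_f / 2.0
    return global_f


def aae(pr_est, pr_true) -> float:
    """Average absolute error (BPM): mean |PR_est − PR_true| over windows."""
    est = np.asarray(pr_est, dtype=float)
    true = np.asarray(pr_true, dtype=float)
    if est.shape != true.shape:
        raise ValueError("series lengths differ")
    if est.size < 1:
        raise ValueError("empty series")
    return float(np.mean(np.abs(est - true)))


def agreement(pr_est, pr_true) -> AgreementStats:
    """Bland-Altman bias/limits of agreement and Pearson correlation."""
    est = np.asarray(pr_est, dtype=float)
    true = np.asarray(pr_true, dtype=float)
    if est.shape != true.shape:
        raise ValueError("series lengths differ")
    if est.size < 3:
        raise ValueError("need at least 3 paired values")
    diff = est - true
    bias = float(diff.mean())
    sd = float(diff.std(ddof=0))
    if np.var(est) == 0 or np.var(true) == 0:
        raise ValueError("correlation undefined for zero-variance series")
    r, _ = stats.pearsonr(est, true)
    return AgreementStats(
        aae_bpm=aae(est, true), bias_bpm=bias,
        loa_low_bpm=bias - 1.96 * sd, loa_high_bpm=bias + 1.96 * sd,
        pearson_r=float(r),
    )
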