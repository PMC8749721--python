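"""Digital filtering stack: mains-rejection comb, Butterworth low-pass,
direct-form-II application, and frequency-response evaluation.

The powerline filter is an 8th-order IIR comb at 400 Hz sampling::

    y(n) = (1 + rh0)/2 · [x(n) − x(n−N)] + rh0 · y(n−N)

with N = 8 and rh0 = 0.96852105385218623, placing notches at every multiple
of fs/N = 50 Hz (including DC).  EEG is then smoothed with a 2nd-order
direct-form-II Butterworth low-pass at 30 Hz.  Peripheral channels get
bandwidth-matched 2nd-order low-passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import signal

COMB_N = 8
COMB_RH0 = 0.96852105385218623

#: Unstated in the protocol description; chosen from each signal's bandwidth.
PERIPHERAL_CUTOFFS_HZ = {"EDA": 5.0, "SKT": 1.0, "PPG": 8.0}


@dataclass
class IIRSpec:
    """Recursive filter: transfer function b/a at sampling rate fs."""

    b: np.ndarray
    a: np.ndarray
    fs: float
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if abs(self.a[0] - 1.0) > 1e-12:
            self.b = self.b / self.a[0]
            self.a = self.a / self.a[0]

    @property
    def order(self) -> int:
        return max(len(self.a), len(self.b)) - 1

    def is_stable(self) -> bool:
        poles = np.roots(self.a)
        return bool(np.all(np.abs(poles) < 1.0))

    def to_yaml(self, path=None) -> str:
        doc = {
            "b": self.b.tolist(),
            "a": self.a.tolist(),
            "fs": float(self.fs),
            "design": self.design,
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "IIRSpec":
        if hasattr(source, "read") or "\n" in str(source):
            doc = yaml.safe_load(source if hasattr(source, "read")
                                 else str(source))
        else:
            with open(source) as f:
                doc = yaml.safe_load(f)
        return cls(b=doc["b"], a=doc["a"], fs=doc["fs"],
                   design=doc.get("design", {}))


@dataclass
class FrequencyResponse:
    freqs: np.ndarray
    magnitude_db: np.ndarray
    phase_rad: np.ndarray


def design_comb(n: int = COMB_N, rh0: float = COMB_RH0,
                fs: float = 400.0) -> IIRSpec:
    """IIR notch comb with zeros at k·fs/N, k = 0..N/2.

    ``rh0`` sets the notch bandwidth: poles sit at radius rh0^(1/N) under
    each zero, so values near 1 give narrow notches.
    """
    if not 0 < rh0 < 1:
        raise ValueError(f"rh0 must be in (0, 1) for stability, got {rh0}")
    if n < 1:
        raise ValueError("comb order must be >= 1")
    g = (1.0 + rh0) / 2.0
    b = np.zeros(n + 1)
    a = np.zeros(n + 1)
    b[0], b[n] = g, -g
    a[0], a[n] = 1.0, -rh0
    return IIRSpec(b=b, a=a, fs=fs,
                   design={"kind": "comb", "N": n, "rh0": rh0})


def design_butterworth_lp(order: int, fc: float, fs: float) -> IIRSpec:
    """Standard bilinear-transform Butterworth low-pass."""
    if not 0 < fc < fs / 2:
        raise ValueError(f"cutoff {fc} Hz outside (0, fs/2) for fs={fs}")
    b, a = signal.butter(order, fc, btype="low", fs=fs)
    return IIRSpec(b=b, a=a, fs=fs,
                   design={"kind": "butterworth_lp", "order": order, "fc": fc})


def design_peripheral_lp(channel: str, fs: float = 100.0) -> IIRSpec:
    """2nd-order low-pass at the channel's default bandwidth."""
    key = channel.upper()
    if key not in PERIPHERAL_CUTOFFS_HZ:
        raise KeyError(
            f"unknown channel {channel!r}; expected one of "
            f"{sorted(PERIPHERAL_CUTOFFS_HZ)}"
        )
    return design_butterworth_lp(2, PERIPHERAL_CUTOFFS_HZ[key], fs)


def apply_iir_df2(x, spec: IIRSpec, zero_phase: bool = False) -> np.ndarray:
    """Run the filter as a direct-form-II recursion with zero initial state.

    With ``zero_phase=True`` the filter is applied forward and backward
    (offline analysis); the default is the causal streaming form.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    if zero_phase:
        return signal.filtfilt(spec.b, spec.a, x)
    return signal.lfilter(spec.b, spec.a, x)


def frequency_response(spec: IIRSpec, freqs) -> FrequencyResponse:
    """Exact rational-transfer-function evaluation on a frequency grid."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or np.any(freqs > spec.fs / 2):
        raise ValueError("frequency grid must lie within [0, fs/2]")
    _, h = signal.freqz(spec.b, spec.a, worN=freqs, fs=spec.fs)
    with np.errstate(divide="ignore"):
        mag_db = 20.0 * np.log10(np.abs(h))
    return FrequencyResponse(freqs=freqs, magnitude_db=mag_db,
                             phase_rad=np.unwrap(np.angle(h)))


def attenuation_db(spec: IIRSpec, f_hz: float) -> float:
    """Positive attenuation (−gain) at a single frequency, in dB."""
    return -float(frequency_response(spec, np.array([f_hz])).magnitude_db[0])


def measured_attenuation_db(spec: IIRSpec, f_hz: float,
                            duration_s: float = 10.0,
                            settle_s: float = 8.0) -> float:
    """Attenuation of a unit sinusoid measured after the transient settles.

    This mirrors how a notch depth is read off a real instrument: finite
    observation gives a finite number even where the transfer function has
    an exact zero.
    """
    n = int(round(duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    x = np.sin(2 * np.pi * f_hz * t)
    y = apply_iir_df2(x, spec)
    tail = y[int(settle_s * spec.fs):]
    rms_in = 1.0 / np.sqrt(2.0)
    rms_out = float(np.sqrt(np.mean(tail ** 2)))
    if rms_out == 0.0:
        return np.inf
    return 20.0 * np.log10(rms_in / rms_out)


def eeg_filter_chain(x, fs: float = 400.0, zero_phase: bool = False):
    """Comb mains rejection followed by the 30 Hz low-pass."""
    comb = design_comb(fs=fs)
    lp = design_butterworth_lp(2, 30.0, fs)
    return apply_iir_df2(apply_iir_df2(x, comb, zero_phase), lp, zero_phase)
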