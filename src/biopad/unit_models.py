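"""Analog-front-end and unit-conversion models.

Pure functions implementing the acquisition circuitry's printed equations:
the instrumentation-amplifier gain/CMRR relations, the DC-correction +
low-pass cascade frequency response, the bipolar 24-bit Σ-Δ ADC code
conversion, the EDA divider-to-conductance algebra, and the affine skin
temperature calibration of the LMT70 sensor.  These serve double duty: they
convert decoded wire codes to physical units, and they are an analytically
verifiable model of the front end.

Two printed relations are internally inconsistent and are therefore exposed
through :class:`ConversionMode`:

* the EDA conductance formula carries a trailing 1e3 factor that would put
  healthy skin conductance in the millisiemens range; the default
  ``consistent`` mode drops it, yielding ρ = 16.5/(8·U − 3.3) μS, which
  lands tonic levels in the usual 1–20 μS window for the stated 0.4–2.4 V
  divider output;
* the SKT slope is printed positive, but the LMT70's output falls with
  temperature; the default uses −0.1943 °C/mV so its ~900 mV output maps
  into the 30–40 °C forehead range.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

VREF = 2.5          # ADC reference, volts
ADC_FULLSCALE = 2 ** 23 - 1   # max magnitude of a signed 24-bit code
IA_INTERNAL_OHMS = 19_800.0   # AD8422 internal gain-set constant

#: Total analog gain from electrode to ADC: IA gain 100 × filter stage 2.
EEG_CHAIN_GAIN = 200.0


class EdaMode(str, enum.Enum):
    CONSISTENT = "consistent"
    AS_PRINTED = "as_printed"


class SktSlope(str, enum.Enum):
    NEGATIVE = "negative"
    AS_PRINTED_POSITIVE = "as_printed_positive"


@dataclass(frozen=True)
class ConversionMode:
    """Resolution of the printed-equation inconsistencies (see module doc)."""

    eda_mode: EdaMode = EdaMode.CONSISTENT
    skt_slope_sign: SktSlope = SktSlope.NEGATIVE


DEFAULT_MODE = ConversionMode()

SKT_SLOPE_C_PER_MV = 0.1943
SKT_INTERCEPT_C = 213.340


@dataclass(frozen=True)
class AfeConstants:
    """Front-end component values, loadable from the ``afe:`` YAML section."""

    rg_ohms: float = 200.0           # IA gain-set resistor
    vref_volts: float = VREF
    pga: float = 1.0
    hp_corner_hz: float = 0.5        # DC-correction loop corner
    lp_corner_hz: float = 35.0       # analog anti-alias corner
    filter_stage_gain: float = 2.0
    r_sallen_ohms: float = 300e3     # EDA Sallen-Key stage
    c_sallen_farads: float = 0.1e-6
    r3_ohms: float = 200e3           # EDA feedback resistor (drive current)
    skt_slope_c_per_mv: float = SKT_SLOPE_C_PER_MV
    skt_intercept_c: float = SKT_INTERCEPT_C

    @property
    def ia_gain(self) -> float:
        return ia_gain(self.rg_ohms)

    @property
    def cmrr_db(self) -> float:
        return cmrr_db(self.ia_gain)

    @property
    def eda_cutoff_hz(self) -> float:
        return sallen_key_cutoff(self.r_sallen_ohms, self.c_sallen_farads)

    @property
    def safety_current_amps(self) -> float:
        return eda_safety_current_amps(self.r3_ohms)

    @classmethod
    def from_yaml(cls, source) -> "AfeConstants":
        import yaml

        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        elif "\n" in str(source) or ":" in str(source):
            doc = yaml.safe_load(str(source))
        else:
            with open(source) as f:
                doc = yaml.safe_load(f)
        return cls(**(doc or {}).get("afe", doc or {}))


def ia_gain(rg_ohms: float) -> float:
    """Instrumentation-amplifier gain G = 1 + 19.8 kΩ / Rg."""
    if rg_ohms <= 0:
        raise ValueError(f"gain resistor must be positive, got {rg_ohms}")
    return 1.0 + IA_INTERNAL_OHMS / rg_ohms


def cmrr_db(gain: float) -> float:
    """Common-mode rejection ratio in dB: 80 + 20·log10(G)."""
    if gain < 1:
        raise ValueError(f"gain must be >= 1, got {gain}")
    return 80.0 + 20.0 * math.log10(gain)


def afe_frequency_response(f_hz):
    """Complex gain of the EEG front end at frequency ``f_hz``.

    Cascade: first-order high-pass at 0.5 Hz (integral-feedback DC
    correction) × IA gain 100 × second-order Butterworth low-pass at 35 Hz
    × filter-stage gain 2.  DC is fully rejected; the passband plateau is
    ~200×.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    s = 1j * 2 * np.pi * f
    w_hp = 2 * np.pi * 0.5
    w_lp = 2 * np.pi * 35.0
    h_hp = s / (s + w_hp)
    h_lp = w_lp ** 2 / (s ** 2 + math.sqrt(2) * w_lp * s + w_lp ** 2)
    h = h_hp * 100.0 * h_lp * 2.0
    return h if h.ndim else complex(h)


def adc_to_volts(code, pga: float = 1.0):
    """Bipolar 24-bit Σ-Δ conversion: V = (2·VREF/(2^23−1)) · L / PGA."""
    if pga < 1:
        raise ValueError(f"PGA must be >= 1, got {pga}")
    arr = np.asarray(code, dtype=float)
    if np.any(arr < -(2 ** 23)) or np.any(arr > 2 ** 23 - 1):
        raise ValueError("ADC code outside signed 24-bit range")
    v = (2.0 * VREF / ADC_FULLSCALE) * arr / pga
    return v if v.ndim else float(v)


def volts_to_adc(volts, pga: float = 1.0):
    """Inverse of :func:`adc_to_volts`, rounded to the nearest code."""
    v = np.asarray(volts, dtype=float)
    code = np.rint(v * pga * ADC_FULLSCALE / (2.0 * VREF))
    return code.astype(np.int64) if code.ndim else int(code)


def sallen_key_cutoff(r_ohms: float, c_farads: float) -> float:
    """Sallen-Key corner frequency fp = 1/(2πRC)."""
    if r_ohms <= 0 or c_farads <= 0:
        raise ValueError("R and C must be positive")
    return 1.0 / (2.0 * math.pi * r_ohms * c_farads)


def eda_volts_to_microsiemens(ueda, mode: ConversionMode = DEFAULT_MODE):
    """Skin conductance from the EDA divider output voltage.

    ``consistent`` mode: ρ = 16.5/(8·U − 3.3) μS.  ``as_printed`` keeps the
    trailing ×10³.  Valid only where 8·U − 3.3 > 0.
    """
    u = np.asarray(ueda, dtype=float)
    denom = 8.0 * u - 3.3
    if np.any(denom <= 0):
        raise ValueError("EDA voltage out of valid range (8·U − 3.3 must be > 0)")
    rho = 16.5 / denom
    if _eda_mode(mode) is EdaMode.AS_PRINTED:
        rho = rho * 1e3
    return rho if rho.ndim else float(rho)


def eda_microsiemens_to_volts(rho_us, mode: ConversionMode = DEFAULT_MODE):
    """Inverse conductance-to-voltage map (used when synthesizing wire codes)."""
    rho = np.asarray(rho_us, dtype=float)
    if _eda_mode(mode) is EdaMode.AS_PRINTED:
        rho = rho / 1e3
    if np.any(rho <= 0):
        raise ValueError("conductance must be positive")
    u = (16.5 / rho + 3.3) / 8.0
    return u if u.ndim else float(u)


def eda_safety_current_amps(r3_ohms: float) -> float:
    """Drive current through the skin implied by the divider: I = (3.3/16)/R3.

    The design requirement is < 10 μA.
    """
    if r3_ohms <= 0:
        raise ValueError("R3 must be positive")
    return (3.3 / 16.0) / r3_ohms


def skt_millivolts_to_celsius(vtao_mv, mode: ConversionMode = DEFAULT_MODE):
    """LMT70 calibration T = m·V + b with |m| = 0.1943 °C/mV, b = 213.340 °C."""
    v = np.asarray(vtao_mv, dtype=float)
    m = SKT_SLOPE_C_PER_MV
    if _skt_slope(mode) is SktSlope.NEGATIVE:
        m = -m
    t = m * v + SKT_INTERCEPT_C
    return t if t.ndim else float(t)


def skt_celsius_to_millivolts(t_c, mode: ConversionMode = DEFAULT_MODE):
    t = np.asarray(t_c, dtype=float)
    m = SKT_SLOPE_C_PER_MV
    if _skt_slope(mode) is SktSlope.NEGATIVE:
        m = -m
    v = (t - SKT_INTERCEPT_C) / m
    return v if v.ndim else float(v)


def _eda_mode(mode) -> EdaMode:
    if isinstance(mode, ConversionMode):
        return EdaMode(mode.eda_mode)
    return EdaMode(mode)


def _skt_slope(mode) -> SktSlope:
    if isinstance(mode, ConversionMode):
        return SktSlope(mode.skt_slope_sign)
    return SktSlope(mode)
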