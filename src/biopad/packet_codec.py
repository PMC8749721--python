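"""Bit-exact codec for the device's 168-byte BLE data frame.

One frame carries 50 ms of signal: 20 ticks of two-channel EEG at 400 Hz as
big-endian 24-bit two's-complement ADC codes, and 5 ticks of the peripheral
channels at 100 Hz (EDA, SKT, PPG red, PPG IR as unsigned 16-bit; accel
x/y/z as signed bytes).  Layout::

    offset  0        header 0x7F
    offset  1        length byte 0xE6 (protocol magic, kept as printed)
    offset  2..121   EEG block, tick-major: [ch1 (3B), ch2 (3B)] × 20
    offset  122..166 peripheral block × 5 ticks (9 B per tick):
                     EDA u16, SKT u16, PPG-red u8, PPG-IR u8,
                     accel x i8, y i8, z i8
    offset  167      CRC-8 over bytes 2..166

Multi-byte fields are big-endian.  The 45-byte peripheral block fixes the
PPG wavelengths at one byte each; that is the only per-tick layout that
carries all eight peripheral channels at 100 Hz inside a 168-byte frame.

The CRC defaults to the reflected-0x31 variant (init 0x00, no final XOR),
a common choice for sensor streams; the polynomial is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import unit_models
from .records import (
    EEG_TICKS_PER_FRAME,
    PERIPHERAL_TICKS_PER_FRAME,
    MultiRateRecord,
)

HEADER_BYTE = 0x7F
LENGTH_BYTE = 0xE6
FRAME_LEN = 168
EEG_BLOCK_OFFSET = 2
EEG_BLOCK_LEN = EEG_TICKS_PER_FRAME * 2 * 3          # 120
PERIPHERAL_BLOCK_OFFSET = EEG_BLOCK_OFFSET + EEG_BLOCK_LEN   # 122
PERIPHERAL_BLOCK_LEN = PERIPHERAL_TICKS_PER_FRAME * 9        # 45
CRC_OFFSET = FRAME_LEN - 1                                   # 167
FRAME_DURATION_S = 0.05

# Wire quantization of the peripheral fields (chosen so nominal
# physiological ranges span most of each field's code range).
EDA_VOLTS_FULLSCALE = 3.3        # u16 code 65535 ↔ 3.3 V divider output
SKT_MV_FULLSCALE = 1100.0        # u16 code 65535 ↔ 1100 mV LMT70 output
PPG_OFFSET = 128                 # u8 mid-scale ↔ 0 counts
PPG_COUNTS_PER_LSB = 256.0       # u8: ±128 codes ↔ ±32768 counts
ACCEL_LSB_PER_G = 32.0           # i8: ±128 codes ↔ ±4 g


class FramingError(ValueError):
    """Header or length byte does not match the protocol constants."""


class IntegrityError(ValueError):
    """CRC mismatch on an otherwise well-framed packet."""


class FieldRangeError(ValueError):
    """A sample does not fit its wire field."""


# --------------------------------------------------------------------- CRC

_REFLECTED_POLY_CACHE: dict[int, np.ndarray] = {}


def _crc8_table(poly_reflected: int) -> np.ndarray:
    table = _REFLECTED_POLY_CACHE.get(poly_reflected)
    if table is None:
        table = np.zeros(256, dtype=np.uint8)
        for byte in range(256):
            crc = byte
            for _ in range(8):
                crc = (crc >> 1) ^ poly_reflected if crc & 1 else crc >> 1
            table[byte] = crc
        _REFLECTED_POLY_CACHE[poly_reflected] = table
    return table


def crc8(payload: bytes | bytearray | Sequence[int],
         poly: int = 0x31, init: int = 0x00) -> int:
    """Reflected CRC-8 of ``payload``.

    Default variant: polynomial 0x31 (reflected 0x8C), init 0x00, no final
    XOR.  The empty payload maps to the init value.
    """
    poly_reflected = _reflect8(poly)
    table = _crc8_table(poly_reflected)
    crc = init & 0xFF
    for b in bytes(payload):
        crc = int(table[crc ^ b])
    return crc


def _reflect8(x: int) -> int:
    r = 0
    for i in range(8):
        if x & (1 << i):
            r |= 1 << (7 - i)
    return r


# ------------------------------------------------------------------ frames

@dataclass
class EncodedFrame:
    """One wire frame plus bookkeeping."""

    raw: bytes
    frame_index: int = 0
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        if len(self.raw) != FRAME_LEN:
            raise FramingError(f"frame must be {FRAME_LEN} bytes, got {len(self.raw)}")


@dataclass
class PeripheralSamples:
    """5 ticks of peripheral wire codes (one frame's worth)."""

    eda: np.ndarray      # (5,) uint16 codes
    skt: np.ndarray      # (5,) uint16
    ppg_red: np.ndarray  # (5,) uint8
    ppg_ir: np.ndarray   # (5,) uint8
    accel: np.ndarray    # (5, 3) int8


@dataclass
class StreamDiagnostics:
    frames_ok: int = 0
    frames_crc_fail: int = 0
    bytes_skipped_resync: int = 0
    gaps: list = field(default_factory=list)


def encode_frame(eeg_codes, peripheral: PeripheralSamples,
                 frame_index: int = 0) -> EncodedFrame:
    """Pack one frame.  ``eeg_codes`` is a 20×2 grid of signed 24-bit codes."""
    eeg = np.asarray(eeg_codes, dtype=np.int64)
    if eeg.shape != (EEG_TICKS_PER_FRAME, 2):
        raise ValueError(f"eeg_codes must be {EEG_TICKS_PER_FRAME}x2, got {eeg.shape}")
    buf = bytearray(FRAME_LEN)
    buf[0] = HEADER_BYTE
    buf[1] = LENGTH_BYTE
    pos = EEG_BLOCK_OFFSET
    for tick in range(EEG_TICKS_PER_FRAME):
        for ch in range(2):
            code = int(eeg[tick, ch])
            if not -(2 ** 23) <= code <= 2 ** 23 - 1:
                raise FieldRangeError(
                    f"EEG code {code} out of 24-bit range at tick {tick}, channel {ch}"
                )
            buf[pos:pos + 3] = (code & 0xFFFFFF).to_bytes(3, "big")
            pos += 3
    for tick in range(PERIPHERAL_TICKS_PER_FRAME):
        for name, arr in (("eda", peripheral.eda), ("skt", peripheral.skt)):
            v = int(arr[tick])
            if not 0 <= v <= 0xFFFF:
                raise FieldRangeError(f"{name} code {v} out of u16 range at tick {tick}")
            buf[pos:pos + 2] = v.to_bytes(2, "big")
            pos += 2
        for name, arr in (("ppg_red", peripheral.ppg_red),
                          ("ppg_ir", peripheral.ppg_ir)):
            v = int(arr[tick])
            if not 0 <= v <= 0xFF:
                raise FieldRangeError(f"{name} code {v} out of u8 range at tick {tick}")
            buf[pos] = v
            pos += 1
        for axis in range(3):
            v = int(peripheral.accel[tick, axis])
            if not -128 <= v <= 127:
                raise FieldRangeError(
                    f"accel axis {axis} code {v} out of i8 range at tick {tick}"
                )
            buf[pos] = v & 0xFF
            pos += 1
    assert pos == CRC_OFFSET
    buf[CRC_OFFSET] = crc8(buf[EEG_BLOCK_OFFSET:CRC_OFFSET])
    return EncodedFrame(raw=bytes(buf), frame_index=frame_index,
                        timestamp_s=frame_index * FRAME_DURATION_S)


def decode_frame(raw: bytes):
    """Unpack one frame; inverse of :func:`encode_frame`.

    Returns ``(eeg_codes, PeripheralSamples)``.
    """
    if len(raw) != FRAME_LEN:
        raise FramingError(f"frame must be {FRAME_LEN} bytes, got {len(raw)}")
    if raw[0] != HEADER_BYTE or raw[1] != LENGTH_BYTE:
        raise FramingError(
            f"bad framing bytes {raw[0]:#04x} {raw[1]:#04x}"
        )
    if crc8(raw[EEG_BLOCK_OFFSET:CRC_OFFSET]) != raw[CRC_OFFSET]:
        raise IntegrityError("CRC mismatch")
    eeg = np.zeros((EEG_TICKS_PER_FRAME, 2), dtype=np.int64)
    pos = EEG_BLOCK_OFFSET
    for tick in range(EEG_TICKS_PER_FRAME):
        for ch in range(2):
            code = int.from_bytes(raw[pos:pos + 3], "big")
            if code & 0x800000:          # sign-extend 24 -> 64 bit
                code -= 1 << 24
            eeg[tick, ch] = code
            pos += 3
    eda = np.zeros(PERIPHERAL_TICKS_PER_FRAME, dtype=np.uint16)
    skt = np.zeros_like(eda)
    ppg_red = np.zeros(PERIPHERAL_TICKS_PER_FRAME, dtype=np.uint8)
    ppg_ir = np.zeros_like(ppg_red)
    accel = np.zeros((PERIPHERAL_TICKS_PER_FRAME, 3), dtype=np.int8)
    for tick in range(PERIPHERAL_TICKS_PER_FRAME):
        eda[tick] = int.from_bytes(raw[pos:pos + 2], "big"); pos += 2
        skt[tick] = int.from_bytes(raw[pos:pos + 2], "big"); pos += 2
        ppg_red[tick] = raw[pos]; pos += 1
        ppg_ir[tick] = raw[pos]; pos += 1
        for axis in range(3):
            v = raw[pos]
            accel[tick, axis] = v - 256 if v > 127 else v
            pos += 1
    return eeg, PeripheralSamples(eda=eda, skt=skt, ppg_red=ppg_red,
                                  ppg_ir=ppg_ir, accel=accel)


def decode_stream(data: bytes):
    """Scan a byte stream for frames, resynchronizing on the 0x7F 0xE6 pattern.

    Returns ``(frames, StreamDiagnostics)`` where each element of ``frames``
    is the ``(eeg_codes, PeripheralSamples)`` pair of one CRC-valid frame.
    Malformed regions are skipped and counted; every input byte is accounted
    for in the diagnostics.
    """
    frames = []
    diag = StreamDiagnostics()
    pos = 0
    n = len(data)
    idx = 0
    while pos + FRAME_LEN <= n:
        if data[pos] == HEADER_BYTE and data[pos + 1] == LENGTH_BYTE:
            candidate = data[pos:pos + FRAME_LEN]
            try:
                decoded = decode_frame(candidate)
            except IntegrityError:
                diag.frames_crc_fail += 1
                pos += FRAME_LEN
                continue
            frames.append(decoded)
            diag.frames_ok += 1
            idx += 1
            pos += FRAME_LEN
        else:
            diag.bytes_skipped_resync += 1
            pos += 1
    diag.bytes_skipped_resync += n - pos
    return frames, diag


# --------------------------------------------- physical-unit (de)quantization

def quantize_record(record: MultiRateRecord):
    """Convert a physical-unit record to per-frame wire codes.

    Yields ``(eeg_codes, PeripheralSamples)`` per 50 ms frame.  Values outside
    a field's code range are clipped with a warning.
    """
    if not record.is_frame_aligned():
        raise ValueError("record length does not divide into 50 ms frames")
    n_frames = record.n_peripheral // PERIPHERAL_TICKS_PER_FRAME

    eeg_volts = record.eeg * 1e-6 * unit_models.EEG_CHAIN_GAIN
    eeg_codes = np.rint(eeg_volts * unit_models.ADC_FULLSCALE
                        / (2.0 * unit_models.VREF)).astype(np.int64)
    eda_codes = np.rint(unit_models.eda_microsiemens_to_volts(record.eda)
                        * 65535.0 / EDA_VOLTS_FULLSCALE).astype(np.int64)
    skt_codes = np.rint(unit_models.skt_celsius_to_millivolts(record.skt)
                        * 65535.0 / SKT_MV_FULLSCALE).astype(np.int64)
    ppg_codes = np.rint(record.ppg / PPG_COUNTS_PER_LSB
                        + PPG_OFFSET).astype(np.int64)
    accel_codes = np.rint(record.accel * ACCEL_LSB_PER_G).astype(np.int64)

    clipped = False
    for arr, lo, hi in ((eeg_codes, -(2 ** 23), 2 ** 23 - 1),
                        (eda_codes, 0, 65535), (skt_codes, 0, 65535),
                        (ppg_codes, 0, 255), (accel_codes, -128, 127)):
        if arr.size and (arr.min() < lo or arr.max() > hi):
            clipped = True
        np.clip(arr, lo, hi, out=arr)
    if clipped:
        warnings.warn("physical values clipped to wire code range",
                      RuntimeWarning, stacklevel=2)

    for i in range(n_frames):
        e = eeg_codes[i * EEG_TICKS_PER_FRAME:(i + 1) * EEG_TICKS_PER_FRAME]
        sl = slice(i * PERIPHERAL_TICKS_PER_FRAME,
                   (i + 1) * PERIPHERAL_TICKS_PER_FRAME)
        yield e, PeripheralSamples(
            eda=eda_codes[sl].astype(np.uint16),
            skt=skt_codes[sl].astype(np.uint16),
            ppg_red=ppg_codes[sl, 0].astype(np.uint8),
            ppg_ir=ppg_codes[sl, 1].astype(np.uint8),
            accel=accel_codes[sl].astype(np.int8),
        )


def frames_to_record(frames: Iterable, frame_indices=None) -> MultiRateRecord:
    """Concatenate decoded frames into a physical-unit record.

    ``frames`` are ``(eeg_codes, PeripheralSamples)`` pairs in index order;
    a gap in ``frame_indices`` is recorded in the diagnostics.
    """
    frames = list(frames)
    diag: dict = {"gaps": []}
    if frame_indices is not None:
        idx = list(frame_indices)
        for a, b in zip(idx, idx[1:]):
            if b != a + 1:
                diag["gaps"].append((a, b))
        if diag["gaps"]:
            warnings.warn(f"frame-index gaps: {diag['gaps']}", RuntimeWarning,
                          stacklevel=2)
    if not frames:
        return MultiRateRecord(
            eeg=np.zeros((0, 2)), eda=np.zeros(0), skt=np.zeros(0),
            ppg=np.zeros((0, 2)), accel=np.zeros((0, 3)), diagnostics=diag,
        )
    eeg_codes = np.concatenate([f[0] for f in frames])
    eda_codes = np.concatenate([f[1].eda for f in frames]).astype(float)
    skt_codes = np.concatenate([f[1].skt for f in frames]).astype(float)
    ppg_red = np.concatenate([f[1].ppg_red for f in frames]).astype(float)
    ppg_ir = np.concatenate([f[1].ppg_ir for f in frames]).astype(float)
    accel_codes = np.concatenate([f[1].accel for f in frames]).astype(float)

    eeg_uv = (unit_models.adc_to_volts(eeg_codes)
              / unit_models.EEG_CHAIN_GAIN * 1e6)
    # lenient decode: EDA codes below the conductance formula's valid
    # voltage region (8U - 3.3 <= 0) become NaN rather than failing
    eda_volts = eda_codes * EDA_VOLTS_FULLSCALE / 65535.0
    denom = 8.0 * eda_volts - 3.3
    eda_us = np.where(denom > 0, 16.5 / np.where(denom > 0, denom, 1.0),
                      np.nan)
    skt_c = unit_models.skt_millivolts_to_celsius(
        skt_codes * SKT_MV_FULLSCALE / 65535.0)
    ppg = np.stack([ppg_red - PPG_OFFSET, ppg_ir - PPG_OFFSET],
                   axis=1) * PPG_COUNTS_PER_LSB
    accel = accel_codes / ACCEL_LSB_PER_G
    return MultiRateRecord(eeg=eeg_uv, eda=eda_us, skt=skt_c, ppg=ppg,
                           accel=accel, diagnostics=diag)


def write_bin(path, frames: Iterable[EncodedFrame]) -> int:
    """Write encoded frames to a raw ``.bin`` packet-stream file."""
    n = 0
    with open(path, "wb") as f:
        for fr in frames:
            f.write(fr.raw)
            n += 1
    return n


def read_bin(path):
    """Read a raw packet stream file; returns ``(frames, diagnostics)``."""
    with open(path, "rb") as f:
        return decode_stream(f.read())
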