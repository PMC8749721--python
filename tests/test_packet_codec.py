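"""Wire-frame codec: CRC, layout, round trips, stream resynchronization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biopad import packet_codec as pc
from biopad.records import MultiRateRecord


def crc8_longdiv(payload: bytes, poly: int = 0x31) -> int:
    """Independent oracle: polynomial long division over GF(2).

    Reflected variant: reverse the bits of each input byte, append 8 zero
    bits, divide MSB-first by (x^8 | poly), reverse the 8-bit remainder.
    """
    def rev8(x):
        return int(f"{x:08b}"[::-1], 2)

    bits = []
    for byte in payload:
        bits.extend(int(b) for b in f"{rev8(byte):08b}")
    bits.extend([0] * 8)
    divisor = [1] + [int(b) for b in f"{poly:08b}"]
    for i in range(len(bits) - 8):
        if bits[i]:
            for j, d in enumerate(divisor):
                bits[i + j] ^= d
    rem = int("".join(map(str, bits[-8:])), 2)
    return rev8(rem)


def random_frame_inputs(rng):
    eeg = rng.integers(-(2 ** 23), 2 ** 23, size=(20, 2))
    peripheral = pc.PeripheralSamples(
        eda=rng.integers(0, 65536, 5).astype(np.uint16),
        skt=rng.integers(0, 65536, 5).astype(np.uint16),
        ppg_red=rng.integers(0, 256, 5).astype(np.uint8),
        ppg_ir=rng.integers(0, 256, 5).astype(np.uint8),
        accel=rng.integers(-128, 128, (5, 3)).astype(np.int8),
    )
    return eeg, peripheral


class TestCrc8:
    def test_empty_payload_is_init_value(self):
        assert pc.crc8(b"") == 0x00

    def test_standard_check_value(self):
        # reflected poly-0x31 CRC of the canonical 9-digit check string
        assert pc.crc8(b"123456789") == crc8_longdiv(b"123456789") == 0xA1

    def test_matches_longdiv_oracle_on_random_payloads(self, rng):
        for n in (1, 2, 17, 64, 165):
            payload = bytes(rng.integers(0, 256, n).tolist())
            assert pc.crc8(payload) == crc8_longdiv(payload)

    def test_every_single_bit_flip_changes_checksum(self, rng):
        payload = bytearray(rng.integers(0, 256, 64).tolist())
        ref = pc.crc8(payload)
        for i in range(64):
            for bit in range(8):
                flipped = bytearray(payload)
                flipped[i] ^= 1 << bit
                assert pc.crc8(flipped) != ref

    def test_deterministic(self):
        assert pc.crc8(b"abc") == pc.crc8(b"abc")


class TestFrameCodec:
    def test_frame_is_168_bytes_with_magic_bytes(self, rng):
        frame = pc.encode_frame(*random_frame_inputs(rng))
        assert len(frame.raw) == 168
        assert frame.raw[0] == 0x7F
        assert frame.raw[1] == 0xE6

    def test_all_zero_samples_give_zero_payload(self):
        peripheral = pc.PeripheralSamples(
            eda=np.zeros(5, np.uint16), skt=np.zeros(5, np.uint16),
            ppg_red=np.zeros(5, np.uint8), ppg_ir=np.zeros(5, np.uint8),
            accel=np.zeros((5, 3), np.int8))
        frame = pc.encode_frame(np.zeros((20, 2), int), peripheral)
        assert set(frame.raw[2:167]) == {0}
        assert frame.raw[167] == pc.crc8(bytes(165))

    def test_layout_offsets_match_hand_packed_reference(self):
        eeg = np.zeros((20, 2), dtype=np.int64)
        eeg[0, 0] = 0x123456
        eeg[0, 1] = -1            # 0xFFFFFF two's complement
        eeg[19, 1] = -(2 ** 23)   # 0x800000
        peripheral = pc.PeripheralSamples(
            eda=np.array([0xABCD, 0, 0, 0, 0x0102], np.uint16),
            skt=np.array([0x1234, 0, 0, 0, 0], np.uint16),
            ppg_red=np.array([0xEE, 0, 0, 0, 0], np.uint8),
            ppg_ir=np.array([0x77, 0, 0, 0, 0], np.uint8),
            accel=np.array([[-1, 2, -128]] + [[0, 0, 0]] * 4, np.int8))
        raw = pc.encode_frame(eeg, peripheral).raw
        assert raw[2:5] == bytes([0x12, 0x34, 0x56])        # EEG t0 ch1
        assert raw[5:8] == bytes([0xFF, 0xFF, 0xFF])        # EEG t0 ch2
        assert raw[119:122] == bytes([0x80, 0x00, 0x00])    # EEG t19 ch2
        assert raw[122:124] == bytes([0xAB, 0xCD])          # EDA tick 0
        assert raw[124:126] == bytes([0x12, 0x34])          # SKT tick 0
        assert raw[126] == 0xEE and raw[127] == 0x77        # PPG red/IR
        assert raw[128:131] == bytes([0xFF, 0x02, 0x80])    # accel x,y,z
        assert raw[158:160] == bytes([0x01, 0x02])          # EDA tick 4 (122+4*9)

    def test_round_trip_identity_over_random_frames(self, rng):
        for _ in range(200):
            eeg, peripheral = random_frame_inputs(rng)
            eeg2, p2 = pc.decode_frame(pc.encode_frame(eeg, peripheral).raw)
            assert np.array_equal(eeg, eeg2)
            for fld in ("eda", "skt", "ppg_red", "ppg_ir", "accel"):
                assert np.array_equal(getattr(peripheral, fld),
                                      getattr(p2, fld))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 32 - 1))
    def test_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        eeg, peripheral = random_frame_inputs(rng)
        eeg2, p2 = pc.decode_frame(pc.encode_frame(eeg, peripheral).raw)
        assert np.array_equal(eeg, eeg2)
        assert np.array_equal(peripheral.accel, p2.accel)

    def test_out_of_range_eeg_code_names_channel_and_tick(self, rng):
        eeg, peripheral = random_frame_inputs(rng)
        eeg[7, 1] = 2 ** 23
        with pytest.raises(pc.FieldRangeError, match="tick 7.*channel 1"):
            pc.encode_frame(eeg, peripheral)

    def test_bad_header_raises_framing_error(self, rng):
        raw = bytearray(pc.encode_frame(*random_frame_inputs(rng)).raw)
        raw[0] = 0x00
        with pytest.raises(pc.FramingError):
            pc.decode_frame(bytes(raw))

    def test_flipped_payload_bit_raises_integrity_error(self, rng):
        raw = bytearray(pc.encode_frame(*random_frame_inputs(rng)).raw)
        raw[50] ^= 0x10
        with pytest.raises(pc.IntegrityError):
            pc.decode_frame(bytes(raw))


class TestDecodeStream:
    def _frames(self, rng, n):
        return [pc.encode_frame(*random_frame_inputs(rng)).raw
                for _ in range(n)]

    def test_clean_concatenation(self, rng):
        stream = b"".join(self._frames(rng, 5))
        frames, diag = pc.decode_stream(stream)
        assert len(frames) == 5
        assert diag.frames_ok == 5
        assert diag.bytes_skipped_resync == 0

    def test_garbage_prefix_is_skipped_and_counted(self, rng):
        stream = b"\x01\x02\x03" + b"".join(self._frames(rng, 2))
        frames, diag = pc.decode_stream(stream)
        assert len(frames) == 2
        assert diag.bytes_skipped_resync == 3

    def test_resync_after_any_short_garbage_prefix(self, rng):
        body = b"".join(self._frames(rng, 3))
        for npfx in (1, 42, 167):
            prefix = bytes(rng.integers(0, 256, npfx).tolist())
            frames, _ = pc.decode_stream(prefix + body)
            assert len(frames) >= 3  # prefix may accidentally frame, never drop

    def test_corrupted_crc_between_good_frames(self, rng):
        good = self._frames(rng, 3)
        bad = bytearray(good[1])
        bad[167] ^= 0xFF
        frames, diag = pc.decode_stream(good[0] + bytes(bad) + good[2])
        assert diag.frames_ok == 2
        assert diag.frames_crc_fail == 1

    def test_diagnostics_conserve_bytes(self, rng):
        stream = (b"\xde\xad" + b"".join(self._frames(rng, 4))
                  + b"\x7f\xe6garbage")
        _, diag = pc.decode_stream(stream)
        consumed = 168 * (diag.frames_ok + diag.frames_crc_fail) \
            + diag.bytes_skipped_resync
        assert consumed == len(stream)


class TestFramesToRecord:
    def test_twenty_frames_make_one_second(self, rng):
        frames = [pc.decode_frame(pc.encode_frame(*random_frame_inputs(rng)).raw)
                  for _ in range(20)]
        record = pc.frames_to_record(frames)
        assert record.n_eeg == 400
        assert record.n_peripheral == 100

    def test_empty_input_gives_empty_record(self):
        record = pc.frames_to_record([])
        assert record.n_eeg == 0 and record.n_peripheral == 0

    def test_frame_index_gap_is_flagged(self, rng):
        frames = [pc.decode_frame(pc.encode_frame(*random_frame_inputs(rng)).raw)
                  for _ in range(3)]
        with pytest.warns(RuntimeWarning, match="gap"):
            record = pc.frames_to_record(frames, frame_indices=[0, 1, 3])
        assert record.diagnostics["gaps"] == [(1, 3)]

    def test_physical_units_round_trip_within_quantization(self):
        rng = np.random.default_rng(7)
        m = 25
        record = MultiRateRecord(
            eeg=rng.uniform(-150, 150, (4 * m, 2)),
            eda=rng.uniform(2.0, 20.0, m),
            skt=rng.uniform(30.0, 40.0, m),
            ppg=rng.uniform(-8000, 8000, (m, 2)),
            accel=rng.uniform(-2, 2, (m, 3)),
        )
        frames = [pc.decode_frame(pc.encode_frame(e, p).raw)
                  for e, p in pc.quantize_record(record)]
        back = pc.frames_to_record(frames)
        eeg_lsb_uv = 2 * 2.5 / (2 ** 23 - 1) / 200.0 * 1e6
        assert np.abs(back.eeg - record.eeg).max() <= eeg_lsb_uv
        assert np.abs(back.skt - record.skt).max() <= 1100 / 65535 * 0.1943
        assert np.abs(back.ppg - record.ppg).max() <= pc.PPG_COUNTS_PER_LSB
        assert np.abs(back.accel - record.accel).max() <= 1 / pc.ACCEL_LSB_PER_G
        # EDA quantization is nonlinear in conductance; bound via voltage LSB
        assert np.abs(back.eda - record.eda).max() <= 0.05
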