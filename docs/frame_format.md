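# Wire frame format

One frame carries 50 ms of the multimodal stream: 20 EEG ticks at 400 Hz and
5 peripheral ticks at 100 Hz. Twenty frames per second, 168 bytes each.
Multi-byte fields are big-endian.

| Offset    | Size | Field                                                  |
|-----------|------|--------------------------------------------------------|
| 0         | 1    | Header, constant `0x7F`                                |
| 1         | 1    | Length byte, constant `0xE6` (protocol magic)          |
| 2–121     | 120  | EEG block: 20 ticks × [ch1 (3 B), ch2 (3 B)], signed 24-bit two's-complement ADC codes |
| 122–166   | 45   | Peripheral block: 5 ticks × 9 B (layout below)         |
| 167       | 1    | CRC-8 over bytes 2–166                                  |

Peripheral tick layout (9 bytes, repeated 5×; tick *k* starts at offset
122 + 9·*k*):

| Rel. offset | Size | Field   | Encoding                                   |
|-------------|------|---------|--------------------------------------------|
| 0           | 2    | EDA     | unsigned; code·3.3/65535 = divider volts   |
| 2           | 2    | SKT     | unsigned; code·1100/65535 = sensor mV      |
| 4           | 1    | PPG red | unsigned; (code − 128)·256 = counts        |
| 5           | 1    | PPG IR  | unsigned; (code − 128)·256 = counts        |
| 6           | 1    | accel x | signed; code/32 = g                        |
| 7           | 1    | accel y | signed; code/32 = g                        |
| 8           | 1    | accel z | signed; code/32 = g                        |

The 45-byte peripheral block fixes the two PPG wavelengths at one byte each:
that is the only per-tick layout that carries all eight peripheral channels
at 100 Hz inside a 168-byte frame.

**CRC.** Reflected CRC-8, polynomial `0x31`, initial value `0x00`, no final
XOR (check value of `"123456789"` is `0xA1`). The polynomial and init are
configurable in `biopad.packet_codec.crc8`.

**Resynchronization.** `decode_stream` scans for the `0x7F 0xE6` pattern,
validates the CRC, and skips (and counts) any bytes that do not frame; a
candidate frame with a bad CRC is counted and skipped whole.
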