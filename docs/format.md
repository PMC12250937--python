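# The `.nsf` stream container

`.nsf` ("neural stream format") is the bit-exact serialization of the framed
multiplexed data stream the processing engine consumes and produces. All
fields are **little-endian**. A file is a 16-byte header followed by zero or
more fixed-length frames; one frame corresponds to one sampling period
(one "acquisition loop") across all channels.

## Header (16 bytes)

| offset | size | field             | value                                  |
|-------:|-----:|-------------------|----------------------------------------|
| 0      | 4    | magic_tag         | ASCII `NSF1`                           |
| 4      | 2    | version           | u16, currently 1                       |
| 6      | 4    | fs_hz             | u32 sampling rate (20000/25000/30000)  |
| 10     | 1    | n_headstages      | u8, 1..8                               |
| 11     | 1    | n_channels_per_hs | u8, 1..16                              |
| 12     | 1    | payload_kind      | u8: 0 = raw, 1 = filtered + spike flags|
| 13     | 3    | reserved          | zero bytes                             |

## Frame

| field       | size                  | notes                                        |
|-------------|-----------------------|----------------------------------------------|
| sync_word   | 8                     | u64 constant `0x5AFEC0DE5A17E5D1`            |
| frame_index | 4                     | u32, informative (not used for ordering)     |
| samples     | 2 × n_channels        | i16, **channel-major**: `for ch: for hs`     |
| spike_flags | ceil(n_channels / 8)  | only when payload_kind = 1, LSB-first bitmap |

`n_channels = n_headstages * n_channels_per_hs`. The sample for channel
`(hs, ch)` occupies slot `ch * n_headstages + hs`; flag bit for slot `s` is
bit `s % 8` of byte `s // 8`. In a filtered stream a set flag in frame `t`
means the detector fired at step `t`, i.e. the spike's peak sample arrived
in frame `t-1`.

Decoders must treat the sync word as the only frame delimiter: on a
mismatch at an expected frame boundary they scan byte-by-byte for the next
sync word (one resynchronization event per contiguous corrupted region) and
never emit samples from a corrupted region. Sample values that happen to
equal sync-word fragments are harmless because resynchronization is only
triggered at frame boundaries. A partial trailing frame is dropped and
counted.

## Worked example

1 headstage × 1 channel, raw payload, two samples: −500 then +1000 counts.
Total length 16 + 2 × (8 + 4 + 2) = 44 bytes.

```
header:  4e 53 46 31  01 00  20 4e 00 00  01  01  00  00 00 00
         'N  S  F  1' ver=1  fs=20000     hs  ch  raw reserved

frame 0: d1 e5 17 5a de c0 fe 5a  00 00 00 00  0c fe
         sync word (LE)           index=0      -500 = 0xfe0c

frame 1: d1 e5 17 5a de c0 fe 5a  01 00 00 00  e8 03
         sync word (LE)           index=1      1000 = 0x03e8
```

With payload_kind = 1 and a 2 × 2 layout the frame grows to
8 + 4 + 4·2 + 1 = 21 bytes (one flag byte for four channels).
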