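# Wire format (normative)

Binary protocol for block-wise streaming of neural signals, packed state
vectors, and broker commands. All multi-byte integers and floats are
**little-endian**. Strings are `uint16` byte length + UTF-8 payload.
Every packet is self-delimiting and starts with one descriptor byte, so
packets can be concatenated back-to-back on any reliable byte stream and
re-segmented at arbitrary boundaries.

## Transport

Packets are carried over a plain TCP connection (the replay server) — the
payloads are transport-agnostic, so the same bytes could be carried as
WebSocket binary messages (one packet per message) by a different
transport layer. The server sends `SignalProperties` then `StateList` once
per connection, then one `SignalBlock` packet per sample block, then a
`Response` from client id `server` with payload `end-of-stream`.

## Descriptor bytes

| byte | packet           |
|------|------------------|
| 1    | SignalProperties |
| 2    | StateList        |
| 3    | SignalBlock      |
| 4    | StateVector (standalone) |
| 5    | Command          |
| 6    | Response         |

## SignalProperties (1)

| field            | type    |
|------------------|---------|
| n_channels       | uint32  |
| n_elements       | uint32  |
| sampling_rate_hz | float64 |
| units            | string  |
| channel_labels   | n_channels × string |

Labels are unique and non-empty; their count equals `n_channels`.

## StateList (2)

| field    | type   |
|----------|--------|
| n_states | uint16 |

then per state:

| field       | type   | constraint |
|-------------|--------|------------|
| name        | string | unique     |
| bit_width   | uint8  | 1..32      |
| byte_offset | uint16 | ≥ 0        |
| bit_offset  | uint8  | 0..7       |

State fields must not overlap in the packed vector. A state's first bit is
`byte_offset*8 + bit_offset`; values are packed LSB-first.

## SignalBlock (3)

One sample block: the signal payload followed inline by the state-vector
section (the two are produced together, once per block; the receiver
re-associates them trivially and assigns `block_index` by arrival order —
no index is carried on the wire).

| field       | type   | note |
|-------------|--------|------|
| value_type  | uint8  | 0 = float32, 1 = float64 |
| n_channels  | uint32 | |
| n_elements  | uint32 | |
| values      | n_channels × n_elements × value_type | channel-major |
| sv_n_elements | uint32 | must equal n_elements |
| bytes_per_sample | uint16 | from the governing StateList (0 = no states) |
| packed states | sv_n_elements × bytes_per_sample bytes | LSB-first per StateList |

Worked size example — 1 channel × 1 element, no states:
`1 (descriptor) + 1 (value type) + 4 + 4 (dims) + 4 (one float32) + 4 + 2
(empty state-vector header) = 20 bytes`.

## StateVector (4)

A standalone state-vector section (same layout as the trailing section of
a SignalBlock): `uint32 n_elements`, `uint16 bytes_per_sample`, packed
bytes. Decoding a non-empty state vector requires the stream's StateList.

## Command (5) / Response (6)

Command: `client_id` string, `text` string (opaque command text).
Response: `client_id` string, `uint8` status (0 = ok, 1 = error),
`payload` string. Commands from any number of clients are executed
strictly FIFO in arrival order; every response carries the `client_id` of
the request it answers and is routed only to the issuing client.

## Compatibility note

The packet *names and roles* mirror the signal-properties / state-list /
generic-signal / state-vector stream of the BCI2000 binary format; the
byte layout above is this package's own documented dialect and bit-level
compatibility with BCI2000 is not claimed or tested.
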