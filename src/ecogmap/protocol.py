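"""Binary wire protocol for block-wise neural signal streaming.

The stream carries a short handshake describing the signal and the packed
per-sample state vector (``SignalProperties`` + ``StateList``), then one
signal/state packet per sample block, plus request/response envelopes for a
multi-client command broker. The byte layout is documented normatively in
``docs/wire_format.md``: little-endian throughout, strings as uint16 length +
UTF-8, one descriptor byte per packet, packets self-delimiting so that they
can be concatenated back-to-back on any reliable byte stream.

Descriptor bytes::

    1  SignalProperties
    2  StateList
    3  SignalBlock  (signal payload followed inline by the state-vector section)
    4  StateVector  (standalone; requires a StateList context to decode)
    5  Command
    6  Response
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .exceptions import ConfigError, IncompletePacketError, ProtocolError

DESC_SIGNAL_PROPERTIES = 1
DESC_STATE_LIST = 2
DESC_SIGNAL_BLOCK = 3
DESC_STATE_VECTOR = 4
DESC_COMMAND = 5
DESC_RESPONSE = 6

#: value-type byte of the signal payload
VTYPE_FLOAT32 = 0
VTYPE_FLOAT64 = 1

_VTYPE_DTYPE = {VTYPE_FLOAT32: np.dtype("<f4"), VTYPE_FLOAT64: np.dtype("<f8")}


# ---------------------------------------------------------------------------
# packet types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalProperties:
    """Dimensionality and rate of the signal carried by a stream."""

    n_channels: int
    n_elements: int
    sampling_rate_hz: float
    channel_labels: tuple[str, ...]
    units: str = "uV"

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ConfigError("n_channels must be a positive count")
        if self.n_elements < 1:
            raise ConfigError("n_elements must be a positive count")
        if not self.sampling_rate_hz > 0:
            raise ConfigError("sampling_rate_hz must be > 0")
        if len(self.channel_labels) != self.n_channels:
            raise ConfigError(
                "channel_labels: expected %d labels, got %d"
                % (self.n_channels, len(self.channel_labels))
            )
        if any(not lab for lab in self.channel_labels):
            raise ConfigError("channel_labels: labels must be non-empty")
        if len(set(self.channel_labels)) != self.n_channels:
            raise ConfigError("channel_labels: labels must be unique")


@dataclass(frozen=True)
class StateDefinition:
    """One named integer state and its position in the packed state vector."""

    name: str
    bit_width: int
    byte_offset: int
    bit_offset: int = 0

    def validate(self) -> None:
        if not 1 <= self.bit_width <= 32:
            raise ConfigError(f"state {self.name!r}: bit_width must be in [1, 32]")
        if self.byte_offset < 0:
            raise ConfigError(f"state {self.name!r}: byte_offset must be >= 0")
        if not 0 <= self.bit_offset <= 7:
            raise ConfigError(f"state {self.name!r}: bit_offset must be in [0, 7]")

    @property
    def first_bit(self) -> int:
        return self.byte_offset * 8 + self.bit_offset


@dataclass(frozen=True)
class StateList:
    """Ordered collection of state definitions governing a stream."""

    states: tuple[StateDefinition, ...] = ()

    def validate(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ConfigError("state names must be unique")
        spans: list[tuple[int, int, str]] = []
        for s in self.states:
            s.validate()
            spans.append((s.first_bit, s.first_bit + s.bit_width, s.name))
        spans.sort()
        for (a0, a1, an), (b0, b1, bn) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ConfigError(f"states {an!r} and {bn!r} overlap in the packed vector")

    @property
    def bytes_per_sample(self) -> int:
        if not self.states:
            return 0
        last = max(s.first_bit + s.bit_width for s in self.states)
        return (last + 7) // 8


class SignalBlock:
    """One sample block: channels x n_elements values plus per-sample states.

    ``values`` is channels-major; ``states`` maps state name to an unsigned
    integer vector of length ``n_elements``.
    """

    __slots__ = ("block_index", "values", "states")

    def __init__(
        self,
        block_index: int,
        values: np.ndarray,
        states: Mapping[str, np.ndarray] | None = None,
    ):
        self.block_index = int(block_index)
        self.values = np.atleast_2d(np.asarray(values, dtype=np.float64))
        self.states = {k: np.asarray(v, dtype=np.uint32) for k, v in (states or {}).items()}
        if self.block_index < 0:
            raise ConfigError("block_index must be non-negative")
        for name, vec in self.states.items():
            if vec.shape != (self.n_elements,):
                raise ConfigError(
                    f"state {name!r}: expected {self.n_elements} per-sample values"
                )

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_elements(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalBlock):
            return NotImplemented
        return (
            self.block_index == other.block_index
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values)
            and self.states.keys() == other.states.keys()
            and all(np.array_equal(self.states[k], other.states[k]) for k in self.states)
        )

    def __repr__(self) -> str:
        return (
            f"SignalBlock(index={self.block_index}, "
            f"{self.n_channels}x{self.n_elements}, states={sorted(self.states)})"
        )


@dataclass(frozen=True)
class StateVector:
    """Standalone per-sample state packet (descriptor 4)."""

    values: Mapping[str, np.ndarray]
    n_elements: int

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StateVector):
            return NotImplemented
        return (
            self.n_elements == other.n_elements
            and self.values.keys() == other.values.keys()
            and all(np.array_equal(self.values[k], other.values[k]) for k in self.values)
        )


@dataclass(frozen=True)
class CommandEnvelope:
    """A queued command from one client; the broker serializes execution."""

    client_id: str
    text: str


@dataclass(frozen=True)
class CommandResponse:
    """Response routed back to the client that issued the command."""

    client_id: str
    status: str  # "ok" | "error"
    payload: str = ""


Packet = (
    SignalProperties | StateList | SignalBlock | StateVector | CommandEnvelope | CommandResponse
)


# ---------------------------------------------------------------------------
# state-vector bit packing
# ---------------------------------------------------------------------------

def pack_states(
    values: Mapping[str, np.ndarray], state_list: StateList, n_elements: int
) -> bytes:
    """Pack named per-sample state values into the declared bit layout."""
    state_list.validate()
    bps = state_list.bytes_per_sample
    if bps == 0:
        return b""
    samples = [0] * n_elements
    for sdef in state_list.states:
        vec = values.get(sdef.name)
        if vec is None:
            continue  # absent state packs as zero
        vec = np.asarray(vec)
        if vec.shape != (n_elements,):
            raise ProtocolError(f"state {sdef.name!r}: wrong length")
        limit = 1 << sdef.bit_width
        shift = sdef.first_bit
        for i, v in enumerate(vec.tolist()):
            v = int(v)
            if not 0 <= v < limit:
                raise ProtocolError(
                    f"state {sdef.name!r}: value {v} does not fit bit_width {sdef.bit_width}"
                )
            samples[i] |= v << shift
    out = bytearray(n_elements * bps)
    for i, s in enumerate(samples):
        out[i * bps : (i + 1) * bps] = s.to_bytes(bps, "little")
    return bytes(out)


def unpack_states(
    data: bytes, state_list: StateList, n_elements: int
) -> dict[str, np.ndarray]:
    """Inverse of :func:`pack_states`."""
    bps = state_list.bytes_per_sample
    if len(data) != n_elements * bps:
        raise ProtocolError("state-vector payload has the wrong length")
    out = {s.name: np.zeros(n_elements, dtype=np.uint32) for s in state_list.states}
    if bps == 0:
        return out
    ints = [int.from_bytes(data[i * bps : (i + 1) * bps], "little") for i in range(n_elements)]
    for sdef in state_list.states:
        mask = (1 << sdef.bit_width) - 1
        shift = sdef.first_bit
        vec = out[sdef.name]
        for i, s in enumerate(ints):
            vec[i] = (s >> shift) & mask
    return out


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _enc_str(s: str) -> bytes:
    raw = s.encode("utf-8")
    if len(raw) > 0xFFFF:
        raise ProtocolError("string too long for uint16 length prefix")
    return struct.pack("<H", len(raw)) + raw


def _enc_statevec_section(
    states: Mapping[str, np.ndarray], state_list: StateList | None, n_elements: int
) -> bytes:
    sl = state_list if state_list is not None else StateList()
    if states and state_list is None:
        raise ProtocolError("encoding a block with states requires a StateList context")
    packed = pack_states(states, sl, n_elements)
    return struct.pack("<IH", n_elements, sl.bytes_per_sample) + packed


def encode_packet(
    packet: Packet,
    state_list: StateList | None = None,
    value_type: int = VTYPE_FLOAT32,
) -> bytes:
    """Encode one packet into its self-delimiting byte form.

    ``state_list`` supplies the packing layout when ``packet`` carries
    per-sample states (SignalBlock / StateVector). Deterministic: the same
    packet always yields identical bytes.
    """
    if isinstance(packet, SignalProperties):
        packet.validate()
        out = bytearray([DESC_SIGNAL_PROPERTIES])
        out += struct.pack("<IId", packet.n_channels, packet.n_elements, packet.sampling_rate_hz)
        out += _enc_str(packet.units)
        for lab in packet.channel_labels:
            out += _enc_str(lab)
        return bytes(out)

    if isinstance(packet, StateList):
        packet.validate()
        out = bytearray([DESC_STATE_LIST])
        out += struct.pack("<H", len(packet.states))
        for s in packet.states:
            out += _enc_str(s.name)
            out += struct.pack("<BHB", s.bit_width, s.byte_offset, s.bit_offset)
        return bytes(out)

    if isinstance(packet, SignalBlock):
        if value_type not in _VTYPE_DTYPE:
            raise ProtocolError(f"unknown value type {value_type}")
        dtype = _VTYPE_DTYPE[value_type]
        out = bytearray([DESC_SIGNAL_BLOCK, value_type])
        out += struct.pack("<II", packet.n_channels, packet.n_elements)
        out += np.ascontiguousarray(packet.values, dtype=dtype).tobytes()
        out += _enc_statevec_section(packet.states, state_list, packet.n_elements)
        return bytes(out)

    if isinstance(packet, StateVector):
        out = bytearray([DESC_STATE_VECTOR])
        out += _enc_statevec_section(packet.values, state_list, packet.n_elements)
        return bytes(out)

    if isinstance(packet, CommandEnvelope):
        return bytes([DESC_COMMAND]) + _enc_str(packet.client_id) + _enc_str(packet.text)

    if isinstance(packet, CommandResponse):
        if packet.status not in ("ok", "error"):
            raise ConfigError("response status must be 'ok' or 'error'")
        code = 0 if packet.status == "ok" else 1
        return (
            bytes([DESC_RESPONSE])
            + _enc_str(packet.client_id)
            + struct.pack("<B", code)
            + _enc_str(packet.payload)
        )

    raise ProtocolError(f"cannot encode object of type {type(packet).__name__}")


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

class _Cursor:
    __slots__ = ("buf", "pos")

    def __init__(self, buf: bytes):
        self.buf = buf
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise IncompletePacketError("truncated packet")
        out = self.buf[self.pos : self.pos + n]
        self.pos += n
        return out

    def unpack(self, fmt: str):
        return struct.unpack(fmt, self.take(struct.calcsize(fmt)))

    def take_str(self) -> str:
        (n,) = self.unpack("<H")
        return self.take(n).decode("utf-8")


def _dec_statevec_section(cur: _Cursor, state_list: StateList | None):
    n_elements, bps = cur.unpack("<IH")
    payload = cur.take(n_elements * bps)
    if bps == 0:
        return {}, n_elements
    if state_list is None:
        raise ProtocolError("decoding a non-empty state vector requires a StateList context")
    if state_list.bytes_per_sample != bps:
        raise ProtocolError(
            "state-vector bytes-per-sample %d does not match the StateList (%d)"
            % (bps, state_list.bytes_per_sample)
        )
    return unpack_states(payload, state_list, n_elements), n_elements


def decode_packet(
    data: bytes,
    state_list: StateList | None = None,
    block_index: int = 0,
) -> tuple[Packet, bytes]:
    """Decode one packet from the head of ``data``.

    Returns the packet and the unconsumed byte suffix, so packets can be
    streamed back-to-back. Raises :class:`IncompletePacketError` when the
    buffer ends mid-packet and :class:`ProtocolError` on an unknown
    descriptor byte.
    """
    if not data:
        raise IncompletePacketError("empty buffer")
    cur = _Cursor(bytes(data))
    (desc,) = cur.unpack("<B")

    if desc == DESC_SIGNAL_PROPERTIES:
        n_ch, n_el, rate = cur.unpack("<IId")
        units = cur.take_str()
        labels = tuple(cur.take_str() for _ in range(n_ch))
        pkt: Packet = SignalProperties(n_ch, n_el, rate, labels, units)
    elif desc == DESC_STATE_LIST:
        (n_states,) = cur.unpack("<H")
        states = []
        for _ in range(n_states):
            name = cur.take_str()
            bw, byo, bio = cur.unpack("<BHB")
            states.append(StateDefinition(name, bw, byo, bio))
        pkt = StateList(tuple(states))
    elif desc == DESC_SIGNAL_BLOCK:
        (vtype,) = cur.unpack("<B")
        if vtype not in _VTYPE_DTYPE:
            raise ProtocolError(f"unknown signal value type {vtype}")
        dtype = _VTYPE_DTYPE[vtype]
        n_ch, n_el = cur.unpack("<II")
        raw = cur.take(n_ch * n_el * dtype.itemsize)
        values = np.frombuffer(raw, dtype=dtype).reshape(n_ch, n_el).astype(np.float64)
        states, sv_n = _dec_statevec_section(cur, state_list)
        if sv_n != n_el:
            raise ProtocolError("state-vector length does not match the signal block")
        pkt = SignalBlock(block_index, values, states)
    elif desc == DESC_STATE_VECTOR:
        states, n_el = _dec_statevec_section(cur, state_list)
        pkt = StateVector(states, n_el)
    elif desc == DESC_COMMAND:
        pkt = CommandEnvelope(cur.take_str(), cur.take_str())
    elif desc == DESC_RESPONSE:
        client = cur.take_str()
        (code,) = cur.unpack("<B")
        payload = cur.take_str()
        pkt = CommandResponse(client, "ok" if code == 0 else "error", payload)
    else:
        raise ProtocolError(f"unknown descriptor byte {desc}")

    return pkt, bytes(data[cur.pos :])


class StreamDecoder:
    """Incremental decoder over an arbitrarily fragmented byte stream.

    Buffers fragments until whole packets are available; tracks the stream's
    ``SignalProperties`` and ``StateList`` context so signal blocks can be
    decoded, and assigns ``block_index`` to signal blocks by arrival order
    (the wire carries no explicit index).
    """

    def __init__(self) -> None:
        self._buf = bytearray()
        self.properties: SignalProperties | None = None
        self.state_list: StateList | None = None
        self._next_block = 0

    def feed(self, data: bytes) -> list[Packet]:
        """Append bytes; return every packet completed by them, in order."""
        self._buf += data
        out: list[Packet] = []
        while self._buf:
            try:
                pkt, rest = decode_packet(
                    bytes(self._buf), self.state_list, block_index=self._next_block
                )
            except IncompletePacketError:
                break
            self._buf = bytearray(rest)
            if isinstance(pkt, SignalProperties):
                self.properties = pkt
            elif isinstance(pkt, StateList):
                self.state_list = pkt
            elif isinstance(pkt, SignalBlock):
                self._next_block += 1
            out.append(pkt)
        return out


# ---------------------------------------------------------------------------
# command broker
# ---------------------------------------------------------------------------

class CommandBroker:
    """Strict-FIFO serializer of commands from any number of clients.

    Commands are queued in arrival order and executed one at a time; each
    response carries the ``client_id`` of the request it answers, so a
    transport layer can route it back to the issuing client only. An executor
    failure produces an error-status response for that command and leaves
    every other queued command untouched.
    """

    def __init__(self) -> None:
        self._queue: list[CommandEnvelope] = []

    def submit(self, request: CommandEnvelope) -> None:
        self._queue.append(request)

    def __len__(self) -> int:
        return len(self._queue)

    def dispatch(self, executor: Callable[[str], str]) -> list[CommandResponse]:
        """Drain the queue through ``executor``; responses in execution order."""
        responses: list[CommandResponse] = []
        while self._queue:
            req = self._queue.pop(0)
            try:
                payload = executor(req.text)
                responses.append(CommandResponse(req.client_id, "ok", str(payload)))
            except Exception as exc:  # noqa: BLE001 - isolate executor faults
                responses.append(CommandResponse(req.client_id, "error", str(exc)))
        return responses


def broker_dispatch(
    queue: Iterable[CommandEnvelope],
    request: CommandEnvelope,
    executor: Callable[[str], str],
) -> tuple[list[CommandEnvelope], list[CommandResponse]]:
    """Functional form of the broker: enqueue ``request``, drain FIFO.

    Returns the (empty) queue state and the responses in execution order.
    """
    broker = CommandBroker()
    for env in queue:
        broker.submit(env)
    broker.submit(request)
    responses = broker.dispatch(executor)
    return [], responses
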