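"""Wire protocol: round-trips, stream re-segmentation, state packing, broker."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecogmap.exceptions import ConfigError, IncompletePacketError, ProtocolError
from ecogmap.protocol import (
    CommandBroker,
    CommandEnvelope,
    CommandResponse,
    SignalBlock,
    SignalProperties,
    StateDefinition,
    StateList,
    StreamDecoder,
    broker_dispatch,
    decode_packet,
    encode_packet,
    pack_states,
    unpack_states,
)

STATE_LIST = StateList(
    (
        StateDefinition("StimulusCode", bit_width=16, byte_offset=0, bit_offset=0),
        StateDefinition("Running", bit_width=1, byte_offset=2, bit_offset=0),
        StateDefinition("Flag3", bit_width=3, byte_offset=2, bit_offset=1),
    )
)


def make_block(rng, n_ch=4, n_el=16, index=0):
    values = np.round(rng.normal(size=(n_ch, n_el)).astype(np.float32), 3)
    states = {
        "StimulusCode": rng.integers(0, 2**16, n_el).astype(np.uint32),
        "Running": rng.integers(0, 2, n_el).astype(np.uint32),
        "Flag3": rng.integers(0, 8, n_el).astype(np.uint32),
    }
    return SignalBlock(index, values, states)


@pytest.mark.parametrize(
    "packet",
    [
        SignalProperties(2, 20, 1000.0, ("c1", "c2"), "uV"),
        STATE_LIST,
        CommandEnvelope("cliA", "Get System State"),
        CommandResponse("cliA", "error", "no such verb"),
    ],
    ids=["properties", "statelist", "command", "response"],
)
def test_roundtrip_identity(packet):
    encoded = encode_packet(packet)
    decoded, rest = decode_packet(encoded)
    assert decoded == packet
    assert rest == b""


def test_signal_block_roundtrip(rng):
    block = make_block(rng, index=3)
    encoded = encode_packet(block, STATE_LIST)
    decoded, rest = decode_packet(encoded, STATE_LIST, block_index=3)
    assert decoded == block
    assert rest == b""


def test_minimal_block_byte_length():
    """1 channel x 1 element, no states: descriptor + value-type + two uint32
    dims + one float32 + the empty state-vector header = 20 bytes."""
    block = SignalBlock(0, np.zeros((1, 1)))
    encoded = encode_packet(block, StateList())
    assert len(encoded) == 1 + 1 + 4 + 4 + 4 + 4 + 2


def test_standalone_state_vector_roundtrip(rng):
    from ecogmap.protocol import StateVector

    sv = StateVector(
        {
            "StimulusCode": rng.integers(0, 2**16, 12).astype(np.uint32),
            "Running": rng.integers(0, 2, 12).astype(np.uint32),
            "Flag3": rng.integers(0, 8, 12).astype(np.uint32),
        },
        12,
    )
    decoded, rest = decode_packet(encode_packet(sv, STATE_LIST), STATE_LIST)
    assert decoded == sv
    assert rest == b""


def test_stream_split_returns_remainder(rng):
    props = SignalProperties(1, 4, 500.0, ("a",))
    block = SignalBlock(0, np.ones((1, 4)))
    stream = encode_packet(props) + encode_packet(block, StateList())
    first, rest = decode_packet(stream, StateList())
    assert first == props
    assert rest == encode_packet(block, StateList())


def test_unknown_descriptor_names_byte():
    with pytest.raises(ProtocolError, match="250"):
        decode_packet(bytes([250, 0, 0]))


def test_truncated_payload_signals_incomplete():
    encoded = encode_packet(SignalProperties(2, 8, 250.0, ("x", "y")))
    with pytest.raises(IncompletePacketError):
        decode_packet(encoded[:-3])


def test_invalid_properties_rejected_before_encoding():
    bad = SignalProperties(2, 8, 250.0, ("only-one",))
    with pytest.raises(ConfigError, match="channel_labels"):
        encode_packet(bad)


def test_overlapping_states_rejected():
    overlapping = StateList(
        (StateDefinition("a", 8, 0, 0), StateDefinition("b", 4, 0, 4))
    )
    with pytest.raises(ConfigError, match="overlap"):
        overlapping.validate()


def test_state_value_must_fit_bit_width():
    sl = StateList((StateDefinition("s", 2, 0, 0),))
    with pytest.raises(ProtocolError, match="bit_width"):
        pack_states({"s": np.array([4])}, sl, 1)


# -- property tests ---------------------------------------------------------

packet_dims = st.tuples(
    st.integers(1, 64),  # channels
    st.integers(1, 256),  # elements
    st.integers(0, 8),  # states
)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(dims=packet_dims, seed=st.integers(0, 2**20))
def test_roundtrip_randomized_blocks(dims, seed):
    """encode . decode is the identity for random valid signal blocks."""
    n_ch, n_el, n_states = dims
    rng = np.random.default_rng(seed)
    defs = tuple(
        StateDefinition(f"s{i}", bit_width=int(rng.integers(1, 17)), byte_offset=3 * i)
        for i in range(n_states)
    )
    sl = StateList(defs)
    states = {
        d.name: rng.integers(0, 2**d.bit_width, n_el).astype(np.uint32) for d in defs
    }
    block = SignalBlock(0, rng.normal(size=(n_ch, n_el)).astype(np.float32), states)
    decoded, rest = decode_packet(encode_packet(block, sl), sl)
    assert rest == b""
    assert decoded == block


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20), data=st.data())
def test_stream_resegmentation(seed, data):
    """Splitting a multi-packet stream at arbitrary boundaries and feeding the
    fragments recovers the same packet sequence with indices by arrival."""
    rng = np.random.default_rng(seed)
    packets = [
        SignalProperties(3, 8, 1000.0, ("a", "b", "c")),
        STATE_LIST,
        make_block(rng, 3, 8, 0),
        make_block(rng, 3, 8, 1),
        CommandResponse("x", "ok", "done"),
    ]
    stream = b"".join(encode_packet(p, STATE_LIST) for p in packets)
    n_cuts = data.draw(st.integers(0, 6))
    cuts = sorted(data.draw(st.integers(0, len(stream))) for _ in range(n_cuts))
    decoder = StreamDecoder()
    received = []
    prev = 0
    for cut in cuts + [len(stream)]:
        received.extend(decoder.feed(stream[prev:cut]))
        prev = cut
    assert received == packets


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20))
def test_state_packing_is_identity(seed):
    """pack-then-unpack recovers every state; no bleed across bit boundaries."""
    rng = np.random.default_rng(seed)
    widths = rng.integers(1, 33, size=4)
    offset = 0
    defs = []
    for i, w in enumerate(widths):
        defs.append(StateDefinition(f"s{i}", int(w), offset // 8, offset % 8))
        offset += int(w)
    sl = StateList(tuple(defs))
    n = 32
    values = {
        d.name: rng.integers(0, 2**d.bit_width, n, dtype=np.uint64).astype(np.uint32)
        for d in defs
    }
    recovered = unpack_states(pack_states(values, sl, n), sl, n)
    for d in defs:
        np.testing.assert_array_equal(recovered[d.name], values[d.name])


# -- broker -----------------------------------------------------------------

def test_broker_fifo_and_routing():
    broker = CommandBroker()
    for client, text in [("A", "x"), ("B", "y"), ("A", "z")]:
        broker.submit(CommandEnvelope(client, text))
    responses = broker.dispatch(lambda cmd: f"echo:{cmd}")
    assert [r.payload for r in responses] == ["echo:x", "echo:y", "echo:z"]
    assert [r.client_id for r in responses if r.client_id == "A"] == ["A", "A"]
    a_payloads = [r.payload for r in responses if r.client_id == "A"]
    assert a_payloads == ["echo:x", "echo:z"]


def test_broker_executor_failure_is_isolated():
    broker = CommandBroker()
    for client, text in [("A", "x"), ("B", "y"), ("A", "z")]:
        broker.submit(CommandEnvelope(client, text))

    def executor(cmd):
        if cmd == "y":
            raise RuntimeError("boom")
        return "ok:" + cmd

    responses = broker.dispatch(executor)
    by_client = {}
    for r in responses:
        by_client.setdefault(r.client_id, []).append(r)
    assert [r.status for r in by_client["B"]] == ["error"]
    assert [r.status for r in by_client["A"]] == ["ok", "ok"]


def test_broker_hundred_clients_execute_in_arrival_order(rng):
    """Interleaved submissions from 100 clients execute in arrival order,
    matching a single-threaded reference replay."""
    broker = CommandBroker()
    order = rng.permutation(100)
    arrival = [(f"client{i}", f"cmd{i}") for i in order]
    for client, text in arrival:
        broker.submit(CommandEnvelope(client, text))
    executed = []
    responses = broker.dispatch(lambda cmd: executed.append(cmd) or cmd)
    assert executed == [text for _, text in arrival]  # reference replay
    assert [(r.client_id, r.payload) for r in responses] == arrival


def test_broker_dispatch_functional_form():
    queue = [CommandEnvelope("A", "first")]
    new_queue, responses = broker_dispatch(queue, CommandEnvelope("B", "second"), str.upper)
    assert new_queue == []
    assert [(r.client_id, r.payload) for r in responses] == [("A", "FIRST"), ("B", "SECOND")]
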