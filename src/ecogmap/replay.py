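"""Session replay over the wire protocol, and the mapping client.

The replay server stands in for a live acquisition system: it serves a
stored session file over TCP in the block-wise binary protocol, in real,
scaled, or as-fast-as-possible time. Every client receives the identical
packet sequence — ``SignalProperties`` + ``StateList`` once per connection,
then one signal/state packet per sample block — and may interleave command
packets, which a strict-FIFO broker executes one at a time with responses
routed back to the issuing client. With ``tap="features"`` the server runs
the preprocessing chain and Burg estimator itself and streams the feature
series; with ``tap="raw"`` the client runs the full chain locally. Either
way the resulting map equals the offline pipeline on the same file: pacing
(``speed``) is wall-clock only and cannot affect results.
"""

from __future__ import annotations

import asyncio
import logging
from dataclasses import dataclass, field

import numpy as np

from .dsp import Decimator, StreamingCascade, common_average_reference
from .exceptions import ConfigError, ProtocolError
from .mapping import IncrementalMapper, detect_trial_onsets, extract_trial_tensor
from .pipeline import PipelineConfig, extract_features, result_to_record
from .protocol import (
    CommandBroker,
    CommandEnvelope,
    CommandResponse,
    SignalBlock,
    SignalProperties,
    StateDefinition,
    StateList,
    StreamDecoder,
    encode_packet,
)
from .records import MapRecord
from .simulate import SimSession
from .spectral import FeatureSeries, StreamingBandPower

logger = logging.getLogger(__name__)

STIMULUS_STATE = StateDefinition("StimulusCode", bit_width=16, byte_offset=0, bit_offset=0)

RAW_UNITS = "uV"
FEATURE_UNITS = "log-bandpower"
END_OF_STREAM = "end-of-stream"


@dataclass
class ReplayConfig:
    """Replay parameters: block size (ms), which tap to emulate, and the
    wall-clock speed multiplier (0 = as fast as possible)."""

    block_ms: float = 20.0
    tap: str = "raw"
    speed: float = 0.0
    host: str = "127.0.0.1"
    port: int = 0

    def validate(self) -> None:
        if self.tap not in ("raw", "features"):
            raise ConfigError("tap must be 'raw' or 'features'")
        if self.block_ms <= 0:
            raise ConfigError("block_ms must be > 0")
        if self.speed < 0:
            raise ConfigError("speed must be >= 0")


def _session_packets(
    session: SimSession, config: ReplayConfig, pipeline: PipelineConfig | None
) -> tuple[list[bytes], float]:
    """Pre-encode the full packet sequence once; returns (packets, block_s).

    Identical bytes go to every client, which makes the broadcast contract
    (byte-identical streams) trivially true.
    """
    state_list = StateList((STIMULUS_STATE,))
    if config.tap == "raw":
        fs = session.config.fs_native_hz
        block_n = config.block_ms * fs / 1000.0
        if abs(block_n - round(block_n)) > 1e-9 or round(block_n) < 1:
            raise ConfigError("block_ms must be a whole number of samples at the tap rate")
        block_n = int(round(block_n))
        props = SignalProperties(
            session.signal.shape[0], block_n, fs, session.channel_labels, RAW_UNITS
        )
        sig, st = session.signal, session.state
    else:
        if pipeline is None:
            raise ConfigError("tap='features' requires a pipeline config")
        feats = extract_features(session, pipeline)
        block_n = 1  # one feature step per block
        props = SignalProperties(
            feats.values.shape[0],
            1,
            1000.0 / pipeline.burg.slide_ms,
            session.channel_labels,
            FEATURE_UNITS,
        )
        sig, st = feats.values, feats.state

    packets = [encode_packet(props), encode_packet(state_list)]
    n = sig.shape[1]
    for i, start in enumerate(range(0, n, block_n)):
        block = SignalBlock(
            i,
            sig[:, start : start + block_n],
            {"StimulusCode": st[start : start + block_n]},
        )
        packets.append(encode_packet(block, state_list))
    return packets, block_n / props.sampling_rate_hz


class ReplayServer:
    """Asyncio TCP replay service; supports any number of concurrent clients.

    Command verbs (opaque text on the wire, FIFO-executed): ``get-state``,
    ``start``, ``stop``, ``set-parameter <name> <value>``.
    """

    def __init__(
        self,
        session: SimSession,
        config: ReplayConfig | None = None,
        pipeline: PipelineConfig | None = None,
    ):
        self.config = config or ReplayConfig()
        self.config.validate()
        self.session = session
        self._packets, self._block_s = _session_packets(session, self.config, pipeline)
        self._broker = CommandBroker()
        self._broker_lock = asyncio.Lock()
        self._parameters: dict[str, str] = {}
        self._system_state = "Running"
        self._server: asyncio.AbstractServer | None = None

    # -- command execution --------------------------------------------------

    def _execute(self, text: str) -> str:
        parts = text.strip().split()
        if not parts:
            raise ValueError("empty command")
        verb = parts[0].lower()
        if verb == "get-state":
            return self._system_state
        if verb == "start":
            self._system_state = "Running"
            return "ok"
        if verb == "stop":
            self._system_state = "Suspended"
            return "ok"
        if verb == "set-parameter":
            if len(parts) < 3:
                raise ValueError("set-parameter needs a name and a value")
            self._parameters[parts[1]] = " ".join(parts[2:])
            return "ok"
        raise ValueError(f"unknown command verb {verb!r}")

    # -- lifecycle ----------------------------------------------------------

    async def start(self) -> None:
        self._server = await asyncio.start_server(
            self._handle_client, self.config.host, self.config.port
        )

    @property
    def port(self) -> int:
        assert self._server is not None
        return self._server.sockets[0].getsockname()[1]

    async def stop(self) -> None:
        if self._server is not None:
            self._server.close()
            await self._server.wait_closed()

    async def serve_forever(self) -> None:
        await self.start()
        assert self._server is not None
        async with self._server:
            await self._server.serve_forever()

    # -- per-connection handling --------------------------------------------

    async def _handle_client(self, reader: asyncio.StreamReader, writer: asyncio.StreamWriter):
        out: asyncio.Queue[bytes | None] = asyncio.Queue()

        async def drain_writer():
            while True:
                item = await out.get()
                if item is None:
                    break
                writer.write(item)
                await writer.drain()

        async def read_commands():
            decoder = StreamDecoder()
            try:
                while True:
                    data = await reader.read(4096)
                    if not data:
                        return
                    for pkt in decoder.feed(data):
                        if isinstance(pkt, CommandEnvelope):
                            async with self._broker_lock:
                                self._broker.submit(pkt)
                                responses = self._broker.dispatch(self._execute)
                            for resp in responses:
                                await out.put(encode_packet(resp))
            except (ProtocolError, ConnectionError) as exc:
                logger.warning("closing client after protocol violation: %s", exc)
                writer.close()

        async def stream_blocks():
            pace = self._block_s / self.config.speed if self.config.speed > 0 else 0.0
            for pkt in self._packets:
                await out.put(pkt)
                if pace:
                    await asyncio.sleep(pace)
            await out.put(
                encode_packet(CommandResponse("server", "ok", END_OF_STREAM))
            )

        writer_task = asyncio.create_task(drain_writer())
        reader_task = asyncio.create_task(read_commands())
        try:
            await stream_blocks()
            # wait for the client to finish issuing commands (it closes, or at
            # least half-closes, once it has seen the end-of-stream marker), so
            # every late response is flushed before the writer stops
            await reader_task
            await out.put(None)
            await writer_task
        except ConnectionError:
            pass
        finally:
            reader_task.cancel()
            writer_task.cancel()
            try:
                writer.close()
                await writer.wait_closed()
            except ConnectionError:
                pass


# ---------------------------------------------------------------------------
# mapping client
# ---------------------------------------------------------------------------

@dataclass
class ClientResult:
    record: MapRecord
    features: FeatureSeries
    responses: list[CommandResponse] = field(default_factory=list)


class _RawTapPipeline:
    """Client-side block-wise chain for the raw tap: CAR -> cascade ->
    decimate -> streaming Burg band power."""

    def __init__(self, pipeline: PipelineConfig, n_channels: int):
        self.pipeline = pipeline
        self.cascade = StreamingCascade(pipeline.cascade, n_channels)
        self.decimator = Decimator(pipeline.cascade)
        self.extractor = StreamingBandPower(pipeline.burg, n_channels)
        self.car_arg = pipeline.car_arg

    def feed(self, block: SignalBlock):
        x = block.values
        if self.car_arg is not False:
            x = common_average_reference(x, self.car_arg)
        y = self.cascade.process(x)
        dec, dec_state = self.decimator.process(y, block.states.get("StimulusCode"))
        return self.extractor.feed(dec, dec_state)


async def run_mapping_client_async(
    host: str, port: int, pipeline: PipelineConfig, commands: list[str] | None = None,
    client_id: str = "mapper",
) -> ClientResult:
    """Connect, consume the stream, and map.

    For a raw tap the full preprocessing chain runs client-side block by
    block; for a feature tap the streamed values are used directly. Trials
    are delivered to an incremental mapper as they complete, and the final
    record equals the offline pipeline on the same session (within float32
    transport rounding). A dropped connection yields a truncation-flagged
    partial record.
    """
    pipeline.validate()
    reader, writer = await asyncio.open_connection(host, port)
    decoder = StreamDecoder()
    props: SignalProperties | None = None
    chain: _RawTapPipeline | None = None
    values: list[np.ndarray] = []
    states: list[np.ndarray] = []
    responses: list[CommandResponse] = []
    complete = False
    pending = list(commands or [])

    half_closed = False
    try:
        while True:
            data = await reader.read(1 << 16)
            if not data:
                break
            for pkt in decoder.feed(data):
                if isinstance(pkt, SignalProperties):
                    props = pkt
                    if pkt.units == RAW_UNITS:
                        chain = _RawTapPipeline(pipeline, pkt.n_channels)
                        if pkt.sampling_rate_hz != pipeline.cascade.fs_native_hz:
                            raise ConfigError("stream rate does not match the pipeline config")
                    elif pkt.units == FEATURE_UNITS:
                        chain = None
                        if abs(pkt.sampling_rate_hz - 1000.0 / pipeline.burg.slide_ms) > 1e-9:
                            raise ConfigError("feature rate does not match the pipeline config")
                    else:
                        raise ProtocolError(f"unknown tap units {pkt.units!r}")
                    # interleave any queued commands once the handshake arrives
                    for text in pending:
                        writer.write(encode_packet(CommandEnvelope(client_id, text)))
                    await writer.drain()
                    pending = []
                elif isinstance(pkt, SignalBlock):
                    if chain is not None:
                        vals, _, st = chain.feed(pkt)
                        if vals.shape[1]:
                            values.append(vals)
                            states.append(st)
                    else:
                        values.append(pkt.values)
                        states.append(pkt.states.get(
                            "StimulusCode", np.zeros(pkt.n_elements, dtype=np.uint32)))
                elif isinstance(pkt, CommandResponse):
                    if pkt.client_id == "server" and pkt.payload == END_OF_STREAM:
                        complete = True
                        if not half_closed:
                            writer.write_eof()  # prompts the server to close
                            half_closed = True
                    else:
                        responses.append(pkt)
    finally:
        writer.close()
        try:
            await writer.wait_closed()
        except ConnectionError:
            pass

    if not values:
        raise ProtocolError("stream carried no signal blocks")
    feat_values = np.concatenate(values, axis=1)
    feat_state = np.concatenate(states)
    burg = pipeline.burg
    n_steps = feat_values.shape[1]
    step_times = (np.arange(n_steps) * burg.slide_samples + burg.window_samples - 1) / burg.fs_proc_hz
    features = FeatureSeries(feat_values, step_times, feat_state, burg)

    onsets = detect_trial_onsets(feat_state)
    tensor = extract_trial_tensor(features, onsets, pipeline.mapping)
    mapper = IncrementalMapper(pipeline.mapping, tensor.bin_times_ms, burg.slide_ms)
    for trial in range(tensor.n_trials):
        mapper.add_trial(tensor.values[trial], int(tensor.stimulus_codes[trial]))
        logger.debug("trial %d/%d mapped", mapper.trial_count, tensor.n_trials)
    assert mapper.result is not None
    labels = (
        props.channel_labels
        if props is not None
        else tuple(f"CH{i + 1:02d}" for i in range(feat_values.shape[0]))
    )
    record = result_to_record(mapper.result, labels, pipeline, truncated=not complete)
    return ClientResult(record=record, features=features, responses=responses)


def run_mapping_client(
    host: str, port: int, pipeline: PipelineConfig, commands: list[str] | None = None
) -> ClientResult:
    """Synchronous wrapper around :func:`run_mapping_client_async`."""
    return asyncio.run(run_mapping_client_async(host, port, pipeline, commands))
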