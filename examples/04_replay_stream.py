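"""Stream a session through the replay server and map it client-side.

Starts an in-process TCP replay server (raw tap), runs the mapping client
against it — the client applies CAR, the cascade, decimation and the Burg
estimator block by block, updates the map after every trial — and checks
the streamed record against the offline pipeline on the same session.
"""

import asyncio

import numpy as np

from ecogmap import PipelineConfig, SimConfig, generate_session
from ecogmap.pipeline import run_offline
from ecogmap.replay import ReplayConfig, ReplayServer, run_mapping_client_async

session = generate_session(SimConfig(n_channels=8, n_trials=6, modulated_channels=(0, 2), seed=7))
pipe = PipelineConfig(car="all")


async def main():
    server = ReplayServer(session, ReplayConfig(tap="raw", speed=0.0))
    await server.start()
    print(f"replay server on port {server.port}: raw tap, 20 ms blocks, unpaced")
    try:
        client = await run_mapping_client_async(
            "127.0.0.1", server.port, pipe, commands=["get-state"]
        )
    finally:
        await server.stop()
    return client


client = asyncio.run(main())
record = client.record
print(f"server state response: {client.responses[0].payload!r}")
print(f"streamed record: {record.n_trials} trials, "
      f"{record.significant.sum()} significant bins, truncated={record.truncated}")

offline = run_offline(session, pipe).result
same_mask = np.array_equal(record.significant, offline.significant)
dz = np.nanmax(np.abs(record.z_display - offline.z_display))
print(f"streamed vs offline: masks equal = {same_mask}, max |dz| = {dz:.2e}")
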