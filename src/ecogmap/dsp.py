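"""Block-wise preprocessing chain: common average reference, Butterworth
cascade, decimation to the processing rate.

The cascade follows the clinical high-gamma configuration: a 4th-order
low-pass at 110 Hz, a 2nd-order high-pass at 70 Hz, and a 4th-order notch
(band-stop) centred on the mains frequency, all realized as second-order
sections from bilinear-transform Butterworth designs, so the -3 dB points
land exactly on the printed cutoffs. Filters carry per-channel state across
sample blocks: processing a signal block-by-block is numerically identical
to one offline call.

Decimation is plain sample-picking with a phase counter — the 110 Hz
low-pass is the anti-alias filter for the factor-2 drop from 1 kHz to the
500 Hz processing rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigError


@dataclass(frozen=True)
class CascadeSpec:
    """Cascade parameters (Hz). ``notch_bw_hz`` is the -3 dB band-stop width;
    the notch is realized as a Butterworth band-stop at
    ``notch_hz ± notch_bw_hz/2``."""

    fs_native_hz: float = 1000.0
    lowpass_order: int = 4
    lowpass_hz: float = 110.0
    highpass_order: int = 2
    highpass_hz: float = 70.0
    notch_order: int = 4
    notch_hz: float = 60.0
    notch_bw_hz: float = 4.0
    decim_target_hz: float = 500.0

    def validate(self) -> None:
        nyq = self.fs_native_hz / 2.0
        for name in ("lowpass_hz", "highpass_hz"):
            if not 0 < getattr(self, name) < nyq:
                raise ConfigError(f"{name} must lie in (0, fs_native/2)")
        if not 0 < self.notch_hz - self.notch_bw_hz / 2 < self.notch_hz + self.notch_bw_hz / 2 < nyq:
            raise ConfigError("notch band must lie in (0, fs_native/2)")
        if self.notch_order % 2:
            raise ConfigError("notch_order must be even (band-stop doubles the prototype order)")
        if self.decim_target_hz <= 0 or self.fs_native_hz % self.decim_target_hz != 0:
            raise ConfigError("fs_native_hz must be an integer multiple of decim_target_hz")

    @property
    def decim_factor(self) -> int:
        return int(round(self.fs_native_hz / self.decim_target_hz))


def _butter_sos(order: int, Wn, btype: str, fs: float) -> np.ndarray:
    return sps.butter(order, Wn, btype=btype, fs=fs, output="sos")


def design_cascade(spec: CascadeSpec) -> dict[str, np.ndarray]:
    """Second-order-section coefficients per cascade section.

    Returns ``{"lowpass": sos, "highpass": sos, "notch": sos}``; every
    section is stable (all poles strictly inside the unit circle — asserted).
    """
    spec.validate()
    lo = spec.notch_hz - spec.notch_bw_hz / 2
    hi = spec.notch_hz + spec.notch_bw_hz / 2
    sections = {
        "lowpass": _butter_sos(spec.lowpass_order, spec.lowpass_hz, "lowpass", spec.fs_native_hz),
        "highpass": _butter_sos(spec.highpass_order, spec.highpass_hz, "highpass", spec.fs_native_hz),
        "notch": _butter_sos(spec.notch_order // 2, [lo, hi], "bandstop", spec.fs_native_hz),
    }
    for name, sos in sections.items():
        _, poles, _ = sps.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0):
            raise ConfigError(f"{name} section is unstable at fs={spec.fs_native_hz}")
    return sections


def cascade_sos(spec: CascadeSpec) -> np.ndarray:
    """All sections stacked in application order (LP -> HP -> notch)."""
    d = design_cascade(spec)
    return np.vstack([d["lowpass"], d["highpass"], d["notch"]])


def export_sos_csv(spec: CascadeSpec, path) -> None:
    """Write every section's second-order-section coefficients to CSV for
    inspection (section, row, b0, b1, b2, a0, a1, a2)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["section", "row", "b0", "b1", "b2", "a0", "a1", "a2"])
        for name, sos in design_cascade(spec).items():
            for i, row in enumerate(sos):
                writer.writerow([name, i] + [repr(float(v)) for v in row])


def common_average_reference(
    values: np.ndarray, included: np.ndarray | list[int] | None = None
) -> np.ndarray:
    """Subtract the cross-channel mean over ``included`` channels from each
    included channel; excluded channels pass through unchanged."""
    values = np.asarray(values, dtype=np.float64)
    n_ch = values.shape[0]
    idx = np.arange(n_ch) if included is None else np.asarray(sorted(included), dtype=int)
    if len(idx) < 2:
        raise ConfigError("common average reference requires >= 2 included channels")
    if idx.min() < 0 or idx.max() >= n_ch:
        raise ConfigError("CAR channel index out of range")
    out = values.copy()
    out[idx] -= values[idx].mean(axis=0, keepdims=True)
    return out


class StreamingCascade:
    """The full IIR cascade with per-channel filter memory across blocks."""

    def __init__(self, spec: CascadeSpec, n_channels: int):
        spec.validate()
        self.spec = spec
        self.n_channels = n_channels
        self.sos = cascade_sos(spec)
        self._zi = np.zeros((self.sos.shape[0], n_channels, 2))

    def process(self, block: np.ndarray) -> np.ndarray:
        """Filter one channels x samples block, continuing from prior state."""
        block = np.atleast_2d(np.asarray(block, dtype=np.float64))
        if block.shape[0] != self.n_channels:
            raise ConfigError(
                f"block has {block.shape[0]} channels, cascade expects {self.n_channels}"
            )
        out, self._zi = sps.sosfilt(self.sos, block, axis=1, zi=self._zi)
        return out


class Decimator:
    """Integer-factor sample picker with phase continuity across blocks."""

    def __init__(self, spec: CascadeSpec):
        spec.validate()
        self.factor = spec.decim_factor
        self._phase = 0  # samples until the next kept sample

    def process(
        self, block: np.ndarray, state: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Keep every k-th sample of a channels x samples block (and of the
        per-sample state vector, if given)."""
        block = np.atleast_2d(np.asarray(block))
        n = block.shape[1]
        kept = np.arange(self._phase, n, self.factor)
        self._phase = (self._phase - n) % self.factor
        out_state = None if state is None else np.asarray(state)[kept]
        return block[:, kept], out_state


def filter_and_decimate(
    signal: np.ndarray,
    spec: CascadeSpec,
    state: np.ndarray | None = None,
    car_channels: list[int] | None | bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Offline convenience: (optional CAR) -> cascade -> decimate, one call.

    ``car_channels``: ``False`` disables the reference, ``None`` references
    over all channels, a list restricts the included channels.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    if car_channels is not False:
        x = common_average_reference(x, None if car_channels is None else car_channels)
    cascade = StreamingCascade(spec, x.shape[0])
    y = cascade.process(x)
    dec = Decimator(spec)
    return dec.process(y, state)
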