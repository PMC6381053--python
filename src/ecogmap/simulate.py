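"""Seeded generator of ECoG-like sessions with known high-gamma modulation.

The generator emulates the statistical structure a subdural recording hands
to the mapping pipeline, not neural waveform morphology: per-channel 1/f
background noise, a common-mode waveform shared by all channels, mains-line
contamination, a per-sample ``StimulusCode`` state that is zero between
trials, and — on a chosen subset of channels — a multiplicative burst of the
channel's own band-limited (high-gamma) noise at a fixed latency after each
stimulus onset. Because the burst scales the in-band *amplitude* by
``mod_gain``, in-band power during the burst plateau is exactly
``mod_gain**2`` times baseline, which gives every downstream stage a
closed-form ground truth.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .exceptions import ConfigError, SchemaError

_EDS_MAGIC = b"EDS1"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic session.

    Amplitudes are µV; durations are seconds. Defaults are the package's
    standard desk-scale fixture: 16 channels at 1 kHz, 30 trials of 2 s with
    2 s inter-stimulus intervals, 3 modulated channels with a high-gamma
    burst 0.2–0.8 s after stimulus onset at 3x band amplitude.
    """

    n_channels: int = 16
    fs_native_hz: float = 1000.0
    n_trials: int = 30
    trial_s: float = 2.0
    isi_s: float = 2.0
    one_over_f_exponent: float = 1.0
    background_scale: float = 15.0
    line_hz: float = 60.0
    line_amp: float = 5.0
    common_mode_amp: float = 10.0
    modulated_channels: tuple[int, ...] = (0, 1, 2)
    mod_band_hz: tuple[float, float] = (70.0, 110.0)
    mod_onset_s: float = 0.2
    mod_duration_s: float = 0.6
    mod_gain: float = 3.0
    ramp_s: float = 0.010
    stimulus_codes: tuple[int, ...] = (1,)
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if self.fs_native_hz <= 0:
            raise ConfigError("fs_native_hz must be > 0")
        lo, hi = self.mod_band_hz
        if not 0 < lo < hi < self.fs_native_hz / 2:
            raise ConfigError("mod_band_hz must satisfy 0 < low < high < fs_native/2")
        if self.trial_s <= self.mod_onset_s + self.mod_duration_s:
            raise ConfigError("trial_s must exceed mod_onset_s + mod_duration_s")
        if self.mod_gain < 0:
            raise ConfigError("mod_gain must be >= 0")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if any(c < 0 or c >= self.n_channels for c in self.modulated_channels):
            raise ConfigError("modulated_channels indices out of range")
        if any(code <= 0 for code in self.stimulus_codes):
            raise ConfigError("stimulus_codes must be positive integers")
        if self.isi_s <= 0:
            raise ConfigError("isi_s must be > 0")

    # -- derived timing -----------------------------------------------------

    @property
    def total_samples(self) -> int:
        period = self.trial_s + self.isi_s
        return int(round(self.fs_native_hz * (self.isi_s + self.n_trials * period)))

    def onset_samples(self) -> np.ndarray:
        """Stimulus-onset sample index of every trial."""
        period = self.trial_s + self.isi_s
        starts = self.isi_s + np.arange(self.n_trials) * period
        return np.round(starts * self.fs_native_hz).astype(int)

    def burst_intervals_s(self) -> np.ndarray:
        """(n_trials, 2) start/end of the injected burst in session time."""
        onsets = self.onset_samples() / self.fs_native_hz
        return np.column_stack(
            [onsets + self.mod_onset_s, onsets + self.mod_onset_s + self.mod_duration_s]
        )


@dataclass
class SimSession:
    """A generated recording: signal (channels x samples, µV), per-sample
    StimulusCode state, and the config that produced it."""

    signal: np.ndarray
    state: np.ndarray
    config: SimConfig
    channel_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.channel_labels:
            self.channel_labels = tuple(
                f"CH{i + 1:02d}" for i in range(self.signal.shape[0])
            )


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, exponent: float,
                      rms: float) -> np.ndarray:
    """1/f^exponent noise via FFT magnitude shaping, scaled to an exact RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    if sd == 0:
        return x
    return x * (rms / sd)


def _band_limited(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """The band-limited component of ``x`` via an ideal FFT mask."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return np.fft.irfft(spec * mask, n=len(x))


def _burst_envelope(config: SimConfig, n: int) -> np.ndarray:
    """Multiplicative gain-minus-one envelope with raised-cosine on/off ramps.

    Zero outside every burst, (mod_gain - 1) on the plateau; the ramps lie
    inside the burst interval so injected energy never leaks outside it.
    """
    fs = config.fs_native_hz
    env = np.zeros(n)
    ramp_n = max(1, int(round(config.ramp_s * fs)))
    dur_n = int(round(config.mod_duration_s * fs))
    ramp_n = min(ramp_n, dur_n // 2)
    up = 0.5 * (1 - np.cos(np.pi * np.arange(1, ramp_n + 1) / ramp_n))
    shape = np.ones(dur_n)
    shape[:ramp_n] = up
    shape[dur_n - ramp_n:] = up[::-1]
    for start_s, _ in config.burst_intervals_s():
        i0 = int(round(start_s * fs))
        seg = shape[: max(0, min(dur_n, n - i0))]
        env[i0 : i0 + len(seg)] = seg
    return env * (config.mod_gain - 1.0)


def generate_session(config: SimConfig) -> SimSession:
    """Generate one session; bit-identical for identical config (incl. seed)."""
    config.validate()
    n = config.total_samples
    fs = config.fs_native_hz
    rng = np.random.default_rng(config.seed)

    signal = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        signal[ch] = _one_over_f_noise(
            rng, n, fs, config.one_over_f_exponent, config.background_scale
        )

    if config.modulated_channels and config.mod_gain != 1.0:
        env = _burst_envelope(config, n)
        for ch in config.modulated_channels:
            band = _band_limited(signal[ch], fs, config.mod_band_hz)
            signal[ch] += env * band

    common = _one_over_f_noise(rng, n, fs, config.one_over_f_exponent,
                               config.common_mode_amp)
    t = np.arange(n) / fs
    line = config.line_amp * np.sin(2 * np.pi * config.line_hz * t + rng.uniform(0, 2 * np.pi))
    signal += common + line

    state = np.zeros(n, dtype=np.uint16)
    trial_n = int(round(config.trial_s * fs))
    for k, onset in enumerate(config.onset_samples()):
        code = config.stimulus_codes[k % len(config.stimulus_codes)]
        state[onset : onset + trial_n] = code

    return SimSession(signal=signal, state=state, config=config)


# ---------------------------------------------------------------------------
# ground truth at the feature-bin level
# ---------------------------------------------------------------------------

def session_truth_mask(
    config: SimConfig,
    window_s: float,
    slide_s: float,
    fs_proc_hz: float,
) -> np.ndarray:
    """Boolean (channels, steps) mask of truly modulated feature bins.

    A feature step emitted at time t summarizes the causal sample window
    (t - window_s, t]; the bin is true iff that support overlaps an injected
    burst and the channel is modulated. Step timing mirrors the feature
    extractor: right-aligned windows at the decimated rate.
    """
    win_n = int(round(window_s * fs_proc_hz))
    slide_n = int(round(slide_s * fs_proc_hz))
    k = int(round(config.fs_native_hz / fs_proc_hz))
    n_proc = (config.total_samples + k - 1) // k  # decimator keeps indices 0, k, 2k, ...
    n_steps = max(0, (n_proc - win_n) // slide_n + 1)
    step_t = (np.arange(n_steps) * slide_n + win_n - 1) / fs_proc_hz
    mask = np.zeros((config.n_channels, n_steps), dtype=bool)
    if config.mod_gain == 1.0 or not config.modulated_channels:
        return mask
    hit = np.zeros(n_steps, dtype=bool)
    for start, end in config.burst_intervals_s():
        hit |= (step_t > start) & (step_t - window_s < end)
    for ch in config.modulated_channels:
        mask[ch] = hit
    return mask


def ground_truth_mask(
    config: SimConfig,
    onset_steps: np.ndarray,
    bin_offsets: np.ndarray,
    window_s: float,
    slide_s: float,
    fs_proc_hz: float,
) -> np.ndarray:
    """Trials x channels x bins truth tensor on the mapping's bin grid.

    ``onset_steps`` are the feature-step indices the mapping aligned trials
    to; ``bin_offsets`` the per-bin step offsets relative to onset. Raises
    if any trial's window leaves the session.
    """
    sess = session_truth_mask(config, window_s, slide_s, fs_proc_hz)
    n_steps = sess.shape[1]
    onset_steps = np.asarray(onset_steps, dtype=int)
    bin_offsets = np.asarray(bin_offsets, dtype=int)
    idx = onset_steps[:, None] + bin_offsets[None, :]
    if idx.min() < 0 or idx.max() >= n_steps:
        raise ConfigError("analysis window/slide inconsistent with session length")
    return np.transpose(sess[:, idx], (1, 0, 2))


# ---------------------------------------------------------------------------
# ".eds" single-file session container
# ---------------------------------------------------------------------------

def _rle_encode(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean matrix row-wise as [row, start, length]."""
    runs = []
    for r, row in enumerate(np.asarray(mask, dtype=bool)):
        padded = np.diff(np.concatenate([[0], row.view(np.int8), [0]]))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        for s, e in zip(starts, ends):
            runs.append([int(r), int(s), int(e - s)])
    return runs


def save_session(session: SimSession, path: str | Path) -> None:
    """Write the documented single-file container: a JSON header followed by
    little-endian float32 signal (channel-major) and uint16 state samples."""
    config = session.config
    header = {
        "format": "eds",
        "version": 1,
        "n_channels": int(session.signal.shape[0]),
        "n_samples": int(session.signal.shape[1]),
        "channel_labels": list(session.channel_labels),
        "state_name": "StimulusCode",
        "signal_dtype": "<f4",
        "state_dtype": "<u2",
        "config": asdict(config),
        "truth_rle": _rle_encode(
            session_truth_mask(config, 0.256, 0.020, 500.0)
            if config.fs_native_hz % 500.0 == 0
            else np.zeros((config.n_channels, 0), dtype=bool)
        ),
        "truth_grid": {"window_s": 0.256, "slide_s": 0.020, "fs_proc_hz": 500.0},
    }
    raw = json.dumps(header).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_EDS_MAGIC)
        fh.write(struct.pack("<I", len(raw)))
        fh.write(raw)
        fh.write(np.ascontiguousarray(session.signal, dtype="<f4").tobytes())
        fh.write(np.ascontiguousarray(session.state, dtype="<u2").tobytes())


def load_session(path: str | Path) -> SimSession:
    with open(path, "rb") as fh:
        if fh.read(4) != _EDS_MAGIC:
            raise SchemaError(f"{path}: not an .eds session file")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen).decode("utf-8"))
        n_ch, n_s = header["n_channels"], header["n_samples"]
        sig = np.frombuffer(fh.read(n_ch * n_s * 4), dtype="<f4")
        state = np.frombuffer(fh.read(n_s * 2), dtype="<u2")
    if sig.size != n_ch * n_s or state.size != n_s:
        raise SchemaError(f"{path}: truncated payload")
    cfg_dict = header["config"]
    for key in ("modulated_channels", "mod_band_hz", "stimulus_codes"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = SimConfig(**cfg_dict)
    return SimSession(
        signal=sig.reshape(n_ch, n_s).astype(np.float64),
        state=state.astype(np.uint16).copy(),
        config=config,
        channel_labels=tuple(header["channel_labels"]),
    )
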