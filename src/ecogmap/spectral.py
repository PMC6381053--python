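"""Burg autoregressive spectral estimation and high-gamma band power.

On each sliding window of the filtered 500 Hz signal an AR(p) model is fit
by the Burg lattice recursion: at each stage the reflection coefficient
minimizes the summed forward + backward prediction error power, and the AR
coefficients are updated by the Levinson recursion. With the convention
A(z) = 1 + sum_k a_k z^{-k}, the one-sided power spectral density of the
fitted model is

    P(f) = 2 * sigma2 / (fs * |A(e^{-2*pi*i*f/fs})|^2),

where sigma2 is the final prediction-error (residual) variance. Band power
is the trapezoidal integral of P over the high-gamma band on a fixed
frequency grid, optionally natural-log transformed. Windows are
right-aligned — the step emitted at time t uses samples (t - window, t] —
so the series is causal and identical whether computed block-wise from a
stream or offline from the concatenated signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigError, DegenerateInputError

_DEN_FLOOR = 1e-300  # guards the reflection-coefficient quotient


@dataclass(frozen=True)
class BurgConfig:
    """Feature-extraction parameters.

    ``window_ms``/``slide_ms`` default to a 256 ms window sliding by 20 ms,
    the upper end of the usual real-time spectral-feature configuration.
    ``model_order`` 16 at 500 Hz resolves a single high-gamma peak in such
    windows. ``eval_step_hz`` sets the PSD evaluation grid inside
    ``band_hz``; band power integrates over that grid.
    """

    model_order: int = 16
    window_ms: float = 256.0
    slide_ms: float = 20.0
    band_hz: tuple[float, float] = (70.0, 110.0)
    eval_step_hz: float = 2.0
    fs_proc_hz: float = 500.0
    log_transform: bool = True

    def validate(self) -> None:
        if self.model_order < 1:
            raise ConfigError("model_order must be >= 1")
        if self.model_order >= self.window_samples:
            raise ConfigError("model_order must be smaller than the window length")
        if self.slide_ms <= 0 or self.slide_ms > self.window_ms:
            raise ConfigError("slide_ms must be in (0, window_ms]")
        lo, hi = self.band_hz
        if not 0 < lo < hi < self.fs_proc_hz / 2:
            raise ConfigError("band_hz must lie within (0, fs_proc/2)")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_ms * self.fs_proc_hz / 1000.0))

    @property
    def slide_samples(self) -> int:
        return int(round(self.slide_ms * self.fs_proc_hz / 1000.0))

    @property
    def eval_freqs_hz(self) -> np.ndarray:
        lo, hi = self.band_hz
        n = int(round((hi - lo) / self.eval_step_hz))
        return lo + self.eval_step_hz * np.arange(n + 1)


@dataclass
class FeatureSeries:
    """Per-channel (log) band power, one value per slide step.

    ``step_times_s`` is the session time of each window's last sample;
    ``state`` carries the StimulusCode value at that sample.
    """

    values: np.ndarray  # (channels, steps)
    step_times_s: np.ndarray
    state: np.ndarray  # (steps,) uint
    config: BurgConfig
    channel_labels: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Burg recursion
# ---------------------------------------------------------------------------

def burg_batch(windows: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Fit AR(order) models to every row of ``windows`` by the Burg method.

    Returns ``(a, sigma2)`` with ``a`` of shape (n_windows, order) under the
    convention A(z) = 1 + sum a_k z^{-k}, and ``sigma2`` the residual
    variance per window. Vectorized over windows: each lattice stage is a
    handful of elementwise array operations, so the per-window cost is the
    same whether one window or tens of thousands are fit.
    """
    X = np.atleast_2d(np.asarray(windows, dtype=np.float64))
    n_win, n = X.shape
    if order < 1:
        raise ConfigError("order must be >= 1")
    if order >= n:
        raise ConfigError(f"order {order} must be smaller than the window length {n}")

    f = X.copy()
    b = X.copy()
    a = np.zeros((n_win, order))
    E = np.einsum("ij,ij->i", X, X) / n
    degenerate = E <= 0

    for m in range(1, order + 1):
        fm = f[:, m:]
        bm = b[:, m - 1 : n - 1]
        num = -2.0 * np.einsum("ij,ij->i", fm, bm)
        den = np.einsum("ij,ij->i", fm, fm) + np.einsum("ij,ij->i", bm, bm)
        k = num / np.maximum(den, _DEN_FLOOR)
        k[den <= _DEN_FLOOR] = 0.0
        if m > 1:
            a[:, : m - 1] += k[:, None] * a[:, m - 2 :: -1]
        a[:, m - 1] = k
        f_new = fm + k[:, None] * bm
        b[:, m:n] = bm + k[:, None] * fm
        f[:, m:n] = f_new
        E = E * (1.0 - k * k)

    if np.any(degenerate):
        a[degenerate] = 0.0
        E = E.copy()
        E[degenerate] = 0.0
    return a, E


def burg_fit(window: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg fit of a single window; raises on a constant (degenerate) input."""
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1:
        raise ConfigError("burg_fit expects a 1-D sample vector")
    if np.ptp(x) == 0:
        raise DegenerateInputError("window is constant; AR model undefined")
    a, E = burg_batch(x[None, :], order)
    return a[0], float(E[0])


def reflection_coefficients(window: np.ndarray, order: int) -> np.ndarray:
    """The per-stage reflection coefficients (all magnitudes < 1 by the Burg
    construction); exposed for diagnostics and property testing."""
    x = np.asarray(window, dtype=np.float64)
    ks = []
    f = x.copy()
    b = x.copy()
    n = len(x)
    for m in range(1, order + 1):
        fm, bm = f[m:], b[m - 1 : n - 1]
        den = fm @ fm + bm @ bm
        k = 0.0 if den <= _DEN_FLOOR else -2.0 * (fm @ bm) / den
        ks.append(k)
        f_new = fm + k * bm
        b[m:n] = bm + k * fm
        f[m:n] = f_new
    return np.asarray(ks)


# ---------------------------------------------------------------------------
# AR spectrum and band power
# ---------------------------------------------------------------------------

def ar_spectrum(
    a: np.ndarray, sigma2: np.ndarray | float, freqs: np.ndarray, fs: float
) -> np.ndarray:
    """One-sided AR PSD at ``freqs``; batched over leading dimensions of ``a``.

    ``a`` has shape (..., p); the result has shape (..., n_freqs). An
    order-0 model (empty ``a``) yields the flat spectrum 2*sigma2/fs.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    if np.any(freqs < 0) or np.any(freqs > fs / 2):
        raise ConfigError("freqs must lie within [0, fs/2]")
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    p = a.shape[-1]
    sigma2 = np.asarray(sigma2, dtype=np.float64)
    if p == 0:
        denom = np.ones(a.shape[:-1] + (freqs.size,))
    else:
        k = np.arange(1, p + 1)
        E = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)  # (F, p)
        A = 1.0 + a @ E.T  # (..., F)
        denom = np.abs(A) ** 2
    return 2.0 * sigma2[..., None] / (fs * denom)


def band_power_from_fit(
    a: np.ndarray, sigma2: np.ndarray | float, config: BurgConfig
) -> np.ndarray:
    """Trapezoidal band-power integral of the fitted AR PSD (optionally log)."""
    freqs = config.eval_freqs_hz
    psd = ar_spectrum(a, sigma2, freqs, config.fs_proc_hz)
    power = np.trapezoid(psd, freqs, axis=-1)
    if config.log_transform:
        power = np.log(np.maximum(power, np.finfo(np.float64).tiny))
    return power


# ---------------------------------------------------------------------------
# sliding-window extraction
# ---------------------------------------------------------------------------

def compute_feature_series(
    signal: np.ndarray,
    state: np.ndarray | None,
    config: BurgConfig,
    channel_labels: tuple[str, ...] = (),
) -> FeatureSeries:
    """Offline feature extraction over a channels x samples array at fs_proc.

    Emits floor((N - window)/slide) + 1 steps; the first step appears only
    once a full window of history exists (documented warm-up).
    """
    config.validate()
    x = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    n_ch, n = x.shape
    win, sl = config.window_samples, config.slide_samples
    if n < win:
        raise ConfigError("signal shorter than one analysis window")
    n_steps = (n - win) // sl + 1
    values = np.empty((n_ch, n_steps))
    for ch in range(n_ch):
        windows = sliding_window_view(x[ch], win)[::sl][:n_steps]
        a, E = burg_batch(windows, config.model_order)
        values[ch] = band_power_from_fit(a, E, config)
    last_idx = np.arange(n_steps) * sl + win - 1
    step_times = last_idx / config.fs_proc_hz
    st = (
        np.zeros(n_steps, dtype=np.uint32)
        if state is None
        else np.asarray(state)[last_idx].astype(np.uint32)
    )
    return FeatureSeries(values, step_times, st, config, tuple(channel_labels))


def write_features_csv(features: FeatureSeries, path) -> None:
    """Long-format CSV export: step_time_s, channel, value."""
    import csv

    labels = features.channel_labels or tuple(
        f"CH{i + 1:02d}" for i in range(features.values.shape[0])
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step_time_s", "channel", "value"])
        for s, t in enumerate(features.step_times_s):
            for c, label in enumerate(labels):
                writer.writerow([repr(float(t)), label, repr(float(features.values[c, s]))])


class StreamingBandPower:
    """Block-wise feature extractor equal to the offline computation.

    Buffers incoming processed-rate samples and emits one feature step per
    completed slide; numerically identical to
    :func:`compute_feature_series` on the concatenated signal because both
    run the same Burg kernel on the same sample windows.
    """

    def __init__(self, config: BurgConfig, n_channels: int):
        config.validate()
        self.config = config
        self.n_channels = n_channels
        self._sig = np.empty((n_channels, 0))
        self._state = np.empty(0, dtype=np.uint32)
        self._consumed = 0  # processed-rate samples already discarded
        self._next_start = 0  # absolute start index of the next window

    def feed(self, block: np.ndarray, state: np.ndarray | None = None):
        """Append one block; return (values, step_times, states) for every
        newly completed step (possibly empty arrays)."""
        block = np.atleast_2d(np.asarray(block, dtype=np.float64))
        if block.shape[0] != self.n_channels:
            raise ConfigError("block channel count mismatch")
        st = (
            np.zeros(block.shape[1], dtype=np.uint32)
            if state is None
            else np.asarray(state).astype(np.uint32)
        )
        self._sig = np.concatenate([self._sig, block], axis=1)
        self._state = np.concatenate([self._state, st])

        cfg = self.config
        win, sl = cfg.window_samples, cfg.slide_samples
        total = self._consumed + self._sig.shape[1]
        starts = []
        while self._next_start + win <= total:
            starts.append(self._next_start)
            self._next_start += sl
        if not starts:
            return (
                np.empty((self.n_channels, 0)),
                np.empty(0),
                np.empty(0, dtype=np.uint32),
            )
        # one Burg batch over (steps x channels) keeps the per-block cost flat
        rel = np.asarray(starts) - self._consumed
        windows = np.concatenate([self._sig[:, r : r + win] for r in rel], axis=0)
        a, E = burg_batch(windows, cfg.model_order)
        power = band_power_from_fit(a, E, cfg)
        values = power.reshape(len(starts), self.n_channels).T.copy()
        last_idx = np.asarray(starts) + win - 1
        states = self._state[last_idx - self._consumed]
        # drop history no window can need any more
        keep_from = self._next_start - self._consumed
        if keep_from > 0:
            self._sig = self._sig[:, keep_from:]
            self._state = self._state[keep_from:]
            self._consumed = self._next_start
        return values, last_idx / cfg.fs_proc_hz, states
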