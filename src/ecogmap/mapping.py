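"""Trial-locked spatial-temporal functional mapping.

Stimulus onsets are the 0 -> non-zero transitions of the StimulusCode state
sampled at the feature rate. For each trial a fixed window of feature bins
around onset is extracted into a trials x channels x bins tensor. A per-
channel baseline distribution pools every bin whose center lies in the
pre-stimulus baseline window across all trials; each time-channel bin's
across-trials sample is then compared to that pool with a two-tailed
two-sample (Welch) t-test. The resulting p-values are thresholded jointly
over all testable time-channel bins by the Benjamini-Hochberg step-up rule
at FDR level q, and display values are baseline z-scores
(bin mean - baseline mean) / baseline sd. Maps update after every trial by
recomputation over all trials seen so far, so incremental and batch results
are identical; a "live" mode z-scores each feature step against an
exponentially weighted running baseline instead of a trial structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .exceptions import ConfigError
from .spectral import FeatureSeries

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class MapConfig:
    """Mapping parameters. Windows are milliseconds relative to onset; the
    baseline defaults to the 1,000-to-200 ms pre-onset period and the FDR is
    controlled at q = 0.05 over all testable time-channel bins jointly."""

    baseline_window_ms: tuple[float, float] = (-1000.0, -200.0)
    analysis_window_ms: tuple[float, float] = (-1000.0, 2000.0)
    fdr_q: float = 0.05
    min_trials: int = 2
    equal_var: bool = False  # False = Welch; True = pooled-variance t-test

    def validate(self) -> None:
        b0, b1 = self.baseline_window_ms
        a0, a1 = self.analysis_window_ms
        if not (a0 <= b0 < b1 <= a1):
            raise ConfigError("baseline window must lie within the analysis window")
        if b1 > 0:
            raise ConfigError("baseline must end at or before trial onset")
        if not 0 < self.fdr_q < 1:
            raise ConfigError("fdr_q must lie in (0, 1)")
        if self.min_trials < 2:
            raise ConfigError("min_trials must be >= 2")


@dataclass
class TrialTensor:
    """Trials x channels x bins of (log) band power aligned to onsets."""

    values: np.ndarray
    bin_times_ms: np.ndarray
    stimulus_codes: np.ndarray
    onset_steps: np.ndarray
    bin_offsets: np.ndarray
    slide_ms: float
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]


@dataclass
class BaselineDistribution:
    """Per-channel pooled baseline sample with its mean and sd (ddof=1).
    Channels whose pool has zero variance are flagged untestable."""

    pool: np.ndarray  # (channels, n_trials * n_baseline_bins)
    mean: np.ndarray
    sd: np.ndarray
    testable: np.ndarray  # (channels,) bool


@dataclass
class MapResult:
    """Per channel x bin statistics; non-significant bins are mask-false,
    never deleted."""

    t_stat: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    z_display: np.ndarray
    n_trials: int
    bin_times_ms: np.ndarray
    testable_channels: np.ndarray


# ---------------------------------------------------------------------------
# onset detection and tensor extraction
# ---------------------------------------------------------------------------

def detect_trial_onsets(state: np.ndarray) -> list[tuple[int, int]]:
    """One (step index, stimulus code) per maximal run of non-zero state."""
    state = np.asarray(state)
    if state.size == 0:
        return []
    nz = state != 0
    starts = np.flatnonzero(np.diff(np.concatenate([[0], nz.view(np.int8)])) == 1)
    return [(int(i), int(state[i])) for i in starts]


def _offsets_for(window_ms: tuple[float, float], slide_ms: float) -> np.ndarray:
    lo, hi = window_ms
    o0, o1 = lo / slide_ms, hi / slide_ms
    if abs(o0 - round(o0)) > 1e-9 or abs(o1 - round(o1)) > 1e-9:
        raise ConfigError("window bounds must be integer multiples of the feature slide")
    return np.arange(int(round(o0)), int(round(o1)) + 1)


def extract_trial_tensor(
    features: FeatureSeries, onsets: list[tuple[int, int]], config: MapConfig
) -> TrialTensor:
    """Align trials on a common bin grid; edge trials whose analysis window
    leaves the series are dropped with a logged warning."""
    config.validate()
    slide_ms = features.config.slide_ms
    offsets = _offsets_for(config.analysis_window_ms, slide_ms)
    n_steps = features.values.shape[1]
    kept, codes = [], []
    for step, code in onsets:
        if step + offsets[0] < 0 or step + offsets[-1] >= n_steps:
            logger.warning("dropping trial at step %d: analysis window leaves the series", step)
            continue
        kept.append(step)
        codes.append(code)
    if not kept:
        raise ConfigError("no trial has a complete analysis window")
    kept_arr = np.asarray(kept)
    idx = kept_arr[:, None] + offsets[None, :]
    values = np.transpose(features.values[:, idx], (1, 0, 2))
    return TrialTensor(
        values=values,
        bin_times_ms=offsets * slide_ms,
        stimulus_codes=np.asarray(codes),
        onset_steps=kept_arr,
        bin_offsets=offsets,
        slide_ms=slide_ms,
        n_dropped=len(onsets) - len(kept),
    )


# ---------------------------------------------------------------------------
# baseline, tests, BH, z-scores
# ---------------------------------------------------------------------------

def baseline_bin_mask(tensor: TrialTensor, config: MapConfig) -> np.ndarray:
    b0, b1 = config.baseline_window_ms
    t = tensor.bin_times_ms
    return (t >= b0 - 1e-9) & (t <= b1 + 1e-9)


def pool_baseline(tensor: TrialTensor, config: MapConfig) -> BaselineDistribution:
    """Pool all baseline-window bins across trials, per channel."""
    if tensor.n_trials < config.min_trials:
        raise ConfigError(
            f"need >= {config.min_trials} trials, have {tensor.n_trials}"
        )
    mask = baseline_bin_mask(tensor, config)
    pool = tensor.values[:, :, mask].transpose(1, 0, 2).reshape(tensor.values.shape[1], -1)
    mean = pool.mean(axis=1)
    sd = pool.std(axis=1, ddof=1)
    # a numerically constant pool (sd at rounding-noise level) is untestable
    testable = sd > 1e-12 * np.maximum(1.0, np.abs(mean))
    if not np.all(testable):
        logger.warning(
            "channels %s have a degenerate baseline and are excluded from testing",
            np.flatnonzero(~testable).tolist(),
        )
    return BaselineDistribution(pool=pool, mean=mean, sd=sd, testable=testable)


def bin_statistics(
    tensor: TrialTensor, baseline: BaselineDistribution, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed two-sample t-test of each bin's across-trials sample
    against the channel's baseline pool. t > 0 when the bin mean exceeds the
    baseline mean. Degenerate bins (zero variance in both samples) get
    t = 0, p = 1."""
    n_trials, n_ch, n_bins = tensor.values.shape
    t = np.zeros((n_ch, n_bins))
    p = np.ones((n_ch, n_bins))
    for c in range(n_ch):
        if not baseline.testable[c]:
            continue
        res = sstats.ttest_ind(
            tensor.values[:, c, :],
            baseline.pool[c][:, None],
            axis=0,
            equal_var=equal_var,
        )
        tc = np.asarray(res.statistic)
        pc = np.asarray(res.pvalue)
        bad = ~np.isfinite(tc)
        tc[bad] = 0.0
        pc[bad] = 1.0
        t[c] = tc
        p[c] = np.clip(pc, _P_FLOOR, 1.0)
    return t, p


def bh_threshold(
    p_values: np.ndarray, q: float, testable: np.ndarray | None = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up over the flattened family of testable bins.

    k* is the largest k with p_(k) <= k*q/m; the k* smallest p-values are
    rejected. Returns a boolean mask of ``p_values``' shape.
    """
    p = np.asarray(p_values, dtype=np.float64)
    mask = np.ones(p.shape, dtype=bool) if testable is None else np.asarray(testable, bool)
    flat_p = p[mask]
    m = flat_p.size
    reject = np.zeros(p.shape, dtype=bool)
    if m == 0:
        return reject
    order = np.argsort(flat_p, kind="stable")
    ranked = flat_p[order]
    ok = ranked <= q * np.arange(1, m + 1) / m
    if not np.any(ok):
        return reject
    k_star = int(np.max(np.flatnonzero(ok))) + 1
    flat_reject = np.zeros(m, dtype=bool)
    flat_reject[order[:k_star]] = True
    reject[mask] = flat_reject
    return reject


def zscore_map(tensor: TrialTensor, baseline: BaselineDistribution) -> np.ndarray:
    """Display z-scores: (across-trials bin mean - mu_b) / sigma_b per
    channel; untestable channels are NaN-flagged, never silently zero."""
    bin_mean = tensor.values.mean(axis=0)
    z = np.full(bin_mean.shape, np.nan)
    ok = baseline.testable
    z[ok] = (bin_mean[ok] - baseline.mean[ok, None]) / baseline.sd[ok, None]
    return z


def compute_map(tensor: TrialTensor, config: MapConfig) -> MapResult:
    """Full batch computation: baseline -> per-bin tests -> BH mask -> z."""
    config.validate()
    baseline = pool_baseline(tensor, config)
    t, p = bin_statistics(tensor, baseline, equal_var=config.equal_var)
    testable_bins = np.broadcast_to(baseline.testable[:, None], p.shape)
    significant = bh_threshold(p, config.fdr_q, testable_bins)
    z = zscore_map(tensor, baseline)
    return MapResult(
        t_stat=t,
        p_value=p,
        significant=significant,
        z_display=z,
        n_trials=tensor.n_trials,
        bin_times_ms=tensor.bin_times_ms,
        testable_channels=baseline.testable,
    )


# ---------------------------------------------------------------------------
# incremental per-trial updating
# ---------------------------------------------------------------------------

class IncrementalMapper:
    """Per-trial map updating: each accepted trial triggers a recomputation
    over all trials so far, so the result after n trials is identical to one
    batch call on those n trials. Exposes a trial counter."""

    def __init__(self, config: MapConfig, bin_times_ms: np.ndarray, slide_ms: float):
        config.validate()
        self.config = config
        self.bin_times_ms = np.asarray(bin_times_ms, dtype=np.float64)
        self.slide_ms = float(slide_ms)
        self._slices: list[np.ndarray] = []
        self._codes: list[int] = []
        self.result: MapResult | None = None

    @property
    def trial_count(self) -> int:
        return len(self._slices)

    def add_trial(self, trial_slice: np.ndarray, code: int = 0) -> MapResult | None:
        """Accept one channels x bins trial slice; returns the updated map,
        or None while fewer than min_trials trials have arrived."""
        trial_slice = np.asarray(trial_slice, dtype=np.float64)
        if self._slices and trial_slice.shape != self._slices[0].shape:
            raise ConfigError("trial slice does not match the established channel/bin grid")
        if trial_slice.shape[1] != self.bin_times_ms.size:
            raise ConfigError("trial slice does not match the bin grid")
        self._slices.append(trial_slice)
        self._codes.append(int(code))
        if self.trial_count < self.config.min_trials:
            return None
        offsets = np.round(self.bin_times_ms / self.slide_ms).astype(int)
        tensor = TrialTensor(
            values=np.stack(self._slices),
            bin_times_ms=self.bin_times_ms,
            stimulus_codes=np.asarray(self._codes),
            onset_steps=np.zeros(self.trial_count, dtype=int),
            bin_offsets=offsets,
            slide_ms=self.slide_ms,
        )
        self.result = compute_map(tensor, self.config)
        return self.result


# ---------------------------------------------------------------------------
# live activation mode
# ---------------------------------------------------------------------------

class LiveActivation:
    """Running z-score of each channel against an exponentially weighted
    baseline (time constant tau, default 30 s).

    The z of an incoming step uses the baseline statistics from *before*
    that step, so a sudden power step of +k running-sd reads ~k immediately
    and decays as the baseline adapts. During warm-up (the first tau
    seconds, and equal-weight averaging until then) outputs are flagged. In
    the tau -> infinity limit the update weight becomes 1/n, reproducing
    fixed-baseline z-scoring against the cumulative past.
    """

    def __init__(self, n_channels: int, step_s: float, tau_s: float = 30.0):
        if step_s <= 0 or tau_s <= 0:
            raise ConfigError("step_s and tau_s must be > 0")
        self.tau_s = float(tau_s)
        self.step_s = float(step_s)
        self._alpha_inf = -np.expm1(-step_s / tau_s)  # 1 - exp(-dt/tau)
        self._mean = np.zeros(n_channels)
        self._var = np.zeros(n_channels)
        self._count = 0

    @property
    def warmed_up(self) -> bool:
        return self._count * self.step_s >= self.tau_s

    def update(self, values: np.ndarray) -> tuple[np.ndarray, bool]:
        """Feed one per-channel feature step; returns (z, warmed_up)."""
        x = np.asarray(values, dtype=np.float64)
        if self._count == 0:
            z = np.zeros_like(x)
        else:
            sd = np.sqrt(self._var)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(sd > 0, (x - self._mean) / sd, 0.0)
        warmed = self.warmed_up
        self._count += 1
        alpha = max(1.0 / self._count, self._alpha_inf)
        delta = x - self._mean
        self._mean += alpha * delta
        self._var = (1.0 - alpha) * (self._var + alpha * delta * delta)
        return z, warmed
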