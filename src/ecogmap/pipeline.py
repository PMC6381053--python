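"""End-to-end glue: configuration, the offline pipeline, and truth scoring.

``run_offline`` is the reference path every streamed computation must
reproduce: (optional CAR) -> Butterworth cascade -> decimation -> Burg band
power -> onset detection -> trial tensor -> statistical map.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dsp import CascadeSpec, filter_and_decimate
from .exceptions import ConfigError
from .mapping import (
    MapConfig,
    MapResult,
    TrialTensor,
    compute_map,
    detect_trial_onsets,
    extract_trial_tensor,
)
from .records import MapRecord
from .simulate import SimSession, ground_truth_mask
from .spectral import BurgConfig, FeatureSeries, compute_feature_series


@dataclass(frozen=True)
class PipelineConfig:
    """Cross-validated bundle of every stage's parameters.

    ``car`` selects the common-average-reference inclusion list: ``"all"``
    references over every channel, ``"off"`` disables the stage, a list of
    indices restricts it.
    """

    cascade: CascadeSpec = field(default_factory=CascadeSpec)
    burg: BurgConfig = field(default_factory=BurgConfig)
    mapping: MapConfig = field(default_factory=MapConfig)
    car: str | tuple[int, ...] = "all"
    subject_id: str = "SIM"
    task: str = "synthetic"

    def validate(self) -> None:
        self.cascade.validate()
        self.burg.validate()
        self.mapping.validate()
        if self.burg.fs_proc_hz != self.cascade.decim_target_hz:
            raise ConfigError("burg.fs_proc_hz must equal cascade.decim_target_hz")
        if isinstance(self.car, str) and self.car not in ("all", "off"):
            raise ConfigError("car must be 'all', 'off', or a channel list")

    @property
    def car_arg(self):
        """Argument form used by dsp.filter_and_decimate."""
        if self.car == "off":
            return False
        if self.car == "all":
            return None
        return list(self.car)

    def to_dict(self) -> dict:
        d = {
            "cascade": dataclasses.asdict(self.cascade),
            "burg": dataclasses.asdict(self.burg),
            "mapping": dataclasses.asdict(self.mapping),
            "car": self.car if isinstance(self.car, str) else list(self.car),
            "subject_id": self.subject_id,
            "task": self.task,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            cfg = cls(
                cascade=CascadeSpec(**d.get("cascade", {})),
                burg=_burg_from_dict(d.get("burg", {})),
                mapping=_mapping_from_dict(d.get("mapping", {})),
                car=d.get("car", "all") if isinstance(d.get("car", "all"), str)
                else tuple(d["car"]),
                subject_id=d.get("subject_id", "SIM"),
                task=d.get("task", "synthetic"),
            )
        except TypeError as exc:
            raise ConfigError(f"unknown pipeline config field: {exc}") from None
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _burg_from_dict(d: dict) -> BurgConfig:
    d = dict(d)
    if "band_hz" in d:
        d["band_hz"] = tuple(d["band_hz"])
    return BurgConfig(**d)


def _mapping_from_dict(d: dict) -> MapConfig:
    d = dict(d)
    for key in ("baseline_window_ms", "analysis_window_ms"):
        if key in d:
            d[key] = tuple(d[key])
    return MapConfig(**d)


# ---------------------------------------------------------------------------
# offline pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineRun:
    """Everything the offline pipeline produced, for inspection and scoring."""

    features: FeatureSeries
    tensor: TrialTensor
    result: MapResult
    onsets: list[tuple[int, int]]


def extract_features(session: SimSession, config: PipelineConfig) -> FeatureSeries:
    """Preprocess and reduce a session to the per-channel band-power series."""
    config.validate()
    if session.config.fs_native_hz != config.cascade.fs_native_hz:
        raise ConfigError("session rate does not match the cascade's native rate")
    proc, state = filter_and_decimate(
        session.signal, config.cascade, session.state, car_channels=config.car_arg
    )
    return compute_feature_series(proc, state, config.burg, session.channel_labels)


def run_offline(session: SimSession, config: PipelineConfig) -> PipelineRun:
    features = extract_features(session, config)
    onsets = detect_trial_onsets(features.state)
    tensor = extract_trial_tensor(features, onsets, config.mapping)
    result = compute_map(tensor, config.mapping)
    return PipelineRun(features=features, tensor=tensor, result=result, onsets=onsets)


def result_to_record(
    result: MapResult,
    channel_labels: tuple[str, ...],
    config: PipelineConfig,
    truncated: bool = False,
) -> MapRecord:
    return MapRecord(
        subject_id=config.subject_id,
        task=config.task,
        channel_labels=channel_labels,
        bin_times_ms=result.bin_times_ms,
        z_display=result.z_display,
        significant=result.significant,
        n_trials=result.n_trials,
        config=config.to_dict(),
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# scoring against generator ground truth
# ---------------------------------------------------------------------------

def score_against_truth(run: PipelineRun, session: SimSession) -> dict[str, float]:
    """Sensitivity and false-discovery proportion of the significance mask
    against the generator's bin-level truth."""
    cfg = run.features.config
    truth_trials = ground_truth_mask(
        session.config,
        run.tensor.onset_steps,
        run.tensor.bin_offsets,
        cfg.window_ms / 1000.0,
        cfg.slide_ms / 1000.0,
        cfg.fs_proc_hz,
    )
    truth = truth_trials.any(axis=0)  # channels x bins (identical across trials)
    sig = run.result.significant
    n_disc = int(sig.sum())
    false_disc = int((sig & ~truth).sum())
    true_bins = int(truth.sum())
    hits = int((sig & truth).sum())
    return {
        "discoveries": float(n_disc),
        "false_discoveries": float(false_disc),
        "fdp": false_disc / max(1, n_disc),
        "true_bins": float(true_bins),
        "sensitivity": hits / true_bins if true_bins else float("nan"),
    }
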