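"""Run configuration for the lifting-posture pipeline.

A single :class:`RunConfig` carries every tunable of the analysis chain:
simulation protocol (duration, lifting frequency, sampling rate), the
segmentation filter bank (band-pass edges, Savitzky-Golay parameters,
threshold rule), feature options, statistics options and the classifier
benchmark settings.  Configs load from YAML or JSON and serialize back to
a plain dict so run manifests can embed an exact snapshot.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

#: Classifier names benchmarked by default, in report order.
CLASSIFIER_NAMES = ("SVM", "DT", "GB", "RaF", "LR", "kNN", "MLP", "PNN")


@dataclass
class RunConfig:
    """Parameters of one end-to-end run.

    Defaults follow the acquisition protocol the package emulates: 8-minute
    trials at 2.5 liftings/min (20 liftings), a 4th-order 1-50 Hz Butterworth
    band-pass, Savitzky-Golay smoothing with polynomial order 4 and frame
    length 1101 samples, and a per-subject envelope-quantile threshold.
    """

    # --- simulation protocol ---
    sampling_rate: float = 200.0          # Hz
    duration_min: float = 8.0             # minutes per trial
    lifting_frequency: float = 2.5        # liftings per minute
    n_subjects: int = 15
    cohort_seed: int = 20240576

    # --- segmentation ---
    filter_band: tuple[float, float] = (1.0, 50.0)  # Hz
    filter_order: int = 4
    sg_polyorder: int = 4
    sg_framelen: int = 1101               # samples, odd
    threshold_mode: str = "quantile"      # "quantile" | "fixed"
    threshold_value: float = 0.90         # quantile q, or absolute value
    min_duration_s: float = 0.5           # discard shorter ROIs
    min_gap_s: float = 1.0                # merge ROIs separated by less

    # --- features ---
    se_normalized: bool = True            # spectral entropy / log2(N)
    kurt_exponent: int = 4                # literal printed reading: 3

    # --- statistics ---
    alpha: float = 0.05
    axis_mode: str = "mean"               # "mean" over x/y/z or "x" only

    # --- ml benchmark ---
    positive_class: str = "unsafe"
    minmax_scope: str = "fold"            # "fold" | "global"
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    classifier_params: dict[str, dict[str, Any]] = field(default_factory=dict)

    # --- importance ---
    ig_bins: int = 10

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        low, high = self.filter_band
        if not (0 < low < high < self.sampling_rate / 2):
            raise ConfigError(
                f"filter band {self.filter_band} must satisfy "
                f"0 < low < high < Nyquist ({self.sampling_rate / 2} Hz)"
            )
        if self.sg_framelen % 2 == 0 or self.sg_framelen <= self.sg_polyorder:
            raise ConfigError(
                f"sg_framelen {self.sg_framelen} must be odd and exceed "
                f"sg_polyorder {self.sg_polyorder}"
            )
        if self.threshold_mode not in ("quantile", "fixed"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "quantile" and not (0 < self.threshold_value < 1):
            raise ConfigError("quantile threshold_value must lie in (0, 1)")
        if self.threshold_mode == "fixed" and self.threshold_value <= 0:
            raise ConfigError("fixed threshold_value must be positive")
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2 (LOSO undefined below)")
        if self.positive_class not in ("safe", "unsafe"):
            raise ConfigError(f"unknown positive_class {self.positive_class!r}")
        if self.axis_mode not in ("mean", "x"):
            raise ConfigError(f"unknown axis_mode {self.axis_mode!r}")
        if self.minmax_scope not in ("fold", "global"):
            raise ConfigError(f"unknown minmax_scope {self.minmax_scope!r}")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ConfigError(f"unknown classifiers: {sorted(unknown)}")
        if self.ig_bins < 2:
            raise ConfigError("ig_bins must be >= 2")

    # ------------------------------------------------------------------
    @property
    def n_liftings(self) -> int:
        """Liftings per trial implied by the protocol timing."""
        return round(self.lifting_frequency * self.duration_min)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["filter_band"] = list(self.filter_band)
        d["classifiers"] = list(self.classifiers)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "filter_band" in d:
            d["filter_band"] = tuple(d["filter_band"])
        if "classifiers" in d:
            d["classifiers"] = tuple(d["classifiers"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        """Load a config from a YAML or JSON file (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
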