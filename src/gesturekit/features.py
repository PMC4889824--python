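"""Time-domain SEMG features and per-segment feature-vector assembly.

Four classical myoelectric descriptors over a window x_1..x_N:

* MAV  — mean absolute value, (1/N) * sum |x_i|
* WL   — waveform length, sum |x_{i+1} - x_i|
* WAMP — Willison amplitude, count of successive differences with
  |x_i - x_{i+1}| >= threshold (threshold in signal units)
* SSC  — slope sign changes, count of interior points where
  (x_i - x_{i-1}) * (x_i - x_{i+1}) >= threshold (squared signal units)

The indicator thresholds are configurable: WAMP's defaults to 5% of the
training-set median MAV (scale-adaptive, since device units vary), SSC's to
zero with ">= eps" in place of a strict inequality so exact-zero products from
repeated samples are not counted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .semg_data import Segment

FEATURE_NAMES: tuple[str, ...] = ("MAV", "WL", "WAMP", "SSC")

#: Machine-positive floor used for the SSC indicator when the configured
#: threshold is zero, so slope reversals through repeated samples (product
#: exactly zero) do not count.
SSC_EPS = 1e-12

#: WAMP auto-threshold = this fraction of the training-set median MAV.
WAMP_AUTO_FRACTION = 0.05


def _as_vector(x, min_len: int, op: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size < min_len:
        raise ValidationError(f"{op} needs at least {min_len} samples; got {v.size}")
    return v


def mav(x) -> float:
    """Mean absolute value of a window (N >= 1)."""
    v = _as_vector(x, 1, "mav")
    return float(np.mean(np.abs(v)))


def wl(x) -> float:
    """Waveform length: cumulative absolute sample-to-sample variation (N >= 2)."""
    v = _as_vector(x, 2, "wl")
    return float(np.sum(np.abs(np.diff(v))))


def wamp(x, threshold: float) -> int:
    """Willison amplitude: number of successive jumps with magnitude >= threshold."""
    if threshold < 0:
        raise ValidationError(f"wamp threshold must be >= 0; got {threshold}")
    v = _as_vector(x, 2, "wamp")
    return int(np.count_nonzero(np.abs(np.diff(v)) >= threshold))


def ssc(x, threshold: float = 0.0) -> int:
    """Slope sign changes: interior points where the slope reverses.

    Counts i in 2..N-1 with (x_i - x_{i-1}) * (x_i - x_{i+1}) >= threshold.
    A zero threshold is replaced by ``SSC_EPS`` so flat runs do not count.
    """
    if threshold < 0:
        raise ValidationError(f"ssc threshold must be >= 0; got {threshold}")
    v = _as_vector(x, 3, "ssc")
    eff = threshold if threshold > 0 else SSC_EPS
    prod = (v[1:-1] - v[:-2]) * (v[1:-1] - v[2:])
    return int(np.count_nonzero(prod >= eff))


#: Minimum window length each feature requires.
_MIN_LEN = {"MAV": 1, "WL": 2, "WAMP": 2, "SSC": 3}


@dataclass(frozen=True)
class FeatureConfig:
    """Which features to extract and with what thresholds.

    ``wamp_threshold=None`` means "auto": resolve it from training segments
    with :func:`auto_wamp_threshold` before extraction.
    """

    feature_set: tuple[str, ...] = ("MAV",)
    wamp_threshold: float | None = None
    ssc_threshold: float = 0.0
    normalize: str = "none"  # none | zscore

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_set", tuple(self.feature_set))
        if not self.feature_set:
            raise ValidationError("feature_set must be non-empty")
        unknown = [f for f in self.feature_set if f not in FEATURE_NAMES]
        if unknown:
            raise ValidationError(f"unknown features {unknown}; choose from {FEATURE_NAMES}")
        if self.wamp_threshold is not None and self.wamp_threshold < 0:
            raise ValidationError("wamp_threshold must be >= 0")
        if self.ssc_threshold < 0:
            raise ValidationError("ssc_threshold must be >= 0")
        if self.normalize not in ("none", "zscore"):
            raise ValidationError(f"normalize must be 'none' or 'zscore'; got {self.normalize!r}")

    @property
    def min_segment_length(self) -> int:
        return max(_MIN_LEN[f] for f in self.feature_set)

    def fingerprint(self) -> str:
        key = repr((self.feature_set, self.wamp_threshold, self.ssc_threshold, self.normalize))
        return hashlib.sha1(key.encode()).hexdigest()[:12]


@dataclass
class FeatureVector:
    """Per-segment descriptor: channel-major feature values plus the label."""

    values: np.ndarray
    label: str
    config_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must all be finite")


def auto_wamp_threshold(segments: Iterable[Segment]) -> float:
    """Scale-adaptive WAMP threshold: 5% of the median per-channel MAV.

    Fit this on the *training* segments only, then reuse the resolved value
    for test data so train and test features are commensurable.
    """
    mavs = [mav(seg.window[:, c]) for seg in segments for c in range(seg.window.shape[1])]
    if not mavs:
        raise ValidationError("cannot fit WAMP threshold on an empty segment list")
    return WAMP_AUTO_FRACTION * float(np.median(mavs))


def resolve_config(cfg: FeatureConfig, training_segments: Sequence[Segment]) -> FeatureConfig:
    """Return cfg with any auto threshold replaced by a concrete value."""
    if cfg.wamp_threshold is None and "WAMP" in cfg.feature_set:
        return replace(cfg, wamp_threshold=auto_wamp_threshold(training_segments))
    if cfg.wamp_threshold is None:
        return replace(cfg, wamp_threshold=0.0)
    return cfg


def _scalar_feature(name: str, x: np.ndarray, cfg: FeatureConfig) -> float:
    if name == "MAV":
        return mav(x)
    if name == "WL":
        return wl(x)
    if name == "WAMP":
        thr = cfg.wamp_threshold if cfg.wamp_threshold is not None else 0.0
        return float(wamp(x, thr))
    if name == "SSC":
        return float(ssc(x, cfg.ssc_threshold))
    raise ValidationError(f"unknown feature {name!r}")


def extract_features(seg: Segment, cfg: FeatureConfig) -> FeatureVector:
    """Assemble a channel-major feature vector for one segment.

    Order: for each channel in recording order, the features in
    ``cfg.feature_set`` order.  A segment too short for a selected feature
    raises :class:`ConfigurationError` naming that feature.
    """
    for f in cfg.feature_set:
        if seg.n_samples < _MIN_LEN[f]:
            raise ConfigurationError(
                f"feature {f} needs >= {_MIN_LEN[f]} samples; segment has {seg.n_samples}"
            )
    vals = [
        _scalar_feature(f, seg.window[:, c], cfg)
        for c in range(seg.window.shape[1])
        for f in cfg.feature_set
    ]
    return FeatureVector(np.array(vals), seg.label, cfg.fingerprint())


def extract_dataset(
    segments: Sequence[Segment], cfg: FeatureConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Extract all segments into an (X, y) pair (rows follow segment order)."""
    vecs = [extract_features(s, cfg) for s in segments]
    return stack_features(vecs)


def stack_features(vectors: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors into X (n, d) and y (n,) arrays."""
    if not vectors:
        raise ValidationError("empty feature-vector list")
    d = vectors[0].values.size
    if any(v.values.size != d for v in vectors):
        raise ValidationError("feature vectors have inconsistent dimensionality")
    X = np.vstack([v.values for v in vectors])
    y = np.array([v.label for v in vectors])
    return X, y


@dataclass(frozen=True)
class Normalizer:
    """Per-dimension z-score transform fitted on training vectors.

    Dimensions with zero spread pass through unchanged.
    """

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean.size:
            raise ValidationError(
                f"normalizer fitted on {self.mean.size} dims; got {X.shape[1]}"
            )
        safe_sd = np.where(self.sd > 0, self.sd, 1.0)
        return (X - self.mean) / safe_sd


def fit_normalizer(vectors: Sequence[FeatureVector] | np.ndarray) -> Normalizer:
    """Fit per-dimension mean/SD on training data (needs >= 2 rows)."""
    if isinstance(vectors, np.ndarray):
        X = np.atleast_2d(vectors)
    else:
        X, _ = stack_features(list(vectors))
    if X.shape[0] < 2:
        raise ValidationError("normalizer needs at least 2 vectors")
    return Normalizer(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=0))


def feature_dimension_names(channels: Sequence[str], cfg: FeatureConfig) -> list[str]:
    """Names of the vector dimensions, channel-major: '<channel>:<feature>'."""
    return [f"{ch}:{f}" for ch in channels for f in cfg.feature_set]
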