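"""Synthetic two-channel SEMG dataset generator.

The generator emulates a low-rate (16 Hz) two-channel recording of six hand
gestures, each repeated twenty times as rest -> sudden onset -> ~5 s hold ->
return to rest.  A stream at 16 Hz is necessarily a processed (RMS-like)
envelope rather than raw EMG — raw surface EMG has most of its power well
above 8 Hz — so the signal model is a nonnegative activation envelope plus
half-normal noise, not a zero-mean interference pattern.

Channel 1 plays the role of a flexor-site electrode and channel 2 an
extensor-site electrode: hand closing and wrist flexion are flexor-dominant,
hand opening and wrist extension extensor-dominant, and the two finger
gestures (index finger, thumb) are low-amplitude mixed activations placed
deliberately close together so they remain the hardest pair to separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .features import FeatureConfig, FeatureVector, extract_features, resolve_config
from .semg_data import (
    DEFAULT_WINDOW_MS,
    GESTURE_LABELS,
    REST_LABEL,
    Annotation,
    Recording,
    Segment,
    sliding_segments,
)

#: Reference noise scale used to calibrate the amplitude template: with the
#: default template, the closest pair of gesture activation profiles sits
#: class_separation x this many signal units apart.
NOISE_SD_REF = 0.1

# Unit-free activation template rows (flexor channel, extensor channel); the
# IF/T rows are the closest pair by construction.
_BASE_TEMPLATE = {
    "HC": (1.00, 0.40),
    "HO": (0.40, 1.00),
    "WF": (0.90, 0.15),
    "WE": (0.15, 0.90),
    "IF": (0.30, 0.35),
    "T": (0.35, 0.30),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped generation parameters.

    Defaults mirror the acquisition protocol being emulated: 16 Hz, two
    channels, six gestures x 20 repetitions, 5 s holds with rest in between.
    ``class_separation`` scales the minimum pairwise distance between gesture
    activation profiles in units of the reference noise SD.
    """

    sampling_rate_hz: float = 16.0
    n_channels: int = 2
    gestures: tuple[str, ...] = GESTURE_LABELS
    reps_per_gesture: int = 20
    hold_seconds: float = 5.0
    rest_seconds: float = 2.0
    amplitude_matrix: np.ndarray | None = None
    noise_sd: float = 0.1
    onset_jitter_ms: float = 0.0
    class_separation: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be > 0")
        if self.reps_per_gesture < 1:
            raise ValidationError("reps_per_gesture must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.class_separation <= 0:
            raise ValidationError("class_separation must be > 0")
        if self.amplitude_matrix is not None:
            amp = np.asarray(self.amplitude_matrix, dtype=float)
            if amp.shape != (len(self.gestures), self.n_channels):
                raise ValidationError(
                    f"amplitude_matrix must be {len(self.gestures)}x{self.n_channels}"
                )
            if np.any(amp < 0):
                raise ValidationError("amplitude_matrix must be nonnegative")
            object.__setattr__(self, "amplitude_matrix", amp)


def default_amplitude_matrix(
    class_separation: float,
    gestures: Sequence[str] = GESTURE_LABELS,
    n_channels: int = 2,
) -> np.ndarray:
    """Gesture x channel activation template scaled to a target separation.

    The base template is scaled so the minimum pairwise Euclidean distance
    between rows equals ``class_separation * NOISE_SD_REF``; hence the
    separation between the closest gesture pair is exactly class_separation
    noise-reference units, and distances scale linearly in class_separation.
    Extra channels beyond two repeat the two-site pattern.
    """
    if class_separation <= 0:
        raise ValidationError("class_separation must be > 0")
    rows = []
    for g in gestures:
        base = _BASE_TEMPLATE.get(g)
        if base is None:  # unseen label: spread low activations deterministically
            h = (sum(ord(ch) for ch in g) % 7) / 10.0
            base = (0.2 + h / 2.0, 0.7 - h / 2.0)
        row = [base[c % 2] for c in range(n_channels)]
        rows.append(row)
    amp = np.array(rows, dtype=float)
    dists = [
        np.linalg.norm(amp[i] - amp[j])
        for i in range(len(rows))
        for j in range(i + 1, len(rows))
    ]
    min_dist = min(dists)
    if min_dist <= 0:
        raise ValidationError("amplitude template has duplicate gesture rows")
    return amp * (class_separation * NOISE_SD_REF / min_dist)


def generate_recording(cfg: GeneratorConfig) -> Recording:
    """Simulate one labelled recording under the configured protocol.

    Layout per repetition: rest baseline, then a one-sample-step onset
    (optionally jittered), a constant hold at the gesture's activation level,
    and return to rest.  Sample values are envelope + half-normal noise of
    scale ``noise_sd`` (the stream is nonnegative, like a device RMS output).
    Hold intervals are annotated with their gesture label; everything else is
    unannotated rest.  Fully determined by ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    fs = cfg.sampling_rate_hz
    amp = (
        cfg.amplitude_matrix
        if cfg.amplitude_matrix is not None
        else default_amplitude_matrix(cfg.class_separation, cfg.gestures, cfg.n_channels)
    )
    n_hold = int(round(cfg.hold_seconds * fs))
    n_rest = int(round(cfg.rest_seconds * fs))
    jitter_max = int(round(cfg.onset_jitter_ms / 1000.0 * fs))

    env_parts: list[np.ndarray] = []
    annotations: list[Annotation] = []
    cursor = 0
    for g_idx, gesture in enumerate(cfg.gestures):
        for _ in range(cfg.reps_per_gesture):
            jitter = int(rng.integers(-jitter_max, jitter_max + 1)) if jitter_max else 0
            pre = max(n_rest + jitter, 0)
            env_parts.append(np.zeros((pre, cfg.n_channels)))
            cursor += pre
            env_parts.append(np.tile(amp[g_idx], (n_hold, 1)))
            annotations.append(Annotation(cursor, cursor + n_hold, gesture))
            cursor += n_hold
    env_parts.append(np.zeros((n_rest, cfg.n_channels)))  # trailing rest
    envelope = np.vstack(env_parts)
    noise = np.abs(rng.normal(0.0, cfg.noise_sd, size=envelope.shape)) if cfg.noise_sd else 0.0
    samples = envelope + noise

    channel_names = tuple(
        ("flexor", "extensor")[c] if c < 2 else f"ch{c + 1}" for c in range(cfg.n_channels)
    )
    return Recording(
        channels=channel_names,
        samples=samples,
        sampling_rate_hz=fs,
        annotations=tuple(annotations),
        label_set=tuple(cfg.gestures) + (REST_LABEL,),
    )


def generate_segments(
    cfg: GeneratorConfig,
    window_ms: float = DEFAULT_WINDOW_MS,
    label_policy: str = "majority",
    include_rest: bool = False,
) -> list[Segment]:
    """Generate a recording and segment it; REST windows dropped by default."""
    rec = generate_recording(cfg)
    segs = sliding_segments(rec, window_ms=window_ms, label_policy=label_policy)
    if include_rest:
        return segs
    return [s for s in segs if s.label != REST_LABEL]


def generate_feature_dataset(
    cfg: GeneratorConfig,
    feature_cfg: FeatureConfig | None = None,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> list[FeatureVector]:
    """End-to-end: simulate, segment, extract labelled feature vectors.

    REST windows are excluded; any auto threshold in ``feature_cfg`` is
    resolved on the generated segments.
    """
    feature_cfg = feature_cfg or FeatureConfig(feature_set=("MAV",))
    segs = generate_segments(cfg, window_ms=window_ms)
    feature_cfg = resolve_config(feature_cfg, segs)
    return [extract_features(s, feature_cfg) for s in segs]
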