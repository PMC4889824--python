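"""Data model and I/O for surface-EMG recordings, plus sliding-window segmentation.

A :class:`Recording` holds a multi-channel SEMG time series sampled at a fixed
rate together with labelled gesture intervals.  The on-disk representation is a
plain-text signal table (CSV/TSV, one column per channel, optional leading time
column) and a JSON sidecar carrying the sampling rate, channel names and
annotations.  Indices are 0-based and intervals half-open throughout.

Segmentation follows the sliding (non-overlapping) scheme: consecutive windows
of fixed length partition the recording left to right; a trailing remainder
shorter than one window is discarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, MalformedInputError, ValidationError

#: The six gesture classes: hand close/open, wrist flexion/extension,
#: index-finger straightening, thumb straightening.
GESTURE_LABELS: tuple[str, ...] = ("HC", "HO", "WF", "WE", "IF", "T")
REST_LABEL = "REST"
DEFAULT_LABEL_SET: tuple[str, ...] = GESTURE_LABELS + (REST_LABEL,)

#: Window length used throughout the toolkit: 187.5 ms, i.e. exactly 3 samples
#: at the 16 Hz device rate.
DEFAULT_WINDOW_MS = 187.5

_TIME_COLUMN_NAMES = {"time", "t", "timestamp", "time_s", "seconds"}


@dataclass(frozen=True)
class Annotation:
    """A labelled half-open sample interval [start, end)."""

    start: int
    end: int
    label: str


@dataclass
class Recording:
    """A multi-channel SEMG recording with gesture annotations.

    Parameters
    ----------
    channels
        Ordered channel names.
    samples
        Array of shape (n_samples, n_channels); all channels share one length.
    sampling_rate_hz
        Positive sampling rate.
    annotations
        Non-overlapping labelled intervals over sample indices.
    label_set
        Labels annotations may use.  Defaults to the six gestures plus REST.
    """

    channels: tuple[str, ...]
    samples: np.ndarray
    sampling_rate_hz: float
    annotations: tuple[Annotation, ...] = ()
    label_set: tuple[str, ...] = DEFAULT_LABEL_SET

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.samples = np.asarray(self.samples, dtype=float)
        self.annotations = tuple(
            a if isinstance(a, Annotation) else Annotation(*a) for a in self.annotations
        )
        self.label_set = tuple(self.label_set)
        self._validate()

    def _validate(self) -> None:
        if self.samples.ndim != 2:
            raise MalformedInputError(
                f"samples must be 2-D (n_samples, n_channels); got shape {self.samples.shape}"
            )
        if self.samples.shape[1] != len(self.channels):
            raise ValidationError(
                f"{len(self.channels)} channel names but {self.samples.shape[1]} sample columns"
            )
        if not (np.isfinite(self.sampling_rate_hz) and self.sampling_rate_hz > 0):
            raise ValidationError(f"sampling_rate_hz must be > 0; got {self.sampling_rate_hz}")
        n = self.n_total
        prev_end = -1
        for ann in sorted(self.annotations, key=lambda a: a.start):
            if not (0 <= ann.start < ann.end <= n):
                raise ValidationError(
                    f"annotation ({ann.start}, {ann.end}, {ann.label!r}) outside [0, {n}]"
                )
            if ann.start < prev_end:
                raise ValidationError(
                    f"annotations overlap at index {ann.start} (label {ann.label!r})"
                )
            if ann.label not in self.label_set:
                raise ValidationError(
                    f"unknown gesture label {ann.label!r}; expected one of {self.label_set}"
                )
            prev_end = ann.end

    @property
    def n_total(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_total / self.sampling_rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.channels.index(name)]


@dataclass
class Segment:
    """A fixed-length labelled window of a recording.

    ``window`` has shape (N, n_channels) with N >= 3 so that every time-domain
    feature (including slope-sign change) is defined on it.
    """

    window: np.ndarray
    label: str
    source_span: tuple[int, int]
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        if self.window.ndim == 1:
            self.window = self.window[:, None]
        if self.window.shape[0] < 3:
            raise ValidationError(f"segment needs >= 3 samples; got {self.window.shape[0]}")
        if not self.label:
            raise ValidationError("segment label must be non-empty")
        if self.channels and len(self.channels) != self.window.shape[1]:
            raise ValidationError("channel names inconsistent with window width")

    @property
    def n_samples(self) -> int:
        return self.window.shape[0]


def read_recording(signal_path: str | Path, meta_path: str | Path) -> Recording:
    """Read a recording from a signal table plus JSON metadata sidecar.

    The signal file is CSV or TSV with a header row naming the channels; a
    leading time column (named ``time``/``t``/``timestamp``) is ignored.  The
    sidecar declares ``sampling_rate_hz``, ``channel_names`` and ``labels``
    (``[{start, end, label}, ...]``, half-open sample indices).
    """
    meta_path = Path(meta_path)
    signal_path = Path(signal_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    sep = "\t" if signal_path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(signal_path, sep=sep)
    except (pd.errors.ParserError, ValueError) as exc:
        raise MalformedInputError(f"cannot parse signal file {signal_path}: {exc}") from exc
    if df.isna().any().any():
        raise MalformedInputError(
            f"signal file {signal_path} has ragged or missing entries"
        )

    channel_names = meta.get("channel_names")
    if channel_names:
        missing = [c for c in channel_names if c not in df.columns]
        if missing:
            raise MalformedInputError(f"channels {missing} not found in {signal_path}")
        df = df[list(channel_names)]
    elif df.columns[0].strip().lower() in _TIME_COLUMN_NAMES:
        df = df.iloc[:, 1:]

    annotations = tuple(
        Annotation(int(a["start"]), int(a["end"]), str(a["label"]))
        for a in meta.get("labels", [])
    )
    label_set = tuple(meta.get("label_set", DEFAULT_LABEL_SET))
    return Recording(
        channels=tuple(df.columns),
        samples=df.to_numpy(dtype=float),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        annotations=annotations,
        label_set=label_set,
    )


def write_recording(rec: Recording, signal_path: str | Path, meta_path: str | Path) -> None:
    """Write a recording to the tabular + JSON sidecar format.

    Numeric values round-trip through :func:`read_recording` to at least 12
    significant digits.  Non-finite samples are rejected before anything is
    written.
    """
    if not np.all(np.isfinite(rec.samples)):
        raise ValidationError("recording contains non-finite samples; refusing to write")
    signal_path = Path(signal_path)
    meta_path = Path(meta_path)
    df = pd.DataFrame(rec.samples, columns=list(rec.channels))
    df.to_csv(signal_path, index=False, float_format="%.17g")
    meta = {
        "sampling_rate_hz": rec.sampling_rate_hz,
        "channel_names": list(rec.channels),
        "labels": [
            {"start": a.start, "end": a.end, "label": a.label} for a in rec.annotations
        ],
        "label_set": list(rec.label_set),
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)


def window_length_samples(window_ms: float, sampling_rate_hz: float) -> int:
    """Window length in samples: round(window_ms / 1000 * fs).

    At 16 Hz and 187.5 ms this is exactly 3.
    """
    return int(round(window_ms / 1000.0 * sampling_rate_hz))


def _window_label(
    start: int,
    end: int,
    annotations: Sequence[Annotation],
    policy: str,
) -> str | None:
    """Label for the half-open window [start, end) under the given policy.

    ``majority``: the label covering most samples wins; samples outside any
    annotation count as REST.  Ties go to the earlier-starting annotation;
    REST only wins an outright majority.  ``strict``: windows whose samples
    are not all under a single label (REST included) are dropped (None).
    """
    # coverage per overlapping annotation, in annotation start order
    cover: list[tuple[int, int, str]] = []  # (n_covered, ann_start, label)
    covered_total = 0
    for ann in annotations:
        n_cov = min(end, ann.end) - max(start, ann.start)
        if n_cov > 0:
            cover.append((n_cov, ann.start, ann.label))
            covered_total += n_cov
    n_rest = (end - start) - covered_total

    if policy == "strict":
        if n_rest == end - start:
            return REST_LABEL
        if len(cover) == 1 and n_rest == 0:
            return cover[0][2]
        return None
    if policy != "majority":
        raise ConfigurationError(f"unknown label_policy {policy!r}")
    if not cover:
        return REST_LABEL
    best = max(cover, key=lambda c: (c[0], -c[1]))  # most samples; tie -> earliest start
    return best[2] if best[0] >= n_rest else REST_LABEL


def sliding_segments(
    rec: Recording,
    window_ms: float = DEFAULT_WINDOW_MS,
    label_policy: str = "majority",
) -> list[Segment]:
    """Cut a recording into consecutive non-overlapping labelled windows.

    Windows partition the recording left to right; the trailing remainder
    shorter than one window is discarded.  Each window is labelled from the
    annotations it overlaps according to ``label_policy`` (windows outside any
    annotation are REST).  Under ``strict``, mixed-label windows are dropped.

    Raises :class:`ConfigurationError` if the window is shorter than 3 samples
    (slope-sign change needs interior points).  A recording shorter than one
    window yields an empty list.
    """
    n = window_length_samples(window_ms, rec.sampling_rate_hz)
    if n < 3:
        raise ConfigurationError(
            f"window of {window_ms} ms at {rec.sampling_rate_hz} Hz is {n} samples; need >= 3"
        )
    anns = sorted(rec.annotations, key=lambda a: a.start)
    segments: list[Segment] = []
    for start in range(0, rec.n_total - n + 1, n):
        end = start + n
        label = _window_label(start, end, anns, label_policy)
        if label is None:
            continue
        segments.append(
            Segment(
                window=rec.samples[start:end],
                label=label,
                source_span=(start, end),
                channels=rec.channels,
            )
        )
    return segments
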