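"""Segmentation of streams into behaviour-homogeneous windows.

Streams are cut into fixed-length, non-overlapping windows starting at
sample indices 0, T, 2T, ...; the trailing remainder shorter than T is
discarded.  A window is kept only if all of its per-sample behaviour
annotations agree (behavioural homogeneity); its label is that single
behaviour.  Mixed windows are dropped, not majority-voted.

The default window is T=10 timesteps.  A 5-second window preset keeps
125-sample windows (at 25 Hz) and deterministically subsamples 10 equally
spaced timesteps so the model input stays (T=10, 3 axes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .accel_io import AccelStream, LabelCodec, ScalerParams

logger = logging.getLogger(__name__)


@dataclass
class Window:
    """One behaviour-homogeneous window: a T x 3 block with a single label."""

    values: np.ndarray          # (T, 3)
    label_code: int
    span: tuple[str, int]       # (source_id, start sample index)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError(f"window values must be (T, 3), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window contains non-finite values")


@dataclass
class WindowDataset:
    """Model-ready collection of N homogeneous windows.

    Attributes
    ----------
    X : (N, T, 3) float array of (optionally standardised) acceleration.
    y : (N,) integer class codes in [0, C).
    codec : the behaviour-name <-> code mapping.
    scaler : standardisation parameters, or None if X is raw.
    spans : list of (source_id, start index) provenance, parallel to X.
    synthetic : (N,) bool mask, True for SMOTE-generated windows.
    window_seconds : nominal duration of one window.
    """

    X: np.ndarray
    y: np.ndarray
    codec: LabelCodec
    scaler: ScalerParams | None = None
    spans: list | None = None
    synthetic: np.ndarray | None = None
    window_seconds: float | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 3 or self.X.shape[2] != 3:
            raise ValueError(f"X must be (N, T, 3), got {self.X.shape}")
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have equal length")
        if len(self.y) and (self.y.min() < 0 or self.y.max() >= self.codec.num_classes):
            raise ValueError("labels outside [0, C)")
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.y), dtype=bool)
        if self.spans is None:
            self.spans = [("", -1)] * len(self.y)

    def __len__(self) -> int:
        return len(self.y)

    @property
    def T(self) -> int:
        return self.X.shape[1]

    @property
    def num_classes(self) -> int:
        return self.codec.num_classes

    def class_counts(self) -> np.ndarray:
        """Per-class window counts over all C classes (zeros included)."""
        return np.bincount(self.y, minlength=self.codec.num_classes)

    def subset(self, indices: np.ndarray) -> "WindowDataset":
        indices = np.asarray(indices, dtype=np.int64)
        return WindowDataset(
            X=self.X[indices],
            y=self.y[indices],
            codec=self.codec,
            scaler=self.scaler,
            spans=[self.spans[i] for i in indices],
            synthetic=self.synthetic[indices],
            window_seconds=self.window_seconds,
        )


def segment(stream: AccelStream, T: int) -> list[tuple[np.ndarray, np.ndarray, tuple[str, int]]]:
    """Cut a stream into candidate windows of T consecutive samples.

    Returns ``(values, label_sequence, span)`` triples for windows starting
    at 0, T, 2T, ...; the trailing remainder is discarded.  No homogeneity
    check is applied here.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    n = len(stream)
    n_windows = n // T
    if n_windows == 0:
        warnings.warn(
            f"{stream.source_id}: stream of {n} sample(s) shorter than one window (T={T})",
            stacklevel=2,
        )
        return []
    out = []
    for w in range(n_windows):
        start = w * T
        out.append(
            (stream.acc[start:start + T], stream.labels[start:start + T],
             (stream.source_id, start))
        )
    return out


def homogeneity_filter(candidates) -> list[Window]:
    """Keep only candidates whose T per-sample labels are all identical.

    The kept window's label is that single behaviour (still as a raw name in
    ``label_code`` position -1; encoding happens in :func:`build_dataset`).
    Returns ``(values, label_name, span)`` triples packed as raw tuples so the
    codec can be applied later; mixed windows are counted in the log.
    """
    kept = []
    n_mixed = 0
    for values, labels, span in candidates:
        first = labels[0]
        if all(lab == first for lab in labels[1:]):
            kept.append((values, first, span))
        else:
            n_mixed += 1
    if n_mixed:
        logger.info("dropped %d mixed-label window(s)", n_mixed)
    return kept


def subsample_timesteps(values: np.ndarray, T_out: int) -> np.ndarray:
    """Uniformly subsample ``T_out`` equally spaced timesteps from a window.

    Indices are ``round(i * (T_in - 1) / (T_out - 1))`` for i = 0..T_out-1,
    so the first and last samples are always retained.  Used by the
    5-second-window preset (125 samples -> 10 timesteps).
    """
    t_in = values.shape[0]
    if t_in < T_out:
        raise ValueError(f"cannot subsample {T_out} steps from {t_in}")
    idx = np.round(np.arange(T_out) * (t_in - 1) / (T_out - 1)).astype(int)
    return values[idx]


def build_dataset(
    streams: list[AccelStream],
    T: int,
    codec: LabelCodec,
    *,
    model_timesteps: int | None = None,
    rate_hz: float = 25.0,
) -> WindowDataset:
    """Window every stream and assemble the model-ready dataset.

    Each stream is windowed independently (a window never spans two source
    streams), homogeneous windows are kept in deterministic order (stream
    order, then start index) and labels are integer-encoded via ``codec``.
    When ``model_timesteps`` is given and smaller than ``T``, each kept
    window is subsampled to that many equally spaced timesteps.
    """
    values_list, names, spans = [], [], []
    for stream in streams:
        for v, name, span in homogeneity_filter(segment(stream, T)):
            if model_timesteps is not None and model_timesteps < T:
                v = subsample_timesteps(v, model_timesteps)
            values_list.append(v)
            names.append(name)
            spans.append(span)
    t_eff = model_timesteps if (model_timesteps is not None and model_timesteps < T) else T
    if not values_list:
        X = np.zeros((0, t_eff, 3))
        y = np.zeros(0, dtype=np.int64)
    else:
        X = np.stack(values_list)
        y = codec.encode(names)
    return WindowDataset(X=X, y=y, codec=codec, spans=spans,
                         window_seconds=T / rate_hz)
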