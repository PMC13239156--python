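"""Reading, cleaning, encoding and scaling of labelled accelerometer streams.

The on-disk format is the CSV dialect used by collar-accelerometer behaviour
datasets: one row per 25 Hz sample with columns ``TimeStamp_UNIX``,
``TimeStamp_JST``, ``AccX``, ``AccY``, ``AccZ`` (acceleration in g) and an
annotated behaviour ``Label``.  The reader is header-driven, so column order
does not matter; the writer always emits the canonical order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the CSV dialect
CSV_COLUMNS = ["TimeStamp_UNIX", "TimeStamp_JST", "AccX", "AccY", "AccZ", "Label"]
_NUMERIC_COLUMNS = ["TimeStamp_UNIX", "AccX", "AccY", "AccZ"]
_REQUIRED_COLUMNS = ["TimeStamp_UNIX", "TimeStamp_JST", "AccX", "AccY", "AccZ"]

#: sensor full-scale range in g (16-bit accelerometer, +/-2 g)
SENSOR_RANGE_G = 2.0

#: labels dropped by default: unannotated rows and the catch-all category
DEFAULT_DROP_LABELS = frozenset({"", "other"})

_STD_EPS = 1e-8


class FormatError(ValueError):
    """Raised when an input file does not match the expected CSV dialect."""


@dataclass
class AccelStream:
    """A time-ordered labelled triaxial accelerometer recording.

    Attributes
    ----------
    t_unix : (N,) float64 array of seconds since the epoch (non-decreasing).
    t_jst : (N,) array of opaque local-time strings, carried through verbatim.
    acc : (N, 3) float array of acceleration in g (X, Y, Z).
    labels : (N,) array of behaviour-name strings ('' where unannotated).
    rate_hz : nominal sampling rate.
    source_id : provenance string (file name or simulator tag).
    """

    t_unix: np.ndarray
    t_jst: np.ndarray
    acc: np.ndarray
    labels: np.ndarray
    rate_hz: float = 25.0
    source_id: str = ""
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.t_unix = np.asarray(self.t_unix, dtype=np.float64)
        self.t_jst = np.asarray(self.t_jst, dtype=object)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=np.float64))
        if self.acc.size == 0:
            self.acc = self.acc.reshape(0, 3)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.acc.shape[1] != 3:
            raise ValueError(f"acc must have 3 columns, got {self.acc.shape}")
        if not (len(self.t_unix) == len(self.t_jst) == len(self.acc) == len(self.labels)):
            raise ValueError("t_unix, t_jst, acc and labels must have equal length")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(self.t_unix) > 1 and np.any(np.diff(self.t_unix) < 0):
            raise ValueError("t_unix must be non-decreasing")

    def __len__(self) -> int:
        return len(self.t_unix)

    def take(self, index: np.ndarray, source_suffix: str = "") -> "AccelStream":
        """Return a new stream with the rows at ``index`` (order preserved)."""
        return AccelStream(
            t_unix=self.t_unix[index],
            t_jst=self.t_jst[index],
            acc=self.acc[index],
            labels=self.labels[index],
            rate_hz=self.rate_hz,
            source_id=self.source_id + source_suffix,
        )

    def label_inventory(self) -> dict[str, int]:
        """Distinct raw labels and their sample counts, in first-seen order."""
        inventory: dict[str, int] = {}
        for lab in self.labels:
            inventory[lab] = inventory.get(lab, 0) + 1
        return inventory


@dataclass(frozen=True)
class LabelCodec:
    """Bijective behaviour-name <-> integer-code mapping.

    Codes are assigned lexicographically over names so that the encoding is
    deterministic across runs and platforms.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("label names must be unique")
        if tuple(sorted(self.names)) != self.names:
            raise ValueError("label names must be lexicographically sorted")

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "LabelCodec":
        return cls(names=tuple(sorted(set(labels))))

    @property
    def num_classes(self) -> int:
        return len(self.names)

    def code_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"label {name!r} not covered by codec {self.names}") from None

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        lookup = {name: i for i, name in enumerate(self.names)}
        try:
            return np.array([lookup[lab] for lab in labels], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} not covered by codec {self.names}") from None

    def decode(self, codes: Sequence[int]) -> np.ndarray:
        return np.array([self.names[int(c)] for c in codes], dtype=object)

    def to_dict(self) -> dict:
        return {"names": list(self.names)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "LabelCodec":
        return cls(names=tuple(d["names"]))


@dataclass
class ScalerParams:
    """Per-axis standardisation parameters (zero mean, unit variance).

    ``std`` is the population standard deviation, floored at 1e-8 so that a
    constant axis maps to zero instead of dividing by zero.
    """

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.std))):
            raise ValueError("scaler parameters must be finite")
        if np.any(self.std < _STD_EPS):
            raise ValueError(f"std components must be >= {_STD_EPS}")

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScalerParams":
        return cls(mean=np.asarray(d["mean"]), std=np.asarray(d["std"]))


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def read_accel_csv(path: str | Path, rate_hz: float = 25.0) -> AccelStream:
    """Read one accelerometer CSV file into an :class:`AccelStream`.

    Parsing is header-driven (column order is irrelevant).  Rows whose
    timestamp or acceleration values do not parse as numbers are dropped and
    counted in ``n_dropped_rows``.  A missing ``Label`` column yields empty
    labels; any other missing column raises :class:`FormatError`.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    has_label = "Label" in frame.columns

    # pd.to_numeric flags unparseable entries; the actual conversion uses
    # NumPy's string cast, which is round-trip exact where pandas' is not
    coerced = frame[_NUMERIC_COLUMNS].apply(pd.to_numeric, errors="coerce")
    ok = coerced.notna().all(axis=1).to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d unparseable row(s)", path.name, n_dropped)
    numeric = {
        col: frame.loc[ok, col].to_numpy(dtype="U32").astype(np.float64)
        for col in _NUMERIC_COLUMNS
    }

    acc = np.column_stack([numeric["AccX"], numeric["AccY"], numeric["AccZ"]])
    if acc.size and np.any(np.abs(acc) > SENSOR_RANGE_G):
        warnings.warn(
            f"{path.name}: {int(np.sum(np.any(np.abs(acc) > SENSOR_RANGE_G, axis=1)))} "
            f"sample(s) outside the +/-{SENSOR_RANGE_G} g sensor range (passed through)",
            stacklevel=2,
        )
    stream = AccelStream(
        t_unix=numeric["TimeStamp_UNIX"],
        t_jst=frame.loc[ok, "TimeStamp_JST"].to_numpy(dtype=object),
        acc=acc,
        labels=(frame.loc[ok, "Label"].to_numpy(dtype=object) if has_label
                else np.full(int(ok.sum()), "", dtype=object)),
        rate_hz=rate_hz,
        source_id=path.name,
        n_dropped_rows=n_dropped,
    )
    if len(stream) == 0:
        warnings.warn(f"{path.name}: no valid samples", stacklevel=2)
    return stream


def write_accel_csv(stream: AccelStream, path: str | Path) -> None:
    """Write a stream in the canonical column order (UTF-8, '.' decimal).

    Floats are written with ``repr`` shortest round-trip formatting so that a
    read-write-read cycle reproduces the numeric columns bit-exactly.
    """
    frame = pd.DataFrame(
        {
            "TimeStamp_UNIX": [repr(float(v)) for v in stream.t_unix],
            "TimeStamp_JST": stream.t_jst,
            "AccX": [repr(float(v)) for v in stream.acc[:, 0]],
            "AccY": [repr(float(v)) for v in stream.acc[:, 1]],
            "AccZ": [repr(float(v)) for v in stream.acc[:, 2]],
            "Label": stream.labels,
        },
        columns=CSV_COLUMNS,
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Label cleaning
# ---------------------------------------------------------------------------

def clean_labels(stream: AccelStream, drop: Iterable[str] | None = None) -> AccelStream:
    """Remove unannotated samples and dropped behaviour categories.

    By default blank labels (empty or whitespace-only) and the catch-all
    ``"other"`` category are removed, matching the standard cleaning of the
    raw 15-category annotation down to 13 well-defined behaviours.  Matching
    of ``drop`` names is case-insensitive; surviving samples keep their
    relative order.
    """
    drop_set = {d.strip().lower() for d in (DEFAULT_DROP_LABELS if drop is None else drop)}
    stripped = [str(lab).strip() for lab in stream.labels]
    keep = np.array(
        [bool(s) and s.lower() not in drop_set for s in stripped], dtype=bool
    )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("%s: removed %d sample(s) with dropped/blank labels",
                    stream.source_id, n_removed)
    out = stream.take(np.flatnonzero(keep))
    if len(out) == 0:
        warnings.warn(f"{stream.source_id}: no samples left after label cleaning",
                      stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Standardisation
# ---------------------------------------------------------------------------

def fit_scaler(samples: np.ndarray) -> ScalerParams:
    """Fit per-axis standardisation parameters on an (..., 3) array of samples.

    Uses the sample mean and the population standard deviation per axis.
    To avoid information leakage this should be fitted on the training
    partition only (the pipeline enforces that by default).
    """
    x = np.asarray(samples, dtype=np.float64).reshape(-1, 3)
    if x.shape[0] == 0:
        raise ValueError("cannot fit scaler on empty input")
    mean = x.mean(axis=0)
    std = np.maximum(x.std(axis=0), _STD_EPS)
    return ScalerParams(mean=mean, std=std)


def apply_scaler(data, params: ScalerParams):
    """Standardise componentwise: ``x' = (x - mean) / std``.

    Accepts an :class:`AccelStream` (returns a new stream) or any array whose
    last axis has length 3 (windows, tensors, single samples).
    """
    if isinstance(data, AccelStream):
        out = data.take(np.arange(len(data)))
        out.acc = (data.acc - params.mean) / params.std
        return out
    x = np.asarray(data, dtype=np.float64)
    return (x - params.mean) / params.std


def invert_scaler(data, params: ScalerParams):
    """Inverse of :func:`apply_scaler`: ``x = x' * std + mean``."""
    if isinstance(data, AccelStream):
        out = data.take(np.arange(len(data)))
        out.acc = data.acc * params.std + params.mean
        return out
    x = np.asarray(data, dtype=np.float64)
    return x * params.std + params.mean


# ---------------------------------------------------------------------------
# Stratified partitioning
# ---------------------------------------------------------------------------

def split_train_test(dataset, test_fraction: float = 0.20, seed: int = 0):
    """Stratified split of a window dataset into train and test partitions.

    For every class ``c`` with ``n_c`` windows, ``round(n_c * test_fraction)``
    windows go to the test set (capped so at least one window stays in
    training); a class with a single window goes entirely to training with a
    warning.  The partition is disjoint, exhaustive and deterministic for a
    fixed seed.

    The split operates on whole windows, the model's atomic unit; splitting
    raw rows would sever windows across the partition boundary.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    y = np.asarray(dataset.y)
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for c in np.unique(y):
        idx_c = np.flatnonzero(y == c)
        n_c = len(idx_c)
        if n_c == 1:
            warnings.warn(
                f"class {c} has a single window; assigning it to the training set",
                stacklevel=2,
            )
            continue
        n_test = int(round(n_c * test_fraction))
        n_test = min(max(n_test, 0), n_c - 1)
        perm = rng.permutation(idx_c)
        test_idx.append(perm[:n_test])
    test_indices = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], dtype=int)
    mask = np.zeros(len(y), dtype=bool)
    mask[test_indices] = True
    train_indices = np.flatnonzero(~mask)
    return dataset.subset(train_indices), dataset.subset(test_indices)


# ---------------------------------------------------------------------------
# Sidecar metadata
# ---------------------------------------------------------------------------

def save_metadata(path: str | Path, codec: LabelCodec, scaler: ScalerParams | None,
                  extra: Mapping | None = None) -> None:
    """Persist codec + scaler as a JSON sidecar for reuse at inference."""
    payload = {"label_codec": codec.to_dict(),
               "scaler": scaler.to_dict() if scaler is not None else None}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_metadata(path: str | Path) -> tuple[LabelCodec, ScalerParams | None, dict]:
    payload = json.loads(Path(path).read_text())
    codec = LabelCodec.from_dict(payload["label_codec"])
    scaler = ScalerParams.from_dict(payload["scaler"]) if payload.get("scaler") else None
    return codec, scaler, payload
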