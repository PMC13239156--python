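"""Whole-window SMOTE: classical minority oversampling on flattened windows.

Classical SMOTE creates a synthetic minority sample by linear interpolation
between a real sample and one of its k nearest same-class neighbours.
Applied to windowed accelerometer data, the unit of interpolation is the
entire flattened window (time-major, 3T-dimensional), so the short-horizon
temporal structure inside each window is preserved in the synthetic data —
interpolating individual timesteps independently would destroy it.

All classes are oversampled to the majority class count ("match-majority").
The implementation is self-contained: neighbour search is a chunked
brute-force Euclidean k-NN with deterministic tie-breaking, and all random
choices come from a single seeded generator drawn in a fixed order, so the
output is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .windowing import WindowDataset

logger = logging.getLogger(__name__)


@dataclass
class SmoteConfig:
    """Hyperparameters of the window-level SMOTE balancing step.

    k_neighbors defaults to the classical SMOTE value of 5; for a class with
    n samples the effective k is min(k, n-1).  The metric is Euclidean on the
    flattened (standardised) window vectors.
    """

    k_neighbors: int = 5
    target: str | Mapping[int, int] = "match-majority"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def flatten_window(w: np.ndarray) -> np.ndarray:
    """Flatten a (T, 3) window to a 3T vector in time-major layout
    [t0x, t0y, t0z, t1x, ...]."""
    w = np.asarray(w)
    return w.reshape(-1)


def unflatten_window(v: np.ndarray, T: int | None = None) -> np.ndarray:
    """Inverse of :func:`flatten_window`; vector length must be divisible by 3."""
    v = np.asarray(v)
    if v.size % 3 != 0:
        raise ValueError(f"vector length {v.size} not divisible by 3")
    t = v.size // 3
    if T is not None and t != T:
        raise ValueError(f"vector length {v.size} inconsistent with T={T}")
    return v.reshape(t, 3)


def knn_minority(Xc: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """k nearest same-class neighbours of every point, self excluded.

    Returns an (n, k_eff) index table with k_eff = min(k, n-1), neighbours
    ordered by increasing Euclidean distance; exact distance ties are broken
    in favour of the lower index.  n = 1 yields an empty table (such classes
    are replicated verbatim upstream).
    """
    Xc = np.asarray(Xc, dtype=np.float64)
    if Xc.ndim == 1:
        Xc = Xc[:, None]
    n = len(Xc)
    if n < 2:
        return np.zeros((n, 0), dtype=np.int64)
    k_eff = min(k, n - 1)
    sq_norms = np.einsum("ij,ij->i", Xc, Xc)
    out = np.empty((n, k_eff), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        # squared distances; clip the tiny negatives the expansion can produce
        d2 = sq_norms[start:stop, None] + sq_norms[None, :] - 2.0 * (Xc[start:stop] @ Xc.T)
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf
        if k_eff < n - 1:
            # coarse selection, then exact deterministic ordering of the top block
            part = np.argpartition(d2, k_eff, axis=1)[:, : k_eff + 1]
            for r in range(stop - start):
                cand = part[r]
                order = np.lexsort((cand, d2[r, cand]))
                out[start + r] = cand[order][:k_eff]
        else:
            order = np.argsort(d2, axis=1, kind="stable")
            out[start:stop] = order[:, :k_eff]
    return out


def synthesize(x: np.ndarray, neighbor: np.ndarray, lam: float) -> np.ndarray:
    """Interpolate one synthetic point: ``x + lam * (neighbor - x)``, lam in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0, 1]")
    x = np.asarray(x, dtype=np.float64)
    return x + lam * (np.asarray(neighbor, dtype=np.float64) - x)


def _synthesize_class(
    Xc: np.ndarray, n_new: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Generate ``n_new`` synthetic vectors for one class (n >= 2).

    Random draws happen in a fixed order — base indices, then neighbour
    slots, then interpolation coefficients — so results are reproducible.
    """
    nbrs = knn_minority(Xc, k)
    k_eff = nbrs.shape[1]
    base = rng.integers(0, len(Xc), size=n_new)
    slot = rng.integers(0, k_eff, size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    anchors = Xc[base].astype(np.float64)
    targets = Xc[nbrs[base, slot]].astype(np.float64)
    return anchors + lam[:, None] * (targets - anchors)


def balance(dataset: WindowDataset, cfg: SmoteConfig | None = None) -> WindowDataset:
    """Oversample every class of a window dataset to the target count.

    With the default "match-majority" strategy every class is brought up to
    the majority class count.  Original windows are preserved unchanged and
    come first, in their original order; synthetic windows are appended in
    ascending class-code order and flagged in ``dataset.synthetic``.  A class
    with a single window is replicated verbatim (no neighbour to interpolate
    with); the majority class is untouched.  Deterministic for a fixed seed.
    """
    cfg = cfg or SmoteConfig()
    counts = dataset.class_counts()
    present = np.flatnonzero(counts)
    if len(present) < 2:
        raise ValueError("balance() needs at least two classes with windows")

    if isinstance(cfg.target, str):
        if cfg.target != "match-majority":
            raise ValueError(f"unknown target strategy {cfg.target!r}")
        targets = {int(c): int(counts.max()) for c in present}
    else:
        targets = {int(c): int(v) for c, v in cfg.target.items()}

    n, T = len(dataset), dataset.T
    flat = dataset.X.reshape(n, T * 3)
    rng = np.random.default_rng(cfg.seed)

    new_X, new_y, new_spans = [], [], []
    for c in sorted(targets):
        n_c = int(counts[c])
        n_new = targets[c] - n_c
        if n_new <= 0:
            continue
        idx_c = np.flatnonzero(dataset.y == c)
        Xc = flat[idx_c]
        name = dataset.codec.names[c]
        if n_c == 1:
            synth = np.repeat(Xc, n_new, axis=0).astype(np.float64)
            logger.info("class %s: single window replicated %d times", name, n_new)
        else:
            synth = _synthesize_class(Xc, n_new, cfg.k_neighbors, rng)
        new_X.append(synth.astype(dataset.X.dtype, copy=False))
        new_y.append(np.full(n_new, c, dtype=np.int64))
        new_spans.extend([(f"smote:{name}", -1)] * n_new)
        logger.info("class %s: %d -> %d windows (+%d synthetic)",
                    name, n_c, targets[c], n_new)

    if not new_X:
        return dataset

    X_out = np.concatenate([flat] + new_X).reshape(-1, T, 3)
    y_out = np.concatenate([dataset.y] + new_y)
    n_synth = len(y_out) - n
    return WindowDataset(
        X=X_out,
        y=y_out,
        codec=dataset.codec,
        scaler=dataset.scaler,
        spans=list(dataset.spans) + new_spans,
        synthetic=np.concatenate([dataset.synthetic, np.ones(n_synth, dtype=bool)]),
        window_seconds=dataset.window_seconds,
    )
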