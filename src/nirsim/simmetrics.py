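"""The 11 similarity / dissimilarity measures and batch [0,1] normalization.

Five measures are similarity-oriented (larger = more alike): Pearson, SAM,
Hsim, Close, Gsim.  Six are dissimilarity-oriented (larger = more
different): Euclidean, Manhattan, SID, ED/COD, SS/CS, Esim.  Hsim, Close
and Gsim natively live in (0, 1]; every other measure is mapped to [0, 1]
by min-max normalization over the batch of pair values being compared,
with dissimilarities reversed (1 - scaled), so that within- and
between-class averages share one frame.

Notes on the less standard measures:

* SAM is implemented as the cosine between the spectral vectors (no
  arccos) — a shape-only similarity, invariant to positive scaling.
* SID (spectral information divergence) is the symmetric Kullback-Leibler
  divergence D(p||q) + D(q||p) between the spectra converted to discrete
  probability distributions.  Derivative preprocessing produces negative
  values, so the conversion shifts each vector by its minimum plus a small
  epsilon before sum-normalizing (``conversion="shift"``); taking absolute
  values first is available as ``conversion="abs"``.
* ED/COD = (1 - Pearson) x Euclidean; SS/CS = SID x Euclidean x
  (1 - Pearson): combinatorial dissimilarities that vanish iff the
  component factors do.
* Hsim averages 1/(1 + |dx|); Close averages exp(-|dx|) — both equal 1
  iff the vectors coincide, and stay informative in high dimension where
  raw distances concentrate.
* Gsim averages 1 - |dx_i|/(|dx_i| + m_i) with a per-wavenumber scale
  m_i; here m_i is the per-wavenumber range (max - min) over a context
  dataset (the comparison batch), falling back to 1 where the range is 0.
* Esim averages weighted exp(+r_i/2) of the normalized difference ratio
  r_i = |dx_i| / (|dx_i| + |x_i + y_i|) (0 where the denominator is 0),
  with uniform weights 1/n.  Its value grows with difference, so it is
  treated as dissimilarity-oriented for normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    InputError,
    UndefinedValueError,
)
from .spectra import SpectralDataset

__all__ = [
    "MetricSpec",
    "PairValue",
    "METRICS",
    "METRIC_IDS",
    "base_metric",
    "sid",
    "combined_metric",
    "hd_metric",
    "metric_value",
    "pairwise_matrix",
    "normalize_batch",
]

SID_EPS = 1e-12


@dataclass(frozen=True)
class MetricSpec:
    """Identity and orientation of one measure."""

    metric_id: str
    orientation: str  # "similarity" | "dissimilarity"
    native_unit_interval: bool


METRICS: dict[str, MetricSpec] = {
    m.metric_id: m
    for m in [
        MetricSpec("pearson", "similarity", False),
        MetricSpec("euclidean", "dissimilarity", False),
        MetricSpec("sam", "similarity", False),
        MetricSpec("manhattan", "dissimilarity", False),
        MetricSpec("sid", "dissimilarity", False),
        MetricSpec("ed_cod", "dissimilarity", False),
        MetricSpec("ss_cs", "dissimilarity", False),
        MetricSpec("hsim", "similarity", True),
        MetricSpec("close", "similarity", True),
        MetricSpec("gsim", "similarity", True),
        MetricSpec("esim", "dissimilarity", False),
    ]
}

METRIC_IDS: tuple[str, ...] = tuple(METRICS)


@dataclass
class PairValue:
    """One unordered sample pair's raw metric value and its [0,1]
    normalized similarity (filled by :func:`normalize_batch`)."""

    id_a: str
    id_b: str
    raw: float
    normalized: float | None = None

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise InputError(f"pair of a sample with itself: {self.id_a!r}")
        if self.id_a > self.id_b:
            self.id_a, self.id_b = self.id_b, self.id_a


# ---------------------------------------------------------------------------
# scalar metric functions
# ---------------------------------------------------------------------------

def _check_pair(x, y, min_len: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError(f"vectors must be 1-D of equal length, got {x.shape} and {y.shape}")
    if x.size < min_len:
        raise InputError(f"vectors must have length >= {min_len}")
    return x, y


def base_metric(metric_id: str, x, y) -> float:
    """Pearson correlation, Euclidean distance, SAM cosine, or Manhattan
    distance of two equal-length vectors."""
    x, y = _check_pair(x, y)
    if metric_id == "pearson":
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        if denom == 0.0:
            raise UndefinedValueError("pearson undefined for a constant vector")
        return float((xc @ yc) / denom)
    if metric_id == "euclidean":
        return float(np.sqrt(np.sum((x - y) ** 2)))
    if metric_id == "sam":
        denom = np.sqrt((x @ x) * (y @ y))
        if denom == 0.0:
            raise UndefinedValueError("sam undefined for a zero vector")
        return float((x @ y) / denom)
    if metric_id == "manhattan":
        return float(np.sum(np.abs(x - y)))
    raise ConfigurationError(f"unknown base metric {metric_id!r}")


def _to_probability(m: np.ndarray, conversion: str = "shift", eps: float = SID_EPS) -> np.ndarray:
    """Row-wise conversion to discrete probability distributions."""
    if conversion == "shift":
        v = m - m.min(axis=-1, keepdims=True) + eps
    elif conversion == "abs":
        v = np.abs(m) + eps
    else:
        raise ConfigurationError(f"unknown SID conversion {conversion!r}")
    return v / v.sum(axis=-1, keepdims=True)


def sid(x, y, conversion: str = "shift", eps: float = SID_EPS) -> float:
    """Spectral information divergence: symmetric KL sum
    D(p||q) + D(q||p) >= 0, zero iff x == y."""
    x, y = _check_pair(x, y)
    p = _to_probability(x, conversion, eps)
    q = _to_probability(y, conversion, eps)
    return float(np.sum((p - q) * (np.log(p) - np.log(q))))


def combined_metric(metric_id: str, x, y) -> float:
    """ED/COD and SS/CS combinatorial dissimilarities."""
    if metric_id == "ed_cod":
        return (1.0 - base_metric("pearson", x, y)) * base_metric("euclidean", x, y)
    if metric_id == "ss_cs":
        return (
            sid(x, y)
            * base_metric("euclidean", x, y)
            * (1.0 - base_metric("pearson", x, y))
        )
    raise ConfigurationError(f"unknown combined metric {metric_id!r}")


def hd_metric(
    metric_id: str,
    x,
    y,
    context: SpectralDataset | None = None,
    m: Sequence[float] | None = None,
) -> float:
    """High-dimension oriented measures Hsim, Close, Gsim, Esim.

    Gsim needs a per-wavenumber scale m_i, taken as the per-wavenumber
    range of ``context`` (fallback 1 where the range is 0) or supplied
    explicitly via ``m``."""
    x, y = _check_pair(x, y, min_len=1)
    d = np.abs(x - y)
    n = x.size
    if metric_id == "hsim":
        return float(np.mean(1.0 / (1.0 + d)))
    if metric_id == "close":
        return float(np.mean(np.exp(-d)))
    if metric_id == "gsim":
        mi = _gsim_scale(context, m, n)
        return float(np.mean(1.0 - d / (d + mi)))
    if metric_id == "esim":
        s = np.abs(x + y)
        denom = d + s
        ratio = np.divide(d, denom, out=np.zeros_like(d), where=denom > 0.0)
        w = 1.0 / n
        return float(np.sum(w * np.exp(ratio / 2.0)))
    raise ConfigurationError(f"unknown high-dimensional metric {metric_id!r}")


def _gsim_scale(
    context: SpectralDataset | None, m: Sequence[float] | None, n: int
) -> np.ndarray:
    if m is not None:
        mi = np.asarray(m, dtype=float)
        if mi.shape != (n,):
            raise ConfigurationError(f"gsim scale m has shape {mi.shape}, expected ({n},)")
    elif context is not None:
        M = context.values_matrix()
        if M.shape[1] != n:
            raise ConfigurationError("gsim context axis length mismatch")
        mi = M.max(axis=0) - M.min(axis=0)
    else:
        raise ConfigurationError("gsim requires a context dataset or an explicit scale m")
    mi = np.where(mi > 0.0, mi, 1.0)
    return mi


def metric_value(
    metric_id: str, x, y, context: SpectralDataset | None = None
) -> float:
    """Dispatch to the appropriate metric function by id."""
    if metric_id in ("pearson", "euclidean", "sam", "manhattan"):
        return base_metric(metric_id, x, y)
    if metric_id == "sid":
        return sid(x, y)
    if metric_id in ("ed_cod", "ss_cs"):
        return combined_metric(metric_id, x, y)
    if metric_id in ("hsim", "close", "gsim", "esim"):
        return hd_metric(metric_id, x, y, context=context)
    raise ConfigurationError(f"unknown metric {metric_id!r}")


# ---------------------------------------------------------------------------
# vectorized pairwise computation
# ---------------------------------------------------------------------------

def _first_pair_with(ids: list[str], bad_index: int) -> tuple[str, str]:
    other = 1 if bad_index == 0 else 0
    pair = sorted((ids[bad_index], ids[other]))
    return pair[0], pair[1]


def _pairwise_raw(
    X: np.ndarray, ids: list[str], metric_id: str, context: np.ndarray
) -> np.ndarray:
    """Raw metric values for all unordered pairs (upper-triangle order)."""
    iu, ju = np.triu_indices(X.shape[0], k=1)
    A, B = X[iu], X[ju]
    D = A - B

    if metric_id == "euclidean":
        return np.sqrt(np.sum(D * D, axis=1))
    if metric_id == "manhattan":
        return np.sum(np.abs(D), axis=1)
    if metric_id == "pearson":
        Xc = X - X.mean(axis=1, keepdims=True)
        ss = np.sum(Xc * Xc, axis=1)
        bad = np.flatnonzero(ss == 0.0)
        if bad.size:
            a, b = _first_pair_with(ids, int(bad[0]))
            raise UndefinedValueError(
                f"pearson undefined for pair ({a!r}, {b!r}): constant vector"
            )
        num = np.sum(Xc[iu] * Xc[ju], axis=1)
        return num / np.sqrt(ss[iu] * ss[ju])
    if metric_id == "sam":
        ss = np.sum(X * X, axis=1)
        bad = np.flatnonzero(ss == 0.0)
        if bad.size:
            a, b = _first_pair_with(ids, int(bad[0]))
            raise UndefinedValueError(
                f"sam undefined for pair ({a!r}, {b!r}): zero vector"
            )
        return np.sum(A * B, axis=1) / np.sqrt(ss[iu] * ss[ju])
    if metric_id == "sid":
        P = _to_probability(X)
        L = np.log(P)
        return np.sum((P[iu] - P[ju]) * (L[iu] - L[ju]), axis=1)
    if metric_id == "ed_cod":
        return (1.0 - _pairwise_raw(X, ids, "pearson", context)) * _pairwise_raw(
            X, ids, "euclidean", context
        )
    if metric_id == "ss_cs":
        return (
            _pairwise_raw(X, ids, "sid", context)
            * _pairwise_raw(X, ids, "euclidean", context)
            * (1.0 - _pairwise_raw(X, ids, "pearson", context))
        )
    if metric_id == "hsim":
        return np.mean(1.0 / (1.0 + np.abs(D)), axis=1)
    if metric_id == "close":
        return np.mean(np.exp(-np.abs(D)), axis=1)
    if metric_id == "gsim":
        mi = context.max(axis=0) - context.min(axis=0)
        mi = np.where(mi > 0.0, mi, 1.0)
        d = np.abs(D)
        return np.mean(1.0 - d / (d + mi), axis=1)
    if metric_id == "esim":
        d = np.abs(D)
        s = np.abs(A + B)
        denom = d + s
        ratio = np.divide(d, denom, out=np.zeros_like(d), where=denom > 0.0)
        return np.mean(np.exp(ratio / 2.0), axis=1)
    raise ConfigurationError(f"unknown metric {metric_id!r}")


def pairwise_matrix(dataset: SpectralDataset, metric_id: str) -> list[PairValue]:
    """All C(N,2) unordered pair values of one metric over a dataset, with
    batch-normalized similarities filled.

    The Gsim scale and the normalization frame both come from this batch.
    Raises an error naming the offending pair when a metric precondition
    fails (e.g. Pearson on a constant spectrum)."""
    if metric_id not in METRICS:
        raise ConfigurationError(f"unknown metric {metric_id!r}")
    if dataset.n_samples < 2:
        raise InputError("pairwise_matrix needs at least 2 samples")
    X = dataset.values_matrix()
    ids = dataset.sample_ids
    raw = _pairwise_raw(X, ids, metric_id, X)
    iu, ju = np.triu_indices(len(ids), k=1)
    pairs = [
        PairValue(ids[i], ids[j], float(r)) for i, j, r in zip(iu, ju, raw)
    ]
    return normalize_batch(pairs, METRICS[metric_id])


def normalize_batch(
    values: Iterable[PairValue], spec: MetricSpec
) -> list[PairValue]:
    """Map raw pair values of one batch to [0,1] similarities.

    Natively unit-interval metrics (Hsim, Close, Gsim) pass through
    unchanged.  Otherwise min-max over the batch, with dissimilarities
    reversed; a degenerate batch (max == min) maps every value to 1.0."""
    vals = list(values)
    if not vals:
        raise InputError("empty batch")
    if spec.native_unit_interval:
        return [replace(v, normalized=v.raw) for v in vals]
    raw = np.array([v.raw for v in vals])
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        norm = np.ones_like(raw)
    else:
        scaled = (raw - lo) / (hi - lo)
        norm = scaled if spec.orientation == "similarity" else 1.0 - scaled
    return [replace(v, normalized=float(s)) for v, s in zip(vals, norm)]
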