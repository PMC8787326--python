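"""Construction and diagnostics of the two conjugate peptide series.

Given a peptide-activity table, two coupled series are built on natural-log
scale: sorting by the sequence code (BY_CODE) makes the exogenous series
``u = ln(code)`` monotone and carries ``y = ln(EC50)`` along; sorting by
activity (BY_ACTIVITY) makes ``y`` monotone instead.  In any such pair one
member is monotone and the other behaves like a shuffled, random series —
the structural contrast the NARX models in :mod:`pepnarx.narx` exploit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .codec import PeptideRecord, encode_sequence

__all__ = [
    "SeriesGroup",
    "SeriesPair",
    "DistributionSummary",
    "build_series",
    "describe",
    "autocorrelation",
    "cross_correlation",
]


class SeriesGroup(enum.Enum):
    """Which member of the pair is sorted non-decreasing."""

    BY_CODE = "by_code"        # u = ln(code) sorted; y carried along
    BY_ACTIVITY = "by_activity"  # y = ln(EC50) sorted; u carried along


@dataclass(frozen=True)
class SeriesPair:
    """A conjugate (target y, exogenous u) series pair on ln scale.

    ``order`` is the permutation of input indices that produced the sort;
    ``ids`` keeps record identifiers aligned with the series.
    """

    group: SeriesGroup
    y: np.ndarray
    u: np.ndarray
    order: np.ndarray
    ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class DistributionSummary:
    mean: float
    variance: float
    skewness: float
    excess_kurtosis: float
    bin_edges: np.ndarray
    counts: np.ndarray
    #: (mean, variance) of the matched normal used for overlay comparison.
    normal_reference: tuple[float, float]


def build_series(records: list[PeptideRecord], group: SeriesGroup) -> SeriesPair:
    """Build one of the two conjugate series from peptide records.

    Ties (duplicate sequences or equal EC50) are broken by the other member
    of the pair and then by input index, so the result is deterministic.
    """
    if len(records) < 2:
        raise ValueError(f"need at least 2 records to build a series, got {len(records)}")
    y = np.array([r.ln_ec50 for r in records], dtype=float)
    u = np.array([encode_sequence(r.sequence).log_code for r in records], dtype=float)
    idx = np.arange(len(records))
    if group is SeriesGroup.BY_CODE:
        # lexsort: last key is primary
        order = np.lexsort((idx, y, u))
    elif group is SeriesGroup.BY_ACTIVITY:
        order = np.lexsort((idx, u, y))
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown group {group!r}")
    ids = tuple(records[i].id for i in order)
    return SeriesPair(group=group, y=y[order], u=u[order], order=order, ids=ids)


def describe(values: np.ndarray, bins: int | str = "fd") -> DistributionSummary:
    """Moments and histogram of a sample, with a matched-normal reference.

    Default binning is Freedman-Diaconis; pass an integer to override.
    Skewness and excess kurtosis of a constant sample are defined as 0.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("describe expects a 1-D sample of length >= 2")
    mean = float(np.mean(v))
    variance = float(np.var(v))
    if variance == 0.0:
        skewness, kurt = 0.0, 0.0
        counts, edges = np.histogram(v, bins=1)
    else:
        skewness = float(stats.skew(v))
        kurt = float(stats.kurtosis(v))  # Fisher (excess)
        counts, edges = np.histogram(v, bins=bins)
    return DistributionSummary(
        mean=mean,
        variance=variance,
        skewness=skewness,
        excess_kurtosis=kurt,
        bin_edges=edges,
        counts=counts,
        normal_reference=(mean, variance),
    )


def autocorrelation(y: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags 0..max_lag (lag 0 == 1).

    The biased (divide-by-n) estimator guarantees |acf| <= 1.
    """
    v = np.asarray(y, dtype=float)
    n = len(v)
    if not (0 < max_lag < n):
        raise ValueError(f"max_lag must be in (0, n); got {max_lag} with n={n}")
    if np.ptp(v) == 0:
        raise ValueError("autocorrelation is undefined for a constant series")
    c = v - v.mean()
    denom = float(c @ c)  # n * biased variance
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = float(c[: n - k] @ c[k:]) / denom
    return acf


def cross_correlation(y: np.ndarray, u: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of y against u over lags -max_lag..max_lag.

    Entry at lag k is the biased sample correlation between ``y(t+k)`` and
    ``u(t)``; values lie in [-1, 1].  Returns ``(lags, ccf)``.
    """
    a = np.asarray(y, dtype=float)
    b = np.asarray(u, dtype=float)
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    n = len(a)
    if not (0 < max_lag < n):
        raise ValueError(f"max_lag must be in (0, n); got {max_lag} with n={n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("cross-correlation is undefined for a constant series")
    ca = a - a.mean()
    cb = b - b.mean()
    denom = float(np.sqrt((ca @ ca) * (cb @ cb)))
    lags = np.arange(-max_lag, max_lag + 1)
    ccf = np.empty(len(lags))
    for i, k in enumerate(lags):
        if k >= 0:
            ccf[i] = float(ca[k:] @ cb[: n - k]) / denom
        else:
            ccf[i] = float(ca[: n + k] @ cb[-k:]) / denom
    return lags, ccf
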