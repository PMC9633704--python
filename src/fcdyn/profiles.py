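"""Proximal (sub-diagonal) transition series and distal meta-matrix
profiles extracted from a meta-matrix, with their summary measures.

The first sub-diagonal of the meta-matrix is the similarity between
consecutive connectivity patterns (one window step, i.e. one TR apart):
its level measures the rate of connectivity-state change, its spread and
sequential complexity how that rate itself fluctuates. The distal
meta-matrix (dMM) drops the k nearest lags and mirrors the remaining
off-diagonal triangle into a symmetric matrix describing each state's
relation to temporally distant states.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import complexity
from .metamatrix import MetaMatrix

__all__ = [
    "ProximalSeries",
    "DistalMatrix",
    "MeasureSet",
    "DistalSummary",
    "subdiagonal_series",
    "proximal_series",
    "summarize_series",
    "build_distal_matrix",
    "distal_measures",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProximalSeries:
    """Similarity values along the first ``lag_span`` sub-diagonals,
    averaged per start index; length N - lag_span."""

    values: np.ndarray
    lag_span: int
    metric: str
    orientation: str


@dataclass(frozen=True)
class DistalMatrix:
    """Mirrored distal meta-matrix with exclusion lag k.

    D[a, b] = MM[min(a, b), max(a, b) + k] for a != b; the diagonal is
    undefined (NaN). Every defined cell maps to a meta-matrix cell with
    source lag between k + 1 and N - 1.
    """

    values: np.ndarray  # (M, M), M = N - k, diagonal NaN
    k: int
    metric: str
    orientation: str

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MeasureSet:
    """Summary measures of a similarity series: central tendency, spread,
    and sequential complexity."""

    mean: float
    median: float
    sd: float
    shannon_entropy: float
    sample_entropy: float
    effort_to_compress_norm: float
    mean_abs_derivative: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean, "median": self.median, "sd": self.sd,
            "shannon_entropy": self.shannon_entropy,
            "sample_entropy": self.sample_entropy,
            "effort_to_compress_norm": self.effort_to_compress_norm,
            "mean_abs_derivative": self.mean_abs_derivative,
        }


@dataclass(frozen=True)
class DistalSummary:
    """Distal meta-matrix summary: averaged measures plus the mean of each
    column's maximum similarity."""

    measures: MeasureSet
    mean_max_similarity: float
    n_columns_used: int
    mode: str


def subdiagonal_series(mm: MetaMatrix, lag: int) -> np.ndarray:
    """Values MM[i, i+lag] for i = 0 .. N-lag-1, in temporal order."""
    n = mm.n_windows
    if not 1 <= lag <= n - 1:
        raise ValueError(f"lag must be in [1, {n - 1}]")
    return np.diagonal(mm.values, offset=lag).copy()


def proximal_series(mm: MetaMatrix, max_lag: int = 1) -> ProximalSeries:
    """Element-wise mean over sub-diagonals 1..max_lag, aligned on start
    index (series length N - max_lag). max_lag=1 is the plain first
    sub-diagonal."""
    n = mm.n_windows
    if not 1 <= max_lag <= n - 1:
        raise ValueError(f"max_lag must be in [1, {n - 1}]")
    length = n - max_lag
    stack = np.stack([np.diagonal(mm.values, offset=l)[:length]
                      for l in range(1, max_lag + 1)])
    return ProximalSeries(values=stack.mean(axis=0), lag_span=max_lag,
                          metric=mm.metric, orientation=mm.orientation)


def summarize_series(x, bins: int = 10, sampen_m: int = 1,
                     sampen_r: float = 0.2) -> MeasureSet:
    """Summary measures of a real series (length >= 4 for the entropies).

    Entropies of a constant series are 0 (flagged via warning inside
    :mod:`fcdyn.complexity`); the mean absolute first difference is the
    series' average 'acceleration' of change.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("need at least 4 points for entropy measures")
    sampen = complexity.sample_entropy(x, m=sampen_m, r_coeff=sampen_r)
    etc = complexity.effort_to_compress(complexity.symbolize(x, bins=bins))
    return MeasureSet(
        mean=float(x.mean()),
        median=float(np.median(x)),
        sd=float(x.std()),
        shannon_entropy=complexity.shannon_entropy(x, bins=bins),
        sample_entropy=sampen,
        effort_to_compress_norm=etc.normalized,
        mean_abs_derivative=float(np.abs(np.diff(x)).mean()),
    )


def build_distal_matrix(mm: MetaMatrix, k: int) -> DistalMatrix:
    """Distal meta-matrix: exclude the k lags nearest the diagonal and
    mirror the remaining triangle, D[a, b] = MM[min(a,b), max(a,b)+k]."""
    n = mm.n_windows
    if not 1 <= k <= n - 3:
        raise ValueError("fewer than 2 distal lags remain")
    m = n - k
    a, b = np.triu_indices(m, k=1)
    vals = np.full((m, m), np.nan)
    cells = mm.values[a, b + k]
    vals[a, b] = cells
    vals[b, a] = cells
    return DistalMatrix(values=vals, k=k, metric=mm.metric,
                        orientation=mm.orientation)


def distal_measures(mm: MetaMatrix, k: int, mode: str = "per_column",
                    bins: int = 10, sampen_m: int = 1,
                    sampen_r: float = 0.2) -> DistalSummary:
    """Summary measures of the distal meta-matrix.

    mode="per_column": each column's defined cells (ordered by row index,
    i.e. temporal order of the partner windows) are summarised separately
    and the measures averaged across columns; columns with fewer than 4
    defined cells are skipped and logged. mode="vectorized": all defined
    strict-upper cells as one column-major sequence.

    ``mean_max_similarity`` is always the mean over columns of each
    column's maximum.
    """
    dm = build_distal_matrix(mm, k)
    d = dm.values
    m = dm.size
    columns = []
    for c in range(m):
        col = np.delete(d[:, c], c)
        columns.append(col)
    mean_max = float(np.mean([col.max() for col in columns]))

    if mode == "per_column":
        sets = []
        skipped = 0
        for c, col in enumerate(columns):
            if col.size < 4:
                skipped += 1
                log.info("distal column %d has < 4 defined cells; skipped", c)
                continue
            sets.append(summarize_series(col, bins=bins, sampen_m=sampen_m,
                                         sampen_r=sampen_r))
        if not sets:
            raise ValueError("no distal column has enough defined cells")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            agg = {name: float(np.nanmean([s.as_dict()[name] for s in sets]))
                   for name in sets[0].as_dict()}
        measures = MeasureSet(**agg)
        used = len(sets)
    elif mode == "vectorized":
        a, b = np.triu_indices(m, k=1)
        order = np.lexsort((a, b))  # column-major over the upper triangle
        seq = d[a[order], b[order]]
        measures = summarize_series(seq, bins=bins, sampen_m=sampen_m,
                                    sampen_r=sampen_r)
        used = m
    else:
        raise ValueError(f"unknown mode: {mode}")
    return DistalSummary(measures=measures, mean_max_similarity=mean_max,
                         n_columns_used=used, mode=mode)
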