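"""Dynamic structure-function coupling: similarity of each windowed
functional connectivity pattern to the subject's structural connectome.

Each window's FC matrix is proportionally thresholded to the connectome's
edge count (density matching), then compared edge-wise to the structural
weights. The resulting similarity-over-time series is summarised with the
same complexity measures used for the meta-matrix profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cityblock, cosine as cosine_dist

from . import complexity
from .complexity import UndefinedMeasureWarning
from .metamatrix import vectorize_upper
from .synth import StructuralConnectome
from .windows import ConnectivitySeries

__all__ = [
    "StructFuncSeries",
    "StructFuncSummary",
    "threshold_fc_to_density",
    "struct_func_series",
    "struct_func_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructFuncSeries:
    """Per-window similarity of thresholded FC to the structural connectome.

    Undefined windows (zero variance after thresholding) are NaN and
    listed in ``flagged``.
    """

    values: np.ndarray
    metric: str  # pearson | manhattan | cosine
    orientation: str  # similarity | distance
    rank: str  # signed | absolute
    flagged: tuple[int, ...] = ()


@dataclass(frozen=True)
class StructFuncSummary:
    sample_entropy: float
    effort_to_compress_norm: float
    max_similarity: float
    n_windows_used: int


def threshold_fc_to_density(fc: np.ndarray, target_edges: int,
                            rank: str = "signed") -> np.ndarray:
    """Keep exactly ``target_edges`` strict-upper-triangle cells of a
    symmetric FC matrix (the strongest by signed value, or by absolute
    value with rank="absolute"); zero the rest, symmetrise, zero diagonal.

    Ties straddling the cutoff are resolved deterministically by
    (value, row, column) ordering.
    """
    fc = np.asarray(fc, dtype=float)
    r = fc.shape[0]
    if fc.ndim != 2 or fc.shape[1] != r:
        raise ValueError("fc must be square")
    n_pairs = r * (r - 1) // 2
    if not 1 <= target_edges <= n_pairs:
        raise ValueError(f"target_edges must be in [1, {n_pairs}]")
    if rank not in ("signed", "absolute"):
        raise ValueError("rank must be 'signed' or 'absolute'")
    iu, ju = np.triu_indices(r, k=1)
    vals = fc[iu, ju]
    key = np.abs(vals) if rank == "absolute" else vals
    # sort by (key desc, row asc, col asc): last keys in lexsort dominate
    order = np.lexsort((ju, iu, -key))
    keep = order[:target_edges]
    out = np.zeros_like(fc)
    out[iu[keep], ju[keep]] = vals[keep]
    out = out + out.T
    np.fill_diagonal(out, 0.0)
    return out


def _similarity(v_fc: np.ndarray, v_sc: np.ndarray, metric: str) -> float:
    if metric == "pearson":
        if v_fc.std() == 0.0 or v_sc.std() == 0.0:
            return float("nan")
        return float(np.corrcoef(v_fc, v_sc)[0, 1])
    if metric == "manhattan":
        return float(cityblock(v_fc, v_sc))
    if metric == "cosine":
        if not v_fc.any() or not v_sc.any():
            return float("nan")
        return float(cosine_dist(v_fc, v_sc))
    raise ValueError(f"unknown metric: {metric}")


def struct_func_series(cs: ConnectivitySeries, sc: StructuralConnectome,
                       metric: str = "pearson", rank: str = "signed",
                       log_weights: bool = False) -> StructFuncSeries:
    """Similarity of each window's density-matched FC to the connectome.

    Per window the FC matrix is thresholded to the connectome's edge
    count, both matrices are vectorised (strict upper triangle), and the
    chosen metric applied. ``log_weights`` applies log1p to the structural
    weights first (streamline counts are heavy-tailed; off by default).
    """
    if cs.n_regions != sc.n_regions:
        raise ValueError("FC and connectome region counts differ")
    e = sc.edge_count
    if e < 1:
        raise ValueError("empty connectome")
    w = np.log1p(sc.weights) if log_weights else sc.weights
    v_sc = vectorize_upper(w)
    values = np.empty(cs.n_windows)
    flagged = []
    for i, fc in enumerate(cs.matrices):
        thr = threshold_fc_to_density(fc, e, rank=rank)
        values[i] = _similarity(vectorize_upper(thr), v_sc, metric)
        if np.isnan(values[i]):
            flagged.append(i)
    if flagged:
        warnings.warn(f"{len(flagged)} undefined structure-function value(s) "
                      f"flagged: {flagged[:10]}",
                      UndefinedMeasureWarning, stacklevel=2)
    orientation = "similarity" if metric == "pearson" else "distance"
    return StructFuncSeries(values=values, metric=metric,
                            orientation=orientation, rank=rank,
                            flagged=tuple(flagged))


def struct_func_summary(series: StructFuncSeries, bins: int = 10,
                        sampen_m: int = 1,
                        sampen_r: float = 0.2) -> StructFuncSummary:
    """Complexity of the structure-function series: sample entropy,
    normalised effort-to-compress, and the series maximum.

    Flagged (undefined) windows are dropped, not imputed.
    """
    x = series.values[np.isfinite(series.values)]
    if series.flagged:
        log.info("dropping %d flagged windows from structure-function series",
                 len(series.flagged))
    if x.size < 4:
        raise ValueError("need at least 4 defined windows")
    sampen = complexity.sample_entropy(x, m=sampen_m, r_coeff=sampen_r)
    etc = complexity.effort_to_compress(complexity.symbolize(x, bins=bins))
    return StructFuncSummary(sample_entropy=sampen,
                             effort_to_compress_norm=etc.normalized,
                             max_similarity=float(x.max()),
                             n_windows_used=int(x.size))
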