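"""The meta-matrix: pairwise similarity of all windowed connectivity
patterns of one subject, windows ordered in time (also known as
functional connectivity dynamics), plus the temporal-decay-of-similarity
models (TDSM) it is compared against and a 2-D embedding.

A TDSM is a synthetic meta-matrix whose entries decay monotonically with
inter-window lag: the signature of dynamics that never revisit past
states. A high correlation between a subject's meta-matrix and a TDSM
therefore indicates predictable, non-recurrent reconfiguration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .windows import ConnectivitySeries

__all__ = [
    "MetaMatrix",
    "TemporalDecayModel",
    "vectorize_upper",
    "rebuild_from_upper",
    "build_meta_matrix",
    "build_tdsm",
    "tdsm_fit",
    "embed_mm",
]

#: decay constants for the exponential TDSM kinds
TDSM_DECAY = {"exp_slow": 3.0, "exp_fast": 1.5}


@dataclass(frozen=True)
class MetaMatrix:
    """N x N matrix of pairwise pattern similarities or distances.

    ``orientation`` records whether larger values mean more similar
    ("similarity": Pearson) or less ("distance": Manhattan, cosine), so
    directional measures can be interpreted uniformly downstream.
    """

    values: np.ndarray
    metric: str  # pearson | manhattan | cosine
    orientation: str  # similarity | distance

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def signed_similarity(self) -> np.ndarray:
        """Values on a 'higher = more similar' scale (distances negated)."""
        return self.values if self.orientation == "similarity" else -self.values


@dataclass(frozen=True)
class TemporalDecayModel:
    """Model meta-matrix with similarity decaying over inter-window lag.

    ``u`` is the lag profile: u[n-1] = 1 is the zero-lag (diagonal) value
    and u[0] the value at the maximum lag n-1; the model matrix is
    M[i, j] = u[(n-1) - |i-j|].
    """

    n: int
    kind: str  # linear | exp_slow | exp_fast
    decay_constant: float | None
    u: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        lag = np.abs(np.arange(self.n)[:, None] - np.arange(self.n)[None, :])
        return self.u[(self.n - 1) - lag]


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle in row-major order: (0,1), (0,2), ..., (R-2,R-1)."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def rebuild_from_upper(vec: np.ndarray, n: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: symmetric matrix with the given
    strict upper triangle and a constant diagonal."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n * (n - 1) // 2:
        raise ValueError("vector length does not match matrix size")
    out = np.full((n, n), diagonal, dtype=float)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def build_meta_matrix(cs: ConnectivitySeries, metric: str = "pearson") -> MetaMatrix:
    """All-pairs similarity of vectorised connectivity patterns.

    Each window's strict upper triangle is vectorised; entry (i, j) is the
    chosen metric between windows i and j. Pearson yields a similarity
    matrix (diagonal 1); Manhattan and cosine yield distance matrices
    (diagonal 0).
    """
    if cs.n_windows < 2:
        raise ValueError("need at least 2 windows")
    if cs.flagged:
        raise ValueError(f"flagged windows present: {list(cs.flagged)}")
    vecs = np.stack([vectorize_upper(m) for m in cs.matrices])
    if metric == "pearson":
        vals = np.corrcoef(vecs)
        np.fill_diagonal(vals, 1.0)
        vals = np.clip(vals, -1.0, 1.0)
        orientation = "similarity"
    elif metric == "manhattan":
        vals = squareform(pdist(vecs, metric="cityblock"))
        orientation = "distance"
    elif metric == "cosine":
        vals = squareform(pdist(vecs, metric="cosine"))
        orientation = "distance"
    else:
        raise ValueError(f"unknown metric: {metric}")
    vals = (vals + vals.T) / 2.0  # enforce exact symmetry
    return MetaMatrix(values=vals, metric=metric, orientation=orientation)


def build_tdsm(n: int, kind: str) -> TemporalDecayModel:
    """Temporal decay of similarity model.

    Exponential kinds use the lag profile exp(linspace(log(1e-4), log(1),
    n) / c) with c = 3 (slow) or c = 1.5 (fast); the linear kind uses
    u[i] = i / (n - 1). In all kinds u is increasing with u[n-1] = 1, so
    model similarity is maximal on the diagonal and decays with lag.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if kind == "linear":
        u = np.arange(n, dtype=float) / (n - 1)
        c = None
    elif kind in TDSM_DECAY:
        c = TDSM_DECAY[kind]
        u = np.exp(np.linspace(np.log(1e-4), np.log(1.0), n) / c)
    else:
        raise ValueError(f"unknown TDSM kind: {kind}")
    return TemporalDecayModel(n=n, kind=kind, decay_constant=c, u=u)


def tdsm_fit(mm: MetaMatrix, model: TemporalDecayModel) -> float:
    """Pearson correlation between the strict upper triangles of the
    meta-matrix and the model matrix.

    Distance-oriented meta-matrices are negated first so that in both
    orientations a high fit means similarity decays with lag as the
    model prescribes. The trivially-1 diagonal is excluded.
    """
    if mm.n_windows != model.n:
        raise ValueError(f"size mismatch: MM has {mm.n_windows} windows, "
                         f"model has {model.n}")
    a = vectorize_upper(mm.signed_similarity())
    b = vectorize_upper(model.matrix)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        raise ValueError("zero variance in meta-matrix or model")
    return float((a @ b) / denom)


def embed_mm(mm: MetaMatrix, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS of the meta-matrix columns.

    Pairwise Euclidean distances between MM columns are double-centred
    and eigendecomposed; the top ``dims`` coordinates are returned,
    centred at the origin. Points close in the embedding are connectivity
    states with similar relationships to all other states.
    """
    n = mm.n_windows
    if dims >= n:
        raise ValueError("dims must be < number of windows")
    d2 = squareform(pdist(mm.values.T, metric="euclidean")) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)
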