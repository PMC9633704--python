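"""Sequence-complexity kernels: Shannon entropy, sample entropy, and
NSRPS effort-to-compress.

These are the measures applied throughout the package to similarity
timeseries extracted from meta-matrices and structure-function series.
All functions are pure; none perform I/O.

Conventions
-----------
* Shannon entropy is reported in bits (log2); sample entropy uses the
  natural log, following the respective source formulas.
* Sample entropy of a constant series is defined as 0 and emits a
  ``DegenerateSeriesWarning``; an undefined ratio (no template matches)
  propagates as NaN with an ``UndefinedMeasureWarning``, never silently
  as 0 or infinity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SymbolSequence",
    "EtcResult",
    "DegenerateSeriesWarning",
    "UndefinedMeasureWarning",
    "shannon_entropy",
    "sample_entropy",
    "symbolize",
    "nsrps_step",
    "effort_to_compress",
]


class DegenerateSeriesWarning(UserWarning):
    """Input series is constant; entropy measures are defined as 0."""


class UndefinedMeasureWarning(UserWarning):
    """Measure is undefined for this input (e.g. no template matches)."""


@dataclass(frozen=True)
class SymbolSequence:
    """A sequence of nonnegative integer symbols with an explicit alphabet.

    ``alphabet_size`` defaults to ``max(symbols) + 1``; NSRPS allocates
    fresh symbols starting from it. ``bin_edges`` records the
    discretisation when the sequence came from a real-valued series.
    """

    symbols: np.ndarray
    alphabet_size: int = field(default=-1)
    bin_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        sym = np.asarray(self.symbols, dtype=np.int64)
        if sym.ndim != 1 or sym.size < 1:
            raise ValueError("symbols must be a non-empty 1-D sequence")
        if (sym < 0).any():
            raise ValueError("symbols must be nonnegative integers")
        object.__setattr__(self, "symbols", sym)
        if self.alphabet_size < 0:
            object.__setattr__(self, "alphabet_size", int(sym.max()) + 1)
        elif (sym >= self.alphabet_size).any():
            raise ValueError("symbols must be < alphabet_size")

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass(frozen=True)
class EtcResult:
    """Effort-to-compress outcome.

    ``iterations`` is the raw ETC (number of pair substitutions until the
    sequence is constant or a single symbol); ``normalized`` is
    ETC/(L-1), in [0, 1], for input length L >= 2.
    """

    iterations: int
    normalized: float
    trace: tuple[SymbolSequence, ...] | None = None


def shannon_entropy(x, bins: int = 10) -> float:
    """Shannon entropy (bits) of a real series after equal-width binning.

    The histogram spans [min(x), max(x)] with ``bins`` equal-width bins;
    a constant series has entropy 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("need at least one value")
    if x.min() == x.max():
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def _match_count(x: np.ndarray, m: int, r: float) -> int:
    """Ordered pairs (i, j), i != j, of length-m templates with Chebyshev
    distance <= r. Counts over all N - m + 1 templates."""
    n_tpl = x.size - m + 1
    if n_tpl < 2:
        return 0
    tpl = sliding_window_view(x, m)
    dist = np.abs(tpl[:, None, :] - tpl[None, :, :]).max(axis=2)
    return int((dist <= r).sum() - n_tpl)  # subtract the i == j diagonal


def sample_entropy(x, m: int = 1, r_coeff: float = 0.2) -> float:
    """Sample entropy -ln(A/B) with Chebyshev template matching.

    A counts matching template pairs of length m+1, B of length m; the
    tolerance is ``r_coeff`` times the series' standard deviation, so the
    measure is invariant to affine rescaling of ``x``.

    Parameters
    ----------
    x : array-like
        Real-valued series, length >= m + 2.
    m : int
        Shorter template length (the longer is m + 1). Default 1: the
        template pair lengths are 2 and 1.
    r_coeff : float
        Tolerance as a multiple of the standard deviation.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < m + 2:
        raise ValueError(f"need at least {m + 2} points for m={m}")
    sd = float(x.std())
    if sd == 0.0 or np.ptp(x) == 0.0:  # ptp guards against fp residuals
        warnings.warn("constant series: sample entropy defined as 0",
                      DegenerateSeriesWarning, stacklevel=2)
        return 0.0
    r = r_coeff * sd
    b = _match_count(x, m, r)
    a = _match_count(x, m + 1, r)
    if a == 0 or b == 0:
        warnings.warn("no template matches: sample entropy undefined",
                      UndefinedMeasureWarning, stacklevel=2)
        return float("nan")
    return float(-np.log(a / b))


def symbolize(x, bins: int = 10) -> SymbolSequence:
    """Discretise a real series into ``bins`` equal-width bins over its range.

    The maximum value is assigned to the top bin; a constant series maps
    to the all-zero symbol sequence.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("need at least one value")
    lo, hi = float(x.min()), float(x.max())
    edges = np.linspace(lo, hi, bins + 1)
    if lo == hi:
        return SymbolSequence(np.zeros(x.size, dtype=np.int64), bin_edges=edges)
    sym = np.minimum(((x - lo) / (hi - lo) * bins).astype(np.int64), bins - 1)
    return SymbolSequence(sym, bin_edges=edges)


def _as_symbols(s) -> tuple[list[int], int]:
    if isinstance(s, SymbolSequence):
        return s.symbols.tolist(), s.alphabet_size
    seq = SymbolSequence(np.asarray(s, dtype=np.int64))
    return seq.symbols.tolist(), seq.alphabet_size


def nsrps_step(s: SymbolSequence | list | np.ndarray) -> SymbolSequence:
    """One Non-Sequential Recursive Pair Substitution step.

    Adjacent pair frequencies are counted over all overlapping positions;
    the most frequent pair is replaced, greedily left-to-right and
    non-overlapping, by a fresh symbol (the current alphabet size). Ties
    are broken in favour of the pair whose earliest occurrence has the
    smallest start index.
    """
    sym, alpha = _as_symbols(s)
    n = len(sym)
    if n < 2:
        raise ValueError("need at least two symbols")
    counts: dict[tuple[int, int], int] = {}
    first: dict[tuple[int, int], int] = {}
    for i in range(n - 1):
        pair = (sym[i], sym[i + 1])
        if pair in counts:
            counts[pair] += 1
        else:
            counts[pair] = 1
            first[pair] = i
    best = min(counts, key=lambda p: (-counts[p], first[p]))
    out: list[int] = []
    i = 0
    while i < n:
        if i < n - 1 and sym[i] == best[0] and sym[i + 1] == best[1]:
            out.append(alpha)
            i += 2
        else:
            out.append(sym[i])
            i += 1
    return SymbolSequence(np.asarray(out, dtype=np.int64), alphabet_size=alpha + 1)


def effort_to_compress(s, keep_trace: bool = False) -> EtcResult:
    """Effort-to-compress: NSRPS iterations until the sequence is constant
    or reduced to a single symbol.

    ``normalized`` divides by L - 1 (the maximum possible iteration count
    for a length-L input); a length-1 or constant input yields 0.
    """
    if not isinstance(s, SymbolSequence):
        s = SymbolSequence(np.asarray(s, dtype=np.int64))
    length0 = len(s)
    trace: list[SymbolSequence] = []
    cur = s
    iterations = 0
    while len(cur) > 1 and (cur.symbols != cur.symbols[0]).any():
        cur = nsrps_step(cur)
        iterations += 1
        if keep_trace:
            trace.append(cur)
    norm = iterations / (length0 - 1) if length0 >= 2 else 0.0
    return EtcResult(iterations=iterations, normalized=float(norm),
                     trace=tuple(trace) if keep_trace else None)
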