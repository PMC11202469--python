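"""Improved-permutation-entropy (IPE) symbolization.

A real-valued series is mapped through the Gaussian CDF of its own sample
moments, delay-embedded, and quantized into integer symbol patterns that keep
both the absolute amplitude of the first element of each embedding window and
the amplitude differences to the remaining elements.  Unlike ordinal
(Bandt-Pompe) patterns, the alphabet is ``{0, .., L-1}^m``: ``L`` amplitude
levels per element, ``m`` elements per pattern, hence ``L**m`` possible
patterns.  The symbolization is exactly invariant under positive affine
rescaling of the input because the CDF mapping standardizes by the sample
mean and variance first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .exceptions import DegenerateSeriesError, SeriesTooShortError

__all__ = [
    "EmbeddingConfig",
    "NormalizedSeries",
    "SymbolicPhaseSpace",
    "PatternDistribution",
    "ncdf_normalize",
    "delay_embed",
    "uqo",
    "symbolize_phase_space",
    "pattern_distribution",
    "symbolic_distribution",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of the symbolic phase-space reconstruction.

    Parameters
    ----------
    m : int
        Embedding dimension (pattern length), ``>= 2``.  Values in 3..7 are
        the usual operating range; the package default is 4.
    tau : int
        Time delay between elements of an embedding window, ``>= 1``.
    levels : int
        Number of amplitude quantization levels ``L``, ``>= 2``.
    """

    m: int = 4
    tau: int = 1
    levels: int = 4

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"embedding dimension m must be >= 2, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"time delay tau must be >= 1, got {self.tau}")
        if self.levels < 2:
            raise ValueError(f"quantization levels must be >= 2, got {self.levels}")

    @property
    def state_count(self) -> int:
        """Size of the pattern alphabet, ``L**m``."""
        return self.levels**self.m

    @property
    def min_length(self) -> int:
        """Shortest series that yields at least one embedding window."""
        return (self.m - 1) * self.tau + 1


@dataclass(frozen=True)
class NormalizedSeries:
    """A series mapped through the Gaussian CDF of its own sample moments.

    ``values`` lie strictly inside (0, 1).  ``source_mean`` and
    ``source_variance`` are the sample moments of the raw series (variance
    with the 1/N convention) used for the standardization.
    """

    values: np.ndarray
    source_mean: float
    source_variance: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SymbolicPhaseSpace:
    """Matrix of integer symbol patterns.

    ``symbols`` has one row per embedding window and ``m`` columns; every
    entry lies in ``[0, levels-1]``.  ``bin_width`` is the quantization step
    ``(y_max - y_min) / levels`` computed over the whole normalized series.
    """

    symbols: np.ndarray
    bin_width: float
    y_min: float
    y_max: float
    config: EmbeddingConfig


@dataclass(frozen=True)
class PatternDistribution:
    """Probability vector over the ``L**m`` symbolic patterns.

    The pattern index is the mixed-radix code ``sum_k S[j, k] * L**(m-1-k)``
    (first element is the most significant digit); this encoding is stable
    across versions.
    """

    probabilities: np.ndarray
    state_count: int = field(default=0)

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if self.state_count == 0:
            object.__setattr__(self, "state_count", p.size)
        if p.size != self.state_count:
            raise ValueError(
                f"probability vector has {p.size} entries, expected {self.state_count}"
            )
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()!r}, expected 1")

    @classmethod
    def uniform(cls, state_count: int) -> "PatternDistribution":
        return cls(np.full(state_count, 1.0 / state_count), state_count)

    @classmethod
    def delta(cls, state_count: int, index: int = 0) -> "PatternDistribution":
        p = np.zeros(state_count)
        p[index] = 1.0
        return cls(p, state_count)


def _as_array(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "values", x), dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-D series, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return arr


def ncdf_normalize(x) -> NormalizedSeries:
    """Map a series through the Gaussian CDF of its own sample moments.

    Each sample ``x_i`` becomes ``y_i = Phi((x_i - mu) / delta)`` where
    ``Phi`` is the standard normal CDF and ``mu``, ``delta**2`` are the
    sample mean and (1/N) variance of ``x``.  The output lies strictly in
    (0, 1) and is exactly invariant to positive affine rescaling of ``x``.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant (zero variance).
    """
    arr = _as_array(x)
    if arr.size < 2:
        raise SeriesTooShortError(arr.size, 2, "normalization needs two samples")
    mu = float(arr.mean())
    var = float(arr.var())
    if var <= 0.0:
        raise DegenerateSeriesError(
            "series is constant (zero variance); its symbolic dynamics are undefined"
        )
    y = ndtr((arr - mu) / np.sqrt(var))
    return NormalizedSeries(values=y, source_mean=mu, source_variance=var)


def delay_embed(y, cfg: EmbeddingConfig) -> np.ndarray:
    """Build the delay-embedding matrix.

    Row ``j`` (0-based) is ``[y[j], y[j+tau], ..., y[j+(m-1)*tau]]``; there
    are ``N - (m-1)*tau`` rows.

    Raises
    ------
    SeriesTooShortError
        If the series has fewer than ``(m-1)*tau + 1`` samples.
    """
    arr = np.asarray(getattr(y, "values", y), dtype=float)
    n_rows = arr.size - (cfg.m - 1) * cfg.tau
    if n_rows < 1:
        raise SeriesTooShortError(
            arr.size, cfg.min_length, f"embedding with m={cfg.m}, tau={cfg.tau}"
        )
    idx = np.arange(n_rows)[:, None] + cfg.tau * np.arange(cfg.m)[None, :]
    return arr[idx]


def uqo(u: float, y_min: float, y_max: float, levels: int) -> int:
    """Uniform quantization operator: map a value to its amplitude bin.

    Bins are half-open ``[y_min + k*d, y_min + (k+1)*d)`` with
    ``d = (y_max - y_min) / levels``, except the last bin which is closed at
    ``y_max`` so that ``u == y_max`` maps to ``levels - 1``.
    """
    if not y_max > y_min:
        raise ValueError("y_max must exceed y_min")
    if u < y_min or u > y_max:
        raise ValueError(f"value {u} outside quantization range [{y_min}, {y_max}]")
    width = (y_max - y_min) / levels
    k = int(np.floor((u - y_min) / width))
    return min(k, levels - 1)


def symbolize_phase_space(Y: np.ndarray, cfg: EmbeddingConfig,
                          y_min: float | None = None,
                          y_max: float | None = None) -> SymbolicPhaseSpace:
    """Quantize an embedding matrix into integer symbol patterns.

    The first column is quantized directly by the uniform quantization
    operator; column ``k >= 2`` of row ``j`` becomes
    ``S[j, 0] + floor((Y[j, k] - Y[j, 0]) / bin_width)``, i.e. the first
    element's amplitude bin shifted by the quantized amplitude difference.
    Raw shifted symbols can leave ``[0, L-1]``; they are clipped back into
    that range, which keeps the alphabet at exactly ``L**m`` patterns.

    ``y_min``/``y_max`` default to the extremes of ``Y`` itself but should be
    the extremes of the full normalized series (windowing drops samples, so
    the two can differ); :func:`symbolic_distribution` passes them through.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != cfg.m:
        raise ValueError(f"embedding matrix must have {cfg.m} columns, got {Y.shape}")
    lo = float(Y.min()) if y_min is None else float(y_min)
    hi = float(Y.max()) if y_max is None else float(y_max)
    if not hi > lo:
        raise DegenerateSeriesError("normalized series has zero range")
    L = cfg.levels
    width = (hi - lo) / L
    first = np.minimum(np.floor((Y[:, 0] - lo) / width).astype(np.int64), L - 1)
    S = np.empty(Y.shape, dtype=np.int64)
    S[:, 0] = first
    if cfg.m > 1:
        shift = np.floor((Y[:, 1:] - Y[:, :1]) / width).astype(np.int64)
        S[:, 1:] = np.clip(first[:, None] + shift, 0, L - 1)
    return SymbolicPhaseSpace(symbols=S, bin_width=width, y_min=lo, y_max=hi, config=cfg)


def pattern_distribution(S: SymbolicPhaseSpace) -> PatternDistribution:
    """Relative frequencies of the symbol patterns.

    Each row of the symbol matrix is encoded as a mixed-radix integer with
    base ``L`` (first column most significant); the returned vector has one
    entry per possible pattern and sums to 1.
    """
    cfg = S.config
    L = cfg.levels
    sym = S.symbols
    if sym.shape[0] < 1:
        raise ValueError("symbolic phase space is empty")
    radix = L ** np.arange(cfg.m - 1, -1, -1, dtype=np.int64)
    codes = sym @ radix
    counts = np.bincount(codes, minlength=cfg.state_count)
    return PatternDistribution(counts / sym.shape[0], cfg.state_count)


def symbolic_distribution(x, cfg: EmbeddingConfig) -> PatternDistribution:
    """Full pipeline: normalize, embed, symbolize, count.

    Convenience composition of :func:`ncdf_normalize`, :func:`delay_embed`,
    :func:`symbolize_phase_space` (with the quantization range taken over the
    whole normalized series) and :func:`pattern_distribution`.
    """
    y = ncdf_normalize(x)
    Y = delay_embed(y, cfg)
    S = symbolize_phase_space(Y, cfg, y_min=float(y.values.min()),
                              y_max=float(y.values.max()))
    return pattern_distribution(S)
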