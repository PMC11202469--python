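"""The complexity-entropy causality plane and its multiscale extension.

Sweeping the Tsallis weighting parameter q traces a curve (H_q, C_q) in the
plane spanned by normalized entropy and statistical complexity; the curve is
a 2-D signature of the signal's dynamics.  Two scalar features summarize it:
``q_H*``, the q at which H_q attains its minimum, and ``q_C*``, the q at
which C_q attains its maximum.  Coarse-graining the series by non-overlapping
window averaging before symbolization yields one such curve (and feature
pair) per time scale; the concatenated (q_H*, q_C*) pairs across scales form
a feature vector for downstream classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import SeriesTooShortError
from .qstats import entropy_complexity_curve
from .symbolize import EmbeddingConfig, symbolic_distribution

__all__ = [
    "QGrid",
    "PlaneCurve",
    "PlaneFeatures",
    "ScaleConfig",
    "MultiscaleResult",
    "coarse_grain",
    "causality_curve",
    "extract_features",
    "multiscale_features",
    "mean_curve",
]


@dataclass(frozen=True)
class QGrid:
    """Closed arithmetic grid of q values, ``start`` to ``stop`` in ``step``s.

    The default 0..100 in steps of 0.001 (100,001 points) covers the full
    operating range: q = 0 is valid (the q-log degenerates to ``x - 1``) and
    q = 1 is computed through the Shannon limit branch.
    """

    start: float = 0.0
    stop: float = 100.0
    step: float = 0.001

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("q grid must start at a nonnegative value")
        if self.step <= 0:
            raise ValueError("q grid step must be positive")
        if self.stop < self.start:
            raise ValueError("q grid stop must be >= start")

    def values(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step))
        return np.round(self.start + self.step * np.arange(n + 1), 12)

    @classmethod
    def from_string(cls, text: str) -> "QGrid":
        """Parse ``"start:step:stop"``, e.g. ``"0:0.01:10"`` (1001 points)."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"expected start:step:stop, got {text!r}")
        start, step, stop = (float(p) for p in parts)
        return cls(start=start, stop=stop, step=step)


@dataclass(frozen=True)
class PlaneCurve:
    """Per-q entropy and complexity of one series at one scale."""

    q: np.ndarray
    Hq: np.ndarray
    Cq: np.ndarray
    scale: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.q) == len(self.Hq) == len(self.Cq)):
            raise ValueError("q, Hq, Cq must have equal length")


@dataclass(frozen=True)
class PlaneFeatures:
    """Characteristic points of one causality-plane curve.

    ``q_h_star`` is the grid q minimizing H_q and ``q_c_star`` the grid q
    maximizing C_q; ties are broken toward the smallest q.  ``degenerate``
    flags an all-constant curve, for which the extremum location carries no
    information.
    """

    q_h_star: float
    q_c_star: float
    h_min: float
    c_max: float
    scale: int = 1
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "scale": self.scale,
            "q_H_star": self.q_h_star,
            "q_C_star": self.q_c_star,
            "H_min": self.h_min,
            "C_max": self.c_max,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class ScaleConfig:
    """Set of coarse-graining scales (positive integers, default 1..20)."""

    scales: tuple = tuple(range(1, 21))

    def __post_init__(self) -> None:
        scales = tuple(int(s) for s in self.scales)
        if not scales:
            raise ValueError("at least one scale is required")
        if any(s < 1 for s in scales):
            raise ValueError(f"scales must be positive integers, got {scales}")
        object.__setattr__(self, "scales", scales)

    def validate_for(self, n: int, cfg: EmbeddingConfig) -> None:
        """Raise if any scale leaves too few coarse-grained samples to embed."""
        for s in self.scales:
            if n // s < cfg.min_length:
                raise SeriesTooShortError(
                    n // s, cfg.min_length,
                    f"scale {s} of a length-{n} series",
                )


def coarse_grain(x, s: int) -> np.ndarray:
    """Non-overlapping window averages at scale ``s``.

    Output sample ``j`` is the mean of samples ``(j-1)*s + 1 .. j*s`` of the
    input (1-based); the trailing remainder of fewer than ``s`` samples is
    dropped.  ``s = 1`` returns the series unchanged.
    """
    arr = np.asarray(getattr(x, "values", x), dtype=float)
    s = int(s)
    if s < 1:
        raise ValueError(f"scale must be >= 1, got {s}")
    n = arr.size // s
    if n < 1:
        raise SeriesTooShortError(arr.size, s, f"coarse-graining at scale {s}")
    return arr[: n * s].reshape(n, s).mean(axis=1)


def causality_curve(x, cfg: EmbeddingConfig | None = None,
                    grid: QGrid | None = None, scale: int = 1) -> PlaneCurve:
    """Causality-plane curve of one series at one scale.

    The series is coarse-grained, normalized and symbolized once; the
    entropies are then swept over the whole q grid.  Normalization and the
    quantization range are recomputed on the coarse-grained series, so each
    scale sees its own amplitude statistics.
    """
    cfg = cfg or EmbeddingConfig()
    grid = grid or QGrid()
    arr = coarse_grain(x, scale)
    P = symbolic_distribution(arr, cfg)
    q = grid.values()
    qc = entropy_complexity_curve(P, q)
    meta = {"length": int(np.asarray(getattr(x, "values", x)).size),
            "coarse_length": int(arr.size), "m": cfg.m, "tau": cfg.tau,
            "levels": cfg.levels}
    return PlaneCurve(q=q, Hq=qc.Hq, Cq=qc.Cq, scale=int(scale), meta=meta)


def _arg_extreme(q: np.ndarray, values: np.ndarray, minimize: bool) -> tuple[float, float]:
    ext = values.min() if minimize else values.max()
    ties = np.flatnonzero(values == ext)
    return float(q[ties].min()), float(ext)


def extract_features(curve: PlaneCurve) -> PlaneFeatures:
    """Locate q_H* (argmin of H_q) and q_C* (argmax of C_q) on the grid.

    Exact ties are broken toward the smallest q, independently of grid
    ordering.  An all-constant curve is flagged degenerate and reports the
    smallest grid q for both features.
    """
    if len(curve.q) == 0:
        raise ValueError("empty curve")
    degenerate = bool(np.all(curve.Hq == curve.Hq[0]) and np.all(curve.Cq == curve.Cq[0]))
    q_h, h_min = _arg_extreme(curve.q, curve.Hq, minimize=True)
    q_c, c_max = _arg_extreme(curve.q, curve.Cq, minimize=False)
    return PlaneFeatures(q_h_star=q_h, q_c_star=q_c, h_min=h_min, c_max=c_max,
                         scale=curve.scale, degenerate=degenerate)


@dataclass(frozen=True)
class MultiscaleResult:
    """Per-scale curves and features of one series."""

    features: list
    curves: list

    def feature_vector(self) -> np.ndarray:
        """Concatenated (q_H*, q_C*) pairs across scales, the classifier input."""
        return np.array([v for f in self.features for v in (f.q_h_star, f.q_c_star)])


def multiscale_features(x, cfg: EmbeddingConfig | None = None,
                        grid: QGrid | None = None,
                        scales: ScaleConfig | Sequence[int] | None = None) -> MultiscaleResult:
    """Causality-plane features at every coarse-graining scale."""
    cfg = cfg or EmbeddingConfig()
    grid = grid or QGrid()
    if scales is None:
        scales = ScaleConfig()
    elif not isinstance(scales, ScaleConfig):
        scales = ScaleConfig(tuple(scales))
    arr = np.asarray(getattr(x, "values", x), dtype=float)
    scales.validate_for(arr.size, cfg)
    curves = [causality_curve(arr, cfg, grid, scale=s) for s in scales.scales]
    feats = [extract_features(c) for c in curves]
    return MultiscaleResult(features=feats, curves=curves)


def mean_curve(curves: Sequence[PlaneCurve]) -> PlaneCurve:
    """Pointwise-in-q average of an ensemble of curves on a common grid.

    Ensemble experiments average H_q and C_q across realizations before
    locating the characteristic points; per-realization features remain
    available by calling :func:`extract_features` on each member.
    """
    if not curves:
        raise ValueError("need at least one curve")
    q0 = curves[0].q
    for c in curves[1:]:
        if not np.array_equal(c.q, q0):
            raise ValueError("curves are not on a common q grid")
    Hq = np.mean([c.Hq for c in curves], axis=0)
    Cq = np.mean([c.Cq for c in curves], axis=0)
    return PlaneCurve(q=q0, Hq=Hq, Cq=Cq, scale=curves[0].scale,
                      meta={"ensemble_size": len(curves)})
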