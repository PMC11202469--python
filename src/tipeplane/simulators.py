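"""Seeded generators for the synthetic benchmark signals.

Four families: white Gaussian noise (flat power spectrum), pink noise
(power spectral density proportional to 1/f, by spectral shaping),
autoregressive processes of order 1..8 with geometric coefficients
``alpha_i = 1/2**i``, and the x-coordinate of the Lorenz system integrated
with a fourth-order Runge-Kutta scheme.  A helper mixes white Gaussian noise
into any signal at an exact target signal-to-noise ratio.  Every generator
is a pure function of its parameters and seed: identical inputs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "NoiseSpec",
    "ARSpec",
    "LorenzSpec",
    "ar_default_coefficients",
    "white_noise",
    "pink_noise",
    "ar_process",
    "lorenz",
    "add_noise_snr",
    "simulate",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NoiseSpec:
    """White or pink noise: ``kind`` in {"white", "pink"}, length ``n``."""

    kind: str
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("white", "pink"):
            raise ValueError(f"unknown noise kind {self.kind!r}; use 'white' or 'pink'")
        if self.n < 1:
            raise ValueError("n must be positive")


@dataclass(frozen=True)
class ARSpec:
    """Autoregressive process of order ``order`` (0..8; 0 is white noise).

    ``coefficients`` default to the geometric ladder ``1/2, 1/4, ..,
    1/2**order``; the innovation is zero-mean unit-variance Gaussian.  The
    recursion starts from zero history and ``burn_in`` initial samples are
    discarded so the recorded stretch is effectively stationary.
    """

    order: int
    n: int
    coefficients: tuple | None = None
    burn_in: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.order <= 8:
            raise ValueError(f"order must be in 0..8, got {self.order}")
        if self.coefficients is not None:
            coeffs = tuple(float(c) for c in self.coefficients)
            if len(coeffs) != self.order:
                raise ValueError(
                    f"got {len(coeffs)} coefficients for an order-{self.order} process"
                )
            object.__setattr__(self, "coefficients", coeffs)
        if self.n < 1:
            raise ValueError("n must be positive")


@dataclass(frozen=True)
class LorenzSpec:
    """Lorenz-system trajectory settings (sigma=10, rho=28, beta=8/3).

    ``dt`` is the integration step, ``n_points`` the number of recorded
    samples of the observed coordinate after ``burn_in`` discarded steps.
    """

    dt: float = 0.001
    n_points: int = 50_000
    initial_state: tuple = (1.0, 1.0, 1.0)
    coordinate: str = "x"
    burn_in: int = 5000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_points < 1:
            raise ValueError("n_points must be positive")
        if self.coordinate not in ("x", "y", "z"):
            raise ValueError(f"coordinate must be x, y or z, got {self.coordinate!r}")


def ar_default_coefficients(order: int) -> np.ndarray:
    """Geometric coefficient ladder ``alpha_i = 1/2**i`` for i = 1..order."""
    return 1.0 / 2.0 ** np.arange(1, order + 1)


def white_noise(n: int, *, seed=None) -> np.ndarray:
    """Independent standard Gaussian samples (flat power spectrum)."""
    if n < 1:
        raise ValueError("n must be positive")
    return _rng(seed).standard_normal(n)


def pink_noise(n: int, *, seed=None) -> np.ndarray:
    """1/f noise by spectral shaping, standardized to zero mean, unit variance.

    Gaussian white noise is transformed to the frequency domain, each bin's
    amplitude is scaled by ``1/sqrt(f)`` (the DC bin is zeroed), and the
    result is transformed back.  The output power spectral density falls off
    as 1/f by construction.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    w = _rng(seed).standard_normal(n)
    spectrum = np.fft.rfft(w)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    y = np.fft.irfft(spectrum * shape, n)
    return (y - y.mean()) / y.std()


def ar_process(order: int, n: int, *, coefficients=None, burn_in: int = 1000,
               seed=None) -> np.ndarray:
    """Autoregressive series ``x_t = sum_i alpha_i x_{t-i} + w_t``.

    Order 0 degenerates to pure white Gaussian noise.  The recursion is an
    all-pole IIR filter driven by unit-variance Gaussian innovations; it
    starts from zero history and drops ``burn_in`` transient samples.
    """
    spec = ARSpec(order=order, n=n,
                  coefficients=None if coefficients is None else tuple(coefficients),
                  burn_in=burn_in, seed=None)
    w = _rng(seed).standard_normal(spec.n + spec.burn_in)
    if spec.order == 0:
        return w[spec.burn_in:]
    alpha = (np.asarray(spec.coefficients, dtype=float)
             if spec.coefficients is not None
             else ar_default_coefficients(spec.order))
    x = lfilter([1.0], np.concatenate(([1.0], -alpha)), w)
    return x[spec.burn_in:]


_LORENZ_SIGMA, _LORENZ_RHO, _LORENZ_BETA = 10.0, 28.0, 8.0 / 3.0


def _lorenz_deriv(s: np.ndarray) -> np.ndarray:
    x, y, z = s
    return np.array([
        _LORENZ_SIGMA * (y - x),
        x * (_LORENZ_RHO - z) - y,
        x * y - _LORENZ_BETA * z,
    ])


def lorenz(n_points: int = 50_000, *, dt: float = 0.001,
           initial_state=(1.0, 1.0, 1.0), burn_in: int = 5000,
           coordinate: str = "x") -> np.ndarray:
    """Observed coordinate of the Lorenz system, integrated by classic RK4.

    The canonical chaotic parameters sigma=10, rho=28, beta=8/3 are fixed.
    ``burn_in`` integration steps are discarded so recording starts on the
    attractor.  Deterministic: identical arguments give identical output.
    """
    spec = LorenzSpec(dt=dt, n_points=n_points, initial_state=tuple(initial_state),
                      coordinate=coordinate, burn_in=burn_in)
    state = np.array(spec.initial_state, dtype=float)
    comp = "xyz".index(spec.coordinate)
    out = np.empty(spec.n_points)
    h = spec.dt
    for i in range(spec.burn_in + spec.n_points):
        k1 = _lorenz_deriv(state)
        k2 = _lorenz_deriv(state + 0.5 * h * k1)
        k3 = _lorenz_deriv(state + 0.5 * h * k2)
        k4 = _lorenz_deriv(state + h * k3)
        state = state + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"Lorenz integration diverged at step {i}")
        if i >= spec.burn_in:
            out[i - spec.burn_in] = state[comp]
    return out


def add_noise_snr(x, snr_db: float, *, seed=None) -> np.ndarray:
    """Add white Gaussian noise at an exact signal-to-noise ratio in dB.

    The noise realization is rescaled so the recorded sample powers satisfy
    ``10 * log10(mean(x**2) / mean(n**2)) == snr_db`` exactly, not just in
    expectation.
    """
    arr = np.asarray(getattr(x, "values", x), dtype=float)
    p_signal = float(np.mean(arr**2))
    if p_signal <= 0:
        raise ValueError("signal has zero power; SNR is undefined")
    w = _rng(seed).standard_normal(arr.size)
    p_target = p_signal / 10.0 ** (snr_db / 10.0)
    w *= np.sqrt(p_target / np.mean(w**2))
    return arr + w


def simulate(spec) -> np.ndarray:
    """Generate a series from a spec object (used by the CLI for provenance)."""
    if isinstance(spec, NoiseSpec):
        fn = white_noise if spec.kind == "white" else pink_noise
        return fn(spec.n, seed=spec.seed)
    if isinstance(spec, ARSpec):
        return ar_process(spec.order, spec.n, coefficients=spec.coefficients,
                          burn_in=spec.burn_in, seed=spec.seed)
    if isinstance(spec, LorenzSpec):
        return lorenz(spec.n_points, dt=spec.dt, initial_state=spec.initial_state,
                      burn_in=spec.burn_in, coordinate=spec.coordinate)
    raise TypeError(f"unknown simulation spec {type(spec).__name__}")
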