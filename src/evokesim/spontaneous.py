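"""Spontaneous (unstimulated) multichannel dynamics.

Each channel carries a single endogenous oscillation whose instantaneous
angular frequency and amplitude wander chaotically: both are driven by
independent AR(1) processes, squashed into configurable ranges, after which
the phase is obtained by integrating the frequency. The resting signal is
``a_t * sin(phi_t)`` plus Gaussian measurement noise. Channels are sampled
independently per trial and are therefore asymptotically uncorrelated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

__all__ = [
    "SpontaneousSpec",
    "RestingComponents",
    "sample_ar1",
    "stationary_sd",
    "constrain_to_range",
    "integrate_phase",
    "wrap_phase",
    "resting_signal",
    "sample_resting",
]


@dataclass(frozen=True)
class SpontaneousSpec:
    """Hyperparameters of the resting (unstimulated) dynamics.

    Parameters
    ----------
    bf, ba:
        AR(1) coefficients of the instantaneous-frequency and amplitude
        processes; ``|b| < 1`` for stationarity.
    rf:
        Closed interval of allowed angular frequency, radians/sample,
        a subset of ``(0, pi]``.
    ra:
        Closed interval of allowed amplitude (signal units), lower bound >= 0.
    sigma_f, sigma_a:
        Innovation standard deviations of the two AR processes. Their scale
        is largely absorbed by the range squash, so 1.0 is a neutral default.
    sigma_eps:
        Measurement-noise standard deviation.
    F:
        Sampling frequency in Hz (converts radians/sample to Hz).
    n_channels, T, N:
        Channels, time points per trial, and trials.
    """

    bf: float = 0.99
    ba: float = 0.99
    rf: tuple[float, float] = (0.01, 0.25 * np.pi)
    ra: tuple[float, float] = (0.5, 1.5)
    sigma_f: float = 1.0
    sigma_a: float = 1.0
    sigma_eps: float = 0.5
    F: float = 250.0
    n_channels: int = 32
    T: int = 250
    N: int = 250

    def __post_init__(self) -> None:
        problems = []
        if not abs(self.bf) < 1:
            problems.append(f"bf: |{self.bf}| >= 1 (non-stationary)")
        if not abs(self.ba) < 1:
            problems.append(f"ba: |{self.ba}| >= 1 (non-stationary)")
        if not (0 < self.rf[0] <= self.rf[1] <= np.pi):
            problems.append(f"rf: {self.rf} not within (0, pi]")
        if not (0 <= self.ra[0] <= self.ra[1]):
            problems.append(f"ra: {self.ra} lower bound must be >= 0")
        for name in ("sigma_f", "sigma_a", "sigma_eps"):
            if getattr(self, name) < 0:
                problems.append(f"{name}: must be >= 0")
        if self.F <= 0:
            problems.append("F: must be > 0")
        for name in ("n_channels", "T", "N"):
            if getattr(self, name) < 1:
                problems.append(f"{name}: must be >= 1")
        if problems:
            raise ValueError("invalid SpontaneousSpec: " + "; ".join(problems))


@dataclass
class RestingComponents:
    """Per-trial, per-channel resting series, all shaped ``(N, T, n_channels)``.

    ``phi_rest`` is stored unwrapped (cumulative); wrap only at comparison
    points via :func:`wrap_phase`.
    """

    f_rest: np.ndarray
    a_rest: np.ndarray
    phi_rest: np.ndarray

    def __post_init__(self) -> None:
        if not (self.f_rest.shape == self.a_rest.shape == self.phi_rest.shape):
            raise ValueError("resting component shapes differ")


def sample_ar1(
    b: float, sigma: float, T: int, rng: np.random.Generator, size: tuple = ()
) -> np.ndarray:
    """Sample an AR(1) series ``x[t] = b x[t-1] + e[t]``, ``e ~ N(0, sigma^2)``.

    ``x[0] = e[0]``. `size` adds leading batch axes; time is the last axis.
    """
    if not abs(b) < 1:
        raise ValueError(f"AR(1) coefficient must satisfy |b| < 1, got {b}")
    if T < 1:
        raise ValueError("T must be >= 1")
    e = rng.normal(0.0, sigma, size=size + (T,))
    if b == 0 or sigma == 0:
        return e
    return lfilter([1.0], [1.0, -b], e, axis=-1)


def stationary_sd(b: float, sigma: float) -> float:
    """Stationary standard deviation ``sigma / sqrt(1 - b^2)`` of an AR(1)."""
    return sigma / np.sqrt(1.0 - b * b)


def constrain_to_range(
    raw: np.ndarray, interval: tuple[float, float], scale: float
) -> np.ndarray:
    """Squash a zero-mean series into a closed interval.

    A logistic map centred at 0 (the AR mean): ``lo + (hi-lo)*expit(raw/scale)``
    with `scale` the stationary SD of the unconstrained process. Monotone and
    smooth, so ranks are preserved and there are no clipping artefacts; the
    process mean lands on the interval midpoint.
    """
    lo, hi = interval
    if lo > hi:
        raise ValueError(f"invalid interval {interval}")
    if lo == hi:
        warnings.warn(
            f"degenerate range {interval}: output is constant", stacklevel=2
        )
        return np.full_like(np.asarray(raw, dtype=float), lo)
    raw = np.asarray(raw, dtype=float)
    if scale == 0:
        # constant (deterministic) input process sits at the AR mean
        u = np.full_like(raw, 0.5)
    else:
        u = expit(raw / scale)
    return lo + (hi - lo) * u


def integrate_phase(f: np.ndarray) -> np.ndarray:
    """Integrate angular frequency into unwrapped phase.

    ``phi[0] = 0`` and ``phi[t] = phi[t-1] + f[t]`` along the last axis.
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("frequency series contains non-finite values")
    return np.cumsum(f, axis=-1) - f[..., :1]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Map phases onto ``[-pi, pi)``."""
    return np.mod(np.asarray(phi) + np.pi, 2 * np.pi) - np.pi


def resting_signal(
    components: RestingComponents,
    sigma_eps: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resting signal ``x[t] = a_rest[t] sin(phi_rest[t]) + eps[t]``."""
    noise = rng.normal(0.0, sigma_eps, size=components.phi_rest.shape)
    return components.a_rest * np.sin(components.phi_rest) + noise


def sample_resting(
    spec: SpontaneousSpec, rng: np.random.Generator, N: int | None = None
) -> RestingComponents:
    """Sample resting frequency, amplitude and phase for ``N`` trials.

    Arrays are shaped ``(N, T, n_channels)``; every channel and trial is an
    independent draw.
    """
    n = spec.N if N is None else N
    shape = (n, spec.n_channels)  # time appended as last axis, moved after
    f_raw = sample_ar1(spec.bf, spec.sigma_f, spec.T, rng, size=shape)
    a_raw = sample_ar1(spec.ba, spec.sigma_a, spec.T, rng, size=shape)
    f = constrain_to_range(f_raw, spec.rf, stationary_sd(spec.bf, spec.sigma_f))
    a = constrain_to_range(a_raw, spec.ra, stationary_sd(spec.ba, spec.sigma_a))
    phi = integrate_phase(f)
    # (N, C, T) -> (N, T, C)
    return RestingComponents(
        f_rest=np.swapaxes(f, 1, 2).copy(),
        a_rest=np.swapaxes(a, 1, 2).copy(),
        phi_rest=np.swapaxes(phi, 1, 2).copy(),
    )
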