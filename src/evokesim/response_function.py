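"""The temporal response gate G(t; tau).

Every stimulation effect is timed by an asymmetric, piecewise gate that is 0
before the response latency, rises to exactly 1.0 at
``tmax = delta1 + delta2 + tau``, falls back and is 0 again after the fall
window. Each side is, by default, a double-logarithmic curve

    left :  g(t) = 1 - log(1 + ((tmax - t) / T1) ** zeta1)
    right:  g(t) = 1 - log(1 + ((t - tmax) / T2) ** zeta2)

whose scale constants T1, T2 are solved from the two boundary constraints per
piece: value 0 at the window edge and value 1 at ``tmax``:

    T1 = delta2 / (e - 1) ** (1 / zeta1),   T2 = delta3 / (e - 1) ** (1 / zeta2)

with additive constants C1 = C2 = 1. A faster-decaying Gaussian-kernel
("exponential") side is available as an alternative for either piece; it is
affinely renormalised so it also runs from 0 at the window edge to 1 at tmax.

Time is discrete (integer samples). Per-trial latency jitter adds a
Uniform(0, sigma_delta1) draw to ``delta1``, either one shared draw per trial
("absolute" mode) or an independent draw per channel ("relative" mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResponseShape", "normalisation_constants", "evaluate",
           "evaluate_piece", "gate_curve", "jitter_latency"]

_SIDE_KINDS = ("log", "exp")


@dataclass(frozen=True)
class ResponseShape:
    """Latency/rise/fall parametrisation of the response gate.

    All durations are in time points (samples): `delta1` latency (>= 0),
    `delta2` rise duration (>= 1), `delta3` fall duration (>= 1).
    `zeta1`/`zeta2` are the shape exponents of the left/right pieces.
    `sigma_delta1` is the upper bound of the uniform latency jitter and
    `jitter_mode` selects whether one draw is shared by all channels of a
    trial ("absolute") or drawn per channel ("relative").
    """

    delta1: float = 0.0
    delta2: float = 15.0
    delta3: float = 22.0
    zeta1: float = 2.0
    zeta2: float = 4.0
    left_kind: str = "log"
    right_kind: str = "log"
    sigma_delta1: float = 0.0
    jitter_mode: str = "absolute"

    def __post_init__(self) -> None:
        problems = []
        if self.delta1 < 0:
            problems.append(f"delta1: {self.delta1} < 0")
        if self.delta2 < 1:
            problems.append(f"delta2: {self.delta2} < 1")
        if self.delta3 < 1:
            problems.append(f"delta3: {self.delta3} < 1")
        if self.sigma_delta1 < 0:
            problems.append(f"sigma_delta1: {self.sigma_delta1} < 0")
        if self.left_kind not in _SIDE_KINDS or self.right_kind not in _SIDE_KINDS:
            problems.append(
                f"side kinds must be one of {_SIDE_KINDS}, got "
                f"({self.left_kind!r}, {self.right_kind!r})"
            )
        if self.jitter_mode not in ("absolute", "relative"):
            problems.append(f"jitter_mode: {self.jitter_mode!r}")
        if problems:
            raise ValueError("invalid ResponseShape: " + "; ".join(problems))

    def tmax(self, tau: float = 0.0, delta1: float | None = None) -> float:
        d1 = self.delta1 if delta1 is None else delta1
        return d1 + self.delta2 + tau

    @property
    def support_length(self) -> float:
        """Length of the non-zero window, ``delta2 + delta3`` past latency."""
        return self.delta2 + self.delta3


def normalisation_constants(shape: ResponseShape) -> tuple[float, float, float, float]:
    """Solve (C1, C2, T1, T2) from the boundary constraints of each piece.

    Each logarithmic piece must equal 1 at ``tmax`` (distance 0) and 0 at its
    window edge (distance delta2 on the left, delta3 on the right).
    """
    em1 = np.e - 1.0
    C1 = 1.0
    C2 = 1.0
    T1 = shape.delta2 / em1 ** (1.0 / shape.zeta1)
    T2 = shape.delta3 / em1 ** (1.0 / shape.zeta2)
    return C1, C2, T1, T2


def _piece(dist: np.ndarray, width: float, zeta: float, kind: str) -> np.ndarray:
    """Value of one side at non-negative distance `dist` from tmax.

    Runs from 1 at ``dist == 0`` to 0 at ``dist == width``.
    """
    dist = np.asarray(dist, dtype=float)
    if kind == "log":
        em1 = np.e - 1.0
        Tscale = width / em1 ** (1.0 / zeta)
        return 1.0 - np.log1p((dist / Tscale) ** zeta)
    # Gaussian kernel, 3-sigma wide over the window, renormalised so it still
    # spans exactly [0, 1] over [0, width]; decays faster than the log piece.
    s = width / 3.0
    raw = np.exp(-0.5 * (dist / s) ** 2)
    edge = np.exp(-4.5)
    return (raw - edge) / (1.0 - edge)


def evaluate_piece(
    shape: ResponseShape,
    t: np.ndarray,
    tau: float = 0.0,
    side: str = "left",
    delta1: float | None = None,
) -> np.ndarray:
    """Evaluate one side's curve at `t` without masking to its window.

    Used to verify the boundary constraints (both sides meet at 1.0 at tmax).
    """
    tm = shape.tmax(tau, delta1)
    t = np.asarray(t, dtype=float)
    if side == "left":
        return _piece(tm - t, shape.delta2, shape.zeta1, shape.left_kind)
    if side == "right":
        return _piece(t - tm, shape.delta3, shape.zeta2, shape.right_kind)
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def evaluate(
    shape: ResponseShape,
    t: np.ndarray,
    tau: float = 0.0,
    delta1: float | None = None,
) -> np.ndarray:
    """Gate value G(t; tau) for (arrays of) time indices `t`.

    Zero outside ``[delta1 + tau, delta1 + delta2 + delta3 + tau]``, the left
    piece on the rise window, the right piece on the fall window; always in
    [0, 1].
    """
    d1 = shape.delta1 if delta1 is None else delta1
    tm = d1 + shape.delta2 + tau
    t = np.asarray(t, dtype=float)
    out = np.zeros(np.broadcast_shapes(t.shape, np.shape(tm)), dtype=float)
    left = (t >= d1 + tau) & (t <= tm)
    right = (t > tm) & (t <= tm + shape.delta3)
    tm_b = np.broadcast_to(tm, out.shape)
    t_b = np.broadcast_to(t, out.shape)
    out[left] = _piece(tm_b[left] - t_b[left], shape.delta2, shape.zeta1,
                       shape.left_kind)
    out[right] = _piece(t_b[right] - tm_b[right], shape.delta3, shape.zeta2,
                        shape.right_kind)
    return np.clip(out, 0.0, 1.0)


def gate_curve(
    shape: ResponseShape,
    T: int,
    tau: float,
    delta1_eff: np.ndarray | float | None = None,
) -> np.ndarray:
    """Gate sampled on the integer grid ``t = 0..T-1``.

    `delta1_eff` may carry batch axes (e.g. trials x channels of jittered
    latencies); the result then has shape ``batch + (T,)`` with time last.
    """
    t = np.arange(T, dtype=float)
    if delta1_eff is None:
        return evaluate(shape, t, tau)
    d1 = np.asarray(delta1_eff, dtype=float)[..., None]
    tm = d1 + shape.delta2 + tau
    out = np.zeros(np.broadcast_shapes(d1.shape, t.shape), dtype=float)
    left = (t >= d1 + tau) & (t <= tm)
    right = (t > tm) & (t <= tm + shape.delta3)
    tm_b = np.broadcast_to(tm, out.shape)
    t_b = np.broadcast_to(t, out.shape)
    out[left] = _piece(tm_b[left] - t_b[left], shape.delta2, shape.zeta1,
                       shape.left_kind)
    out[right] = _piece(t_b[right] - tm_b[right], shape.delta3, shape.zeta2,
                        shape.right_kind)
    return np.clip(out, 0.0, 1.0)


def jitter_latency(
    shape: ResponseShape,
    n_channels: int,
    rng: np.random.Generator,
    base_delta1: np.ndarray | None = None,
) -> np.ndarray:
    """Effective per-channel latencies for one trial.

    Adds ``Uniform(0, sigma_delta1)`` to the base latency: one shared draw in
    "absolute" mode, independent per-channel draws in "relative" mode. Draws
    are continuous; the result is rounded to the nearest sample.
    """
    base = np.full(n_channels, shape.delta1, dtype=float) \
        if base_delta1 is None else np.asarray(base_delta1, dtype=float)
    if base.shape != (n_channels,):
        raise ValueError("base_delta1 must have one entry per channel")
    if shape.sigma_delta1 == 0:
        return np.round(base)
    if shape.jitter_mode == "absolute":
        jit = np.full(n_channels, rng.uniform(0.0, shape.sigma_delta1))
    else:
        jit = rng.uniform(0.0, shape.sigma_delta1, size=n_channels)
    return np.round(base + jit)
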