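"""Stimulation effects applied to resting dynamics.

When a stimulus of condition k is presented at sample ``tau``, each
stimulus-relevant channel responds per trial with probability theta. A
responding channel may combine four effects, all timed by a response gate
``g_t`` (see :mod:`evokesim.response_function`):

* **phase reset + entrainment** — up to ``tmax`` the ongoing phase is pulled
  toward a condition-specific target phase along the polar gradient,
  ``phi_t = phi_{t-1} + (1-g_t) f_rest_t + g_t grad_t`` (the target is reached
  exactly at ``tmax``, where the gate is 1); afterwards the oscillation
  entrains to a target frequency,
  ``phi_t = phi_{t-1} + g_t f_k + (1-g_t) f_rest_t``.
* **additive oscillation** — a damped sinusoid ``y_t = g_t a_k sin(w_k t + c_k)``
  superposed on the ongoing signal; its argument is anchored at the gate peak,
  so ``c_k`` is the oscillation's phase at the channel's time of maximal
  response.
* **amplitude modulation** — ``a_t = (1 + g_t m_k) a_rest_t``.
* **additive slow (non-oscillatory) response** — ``z_t = g_t s_k`` with
  ``s_k ~ N(mean_k, sd_k)`` drawn once per trial and channel.

The composed signal is ``x_t = a_t sin(phi_t) + z_t + y_t + eps_t``; channels
that do not respond emit exactly their resting signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .response_function import ResponseShape, gate_curve, jitter_latency
from .spontaneous import RestingComponents, wrap_phase

__all__ = [
    "PhaseReset",
    "AdditiveOscillation",
    "AmplitudeModulation",
    "SlowResponse",
    "StimulusEffects",
    "ChannelModel",
    "sample_activations",
    "polar_gradient",
    "kappa_from_sd",
    "sample_target_phase",
    "phase_reset_entrain",
    "additive_oscillation",
    "amplitude_modulation",
    "additive_slow",
    "compose_trials",
]


# --------------------------------------------------------------------------
# per-condition effect parameters

@dataclass(frozen=True)
class PhaseReset:
    """Phase reset to `target_phase_mean`, then entrainment at `entrain_freq`.

    The per-trial target phase is a von Mises draw around the mean with
    circular spread `target_phase_sd` (radians); `entrain_freq` is in
    radians/sample and may be overridden per channel.
    """

    target_phase_mean: float = 0.0
    target_phase_sd: float = 0.0
    entrain_freq: float = 0.15

    def __post_init__(self) -> None:
        if self.target_phase_sd < 0:
            raise ValueError("target_phase_sd must be >= 0")
        if not (0 < self.entrain_freq <= np.pi):
            raise ValueError("entrain_freq must lie in (0, pi]")


@dataclass(frozen=True)
class AdditiveOscillation:
    """Damped additive sinusoid: amplitude `alpha`, frequency `omega`
    (radians/sample), onset phase `gamma`."""

    alpha: float = 1.0
    omega: float = 0.15
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0 < self.omega <= np.pi):
            raise ValueError("omega must lie in (0, pi]")


@dataclass(frozen=True)
class AmplitudeModulation:
    """Proportional amplitude increment `m` at full gate (m=0.1 -> +10%)."""

    m: float = 0.0

    def __post_init__(self) -> None:
        if self.m <= -1:
            raise ValueError("m must be > -1 (amplitude must stay positive)")


@dataclass(frozen=True)
class SlowResponse:
    """Additive non-oscillatory response; the per-trial/channel level is
    ``s ~ N(mean, sd)``, scaled by the gate."""

    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class StimulusEffects:
    """Effect parameters of one condition; ``None`` disables an effect."""

    phase_reset: PhaseReset | None = None
    add_osc: AdditiveOscillation | None = None
    amp_mod: AmplitudeModulation | None = None
    slow: SlowResponse | None = None

    @property
    def any_enabled(self) -> bool:
        return any(
            e is not None
            for e in (self.phase_reset, self.add_osc, self.amp_mod, self.slow)
        )


@dataclass(frozen=True)
class ChannelModel:
    """Which channels are stimulus relevant and how reliably they respond.

    `relevant` holds channel indices; `theta` is the per-channel activation
    probability (scalar broadcast to all relevant channels). Optional
    per-channel overrides introduce latency diversity (`delta1`) and frequency
    diversity (`entrain_freq`, `osc_freq`), and `in_phase` flags the channels
    whose oscillatory condition code is phase-aligned with the slow-response
    condition code (anti-phase channels swap the two conditions' oscillatory
    phase parameters).
    """

    n_channels: int
    relevant: tuple[int, ...] = ()
    theta: float | tuple[float, ...] = 1.0
    delta1: tuple[float, ...] | None = None
    entrain_freq: tuple[float, ...] | None = None
    osc_freq: tuple[float, ...] | None = None
    in_phase: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.n_channels < 1:
            problems.append("n_channels must be >= 1")
        if any(not (0 <= j < self.n_channels) for j in self.relevant):
            problems.append("relevant indices out of range")
        if len(set(self.relevant)) != len(self.relevant):
            problems.append("relevant indices repeated")
        th = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if th.size not in (1, self.n_channels):
            problems.append("theta must be scalar or one value per channel")
        if np.any(th < 0) or np.any(th > 1):
            problems.append("theta must lie in [0, 1]")
        for name in ("delta1", "entrain_freq", "osc_freq", "in_phase"):
            v = getattr(self, name)
            if v is not None and len(v) != self.n_channels:
                problems.append(f"{name} must have one value per channel")
        if problems:
            raise ValueError("invalid ChannelModel: " + "; ".join(problems))

    @property
    def theta_per_channel(self) -> np.ndarray:
        """Activation probability per channel; 0 for non-relevant channels."""
        th = np.zeros(self.n_channels)
        rel = list(self.relevant)
        base = np.atleast_1d(np.asarray(self.theta, dtype=float))
        th[rel] = base[rel] if base.size == self.n_channels else base[0]
        return th


# --------------------------------------------------------------------------
# elementary operations

def sample_activations(
    model: ChannelModel, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_trials, n_channels) mask of responding channels.

    Independent Bernoulli(theta_j) per relevant channel per trial; zeros for
    non-relevant channels.
    """
    theta = model.theta_per_channel
    u = rng.uniform(size=(n_trials, model.n_channels))
    return u < theta


def polar_gradient(target: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Signed shortest angular step from `phi` to `target`, in ``[-pi, pi]``.

    Accepts unwrapped phases: the difference is reduced modulo 2*pi first.
    """
    d = np.mod(np.asarray(target, dtype=float) - np.asarray(phi, dtype=float),
               2 * np.pi)
    return np.where(d > np.pi, d - 2 * np.pi, d)


def kappa_from_sd(sigma_phi: float) -> float:
    """von Mises concentration matching a circular spread `sigma_phi`.

    Solves ``I1(k)/I0(k) = exp(-sigma_phi**2 / 2)``, i.e. matches the mean
    resultant length of a wrapped normal with that SD. ``sigma_phi = 0`` maps
    to infinity (point mass, handled by the caller).
    """
    if sigma_phi < 0:
        raise ValueError("sigma_phi must be >= 0")
    if sigma_phi == 0:
        return np.inf
    r = np.exp(-0.5 * sigma_phi**2)
    if r >= 1.0 - 1e-12:
        return np.inf
    f = lambda k: i1e(k) / i0e(k) - r
    return brentq(f, 1e-10, 1e8)


def sample_target_phase(
    mean: float,
    sigma_phi: float,
    rng: np.random.Generator,
    size: int | tuple | None = None,
) -> np.ndarray | float:
    """Per-trial target phase: a von Mises draw around `mean`.

    ``sigma_phi = 0`` returns the mean exactly.
    """
    kappa = kappa_from_sd(sigma_phi)
    if np.isinf(kappa):
        return float(mean) if size is None else np.full(size, float(mean))
    return rng.vonmises(mean, kappa, size=size)


def phase_reset_entrain(
    phi_prev: np.ndarray,
    f_rest_t: np.ndarray,
    g_t: np.ndarray,
    target: np.ndarray,
    entrain_freq: np.ndarray,
    past_tmax: np.ndarray,
) -> np.ndarray:
    """One step of the stimulated phase recursion.

    Up to and including ``tmax`` (where the gate reaches 1 and the target
    phase is reached exactly): ``phi + (1-g) f_rest + g * grad(target, phi)``;
    after ``tmax`` the entrainment period starts:
    ``phi + g f_k + (1-g) f_rest``.
    """
    g = np.asarray(g_t, dtype=float)
    reset = phi_prev + (1.0 - g) * f_rest_t + g * polar_gradient(target, phi_prev)
    entrain = phi_prev + g * entrain_freq + (1.0 - g) * f_rest_t
    return np.where(past_tmax, entrain, reset)


def additive_oscillation(
    g_t: np.ndarray, alpha: float, omega: np.ndarray, gamma: np.ndarray,
    t_rel: np.ndarray,
) -> np.ndarray:
    """Damped additive sinusoid ``y = g * alpha * sin(omega t_rel + gamma)``.

    `t_rel` is the time relative to the reference sample the caller anchors
    the oscillation at; `gamma` is the phase at ``t_rel = 0``. Trial
    composition anchors at the gate peak ``tmax``, which makes `gamma` the
    oscillation's phase at maximal response — the quantity whose condition
    difference defines the in-/anti-phase coupling with the slow response.
    """
    return g_t * alpha * np.sin(omega * t_rel + gamma)


def amplitude_modulation(
    a_rest_t: np.ndarray, g_t: np.ndarray, m: float
) -> np.ndarray:
    """Gated proportional amplitude increment ``a = (1 + g m) a_rest``."""
    if m <= -1:
        raise ValueError("m must be > -1")
    return (1.0 + g_t * m) * a_rest_t


def additive_slow(g_t: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Gate-scaled constant offset ``z = g * s`` (s fixed within a trial)."""
    return g_t * s


# --------------------------------------------------------------------------
# trial composition

def _resolve_shapes(
    default: ResponseShape, overrides: dict[str, ResponseShape] | None
) -> dict[str, ResponseShape]:
    shapes = {k: default for k in ("phase_reset", "add_osc", "amp_mod", "slow")}
    if overrides:
        unknown = set(overrides) - set(shapes)
        if unknown:
            raise ValueError(f"unknown response-shape overrides: {sorted(unknown)}")
        shapes.update(overrides)
    return shapes


def _effective_phase_params(
    conditions: tuple[StimulusEffects, ...], model: ChannelModel
) -> dict:
    """Per-channel oscillatory phase parameters after the in/anti-phase swap.

    Anti-phase channels exchange the two conditions' target phase (phase
    reset) and onset phase (additive oscillation); only defined for exactly
    two conditions.
    """
    C = model.n_channels
    in_phase = np.ones(C, dtype=bool) if model.in_phase is None \
        else np.asarray(model.in_phase, dtype=bool)
    if not np.all(in_phase) and len(conditions) != 2:
        raise ValueError("anti-phase channels require exactly two conditions")
    out = {}
    for k, cond in enumerate(conditions):
        other = conditions[1 - k] if len(conditions) == 2 else cond
        if cond.phase_reset is not None:
            own = cond.phase_reset.target_phase_mean
            swp = (other.phase_reset.target_phase_mean
                   if other.phase_reset is not None else own)
            out[("reset_mean", k)] = np.where(in_phase, own, swp)
        if cond.add_osc is not None:
            own = cond.add_osc.gamma
            swp = other.add_osc.gamma if other.add_osc is not None else own
            out[("gamma", k)] = np.where(in_phase, own, swp)
    return out


def compose_trials(
    resting: RestingComponents,
    noise: np.ndarray,
    labels: np.ndarray,
    conditions: tuple[StimulusEffects, ...],
    model: ChannelModel,
    tau: int,
    shape: ResponseShape,
    shape_overrides: dict[str, ResponseShape] | None,
    activations: np.ndarray,
    latency_draws: dict[str, np.ndarray],
    target_phase_noise: np.ndarray,
    slow_draws: np.ndarray,
) -> np.ndarray:
    """Compose the stimulated signal ``x = a sin(phi) + z + y + eps``.

    All randomness arrives pre-drawn (activations, per-effect jittered
    latencies, a per-trial von Mises deviation shared across channels, and
    per-trial/channel slow levels), so channels and trials whose effects are
    disabled or inactive reproduce the resting signal bit for bit.
    """
    N, T, C = resting.phi_rest.shape
    if noise.shape != (N, T, C) or labels.shape != (N,):
        raise ValueError("inconsistent shapes between components and labels")
    shapes = _resolve_shapes(shape, shape_overrides)
    phase_params = _effective_phase_params(conditions, model)

    ent_freq = None if model.entrain_freq is None \
        else np.asarray(model.entrain_freq, dtype=float)
    osc_freq = None if model.osc_freq is None \
        else np.asarray(model.osc_freq, dtype=float)

    phi = resting.phi_rest.copy()
    a = resting.a_rest.copy()
    y = np.zeros((N, T, C))
    z = np.zeros((N, T, C))

    t_grid = np.arange(T, dtype=float)

    for k, cond in enumerate(conditions):
        sel = labels == k
        if not np.any(sel) or not cond.any_enabled:
            continue
        act = activations[sel]  # (n_k, C)
        n_k = act.shape[0]

        # --- gates per effect: (n_k, C, T) -> mask inactive channels to 0
        gates = {}
        for name in ("phase_reset", "add_osc", "amp_mod", "slow"):
            if getattr(cond, name) is None:
                continue
            d1 = latency_draws[name][sel]  # (n_k, C) jittered latencies
            g = gate_curve(shapes[name], T, tau, d1)  # (n_k, C, T)
            g = g * act[..., None]
            gates[name] = np.swapaxes(g, 1, 2)  # (n_k, T, C)

        # --- phase reset + entrainment (sequential in time)
        if cond.phase_reset is not None:
            pr = cond.phase_reset
            g = np.swapaxes(gates["phase_reset"], 1, 2)  # (n_k, C, T)
            d1 = latency_draws["phase_reset"][sel]
            tmax = d1 + shapes["phase_reset"].delta2 + tau  # (n_k, C)
            mean = phase_params[("reset_mean", k)]  # (C,)
            target = mean[None, :] + target_phase_noise[sel][:, None]  # (n_k, C)
            fk = ent_freq if ent_freq is not None \
                else np.full(C, pr.entrain_freq)
            f_rest = resting.f_rest[sel]  # (n_k, T, C)
            phi_k = resting.phi_rest[sel].copy()
            for t in range(tau + 1, T):
                step = phase_reset_entrain(
                    phi_k[:, t - 1, :], f_rest[:, t, :], g[:, :, t],
                    target, fk[None, :], past_tmax=(t > tmax),
                )
                phi_k[:, t, :] = step
            # inactive channels keep resting phase exactly
            phi_k = np.where(act[:, None, :], phi_k, resting.phi_rest[sel])
            phi[sel] = phi_k

        # --- additive oscillation (anchored at the per-channel gate peak)
        if cond.add_osc is not None:
            ao = cond.add_osc
            w = osc_freq if osc_freq is not None else np.full(C, ao.omega)
            gamma = phase_params[("gamma", k)]  # (C,)
            tmax_osc = (latency_draws["add_osc"][sel]
                        + shapes["add_osc"].delta2 + tau)  # (n_k, C)
            t_rel = t_grid[None, :, None] - tmax_osc[:, None, :]
            y[sel] = additive_oscillation(
                gates["add_osc"], ao.alpha, w[None, None, :],
                gamma[None, None, :], t_rel,
            )

        # --- amplitude modulation
        if cond.amp_mod is not None:
            a[sel] = amplitude_modulation(
                resting.a_rest[sel], gates["amp_mod"], cond.amp_mod.m
            )

        # --- additive slow response
        if cond.slow is not None:
            s = cond.slow.mean + cond.slow.sd * slow_draws[sel]  # (n_k, C)
            z[sel] = additive_slow(gates["slow"], s[:, None, :])

    return a * np.sin(phi) + z + y + noise
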