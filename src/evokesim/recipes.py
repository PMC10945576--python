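"""Ready-made experiment configurations.

Each recipe builds a two-condition :class:`SimulationConfig` for one of the
canonical simulation designs: phase reset vs additive oscillation as the
oscillatory mechanism, sparse multichannel activation, frequency/latency
diversity, slow-response strength and in-/anti-phase cross-frequency
coupling, and amplitude-modulation strength. Defaults follow the full-scale
study conditions (250 trials of 250 samples at 250 Hz, 32 channels, ongoing
angular frequency 0.01-0.25*pi rad/sample, activation probability 1/6,
effect frequencies 0.1-0.2 rad/sample, response latencies spread over
0-160 ms); pass smaller `n_trials`/`n_times`/`n_channels` for reduced-scale
runs, in which case latency spreads and the slow gate are rescaled with the
epoch.
"""

from __future__ import annotations

import numpy as np

from .effects import (
    AdditiveOscillation,
    AmplitudeModulation,
    ChannelModel,
    PhaseReset,
    SlowResponse,
    StimulusEffects,
)
from .response_function import ResponseShape
from .simulator import SimulationConfig
from .spontaneous import SpontaneousSpec

__all__ = [
    "baseline_config",
    "phase_reset_config",
    "additive_oscillation_config",
    "sparsity_config",
    "diversity_config",
    "coupling_config",
    "amplitude_modulation_config",
]

# condition-coding phases: conditions sit half a cycle apart
_PHASE_1 = np.pi / 2
_PHASE_2 = -np.pi / 2


def _spontaneous(n_trials: int, n_times: int, n_channels: int) -> SpontaneousSpec:
    return SpontaneousSpec(N=n_trials, T=n_times, n_channels=n_channels)


def _fast_shape(n_times: int) -> ResponseShape:
    # rise/fall of the oscillatory effects: 60 ms rise, ~90 ms fall at 250 Hz,
    # kept fixed across epoch lengths (the response is a property of the
    # system, not of the epoch) but clipped into short epochs
    scale = min(1.0, n_times / 250.0)
    return ResponseShape(delta1=0.0, delta2=max(2, round(15 * scale)),
                         delta3=max(2, round(22 * scale)))


def _slow_shape(n_times: int) -> ResponseShape:
    # slow additive response: ramps up in ~100 ms and decays until ~800 ms
    # of a 1 s epoch; rescaled proportionally for shorter epochs
    return ResponseShape(delta1=0.0, delta2=max(2, round(0.1 * n_times)),
                         delta3=max(2, round(0.7 * n_times)))


def _channels(
    n_channels: int,
    theta: float,
    n_relevant: int | None = None,
    diverse_freq: bool = True,
    diverse_latency: bool = True,
    n_times: int = 250,
    in_phase_fraction: float = 1.0,
) -> ChannelModel:
    p = n_channels if n_relevant is None else n_relevant
    freqs = tuple(np.linspace(0.1, 0.2, n_channels)) if diverse_freq else None
    # latency spread 0-160 ms at the full 1 s epoch, proportional otherwise
    max_lat = 0.16 * n_times
    lats = tuple(np.linspace(0.0, max_lat, n_channels)) if diverse_latency else None
    n_in = round(in_phase_fraction * n_channels)
    in_phase = None if in_phase_fraction == 1.0 else \
        tuple(j < n_in for j in range(n_channels))
    return ChannelModel(
        n_channels=n_channels,
        relevant=tuple(range(p)),
        theta=theta,
        delta1=lats,
        entrain_freq=freqs,
        osc_freq=freqs,
        in_phase=in_phase,
    )


def baseline_config(
    n_trials: int = 250, n_times: int = 250, n_channels: int = 32
) -> SimulationConfig:
    """No stimulation effect at all: a chance-level decoding null."""
    return SimulationConfig(
        spontaneous=_spontaneous(n_trials, n_times, n_channels),
        response=_fast_shape(n_times),
        conditions=(StimulusEffects(), StimulusEffects()),
        channels=ChannelModel(n_channels=n_channels, relevant=(), theta=0.0),
    )


def phase_reset_config(
    n_trials: int = 250,
    n_times: int = 250,
    n_channels: int = 32,
    theta: float = 1 / 6,
    slow_diff: float = 0.5,
    amp_mod: float = 0.0,
    target_phase_sd: float = 0.1,
) -> SimulationConfig:
    """Phase reset + entrainment coding, with a coupled slow response.

    Conditions differ in their target phase (half a cycle apart) and, when
    `slow_diff` > 0, in the mean of the slow additive response. `amp_mod`
    adds a condition-independent gated amplitude increment.
    """
    def cond(phase_mean, z_mean):
        return StimulusEffects(
            phase_reset=PhaseReset(target_phase_mean=phase_mean,
                                   target_phase_sd=target_phase_sd),
            amp_mod=AmplitudeModulation(m=amp_mod) if amp_mod else None,
            slow=SlowResponse(mean=z_mean, sd=0.1),
        )

    return SimulationConfig(
        spontaneous=_spontaneous(n_trials, n_times, n_channels),
        response=_fast_shape(n_times),
        response_overrides={"slow": _slow_shape(n_times)},
        conditions=(cond(_PHASE_1, slow_diff / 2), cond(_PHASE_2, -slow_diff / 2)),
        channels=_channels(n_channels, theta, n_times=n_times),
    )


def additive_oscillation_config(
    n_trials: int = 250,
    n_times: int = 250,
    n_channels: int = 32,
    theta: float = 1 / 6,
    n_relevant: int | None = None,
    slow_diff: float = 0.5,
    alpha: float = 1.0,
    diverse_freq: bool = True,
    diverse_latency: bool = True,
    in_phase_fraction: float = 1.0,
    amp_mod: float = 0.0,
    response: ResponseShape | None = None,
) -> SimulationConfig:
    """Additive damped oscillation coding, with a coupled slow response.

    Conditions differ in the oscillation's onset phase (half a cycle apart)
    and optionally in the slow-response mean. Toggle `diverse_freq` /
    `diverse_latency` for the regularity contrast; `in_phase_fraction`
    controls the oscillatory/slow coupling (1.0 = all channels in phase,
    0.0 = all anti-phase).
    """
    zd = 0.0 if slow_diff is None else slow_diff

    def cond(gamma, z_mean):
        return StimulusEffects(
            add_osc=AdditiveOscillation(alpha=alpha, gamma=gamma),
            amp_mod=AmplitudeModulation(m=amp_mod) if amp_mod else None,
            slow=SlowResponse(mean=z_mean, sd=0.1) if slow_diff is not None else None,
        )

    return SimulationConfig(
        spontaneous=_spontaneous(n_trials, n_times, n_channels),
        response=_fast_shape(n_times) if response is None else response,
        response_overrides={"slow": _slow_shape(n_times)},
        conditions=(cond(_PHASE_1, zd / 2), cond(_PHASE_2, -zd / 2)),
        channels=_channels(
            n_channels, theta, n_relevant=n_relevant,
            diverse_freq=diverse_freq, diverse_latency=diverse_latency,
            n_times=n_times, in_phase_fraction=in_phase_fraction,
        ),
    )


def sparsity_config(
    n_relevant: int, theta: float, n_trials: int = 250, n_times: int = 250,
    n_channels: int = 32,
) -> SimulationConfig:
    """Relevant-channel count vs activation probability (few reliable
    channels vs many sparse ones)."""
    return additive_oscillation_config(
        n_trials=n_trials, n_times=n_times, n_channels=n_channels,
        theta=theta, n_relevant=n_relevant,
    )


def diversity_config(
    diverse_freq: bool, diverse_latency: bool, n_trials: int = 250,
    n_times: int = 250, n_channels: int = 32, theta: float = 1 / 6,
) -> SimulationConfig:
    """2x2 frequency/latency diversity design (the regularity contrast).

    This design isolates the oscillatory mechanism: there is no slow
    additive response (a smooth component common to both arms would mask the
    spectral signature being contrasted), and the oscillatory gate spans most
    of the epoch (~70%), long enough for several cycles at 0.1-0.2
    rad/sample — the chequer signature of a single shared response frequency
    only exists while the additive oscillation persists.
    """
    gate = ResponseShape(delta1=0.0, delta2=max(2, round(0.12 * n_times)),
                         delta3=max(2, round(0.6 * n_times)))
    return additive_oscillation_config(
        n_trials=n_trials, n_times=n_times, n_channels=n_channels, theta=theta,
        diverse_freq=diverse_freq, diverse_latency=diverse_latency,
        response=gate, slow_diff=None,
    )


def coupling_config(
    in_phase_fraction: float, n_trials: int = 250, n_times: int = 250,
    n_channels: int = 32, theta: float = 1 / 6, slow_diff: float = 0.5,
) -> SimulationConfig:
    """Oscillatory/slow cross-frequency coupling design."""
    return additive_oscillation_config(
        n_trials=n_trials, n_times=n_times, n_channels=n_channels, theta=theta,
        slow_diff=slow_diff, in_phase_fraction=in_phase_fraction,
    )


def amplitude_modulation_config(
    m: float, n_trials: int = 250, n_times: int = 250, n_channels: int = 32,
    theta: float = 1 / 6,
) -> SimulationConfig:
    """Amplitude-modulation strength design.

    The gated amplitude increment multiplies the ongoing oscillation, so it
    only enlarges the stimulus information when that oscillation is
    phase-locked to the condition; the recipe therefore combines it with a
    phase-reset effect.
    """
    return phase_reset_config(
        n_trials=n_trials, n_times=n_times, n_channels=n_channels, theta=theta,
        amp_mod=m,
    )
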