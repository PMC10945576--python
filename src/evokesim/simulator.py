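"""Dataset assembly: configuration, sampling pipeline, and epoched-data I/O.

A :class:`SimulationConfig` bundles the spontaneous dynamics, the response
gate(s), the per-condition effects and the channel model. `sample_dataset`
draws a balanced, shuffled condition assignment and runs, per trial, the
pipeline resting components -> activations -> latency jitter -> effects ->
composition. One RNG stream per trial is split off a master seed so the
result is reproducible bit for bit regardless of how trials are batched.

Epoched datasets round-trip through HDF5 (datasets ``/data``, ``/labels``,
``/tau``, ``/F``, ``/provenance``); labels can also be exported to CSV.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .effects import (
    AdditiveOscillation,
    AmplitudeModulation,
    ChannelModel,
    PhaseReset,
    SlowResponse,
    StimulusEffects,
    compose_trials,
    kappa_from_sd,
    sample_activations,
)
from .response_function import ResponseShape, jitter_latency
from .spontaneous import (
    RestingComponents,
    SpontaneousSpec,
    constrain_to_range,
    integrate_phase,
    sample_ar1,
    stationary_sd,
)

__all__ = [
    "SimulationConfig",
    "EpochedData",
    "load_config",
    "config_from_dict",
    "sample_dataset",
    "write_epoched",
    "read_epoched",
]

_EFFECT_NAMES = ("phase_reset", "add_osc", "amp_mod", "slow")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated experiment."""

    spontaneous: SpontaneousSpec = field(default_factory=SpontaneousSpec)
    response: ResponseShape = field(default_factory=ResponseShape)
    response_overrides: dict[str, ResponseShape] | None = None
    conditions: tuple[StimulusEffects, ...] = (
        StimulusEffects(),
        StimulusEffects(),
    )
    channels: ChannelModel | None = None
    tau: int = 0

    def __post_init__(self) -> None:
        problems = []
        if len(self.conditions) < 2:
            problems.append("conditions: need at least two")
        if not (0 <= self.tau < self.spontaneous.T):
            problems.append(f"tau: {self.tau} outside [0, T)")
        if self.channels is not None and \
                self.channels.n_channels != self.spontaneous.n_channels:
            problems.append("channels.n_channels != spontaneous.n_channels")
        if self.response_overrides:
            unknown = set(self.response_overrides) - set(_EFFECT_NAMES)
            if unknown:
                problems.append(f"response_overrides: unknown keys {sorted(unknown)}")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    @property
    def channel_model(self) -> ChannelModel:
        if self.channels is not None:
            return self.channels
        return ChannelModel(n_channels=self.spontaneous.n_channels)

    def to_dict(self) -> dict:
        d = {
            "spontaneous": asdict(self.spontaneous),
            "response": asdict(self.response),
            "response_overrides": None if self.response_overrides is None
            else {k: asdict(v) for k, v in self.response_overrides.items()},
            "conditions": [
                {name: (None if getattr(c, name) is None
                        else asdict(getattr(c, name)))
                 for name in _EFFECT_NAMES}
                for c in self.conditions
            ],
            "channels": None if self.channels is None else asdict(self.channels),
            "tau": self.tau,
        }
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_condition(d: dict, errors: list, where: str) -> StimulusEffects:
    kwargs = {}
    ctors = {
        "phase_reset": PhaseReset,
        "add_osc": AdditiveOscillation,
        "amp_mod": AmplitudeModulation,
        "slow": SlowResponse,
    }
    for name, ctor in ctors.items():
        sub = d.get(name)
        if sub is None:
            continue
        try:
            kwargs[name] = ctor(**sub)
        except (TypeError, ValueError) as exc:
            errors.append(f"{where}.{name}: {exc}")
    unknown = set(d) - set(ctors)
    if unknown:
        errors.append(f"{where}: unknown fields {sorted(unknown)}")
    return StimulusEffects(**kwargs)


def config_from_dict(raw: dict) -> SimulationConfig:
    """Build and validate a config from a plain dict (YAML/JSON layout).

    Collects every invalid field before raising, so a broken file reports all
    of its problems at once.
    """
    errors: list[str] = []
    kwargs: dict = {}
    known = {"spontaneous", "response", "response_overrides", "conditions",
             "channels", "effects", "tau", "decode"}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown top-level sections {sorted(unknown)}")

    def _try(name, fn):
        try:
            kwargs[name] = fn()
        except (TypeError, ValueError) as exc:
            errors.append(f"{name}: {exc}")

    if "spontaneous" in raw:
        _try("spontaneous", lambda: SpontaneousSpec(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in raw["spontaneous"].items()
        }))
    if "response" in raw:
        _try("response", lambda: ResponseShape(**raw["response"]))
    if raw.get("response_overrides"):
        _try("response_overrides", lambda: {
            k: ResponseShape(**v) for k, v in raw["response_overrides"].items()
        })
    conds = raw.get("conditions", raw.get("effects"))
    if conds is not None:
        kwargs["conditions"] = tuple(
            _build_condition(c, errors, f"conditions[{i}]")
            for i, c in enumerate(conds)
        )
    if raw.get("channels") is not None:
        _try("channels", lambda: ChannelModel(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in raw["channels"].items()
        }))
    if "tau" in raw:
        kwargs["tau"] = int(raw["tau"])
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return SimulationConfig(**kwargs)


def load_config(path: str) -> SimulationConfig:
    """Read a YAML (or JSON, a YAML subset) configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"configuration file {path!r} is not a mapping")
    return config_from_dict(raw)


@dataclass
class EpochedData:
    """Epoched trials: `data` is ``(N, T, n_channels)``, `labels` the
    condition index per trial, `tau` the stimulus-onset sample, `F` the
    sampling frequency, and `provenance` the config hash + seed."""

    data: np.ndarray
    labels: np.ndarray
    tau: int
    F: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, time, channels)")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must have one entry per trial")
        if not (0 <= self.tau < self.data.shape[1]):
            raise ValueError("tau outside the epoch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def labels_to_csv(self, path: str) -> None:
        pd.DataFrame({"trial": np.arange(self.n_trials),
                      "condition": self.labels}).to_csv(path, index=False)


def _balanced_labels(N: int, n_conditions: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced, shuffled condition assignment (extras spread round-robin)."""
    base = np.arange(N) % n_conditions
    rng.shuffle(base)
    return base


def sample_dataset(config: SimulationConfig, seed: int) -> EpochedData:
    """Sample a full epoched dataset.

    Per trial, a dedicated RNG stream (split from the master seed) draws, in
    fixed order: AR innovations for frequency and amplitude, measurement
    noise, channel activations, per-effect latency jitter, the trial's
    von Mises target-phase deviation, and the slow-response levels. Effects
    are then composed vectorised across trials.
    """
    spec = config.spontaneous
    model = config.channel_model
    N, T, C = spec.N, spec.T, spec.n_channels
    root = np.random.SeedSequence(seed)
    label_ss, trials_ss = root.spawn(2)
    labels = _balanced_labels(N, len(config.conditions),
                              np.random.default_rng(label_ss))

    shapes = {name: (config.response_overrides or {}).get(name, config.response)
              for name in _EFFECT_NAMES}
    base_d1 = {}
    for name in _EFFECT_NAMES:
        if shapes[name] is config.response and model.delta1 is not None:
            # channel latency diversity applies to effects on the default gate
            base_d1[name] = np.asarray(model.delta1, dtype=float)
        else:
            base_d1[name] = np.full(C, shapes[name].delta1, dtype=float)

    sd_f = stationary_sd(spec.bf, spec.sigma_f)
    sd_a = stationary_sd(spec.ba, spec.sigma_a)
    kappas = [
        None if c.phase_reset is None else kappa_from_sd(c.phase_reset.target_phase_sd)
        for c in config.conditions
    ]

    f = np.empty((N, T, C))
    a = np.empty((N, T, C))
    noise = np.empty((N, T, C))
    activ = np.zeros((N, C), dtype=bool)
    lat = {name: np.empty((N, C)) for name in _EFFECT_NAMES}
    vm_dev = np.zeros(N)
    slow_draws = np.empty((N, C))

    for i, tss in enumerate(trials_ss.spawn(N)):
        rng = np.random.default_rng(tss)
        f_raw = sample_ar1(spec.bf, spec.sigma_f, T, rng, size=(C,))
        a_raw = sample_ar1(spec.ba, spec.sigma_a, T, rng, size=(C,))
        f[i] = constrain_to_range(f_raw, spec.rf, sd_f).T
        a[i] = constrain_to_range(a_raw, spec.ra, sd_a).T
        noise[i] = rng.normal(0.0, spec.sigma_eps, size=(T, C))
        activ[i] = sample_activations(model, 1, rng)[0]
        for name in _EFFECT_NAMES:
            lat[name][i] = jitter_latency(shapes[name], C, rng, base_d1[name])
        kap = kappas[labels[i]]
        if kap is not None and np.isfinite(kap):
            vm_dev[i] = rng.vonmises(0.0, kap)
        slow_draws[i] = rng.standard_normal(C)

    resting = RestingComponents(f_rest=f, a_rest=a, phi_rest=integrate_phase(
        np.swapaxes(f, 1, 2)).swapaxes(1, 2))
    x = compose_trials(
        resting, noise, labels, config.conditions, model, config.tau,
        config.response, config.response_overrides, activ, lat, vm_dev,
        slow_draws,
    )
    return EpochedData(
        data=x, labels=labels, tau=config.tau, F=spec.F,
        provenance={"config_hash": config.hash(), "seed": int(seed)},
    )


def write_epoched(data: EpochedData, path: str) -> None:
    """Write an epoched dataset to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=data.data)
        fh.create_dataset("labels", data=data.labels.astype(np.int64))
        fh.create_dataset("tau", data=int(data.tau))
        fh.create_dataset("F", data=float(data.F))
        fh.create_dataset("provenance", data=json.dumps(data.provenance))


def read_epoched(path: str, expected_config: SimulationConfig | None = None) -> EpochedData:
    """Read an epoched dataset; optionally check provenance against a config."""
    with h5py.File(path, "r") as fh:
        missing = [k for k in ("data", "labels", "tau", "F", "provenance")
                   if k not in fh]
        if missing:
            raise ValueError(
                f"not a valid epoched file {path!r}: missing datasets {missing}"
            )
        data = fh["data"][()]
        labels = fh["labels"][()]
        tau = int(fh["tau"][()])
        F = float(fh["F"][()])
        prov = json.loads(fh["provenance"][()])
    if data.ndim != 3 or labels.shape != (data.shape[0],):
        raise ValueError(f"shape mismatch between /data and /labels in {path!r}")
    out = EpochedData(data=data, labels=labels, tau=tau, F=F, provenance=prov)
    if expected_config is not None and \
            prov.get("config_hash") != expected_config.hash():
        warnings.warn(
            "provenance mismatch: file was not generated by this configuration",
            stacklevel=2,
        )
    return out
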