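"""Stimulation effects: activations, circular sampling, the four effect
mechanisms, and trial composition."""

import numpy as np
import pytest

from evokesim.effects import (
    AdditiveOscillation,
    AmplitudeModulation,
    ChannelModel,
    PhaseReset,
    SlowResponse,
    StimulusEffects,
    additive_oscillation,
    additive_slow,
    amplitude_modulation,
    compose_trials,
    kappa_from_sd,
    phase_reset_entrain,
    polar_gradient,
    sample_activations,
    sample_target_phase,
)
from evokesim.response_function import ResponseShape, gate_curve
from evokesim.simulator import sample_dataset
from evokesim.spontaneous import wrap_phase
from evokesim import recipes


class TestActivations:
    def test_certain_single_channel_always_responds(self, rng):
        model = ChannelModel(n_channels=4, relevant=(2,), theta=1.0)
        mask = sample_activations(model, 100, rng)
        assert np.all(mask[:, 2])
        assert not mask[:, [0, 1, 3]].any()

    def test_zero_probability_never_responds(self, rng):
        model = ChannelModel(n_channels=4, relevant=(0, 1, 2, 3), theta=0.0)
        assert not sample_activations(model, 50, rng).any()

    def test_sparse_activation_rate(self, rng):
        model = ChannelModel(n_channels=32, relevant=tuple(range(32)),
                             theta=1 / 6)
        mask = sample_activations(model, 10_000, rng)
        assert mask.mean() == pytest.approx(1 / 6, abs=0.01)


class TestPolarGradient:
    def test_wraps_large_positive_difference(self):
        # a gap of 3*pi/2 is shorter the other way round
        assert polar_gradient(3 * np.pi / 2, 0.0) == pytest.approx(-np.pi / 2)

    def test_zero_at_target(self):
        assert polar_gradient(1.2, 1.2) == pytest.approx(0.0)

    def test_grid_bounded_and_closes_gap(self):
        phis = np.linspace(-np.pi, np.pi, 100)
        targets = np.linspace(-np.pi, np.pi, 100)
        P, T = np.meshgrid(phis, targets)
        grad = polar_gradient(T, P)
        assert np.all(np.abs(grad) <= np.pi + 1e-12)
        # one full step lands on the target modulo 2*pi
        np.testing.assert_allclose(
            wrap_phase(P + grad - T), 0.0, atol=1e-9)

    def test_accepts_unwrapped_phases(self):
        assert polar_gradient(0.5, 0.5 + 6 * np.pi) == pytest.approx(0.0, abs=1e-9)


class TestTargetPhase:
    def test_zero_sd_is_exact(self, rng):
        assert sample_target_phase(0.8, 0.0, rng) == 0.8
        np.testing.assert_array_equal(
            sample_target_phase(0.8, 0.0, rng, size=5), np.full(5, 0.8))

    def test_circular_mean_matches(self, rng):
        draws = sample_target_phase(1.0, 0.5, rng, size=10_000)
        mean = np.angle(np.exp(1j * draws).mean())
        assert mean == pytest.approx(1.0, abs=0.05)

    def test_spread_monotone_in_sd(self, rng):
        resultants = []
        for sd in (0.1, 0.5, 1.0, 2.0):
            draws = sample_target_phase(0.0, sd, rng, size=5_000)
            resultants.append(np.abs(np.exp(1j * draws).mean()))
        assert all(a > b for a, b in zip(resultants, resultants[1:]))

    def test_kappa_mapping_monotone_and_limits(self):
        ks = [kappa_from_sd(sd) for sd in (0.01, 0.1, 1.0, 3.0)]
        assert all(a > b for a, b in zip(ks, ks[1:]))
        assert kappa_from_sd(0.0) == np.inf


class TestPhaseResetEntrain:
    def test_zero_gate_is_resting_update(self):
        nxt = phase_reset_entrain(1.0, 0.2, 0.0, 3.0, 0.15, past_tmax=False)
        assert nxt == pytest.approx(1.2)

    def test_full_gate_reaches_target_in_one_step(self):
        nxt = phase_reset_entrain(0.3, 0.2, 1.0, 2.5, 0.15, past_tmax=False)
        assert wrap_phase(nxt - 2.5) == pytest.approx(0.0, abs=1e-12)

    def test_full_gate_entrains_exactly(self):
        nxt = phase_reset_entrain(1.0, 0.2, 1.0, 0.0, 0.15, past_tmax=True)
        assert nxt == pytest.approx(1.15)

    def test_interpolates_between_regimes(self):
        pre = phase_reset_entrain(0.0, 0.2, 0.5, np.pi / 2, 0.1, past_tmax=False)
        assert pre == pytest.approx(0.5 * 0.2 + 0.5 * np.pi / 2)


class TestAdditiveComponents:
    def test_oscillation_zero_where_gate_zero(self):
        assert additive_oscillation(0.0, 2.0, 0.2, 1.0, 5.0) == 0.0

    def test_oscillation_phase_at_anchor(self):
        assert additive_oscillation(1.0, 2.0, 0.2, 0.7, 0.0) == \
            pytest.approx(2.0 * np.sin(0.7))

    def test_oscillation_vanishes_outside_gate_support(self):
        shape = ResponseShape(delta1=5, delta2=10, delta3=20)
        g = gate_curve(shape, 80, tau=0)
        y = additive_oscillation(g, 1.0, 0.2, 0.0, np.arange(80) - 15.0)
        support = (np.arange(80) >= 5) & (np.arange(80) <= 35)
        assert np.all(y[~support] == 0)

    def test_amplitude_increment_ten_percent_at_peak(self):
        # m = 0.1 at full gate increases amplitude by exactly 10%
        assert amplitude_modulation(2.0, 1.0, 0.1) == pytest.approx(2.2)

    def test_amplitude_unchanged_at_zero_gate(self):
        assert amplitude_modulation(2.0, 0.0, 0.9) == 2.0

    def test_fivefold_amplitude_at_peak(self):
        assert amplitude_modulation(1.0, 1.0, 4.0) == pytest.approx(5.0)

    def test_slow_is_scaled_gate(self):
        g = np.linspace(0, 1, 11)
        np.testing.assert_allclose(additive_slow(g, 0.4), 0.4 * g)


def _tiny_config(**kwargs):
    return recipes.phase_reset_config(
        n_trials=20, n_times=60, n_channels=4, theta=1.0,
        target_phase_sd=0.0, **kwargs)


class TestComposition:
    def test_disabled_effects_reproduce_resting_signal(self):
        cfg = recipes.baseline_config(n_trials=10, n_times=40, n_channels=3)
        ds = sample_dataset(cfg, 3)
        # same seed, but with an (inactive: theta=0) effect configured
        cfg2 = recipes.phase_reset_config(
            n_trials=10, n_times=40, n_channels=3, theta=0.0)
        ds2 = sample_dataset(cfg2, 3)
        np.testing.assert_array_equal(ds.data, ds2.data)

    def test_non_relevant_channels_emit_resting_values(self):
        cfg_all = recipes.additive_oscillation_config(
            n_trials=10, n_times=40, n_channels=4, theta=1.0, n_relevant=2)
        cfg_none = recipes.baseline_config(n_trials=10, n_times=40, n_channels=4)
        ds_eff = sample_dataset(cfg_all, 11)
        ds_rest = sample_dataset(cfg_none, 11)
        np.testing.assert_array_equal(ds_eff.data[:, :, 2:], ds_rest.data[:, :, 2:])
        assert not np.array_equal(ds_eff.data[:, :, :2], ds_rest.data[:, :, :2])

    def test_phase_reset_converges_to_target_at_tmax(self):
        # noiseless target, gate reaching 1: wrapped distance 0 at tmax
        cfg = _tiny_config()
        spec = cfg.spontaneous
        from evokesim.spontaneous import sample_resting

        shape = cfg.response
        model = cfg.channel_model
        ds_rng = np.random.default_rng(5)
        resting = sample_resting(spec, ds_rng, N=20)
        noise = np.zeros((20, spec.T, spec.n_channels))
        labels = np.zeros(20, dtype=int)
        lats = np.round(np.asarray(model.delta1))
        lat = {name: np.tile(lats, (20, 1))
               for name in ("phase_reset", "add_osc", "amp_mod", "slow")}
        act = np.ones((20, spec.n_channels), dtype=bool)
        x = compose_trials(
            resting, noise, labels, cfg.conditions, model, cfg.tau,
            shape, cfg.response_overrides, act, lat,
            np.zeros(20), np.zeros((20, spec.n_channels)),
        )
        # at each channel's tmax the signal phase equals the target:
        # x = a*sin(phi_target) + z, so (x - z)/a == sin(target)
        target = cfg.conditions[0].phase_reset.target_phase_mean
        tmax = (lats + shape.delta2 + cfg.tau).astype(int)
        for j, tm in enumerate(tmax):
            if tm >= spec.T:
                continue
            slow_gate = gate_curve(cfg.response_overrides["slow"], spec.T,
                                   cfg.tau, float(lats[j]))
            z = slow_gate[tm] * cfg.conditions[0].slow.mean
            ratio = (x[:, tm, j] - z) / resting.a_rest[:, tm, j]
            np.testing.assert_allclose(ratio, np.sin(target), atol=1e-9)

    def test_phase_locking_exceeds_resting_baseline(self):
        # within-condition signal concentration at tmax far above the
        # no-effect level, measured past the initial phase-alignment
        # transient shared by all trials (phase starts at 0)
        from evokesim.simulator import SimulationConfig
        from evokesim.spontaneous import SpontaneousSpec

        shape = ResponseShape(delta1=60, delta2=15, delta3=30)
        conds = tuple(
            StimulusEffects(phase_reset=PhaseReset(target_phase_mean=m))
            for m in (np.pi / 2, -np.pi / 2))
        cfg = SimulationConfig(
            spontaneous=SpontaneousSpec(N=80, T=120, n_channels=2, sigma_eps=0.1),
            response=shape,
            conditions=conds,
            channels=ChannelModel(n_channels=2, relevant=(0, 1), theta=1.0),
        )
        ds = sample_dataset(cfg, 21)
        base = sample_dataset(
            recipes.baseline_config(n_trials=80, n_times=120, n_channels=2), 21)
        tm = 75  # delta1 + delta2
        locked = ds.data[ds.labels == 0, tm, 0].std()
        unlocked = base.data[ds.labels == 0, tm, 0].std()
        assert locked < 0.5 * unlocked

    def test_amplitude_only_effect_not_decodable(self):
        # amplitude modulation without any phase effect gives no cross-trial
        # phase locking once the ongoing phases have decohered, so the
        # conditions cannot be separated by a linear decoder
        from evokesim.decoding import compute_tgm
        from evokesim.simulator import SimulationConfig
        from evokesim.spontaneous import SpontaneousSpec

        # response window placed late in the trial, past the initial
        # phase-alignment transient (every trial starts at phase 0)
        shape = ResponseShape(delta1=60, delta2=15, delta3=30)
        conds = (
            StimulusEffects(amp_mod=AmplitudeModulation(m=4.0)),
            StimulusEffects(amp_mod=AmplitudeModulation(m=0.5)),
        )
        cfg = SimulationConfig(
            spontaneous=SpontaneousSpec(N=120, T=120, n_channels=4),
            response=shape,
            conditions=conds,
            channels=ChannelModel(n_channels=4, relevant=(0, 1, 2, 3), theta=1.0),
        )
        tgm = compute_tgm(sample_dataset(cfg, 9), n_folds=5, seed=0)
        late = tgm.accuracy[60:, 60:]
        assert abs(late.mean() - 0.5) < 0.03


class TestChannelModelValidation:
    def test_invalid_model_reports_all_fields(self):
        with pytest.raises(ValueError) as exc:
            ChannelModel(n_channels=2, relevant=(0, 5), theta=1.5,
                         delta1=(1.0,))
        msg = str(exc.value)
        assert "relevant" in msg and "theta" in msg and "delta1" in msg

    def test_anti_phase_requires_two_conditions(self):
        model = ChannelModel(n_channels=2, relevant=(0, 1), theta=1.0,
                             in_phase=(True, False))
        from evokesim.effects import _effective_phase_params

        conds = tuple(
            StimulusEffects(add_osc=AdditiveOscillation(gamma=g))
            for g in (0.0, 1.0, 2.0))
        with pytest.raises(ValueError, match="two conditions"):
            _effective_phase_params(conds, model)

    def test_anti_phase_swaps_condition_phases(self):
        from evokesim.effects import _effective_phase_params

        model = ChannelModel(n_channels=2, relevant=(0, 1), theta=1.0,
                             in_phase=(True, False))
        conds = (
            StimulusEffects(add_osc=AdditiveOscillation(gamma=0.5)),
            StimulusEffects(add_osc=AdditiveOscillation(gamma=-0.5)),
        )
        params = _effective_phase_params(conds, model)
        np.testing.assert_allclose(params[("gamma", 0)], [0.5, -0.5])
        np.testing.assert_allclose(params[("gamma", 1)], [-0.5, 0.5])
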