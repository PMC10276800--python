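"""Chemical Langevin solver: noise amplitudes, conservation, limits."""

import numpy as np
import pytest

from actinwaves import (
    Grid,
    ModelParams,
    NoiseConfig,
    background_states,
    build_actin_network,
    diffusion_noise_increment,
    get_preset,
    make_initial_condition,
    reaction_noise_amplitude,
    simulate_cle,
    simulate_rde,
)
from actinwaves.exceptions import ValidationError


class TestNoiseConfig:
    def test_bad_mode_rejected(self):
        with pytest.raises(ValidationError):
            NoiseConfig(sigma=0.05, mode="bogus")

    def test_bad_convention_rejected(self):
        with pytest.raises(ValidationError):
            NoiseConfig(sigma=0.05, variance_convention="bogus")


class TestReactionNoiseAmplitude:
    def test_origin_only_constant_source_survives(self, fig4_network, fig4_params):
        for conv in ("sum_of_propensities", "as_printed"):
            amp = reaction_noise_amplitude(fig4_network, np.array([0.0, 0.0]), conv)
            assert amp[0] == pytest.approx(np.sqrt(fig4_params.a5))
            assert amp[1] == 0.0

    def test_as_printed_vanishes_on_inhibitor_nullcline(self):
        # parameters chosen so c1*v == c2*u is exact in floating point
        params = ModelParams(c1=0.25, c2=3.0)
        network = build_actin_network(params)
        u = 1.0
        v = params.c2 * u / params.c1  # 12.0
        amp = reaction_noise_amplitude(network, np.array([u, v]), "as_printed")
        assert amp[1] == 0.0

    def test_summed_propensities_identity(self, fig4_network, rng):
        states = rng.uniform(0, 3, size=(2, 100))
        amp = reaction_noise_amplitude(fig4_network, states, "sum_of_propensities")
        R = fig4_network.propensities(states)
        np.testing.assert_allclose(amp[0] ** 2, R[0] + R[1] + R[2] + R[3], rtol=1e-12)
        np.testing.assert_allclose(amp[1] ** 2, R[4] + R[5], rtol=1e-12)

    def test_conventions_differ_only_in_inhibitor_sign(self, fig4_network, rng):
        states = rng.uniform(0, 3, size=(2, 50))
        a_sum = reaction_noise_amplitude(fig4_network, states, "sum_of_propensities")
        a_prn = reaction_noise_amplitude(fig4_network, states, "as_printed")
        np.testing.assert_allclose(a_sum[0], a_prn[0], rtol=1e-12)
        assert np.all(a_sum[1] >= a_prn[1])


class TestDiffusionNoise:
    def test_zero_state_gives_zero_increment(self, rng):
        inc = diffusion_noise_increment(np.zeros((2, 64)), np.array([0.1, 1.0]), 0.1, 1e-3, rng)
        assert np.all(inc == 0)

    def test_mass_conservation_on_the_circle(self, rng):
        for _ in range(20):
            state = np.abs(rng.normal(1, 0.5, size=(2, 128)))
            inc = diffusion_noise_increment(state, np.array([0.1, 1.0]), 0.05, 5e-4, rng)
            # fluxes telescope around the circle: zero total mass change
            assert np.abs(inc.sum(axis=-1)).max() < 1e-12

    def test_increment_variance_matches_flux_difference_formula(self, rng):
        # increment_k = (F_{k+1/2} - F_{k-1/2}) dt/dx with
        # Var(F) = 2 D Xbar/(dx dt), so Var(increment) = 2 (2 D Xbar) dt/dx^3
        D, dx, dt, xbar = 0.5, 0.1, 1e-3, 2.0
        state = np.full((2, 64), xbar)
        samples = np.array(
            [diffusion_noise_increment(state, np.array([D, D]), dx, dt, rng)[0] for _ in range(3000)]
        )
        var = samples.var()
        expected = 2 * (2 * D * xbar) * dt / dx**3
        assert var == pytest.approx(expected, rel=0.1)


class TestSimulateCle:
    def test_zero_noise_reduces_to_deterministic(self, fig4_params, fig4_network):
        g = Grid(-5, 5, 100)
        ic = make_initial_condition("gaussian_bump", fig4_params, g)
        det = simulate_rde(fig4_network, g, ic, T=2.0, save_every=100)
        for mode in ("full", "reaction_only", "additive_u"):
            sto = simulate_cle(
                fig4_network, g, ic, T=2.0, noise=NoiseConfig(sigma=0.0, seed=7, mode=mode),
                save_every=100,
            )
            assert np.array_equal(det.u, sto.u)
            assert np.array_equal(det.v, sto.v)

    def test_zero_noise_reduction_holds_on_numpy_backend(self, fig4_params, fig4_network):
        g = Grid(-5, 5, 64)
        ic = make_initial_condition("gaussian_bump", fig4_params, g)
        det = simulate_rde(fig4_network, g, ic, T=0.5, save_every=50, backend="numpy")
        sto = simulate_cle(
            fig4_network, g, ic, T=0.5, noise=NoiseConfig(sigma=0.0, seed=3),
            save_every=50, backend="numpy",
        )
        assert np.array_equal(det.u, sto.u)
        assert np.array_equal(det.v, sto.v)

    def test_reproducible_for_fixed_seed(self, fig4_params, fig4_network):
        g = Grid(-5, 5, 100)
        ic = make_initial_condition("homog_4v", fig4_params, g, rng=np.random.default_rng(1))
        runs = [
            simulate_cle(fig4_network, g, ic, T=1.0, noise=NoiseConfig(sigma=0.04, seed=11))
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].u, runs[1].u)
        different = simulate_cle(
            fig4_network, g, ic, T=1.0, noise=NoiseConfig(sigma=0.04, seed=12)
        )
        assert not np.array_equal(runs[0].u, different.u)

    def test_one_step_moments_match_drift_and_summed_propensities(
        self, fig4_params, fig4_network
    ):
        # homogeneous state, reaction noise only: each cell is an independent
        # sample of the defining Langevin one-step distribution
        g = Grid(0.0, 1.0, 8)
        sigma, dt = 0.1, 1e-3
        u0, v0 = 0.4, 1.5
        ic = np.stack([np.full(8, u0), np.full(8, v0)])
        drift = fig4_network.drift(np.array([u0, v0]))
        R = fig4_network.propensities(np.array([u0, v0]))
        increments = []
        for seed in range(400):
            f = simulate_cle(
                fig4_network,
                g,
                ic,
                T=dt,
                dt=dt,
                noise=NoiseConfig(sigma=sigma, seed=seed, mode="reaction_only"),
                save_every=1,
            )
            increments.append(f.snapshot(-1) - ic)
        inc = np.array(increments)  # (400, 2, 8) -> 3200 samples per species
        mean = inc.mean(axis=(0, 2))
        var = inc.var(axis=(0, 2))
        np.testing.assert_allclose(mean, drift * dt, atol=4e-4)
        expected_var = sigma**2 * np.array([R[0] + R[1] + R[2] + R[3], R[4] + R[5]]) * dt / g.dx
        np.testing.assert_allclose(var, expected_var, rtol=0.12)

    def test_clamp_fraction_recorded_and_bounded(self, fig4_params, fig4_network):
        g = Grid(-10, 10, 400)
        ic = make_initial_condition("homog_4v", fig4_params, g, rng=np.random.default_rng(0))
        f = simulate_cle(
            fig4_network, g, ic, T=5.0, dt=2e-3, stepper="imex",
            noise=NoiseConfig(sigma=0.046, seed=0),
        )
        assert 0.0 < f.meta["clamp_fraction"] < 0.2

    def test_additive_noise_events_are_shorter_and_narrower(self, fig4_params, fig4_network):
        """Ad-hoc additive white noise on u produces short, narrow
        excursions, unlike the structured activations of the full
        Langevin noise.  Additive noise per cell scales with the grid
        (1/sqrt(dx)), so its level is calibrated on this grid to ~50
        detected events per run; the detector settings are identical for
        both modes."""
        from actinwaves import default_threshold, detect_events

        g = Grid(-10, 10, 400)
        thr = default_threshold(fig4_params)
        events = {}
        for mode, sigma, seeds in (("full", 0.046, (0, 1)), ("additive_u", 0.85, (0,))):
            pooled = []
            for seed in seeds:
                rng = np.random.default_rng(seed)
                ic = make_initial_condition("homog_4v", fig4_params, g, rng=rng)
                f = simulate_cle(
                    fig4_network, g, ic, T=100.0, dt=2e-3, stepper="imex",
                    noise=NoiseConfig(sigma=sigma, seed=seed, mode=mode), save_every=50,
                )
                pooled.extend(detect_events(f, threshold=thr))
            events[mode] = pooled
        assert len(events["additive_u"]) > 10 and len(events["full"]) > 10
        med = {
            m: (
                np.median([e.x_extent for e in evs]),
                np.median([e.duration for e in evs]),
            )
            for m, evs in events.items()
        }
        assert med["additive_u"][0] < med["full"][0]
        assert med["additive_u"][1] < med["full"][1]


def test_sigma_matches_omega_identification():
    p = get_preset("fig4_standing", sigma=0.06)
    assert p.omega == pytest.approx(1 / 0.06**2)
    st = background_states(p)[0]
    assert st.u_star == pytest.approx(0.0523, abs=5e-3)
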