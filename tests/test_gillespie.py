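"""Microscopic exact simulators: well-mixed SSA and spatial SSA (RDME)."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from actinwaves import (
    Grid,
    ModelParams,
    ReactionNetwork,
    background_states,
    build_actin_network,
    get_preset,
    simulate_rdme,
    simulate_ssa_wellmixed,
)
from actinwaves.exceptions import ValidationError
from actinwaves.gillespie import count_rates_wellmixed


class TestWellMixedSsa:
    def test_first_event_from_empty_state_is_the_constant_source(
        self, fig4_network, fig4_params
    ):
        omega = 100.0
        first_times = []
        for seed in range(300):
            times, counts = simulate_ssa_wellmixed(
                fig4_network, omega, np.array([0, 0]), T=1e6, seed=seed, max_events=1
            )
            assert counts[1, 0] == 1 and counts[1, 1] == 0  # a u molecule appears
            first_times.append(times[1])
        mean = np.mean(first_times)
        expected = 1.0 / (fig4_params.a5 * omega)
        se = expected / np.sqrt(len(first_times))
        assert abs(mean - expected) < 3 * se

    def test_counts_never_negative(self, fig4_network):
        for seed in (0, 1, 2):
            _, counts = simulate_ssa_wellmixed(
                fig4_network, 50.0, np.array([10, 10]), T=5.0, seed=seed
            )
            assert counts.min() >= 0

    def test_count_rate_scaling_converges_to_concentration_propensities(
        self, fig4_network
    ):
        conc = np.array([0.714, 1.873])  # not exactly representable at small omega
        R = fig4_network.propensities(conc)
        errs = []
        for omega in (10.0, 100.0, 1000.0):
            counts = np.round(conc * omega).astype(int)
            rates = count_rates_wellmixed(fig4_network, counts, omega)
            errs.append(np.abs(rates / omega - R).max())
        assert errs[0] > errs[-1]
        assert errs[-1] < 1e-3

    def test_first_moments_converge_to_kinetics_ode(self, fig4_params, fig4_network):
        st = background_states(fig4_params)[0]
        y0 = np.array([st.u_star, 2 * st.v_star])
        sol = solve_ivp(
            lambda t, y: fig4_network.drift(y), (0, 2.0), y0,
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        ref = sol.y[:, -1]
        errs = []
        for omega in (100.0, 1000.0, 10000.0):
            finals = []
            for seed in range(10):
                x0 = np.round(y0 * omega).astype(int)
                _, counts = simulate_ssa_wellmixed(fig4_network, omega, x0, T=2.0, seed=seed)
                finals.append(counts[-1] / omega)
            errs.append(np.abs(np.mean(finals, axis=0) - ref).max())
        assert errs[0] > errs[2]
        assert errs[2] < 0.01

    def test_invalid_initial_counts_rejected(self, fig4_network):
        with pytest.raises(ValidationError):
            simulate_ssa_wellmixed(fig4_network, 10.0, np.array([-1, 0]), T=1.0, seed=0)
        with pytest.raises(ValidationError):
            simulate_ssa_wellmixed(fig4_network, 10.0, np.array([0.5, 0.0]), T=1.0, seed=0)

    def test_generic_network_path_birth_death(self):
        # one-species birth-death network exercises the generic engine;
        # stationary mean count is b/d * omega
        params = get_preset("fig4_standing")
        b, d = 5.0, 1.0
        network = ReactionNetwork(
            species_names=("x",),
            stoich=np.array([[1, -1]]),
            propensities=lambda s: np.stack([np.full(np.shape(s[0]), b), d * s[0]]),
            diffusion=np.array([0.0]),
            params=params,
        )
        omega = 10.0
        times, counts = simulate_ssa_wellmixed(network, omega, np.array([0]), T=200.0, seed=3)
        keep = times > 20.0
        mean_count = np.mean(counts[keep, 0])
        assert mean_count == pytest.approx(b / d * omega, rel=0.1)


class TestSpatialSsa:
    def test_diffusion_only_conserves_molecules(self, fig4_network, rng):
        g = Grid(-5, 5, 64)
        ic = rng.integers(0, 30, size=(2, 64))
        f = simulate_rdme(
            fig4_network, g, omega=50.0, ic_counts=ic, T=1.0, seed=5,
            n_snapshots=5, disable_reactions=True,
        )
        vol = 50.0 * g.dx
        np.testing.assert_allclose(f.u.sum(axis=1) * vol, ic[0].sum(), rtol=1e-12)
        np.testing.assert_allclose(f.v.sum(axis=1) * vol, ic[1].sum(), rtol=1e-12)

    def test_single_molecule_msd_grows_like_2dt(self, fig4_params, fig4_network):
        g = Grid(-5, 5, 64)
        ic = np.zeros((2, 64), dtype=np.int64)
        ic[0, 32] = 1
        disps = []
        for seed in range(200):
            f = simulate_rdme(
                fig4_network, g, omega=50.0, ic_counts=ic, T=2.0, seed=seed,
                n_snapshots=3, disable_reactions=True,
            )
            pos = np.array([g.x[np.argmax(c)] for c in f.u])
            disps.append((pos[-1] - pos[0]) ** 2)
        msd = np.mean(disps)
        expected = 2 * fig4_params.Du * 2.0
        se = expected * np.sqrt(2 / len(disps))
        assert abs(msd - expected) < 3 * se

    def test_concentrations_match_count_scaling(self, fig4_network):
        g = Grid(-5, 5, 64)
        ic = np.full((2, 64), 7, dtype=np.int64)
        f = simulate_rdme(fig4_network, g, omega=64.0, ic_counts=ic, T=0.0, seed=0, n_snapshots=1)
        np.testing.assert_allclose(f.u[0], 7 / (64.0 * g.dx))

    def test_front_speed_approaches_deterministic_value(self):
        """A bump nucleates two counter-propagating fronts.  The RDME's
        large-Omega limit is the spatially discrete rate equation, so its
        front speed is compared against the deterministic simulation on
        the same lattice (the continuum value needs joint dx refinement)."""
        from actinwaves import make_initial_condition, measure_speed, simulate_rde

        params = get_preset("fig11_travelling")
        network = build_actin_network(params)
        g = Grid(-6, 6, 77)
        conc = make_initial_condition("gaussian_bump", params, g)
        det = simulate_rde(network, g, conc, T=2.5, save_every=20)
        speed_det = measure_speed(det, window=(0.5, 1.8), x_range=(-6, -0.3))
        vol = 816.0  # effective noise 1/sqrt(vol) ~ 0.035, below nucleation
        ic = np.round(conc * vol).astype(np.int64)
        f = simulate_rdme(
            network, g, omega=vol / g.dx, ic_counts=ic, T=2.5, seed=2, n_snapshots=51
        )
        speed = measure_speed(f, window=(0.5, 1.8), x_range=(-6, -0.3))
        assert speed == pytest.approx(speed_det, rel=0.15)

    def test_invalid_inputs_rejected(self, fig4_network):
        g = Grid(-5, 5, 64)
        with pytest.raises(ValidationError):
            simulate_rdme(fig4_network, g, 50.0, np.zeros((2, 10), dtype=int), T=1.0, seed=0)
        with pytest.raises(ValidationError):
            simulate_rdme(fig4_network, g, 50.0, -np.ones((2, 64), dtype=int), T=1.0, seed=0)
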