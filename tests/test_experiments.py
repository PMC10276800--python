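"""Initial-condition fixtures, experiment pipelines, persistence and CLI."""

import json

import numpy as np
import pytest

from actinwaves import (
    ExperimentConfig,
    Grid,
    NoiseConfig,
    background_states,
    build_actin_network,
    get_preset,
    load_field,
    make_initial_condition,
    run_experiment,
    save_field,
    simulate_cle,
)
from actinwaves.exceptions import ValidationError


@pytest.fixture(scope="module")
def centred_grid():
    # odd cell count puts a cell centre exactly at x = 0
    return Grid(-4.5, 4.5, 9)


class TestFixtures:
    def test_gaussian_bump_values_at_origin(self, fig4_params, centred_grid):
        bg = background_states(fig4_params)[0]
        u0, v0 = make_initial_condition("gaussian_bump", fig4_params, centred_grid)
        k = np.argmin(np.abs(centred_grid.x))
        assert centred_grid.x[k] == pytest.approx(0.0)
        assert u0[k] == pytest.approx(bg.u_star + 1.0)
        assert v0[k] == pytest.approx(bg.v_star + 2.0)

    def test_homog_eq_is_an_equilibrium(self, fig4_params, fig4_network, centred_grid):
        ic = make_initial_condition("homog_eq", fig4_params, centred_grid)
        assert np.abs(fig4_network.drift(ic)).max() < 1e-10

    def test_homog_4v_perturbation_is_small_and_seeded(self, fig4_params, centred_grid):
        bg = background_states(fig4_params)[0]
        ic1 = make_initial_condition(
            "homog_4v", fig4_params, centred_grid, rng=np.random.default_rng(5)
        )
        ic2 = make_initial_condition(
            "homog_4v", fig4_params, centred_grid, rng=np.random.default_rng(5)
        )
        np.testing.assert_array_equal(ic1, ic2)
        assert np.all(ic1[1] == 4 * bg.v_star)
        assert np.abs(ic1[0] - bg.u_star).max() <= 1e-2 * bg.u_star
        assert np.abs(ic1[0] - bg.u_star).max() > 0

    def test_homog_2v_doubles_the_inhibitor(self, fig4_params, centred_grid):
        bg = background_states(fig4_params)[0]
        ic = make_initial_condition("homog_2v", fig4_params, centred_grid)
        assert np.all(ic[1] == 2 * bg.v_star)

    def test_from_file_roundtrip(self, fig4_params, centred_grid, tmp_path):
        ref = make_initial_condition("gaussian_bump", fig4_params, centred_grid)
        path = tmp_path / "ic.csv"
        np.savetxt(path, ref.T, delimiter=",")
        ic = make_initial_condition("from_file", fig4_params, centred_grid, path=path)
        np.testing.assert_allclose(ic, ref)

    def test_unknown_fixture_raises(self, fig4_params, centred_grid):
        with pytest.raises(ValidationError):
            make_initial_condition("bogus", fig4_params, centred_grid)


class TestPersistence:
    def test_field_roundtrip_is_lossless(self, fig4_params, fig4_network, tmp_path):
        g = Grid(-5, 5, 64)
        ic = make_initial_condition("gaussian_bump", fig4_params, g)
        f = simulate_cle(
            fig4_network, g, ic, T=0.5, noise=NoiseConfig(sigma=0.03, seed=9), save_every=50
        )
        path = tmp_path / "field.h5"
        save_field(f, path, preset="fig4_standing")
        g2 = load_field(path)
        np.testing.assert_array_equal(f.u, g2.u)
        np.testing.assert_array_equal(f.v, g2.v)
        np.testing.assert_array_equal(f.times, g2.times)
        assert g2.params == f.params
        assert g2.seed == 9
        assert g2.noise_mode == "full"

    def test_config_file_roundtrip(self, tmp_path):
        cfg = ExperimentConfig(pipeline="scan", preset="fig4_standing", c1_range=(0.2, 0.3))
        path = tmp_path / "cfg.json"
        path.write_text(json.dumps(cfg.to_dict()))
        assert ExperimentConfig.from_file(path) == cfg
        toml = 'pipeline = "scan"\npreset = "fig4_standing"\nc1_range = [0.2, 0.3]\n'
        (tmp_path / "cfg.toml").write_text(toml)
        assert ExperimentConfig.from_file(tmp_path / "cfg.toml") == cfg


class TestRunExperiment:
    def test_scan_pipeline_writes_eigen_table(self, tmp_path):
        cfg = ExperimentConfig(
            pipeline="scan", preset="fig4_standing", n_scan=10, out=str(tmp_path / "scan")
        )
        files = run_experiment(cfg)
        import pandas as pd

        table = pd.read_csv(files[0])
        assert list(table.columns) == ["c1", "u_star", "v_star", "re_l1", "im_l1", "re_l2", "im_l2"]
        assert len(table) == 10
        trans = json.loads(files[1].read_text())
        assert trans["c1_complex_onset"] == pytest.approx(0.25, abs=0.01)
        assert trans["c1_hopf"] == pytest.approx(0.29, abs=0.01)

    def test_stats_replay_is_byte_identical(self, tmp_path):
        cfg = dict(
            pipeline="stats",
            preset="fig4_standing",
            ic_fixture="homog_4v",
            sigmas=(0.05,),
            runs=2,
            T=5.0,
            dt=2e-3,
            stepper="imex",
        )
        files1 = run_experiment(ExperimentConfig(**cfg, out=str(tmp_path / "a")))
        files2 = run_experiment(ExperimentConfig(**cfg, out=str(tmp_path / "b")))
        assert files1[0].read_bytes() == files2[0].read_bytes()
        assert files1[1].read_bytes() == files2[1].read_bytes()

    def test_simulate_pipeline_embeds_config(self, tmp_path):
        cfg = ExperimentConfig(
            pipeline="simulate", preset="fig4_standing", T=1.0, save_every=200,
            out=str(tmp_path / "sim"),
        )
        (path,) = run_experiment(cfg)
        import h5py

        with h5py.File(path) as f:
            stored = json.loads(f.attrs["config"])
        assert stored["preset"] == "fig4_standing"

    def test_unknown_pipeline_raises(self):
        with pytest.raises(ValidationError):
            run_experiment(ExperimentConfig(pipeline="bogus"))


class TestCli:
    def test_steady_prints_background_state(self):
        from click.testing import CliRunner

        from actinwaves.cli import main

        result = CliRunner().invoke(main, ["steady", "--preset", "fig4_standing"])
        assert result.exit_code == 0
        assert "0.0523" in result.output

    def test_scan_subcommand(self, tmp_path):
        from click.testing import CliRunner

        from actinwaves.cli import main

        out = tmp_path / "scan"
        result = CliRunner().invoke(main, ["scan", "--out", str(out)])
        assert result.exit_code == 0
        assert (tmp_path / "scan.csv").exists()

    def test_simulate_subcommand(self, tmp_path):
        from click.testing import CliRunner

        from actinwaves.cli import main

        out = tmp_path / "sim"
        result = CliRunner().invoke(
            main,
            ["simulate", "--preset", "fig4_standing", "--T", "1.0", "--out", str(out)],
        )
        assert result.exit_code == 0
        assert (tmp_path / "sim.h5").exists()

    def test_ssa_subcommand(self):
        from click.testing import CliRunner

        from actinwaves.cli import main

        result = CliRunner().invoke(main, ["ssa", "--omega", "200", "--T", "2.0"])
        assert result.exit_code == 0
        assert "final_counts" in result.output
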