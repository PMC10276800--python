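"""Initial-condition fixtures, experiment presets, config and file I/O.

Everything here is glue: the named initial conditions used throughout the
study (a centred bump on the background state, homogeneous states with an
elevated inhibitor), experiment-level configuration that bundles a
parameter preset with a grid, noise settings and seeds, and HDF5/CSV
persistence that embeds the full resolved configuration for replay.

All quantities are in nondimensional model units; configs load from TOML
or JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cle import NoiseConfig, simulate_cle
from .equilibria import background_states, eigen_scan, jacobian
from .exceptions import ValidationError
from .model import ModelParams, build_actin_network, get_preset
from .pde import Grid, SpaceTimeField, simulate_rde

__all__ = [
    "make_initial_condition",
    "ExperimentConfig",
    "run_experiment",
    "save_field",
    "load_field",
    "events_to_frame",
    "IC_FIXTURES",
    "EXPERIMENTS",
]

logger = logging.getLogger(__name__)

IC_FIXTURES = ("gaussian_bump", "homog_4v", "homog_2v", "homog_eq", "from_file")

#: amplitude of the symmetry-breaking perturbation, relative to u*
PERTURBATION_AMPLITUDE = 1e-2


def make_initial_condition(
    fixture: str,
    params: ModelParams,
    grid: Grid,
    rng: np.random.Generator | None = None,
    path=None,
) -> np.ndarray:
    """Build a named initial condition as a (2, n) state array.

    Fixtures:

    * ``gaussian_bump`` — u = u* + exp(-x^2), v = v* + 2/cosh^2(5x):
      a crude approximation of the localised pulse.
    * ``homog_4v`` — homogeneous (u*, 4 v*) plus a small uniform
      perturbation of amplitude 1e-2 u* on u, drawn from ``rng`` (the
      elevated inhibitor delays the first activation).
    * ``homog_2v`` — homogeneous (u*, 2 v*).
    * ``homog_eq`` — the homogeneous background state.
    * ``from_file`` — two-column CSV (u, v), one row per grid cell.
    """
    bg = background_states(params)[0]
    x = grid.x
    n = grid.n
    if fixture == "gaussian_bump":
        u = bg.u_star + np.exp(-(x**2))
        v = bg.v_star + 2.0 / np.cosh(5.0 * x) ** 2
    elif fixture == "homog_4v":
        if rng is None:
            rng = np.random.default_rng(0)
        u = np.full(n, bg.u_star) + PERTURBATION_AMPLITUDE * bg.u_star * rng.uniform(-1, 1, n)
        v = np.full(n, 4.0 * bg.v_star)
    elif fixture == "homog_2v":
        u = np.full(n, bg.u_star)
        v = np.full(n, 2.0 * bg.v_star)
    elif fixture == "homog_eq":
        u = np.full(n, bg.u_star)
        v = np.full(n, bg.v_star)
    elif fixture == "from_file":
        if path is None:
            raise ValidationError("fixture 'from_file' needs a path")
        data = np.loadtxt(path, delimiter=",")
        if data.shape != (n, 2):
            raise ValidationError(f"file must contain {n} rows of (u, v)")
        u, v = data[:, 0], data[:, 1]
    else:
        raise ValidationError(f"unknown IC fixture {fixture!r}; known: {IC_FIXTURES}")
    return np.stack([u, v])


@dataclass
class ExperimentConfig:
    """Fully resolved description of one experiment."""

    pipeline: str  # "simulate" | "stats" | "scan" | "waves"
    preset: str = "fig4_standing"
    grid: tuple[float, float, int] = (-10.0, 10.0, 400)
    ic_fixture: str = "gaussian_bump"
    T: float = 20.0
    dt: float | None = None
    save_every: int = 50
    sigma: float = 0.0
    noise_mode: str = "full"
    variance_convention: str = "sum_of_propensities"
    stepper: str = "euler"
    sigmas: tuple = ()  # stats pipeline
    c1_range: tuple[float, float] = (0.18, 0.35)  # scan pipeline
    n_scan: int = 35
    runs: int = 1
    base_seed: int = 0
    out: str = "experiment_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        for key in ("grid", "sigmas", "c1_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


#: named experiment presets mirroring the study's figure-level protocols
EXPERIMENTS: dict[str, dict] = {
    "fig3_scan": dict(pipeline="scan", preset="fig4_standing", c1_range=(0.18, 0.35)),
    "fig5_standing": dict(pipeline="simulate", preset="fig4_standing", T=20.0),
    "fig6_splitting": dict(
        pipeline="simulate", preset="fig4_standing", grid=(-60.0, 60.0, 2400), T=100.0
    ),
    "fig7_noise": dict(
        pipeline="simulate", preset="fig4_standing", T=100.0, sigma=0.045, stepper="imex", dt=2e-3
    ),
    "fig8_stats": dict(
        pipeline="stats",
        preset="fig4_standing",
        ic_fixture="homog_4v",
        T=100.0,
        sigmas=tuple(np.round(np.arange(0.030, 0.0601, 0.002), 4)),
        runs=100,
        stepper="imex",
        dt=2e-3,
    ),
    "fig11_travelling": dict(pipeline="simulate", preset="fig11_travelling", T=10.0),
    "fig14_oscillatory": dict(
        pipeline="simulate", preset="fig14_oscillatory", ic_fixture="homog_4v", T=100.0
    ),
    "fig16_oscillatory_noise": dict(
        pipeline="simulate",
        preset="fig14_oscillatory",
        ic_fixture="homog_4v",
        T=100.0,
        sigma=0.01,
        stepper="imex",
        dt=2e-3,
    ),
}


def get_experiment(name: str, **overrides) -> ExperimentConfig:
    try:
        base = EXPERIMENTS[name]
    except KeyError:
        raise ValidationError(f"unknown experiment {name!r}; known: {sorted(EXPERIMENTS)}") from None
    return ExperimentConfig(**{**base, **overrides})


def run_experiment(config: ExperimentConfig) -> list[Path]:
    """Execute a named pipeline and write its outputs.

    Returns the list of files written; every output embeds the resolved
    config (HDF5 attributes or a JSON sidecar).  Replaying an identical
    config reproduces the outputs byte for byte.
    """
    t0 = time.perf_counter()
    params = get_preset(config.preset)
    grid = Grid(*config.grid)
    out = Path(config.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if config.pipeline == "simulate":
        rng = np.random.default_rng(config.base_seed)
        ic = make_initial_condition(config.ic_fixture, params, grid, rng=rng)
        network = build_actin_network(params)
        if config.sigma > 0:
            fld = simulate_cle(
                network,
                grid,
                ic,
                T=config.T,
                noise=NoiseConfig(
                    sigma=config.sigma,
                    seed=config.base_seed,
                    mode=config.noise_mode,
                    variance_convention=config.variance_convention,
                ),
                dt=config.dt,
                save_every=config.save_every,
                stepper=config.stepper,
            )
        else:
            fld = simulate_rde(
                network,
                grid,
                ic,
                T=config.T,
                dt=config.dt,
                save_every=config.save_every,
                stepper=config.stepper,
            )
        path = out.with_suffix(".h5")
        save_field(fld, path, config=config, preset=config.preset)
        written.append(path)

    elif config.pipeline == "stats":
        from .events import ensemble_event_stats

        stats = ensemble_event_stats(
            params,
            sigmas=config.sigmas,
            n_runs=config.runs,
            T=config.T,
            base_seed=config.base_seed,
            grid=grid,
            dt=config.dt,
            stepper=config.stepper,
            save_every=config.save_every,
            mode=config.noise_mode,
            ic_fixture=config.ic_fixture,
        )
        path = out.with_suffix(".csv")
        stats.to_frame().to_csv(path, index=False)
        written.append(path)
        ev_rows = []
        for sigma, evs in stats.events.items():
            for e in evs:
                ev_rows.append((sigma, e.t_on, e.t_off, e.duration, e.x_extent, e.u_max))
        import pandas as pd

        ev_path = out.parent / (out.stem + "_events.csv")
        pd.DataFrame(
            ev_rows, columns=["sigma", "t_on", "t_off", "duration", "width", "max"]
        ).to_csv(ev_path, index=False)
        written.append(ev_path)

    elif config.pipeline == "scan":
        import pandas as pd

        c1_values = np.linspace(*config.c1_range, config.n_scan)
        rows = []
        for c1 in c1_values:
            p = params.with_(c1=float(c1))
            st = background_states(p)[0]
            lam = np.linalg.eigvals(jacobian(p, (st.u_star, st.v_star)))
            lam = lam[np.argsort(-lam.real)]
            rows.append(
                (c1, st.u_star, st.v_star, lam[0].real, lam[0].imag, lam[1].real, lam[1].imag)
            )
        path = out.with_suffix(".csv")
        pd.DataFrame(
            rows, columns=["c1", "u_star", "v_star", "re_l1", "im_l1", "re_l2", "im_l2"]
        ).to_csv(path, index=False)
        written.append(path)
        onset, hopf = eigen_scan(params, config.c1_range)
        sidecar = out.parent / (out.stem + "_transitions.json")
        sidecar.write_text(
            json.dumps({"c1_complex_onset": onset, "c1_hopf": hopf, "config": config.to_dict()},
                       indent=2)
        )
        written.append(sidecar)

    elif config.pipeline == "waves":
        from .waves import solve_wave_profile, travelling_wave_init

        profile0, c_est, wgrid, _ = travelling_wave_init(params)
        prof = solve_wave_profile(params, wgrid, profile0, init_c=c_est)
        import pandas as pd

        path = out.with_suffix(".csv")
        pd.DataFrame({"xi": prof.xi, "phi_u": prof.phi_u, "phi_v": prof.phi_v}).to_csv(
            path, index=False
        )
        sidecar = out.parent / (out.stem + ".json")
        sidecar.write_text(
            json.dumps(
                {"c": prof.c, "residual_norm": prof.residual_norm, "config": config.to_dict()},
                indent=2,
            )
        )
        written.extend([path, sidecar])

    else:
        raise ValidationError(f"unknown pipeline {config.pipeline!r}")

    logger.info("experiment %s finished in %.1fs", config.pipeline, time.perf_counter() - t0)
    return written


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_field(field: SpaceTimeField, path, config: ExperimentConfig | None = None, preset=None):
    """Save a kymograph to HDF5 (datasets /u, /v, /x, /t plus attributes)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("u", data=field.u)
        f.create_dataset("v", data=field.v)
        f.create_dataset("x", data=field.grid.x)
        f.create_dataset("t", data=field.times)
        f.attrs["params"] = json.dumps(field.params.to_dict())
        f.attrs["grid"] = json.dumps([field.grid.x_min, field.grid.x_max, field.grid.n])
        f.attrs["noise_mode"] = field.noise_mode
        f.attrs["seed"] = -1 if field.seed is None else field.seed
        f.attrs["meta"] = json.dumps(field.meta)
        if preset:
            f.attrs["preset"] = preset
        if config is not None:
            f.attrs["config"] = json.dumps(config.to_dict())


def load_field(path) -> SpaceTimeField:
    """Load a kymograph saved by :func:`save_field` (lossless round-trip)."""
    import h5py

    with h5py.File(path, "r") as f:
        u = f["u"][...]
        v = f["v"][...]
        times = f["t"][...]
        gspec = json.loads(f.attrs["grid"])
        params = ModelParams(**json.loads(f.attrs["params"]))
        seed = int(f.attrs["seed"])
        return SpaceTimeField(
            u=u,
            v=v,
            times=times,
            grid=Grid(gspec[0], gspec[1], int(gspec[2])),
            params=params,
            seed=None if seed < 0 else seed,
            noise_mode=str(f.attrs["noise_mode"]),
            meta=json.loads(f.attrs["meta"]),
        )


def events_to_frame(events, run: int | None = None):
    """Event list as a pandas DataFrame (one row per event)."""
    import pandas as pd

    rows = [
        {
            "run": run,
            "t_on": e.t_on,
            "t_off": e.t_off,
            "duration": e.duration,
            "width": e.x_extent,
            "max": e.u_max,
            "n_cells": e.n_cells,
        }
        for e in events
    ]
    return pd.DataFrame(rows)
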