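"""Method-of-lines integration of the reaction-diffusion equations.

The membrane slice is a periodic 1-D domain (a circle).  Space is
discretised by finite volumes with the standard 3-point Laplacian; time
stepping is explicit Euler by default (dt = 0.2 dx^2/max(Du, Dv)), with an
optional IMEX stepper that treats diffusion implicitly through an FFT
solve and allows larger steps.

The private :func:`_integrate` engine is shared with the stochastic
Langevin solver (:mod:`actinwaves.cle`): the deterministic part of a step
is computed by identical operations in both, so the zero-noise Langevin
trajectory is bit-identical to the deterministic one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import IntegrationError, ValidationError
from .model import ModelParams, ReactionNetwork

__all__ = ["Grid", "SpaceTimeField", "laplacian_periodic", "default_dt", "simulate_rde"]

logger = logging.getLogger(__name__)

#: Courant safety factor for the explicit-Euler diffusion limit.
CFL_SAFETY = 0.2


@dataclass(frozen=True)
class Grid:
    """A uniform periodic 1-D grid of cell centres."""

    x_min: float = -10.0
    x_max: float = 10.0
    n: int = 400

    def __post_init__(self):
        if self.n < 8:
            raise ValidationError(f"grid needs n >= 8 cells, got {self.n}")
        if not self.x_max > self.x_min:
            raise ValidationError("grid needs x_max > x_min")

    @property
    def dx(self) -> float:
        return (self.x_max - self.x_min) / self.n

    @property
    def length(self) -> float:
        return self.x_max - self.x_min

    @property
    def x(self) -> np.ndarray:
        """Cell-centre coordinates."""
        return self.x_min + (np.arange(self.n) + 0.5) * self.dx


@dataclass
class SpaceTimeField:
    """A kymograph: solution fields on the space-time lattice.

    ``u`` and ``v`` have shape ``(n_times, grid.n)``; ``times`` is strictly
    increasing and starts at 0.  ``meta`` carries solver provenance
    (noise mode, clamp counts, ...).
    """

    u: np.ndarray
    v: np.ndarray
    times: np.ndarray
    grid: Grid
    params: ModelParams
    seed: int | None = None
    noise_mode: str = "none"
    meta: dict = field(default_factory=dict)

    @property
    def dt_sample(self) -> float:
        """Sampling interval of the stored snapshots."""
        return float(self.times[1] - self.times[0])

    def snapshot(self, index: int = -1) -> np.ndarray:
        """State (2, n) at a stored time index."""
        return np.stack([self.u[index], self.v[index]])


def laplacian_periodic(f: np.ndarray, dx: float) -> np.ndarray:
    """Second-order central-difference Laplacian with periodic wraparound.

    Acts on the last axis.
    """
    f = np.asarray(f)
    if f.shape[-1] < 3:
        raise ValidationError("laplacian needs at least 3 cells")
    return (np.roll(f, 1, axis=-1) - 2.0 * f + np.roll(f, -1, axis=-1)) / (dx * dx)


def default_dt(grid: Grid, params: ModelParams) -> float:
    """Explicit-Euler step obeying the diffusive stability limit."""
    return CFL_SAFETY * grid.dx**2 / max(params.Du, params.Dv)


def _as_state(ic, n: int) -> np.ndarray:
    state = np.array(ic, dtype=float)
    if state.shape != (2, n):
        raise ValidationError(f"initial condition must have shape (2, {n}), got {state.shape}")
    return state


def _integrate(
    network: ReactionNetwork,
    grid: Grid,
    ic,
    T: float,
    dt: float | None,
    save_every: int,
    noise_hook=None,
    clamp: bool = False,
    stepper: str = "euler",
):
    """Shared Euler / IMEX time loop.

    ``noise_hook(state, dt) -> (2, n) increment`` is added after the
    deterministic part of each step; ``clamp`` floors the state at zero
    after the full step and counts affected cells.
    """
    params = network.params
    if dt is None:
        dt = default_dt(grid, params)
    if stepper not in ("euler", "imex"):
        raise ValidationError(f"unknown stepper {stepper!r}")
    if stepper == "euler" and dt > 0.5 * grid.dx**2 / max(params.Du, params.Dv) * (1 + 1e-12):
        raise ValidationError(
            f"dt={dt} violates the explicit diffusion stability limit "
            f"{0.5 * grid.dx**2 / max(params.Du, params.Dv):.3e}"
        )
    state = _as_state(ic, grid.n)
    n_steps = int(round(T / dt))
    save_every = max(1, int(save_every))
    n_saves = n_steps // save_every + 1

    u_out = np.empty((n_saves, grid.n))
    v_out = np.empty((n_saves, grid.n))
    times = np.empty(n_saves)
    u_out[0], v_out[0] = state
    times[0] = 0.0

    D = network.diffusion[:, None]
    dx2 = grid.dx * grid.dx
    inv_dx2 = 1.0 / dx2
    S = network.stoich.astype(float)
    propensities = network.propensities

    if stepper == "imex":
        # implicit diffusion: solve (I - dt D L) x = rhs in Fourier space
        k = np.arange(grid.n)
        lam = -(2.0 - 2.0 * np.cos(2.0 * np.pi * k / grid.n)) * inv_dx2
        denom = 1.0 - dt * network.diffusion[:, None] * lam[None, :]

    n_clamped = 0
    save_idx = 1
    for step in range(1, n_steps + 1):
        R = propensities(state)
        reaction = S @ R
        if stepper == "euler":
            lap = (np.roll(state, 1, axis=-1) - 2.0 * state + np.roll(state, -1, axis=-1)) * inv_dx2
            new = state + dt * (D * lap + reaction)
            if noise_hook is not None:
                new += noise_hook(state, dt)
        else:
            rhs = state + dt * reaction
            if noise_hook is not None:
                rhs = rhs + noise_hook(state, dt)
            new = np.fft.irfft(np.fft.rfft(rhs, axis=-1) / denom[:, : grid.n // 2 + 1], n=grid.n, axis=-1)
        if clamp:
            neg = new < 0.0
            n_clamped += int(np.count_nonzero(neg))
            np.maximum(new, 0.0, out=new)
        state = new
        if step % save_every == 0:
            if not np.all(np.isfinite(state)):
                raise IntegrationError(
                    f"non-finite state at t={step * dt:.6g}", t_bad=step * dt
                )
            u_out[save_idx], v_out[save_idx] = state
            times[save_idx] = step * dt
            save_idx += 1
    if not np.all(np.isfinite(state)):
        raise IntegrationError(f"non-finite state at t={n_steps * dt:.6g}", t_bad=n_steps * dt)

    meta = {"dt": dt, "stepper": stepper, "n_steps": n_steps, "n_clamped": n_clamped}
    if clamp and n_steps:
        meta["clamp_fraction"] = n_clamped / (n_steps * grid.n * 2)
    return u_out[:save_idx], v_out[:save_idx], times[:save_idx], meta


def _use_kernel(network: ReactionNetwork, stepper: str, backend: str) -> bool:
    if backend == "numpy":
        return False
    from ._kernels import HAVE_NUMBA

    ok = network.kind == "actin" and stepper in ("euler", "imex") and HAVE_NUMBA
    if backend == "numba" and not ok:
        raise ValidationError("numba backend requires the actin network")
    return ok


def _check_dt(grid: Grid, params: ModelParams, dt: float, stepper: str) -> None:
    limit = 0.5 * grid.dx**2 / max(params.Du, params.Dv)
    if stepper == "euler" and dt > limit * (1 + 1e-12):
        raise ValidationError(
            f"dt={dt} violates the explicit diffusion stability limit {limit:.3e}"
        )


def simulate_rde(
    network: ReactionNetwork,
    grid: Grid,
    ic,
    T: float,
    dt: float | None = None,
    save_every: int = 20,
    stepper: str = "euler",
    backend: str = "auto",
) -> SpaceTimeField:
    """Integrate the deterministic reaction-diffusion system.

    Parameters
    ----------
    ic
        Initial state of shape ``(2, grid.n)`` (rows u, v).
    save_every
        Store every ``save_every``-th step (plus the initial state).
    backend
        "auto" uses the compiled loop for the built-in actin network,
        "numpy" forces the generic vectorised engine.

    Deterministic and bit-stable for fixed inputs and backend.
    """
    if dt is None:
        dt = default_dt(grid, network.params)
    if _use_kernel(network, stepper, backend):
        from ._kernels import run_actin_euler

        _as_state(ic, grid.n)
        _check_dt(grid, network.params, dt, stepper)
        u, v, times, meta = run_actin_euler(
            network.params, grid, ic, T, dt, save_every, stepper=stepper
        )
    else:
        u, v, times, meta = _integrate(
            network, grid, ic, T, dt, save_every, noise_hook=None, clamp=False, stepper=stepper
        )
    return SpaceTimeField(
        u=u, v=v, times=times, grid=grid, params=network.params, noise_mode="none", meta=meta
    )
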