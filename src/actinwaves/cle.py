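"""Euler-Maruyama integration of the chemical Langevin SPDE.

The mesoscopic description adds two intrinsic-noise terms to the
reaction-diffusion equations, both scaled by sigma = 1/sqrt(Omega):

* reaction noise with per-species variance given by the diagonal of
  S diag(R(X)) S^T (the summed propensities touching each species), and
* a conservative diffusion-noise flux, d/dx( sqrt(2 D X) dW ), discretised
  as independent interface fluxes so that the total mass contribution of
  the term is zero on the periodic domain.

Space-time white noise is represented on the grid by independent
N(0,1)/sqrt(dx dt) draws per cell (or interface) per step.

Two ablation modes support noise-model comparison experiments:
``reaction_only`` drops the diffusion flux term, and ``additive_u``
replaces all noise by additive space-time white noise on the activator.

The v-species reaction variance has two conventions: the systematic
construction gives eps*(c1 v + c2 u) (``sum_of_propensities``, default),
while a commonly printed form of this Langevin equation carries
eps*(-c1 v + c2 u)
(``as_printed``).  Negative variance arguments are clamped to zero before
the square root; states are clamped to >= 0 after every step and the
clamped-cell fraction is reported (the continuum equation does not
guarantee positivity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .model import ReactionNetwork
from .pde import Grid, SpaceTimeField, _integrate

__all__ = [
    "NoiseConfig",
    "reaction_noise_amplitude",
    "diffusion_noise_increment",
    "simulate_cle",
]

logger = logging.getLogger(__name__)

MODES = ("full", "reaction_only", "additive_u")
VARIANCE_CONVENTIONS = ("sum_of_propensities", "as_printed")

#: warn if more than this fraction of cells is clamped per step on average
CLAMP_ALARM_FRACTION = 0.05


@dataclass(frozen=True)
class NoiseConfig:
    """Noise mode, variance convention, strength and seed of a Langevin run."""

    sigma: float
    seed: int = 0
    mode: str = "full"
    variance_convention: str = "sum_of_propensities"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"unknown noise mode {self.mode!r}; known: {MODES}")
        if self.variance_convention not in VARIANCE_CONVENTIONS:
            raise ValidationError(
                f"unknown variance convention {self.variance_convention!r}; "
                f"known: {VARIANCE_CONVENTIONS}"
            )
        if not self.sigma >= 0:
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")


def reaction_noise_amplitude(
    network: ReactionNetwork, state, variance_convention: str = "sum_of_propensities"
) -> np.ndarray:
    """Per-species reaction-noise amplitude sqrt(diag(S diag(R) S^T)).

    With stoichiometric entries in {-1, 0, 1} this is the square root of
    the summed propensities of the reactions touching each species.  Under
    ``as_printed`` the network's literal printed-variance expression is
    used instead.  Negative arguments are clamped to zero.
    """
    if variance_convention == "as_printed":
        if network.printed_variance is None:
            raise ValidationError("network has no printed-variance expression")
        var = network.printed_variance(state)
    else:
        R = network.propensities(state)
        S2 = (network.stoich * network.stoich).astype(float)
        var = np.tensordot(S2, R, axes=(1, 0))
    return np.sqrt(np.maximum(var, 0.0))


def diffusion_noise_increment(
    state, D: np.ndarray, dx: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """One Euler-Maruyama increment of the conservative diffusion noise.

    One independent normal is drawn per cell interface; the flux through
    interface k+1/2 is sqrt(2 D max(0, (X_k + X_{k+1})/2)) xi / sqrt(dx dt)
    and the cell increment is the flux difference times dt/dx, periodic in
    x.  The increments telescope, so their sum over the circle vanishes.
    """
    state = np.asarray(state, dtype=float)
    D = np.asarray(D, dtype=float).reshape((state.shape[0],) + (1,) * (state.ndim - 1))
    xi = rng.standard_normal(state.shape)
    face_mean = 0.5 * (state + np.roll(state, -1, axis=-1))
    F = np.sqrt(2.0 * D * np.maximum(face_mean, 0.0)) * xi / np.sqrt(dx * dt)
    return (F - np.roll(F, 1, axis=-1)) * (dt / dx)


def simulate_cle(
    network: ReactionNetwork,
    grid: Grid,
    ic,
    T: float,
    noise: NoiseConfig,
    dt: float | None = None,
    save_every: int = 20,
    stepper: str = "euler",
    backend: str = "auto",
) -> SpaceTimeField:
    """Euler-Maruyama trajectory of the chemical Langevin SPDE.

    The deterministic part of each step is identical (operation for
    operation) to :func:`actinwaves.pde.simulate_rde` on the same backend,
    so the sigma=0 trajectory coincides with the deterministic one to
    machine precision.  Reproducible for a fixed ``noise.seed``.
    """
    from .pde import _check_dt, _use_kernel, default_dt

    if dt is None:
        dt = default_dt(grid, network.params)
    if _use_kernel(network, stepper, backend):
        from . import _kernels

        _check_dt(grid, network.params, dt, stepper)

        mode_code = {
            "full": _kernels.MODE_FULL,
            "reaction_only": _kernels.MODE_REACTION_ONLY,
            "additive_u": _kernels.MODE_ADDITIVE_U,
        }[noise.mode]
        u, v, times, meta = _kernels.run_actin_euler(
            network.params,
            grid,
            ic,
            T,
            dt,
            save_every,
            sigma=noise.sigma,
            mode=mode_code,
            printed_variance=(noise.variance_convention == "as_printed"),
            clamp=True,
            seed=noise.seed,
            stepper=stepper,
        )
        meta.update(sigma=noise.sigma, variance_convention=noise.variance_convention)
        frac = meta.get("clamp_fraction", 0.0)
        if frac > CLAMP_ALARM_FRACTION:
            logger.warning("clamped %.1f%% of cell updates (sigma=%g)", 100 * frac, noise.sigma)
        return SpaceTimeField(
            u=u,
            v=v,
            times=times,
            grid=grid,
            params=network.params,
            seed=noise.seed,
            noise_mode=noise.mode,
            meta=meta,
        )

    rng = np.random.default_rng(noise.seed)
    sigma = noise.sigma
    dx = grid.dx
    D = network.diffusion
    convention = noise.variance_convention
    mode = noise.mode

    if mode == "additive_u":

        def noise_hook(state, dt):
            inc = np.zeros_like(state)
            inc[0] = sigma * np.sqrt(dt / dx) * rng.standard_normal(state.shape[-1])
            return inc

    else:
        include_flux = mode == "full"

        def noise_hook(state, dt):
            amp = reaction_noise_amplitude(network, state, convention)
            inc = sigma * np.sqrt(dt / dx) * amp * rng.standard_normal(state.shape)
            if include_flux:
                inc += sigma * diffusion_noise_increment(state, D, dx, dt, rng)
            return inc

    u, v, times, meta = _integrate(
        network, grid, ic, T, dt, save_every, noise_hook=noise_hook, clamp=True, stepper=stepper
    )
    meta.update(sigma=sigma, variance_convention=convention)
    frac = meta.get("clamp_fraction", 0.0)
    if frac > CLAMP_ALARM_FRACTION:
        logger.warning("clamped %.1f%% of cell updates (sigma=%g)", 100 * frac, sigma)
    return SpaceTimeField(
        u=u,
        v=v,
        times=times,
        grid=grid,
        params=network.params,
        seed=noise.seed,
        noise_mode=mode,
        meta=meta,
    )
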