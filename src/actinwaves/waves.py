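"""Travelling- and standing-wave profiles, and speed/width measurement.

A localised wave is a profile (Phi_u, Phi_v) moving at fixed speed c; in
the co-moving coordinate xi = x - c t it solves the steady ODE system

    0 = Du Phi_u'' + c Phi_u' + f(Phi_u, Phi_v)
    0 = Dv Phi_v'' + c Phi_v' + g(Phi_u, Phi_v)

with tails in the background state.  The problem is translation
invariant, so when c is unknown the discretised system is augmented with
an integral phase condition <Phi_u_init', Phi_u - Phi_u_init> = 0 pinning
the wave's position, and solved by a damped Newton iteration with an
analytic Jacobian (same periodic finite-difference stencils as the PDE
solver; the domain is taken large enough for the tails to meet smoothly).

Sign convention: positive c means rightward motion (xi = x - c t); the
leftward member of a counter-propagating pair has c < 0 and its mirror
image the opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import background_states, kinetics_jacobian_entries
from .exceptions import MeasurementError, SolverError, TailError
from .model import ModelParams, build_actin_network
from .pde import Grid, SpaceTimeField, simulate_rde

__all__ = [
    "WaveProfile",
    "solve_wave_profile",
    "travelling_wave_init",
    "standing_wave_init",
    "measure_speed",
    "measure_width",
]


@dataclass
class WaveProfile:
    """A converged wave profile with speed and solver residual."""

    xi: np.ndarray
    phi_u: np.ndarray
    phi_v: np.ndarray
    c: float
    residual_norm: float
    params: ModelParams
    n_iter: int = 0

    def state(self) -> np.ndarray:
        """Profile as a (2, n) state array (e.g. for use as a PDE IC)."""
        return np.stack([self.phi_u, self.phi_v])


def _tail_values(arr: np.ndarray, n_edge: int = 5) -> float:
    return 0.5 * (arr[:n_edge].mean() + arr[-n_edge:].mean())


def _check_tails(u, v, params: ModelParams, tail_tol: float, what: str):
    """Verify both components decay to a background state at the domain ends."""
    states = background_states(params)
    tu, tv = _tail_values(u), _tail_values(v)
    bg = min(states, key=lambda s: abs(s.u_star - tu) + abs(s.v_star - tv))
    err = max(
        abs(u[0] - bg.u_star),
        abs(u[-1] - bg.u_star),
        abs(v[0] - bg.v_star),
        abs(v[-1] - bg.v_star),
    )
    if err > tail_tol:
        raise TailError(
            f"{what} tails deviate from background ({bg.u_star:.4g}, {bg.v_star:.4g}) "
            f"by {err:.3g} > {tail_tol}"
        )
    return bg


def _stencils(n: int, dx: float):
    """Sparse periodic Laplacian and first-derivative matrices."""
    from scipy import sparse

    ones = np.ones(n)
    L = sparse.diags([ones, -2.0 * ones, ones], [-1, 0, 1], shape=(n, n), format="lil")
    L[0, n - 1] = 1.0
    L[n - 1, 0] = 1.0
    L = (L / (dx * dx)).tocsr()
    Dxi = sparse.diags([-ones, ones], [-1, 1], shape=(n, n), format="lil")
    Dxi[0, n - 1] = -1.0
    Dxi[n - 1, 0] = 1.0
    Dxi = (Dxi / (2.0 * dx)).tocsr()
    return L, Dxi


def solve_wave_profile(
    params: ModelParams,
    grid: Grid,
    init_profile,
    init_c: float = 0.0,
    fix_c_zero: bool = False,
    tol: float = 1e-8,
    max_iter: int = 50,
    tail_tol: float = 0.35,
) -> WaveProfile:
    """Newton solve of the co-moving wave ODE on a periodic grid.

    ``init_profile`` (shape (2, n)) must already have background-state
    tails, e.g. a pulse clipped from a PDE simulation.  With
    ``fix_c_zero`` the speed is held at 0 and the phase condition is
    dropped (the grid breaks the continuous translation invariance, so
    the square system is solvable); otherwise c is an unknown and the
    system is augmented with the integral phase-condition row.

    Raises :class:`SolverError` on non-convergence (with the last
    residual) and :class:`TailError` for wrong-tail initial data.
    """
    init_profile = np.asarray(init_profile, dtype=float)
    n = grid.n
    if init_profile.shape != (2, n):
        raise ValueError(f"init_profile must have shape (2, {n})")
    u0, v0 = init_profile
    _check_tails(u0, v0, params, tail_tol, "initial profile")

    network = build_actin_network(params)
    L, Dxi = _stencils(n, grid.dx)
    Du, Dv = params.Du, params.Dv
    phase_weight = (Dxi @ u0) * grid.dx  # integral pinning row

    def residual(u, v, c):
        kin = network.drift(np.stack([u, v]))
        Fu = Du * (L @ u) + c * (Dxi @ u) + kin[0]
        Fv = Dv * (L @ v) + c * (Dxi @ v) + kin[1]
        return Fu, Fv

    u, v, c = u0.copy(), v0.copy(), (0.0 if fix_c_zero else float(init_c))
    Fu, Fv = residual(u, v, c)
    phase = float(phase_weight @ (u - u0))
    norm = max(np.abs(Fu).max(), np.abs(Fv).max())

    for iteration in range(max_iter):
        if norm < tol and (fix_c_zero or abs(phase) < 1e-8):
            break
        from scipy import sparse
        from scipy.sparse.linalg import spsolve

        fu, fv, gu, gv = kinetics_jacobian_entries(params, u, v)
        Juu = Du * L + c * Dxi + sparse.diags(fu)
        Jvv = Dv * L + c * Dxi + sparse.diags(gv)
        Juv = sparse.diags(fv)
        Jvu = sparse.diags(gu)
        core = sparse.bmat([[Juu, Juv], [Jvu, Jvv]], format="csr")
        if fix_c_zero:
            step = spsolve(core.tocsc(), np.concatenate([-Fu, -Fv]))
        else:
            phase_row = sparse.csr_matrix(
                np.concatenate([phase_weight, np.zeros(n)])[None, :]
            )
            c_col = sparse.csr_matrix(np.concatenate([Dxi @ u, Dxi @ v])[None, :].T)
            A = sparse.bmat([[core, c_col], [phase_row, None]], format="csc")
            step = spsolve(A, np.concatenate([-Fu, -Fv, [-phase]]))

        # damped update
        lam = 1.0
        for _ in range(12):
            u_try = u + lam * step[:n]
            v_try = v + lam * step[n : 2 * n]
            c_try = c if fix_c_zero else c + lam * step[2 * n]
            Fu_t, Fv_t = residual(u_try, v_try, c_try)
            norm_t = max(np.abs(Fu_t).max(), np.abs(Fv_t).max())
            if norm_t < norm or norm < tol:
                break
            lam *= 0.5
        u, v, c = u_try, v_try, c_try
        Fu, Fv, norm = Fu_t, Fv_t, norm_t
        phase = float(phase_weight @ (u - u0))
    else:
        raise SolverError(
            f"wave profile Newton did not converge in {max_iter} iterations "
            f"(residual {norm:.3e})",
            residual=norm,
        )

    _check_tails(u, v, params, tail_tol, "converged profile")
    return WaveProfile(
        xi=grid.x.copy(),
        phi_u=u,
        phi_v=v,
        c=float(c),
        residual_norm=float(norm),
        params=params,
        n_iter=iteration,
    )


# ---------------------------------------------------------------------------
# initial guesses clipped from PDE simulations
# ---------------------------------------------------------------------------


def _clip_pulse(snapshot, grid: Grid, params: ModelParams, x_lo: float, x_hi: float):
    """Keep the pulse inside [x_lo, x_hi], background state elsewhere."""
    bg = background_states(params)[0]
    x = grid.x
    keep = (x >= x_lo) & (x <= x_hi)
    out = np.stack(
        [
            np.where(keep, snapshot[0], bg.u_star),
            np.where(keep, snapshot[1], bg.v_star),
        ]
    )
    return out


def travelling_wave_init(
    params: ModelParams,
    grid: Grid | None = None,
    T_split: float = 3.0,
    T_relax: float = 4.0,
):
    """Single travelling-wave initial guess from a PDE simulation.

    Splits a centred bump into two counter-propagating waves, clips the
    left-moving one, and relaxes it; returns (profile (2, n), c_estimate,
    grid, relaxation field).
    """
    from .experiments import make_initial_condition

    if grid is None:
        # large domain so the slow inhibitor trail decays before the tails
        # meet around the circle; fine dx to resolve the sharp front
        grid = Grid(-40.0, 40.0, 3200)
    network = build_actin_network(params)
    ic = make_initial_condition("gaussian_bump", params, grid)
    field = simulate_rde(network, grid, ic, T=T_split, dt=1e-3, stepper="imex", save_every=50)
    snap = field.snapshot(-1)
    x = grid.x
    left = x < 0
    xp = x[left][np.argmax(snap[0][left])]
    # wave moves left; the slow inhibitor trail lags behind (to the right)
    clipped = _clip_pulse(snap, grid, params, xp - 3.0, xp + 8.0)
    relax = simulate_rde(network, grid, clipped, T=T_relax, dt=1e-3, stepper="imex", save_every=50)
    c_est = measure_speed(relax, window=(T_relax / 2, T_relax))
    return relax.snapshot(-1), c_est, grid, relax


def standing_wave_init(params: ModelParams, grid: Grid | None = None, T: float = 20.0):
    """Single standing-pulse initial guess: one pulse of the late-time
    double-pulse state of a centred-bump simulation."""
    from .experiments import make_initial_condition

    if grid is None:
        grid = Grid(-20.0, 20.0, 800)
    network = build_actin_network(params)
    ic = make_initial_condition("gaussian_bump", params, grid)
    field = simulate_rde(network, grid, ic, T=T, dt=1e-3, stepper="imex", save_every=100)
    snap = field.snapshot(-1)
    x = grid.x
    left = x < 0
    xp = x[left][np.argmax(snap[0][left])]
    clipped = _clip_pulse(snap, grid, params, xp - 4.0, xp + 4.0)
    # recentre and symmetrise (the standing pulse is even about its peak)
    k = int(np.argmax(clipped[0]))
    clipped = np.roll(clipped, grid.n // 2 - k, axis=1)
    clipped = 0.5 * (clipped + clipped[:, ::-1])
    return clipped, grid


# ---------------------------------------------------------------------------
# measurements on simulated fields
# ---------------------------------------------------------------------------


def measure_speed(
    field: SpaceTimeField,
    window: tuple[float, float],
    x_range: tuple[float, float] | None = None,
    threshold: float | None = None,
) -> float:
    """Wave speed from a least-squares fit of the u-maximum location.

    Tracks the location of the spatial maximum of u (optionally within
    ``x_range``) over the time ``window``, unwraps periodic jumps, and
    returns the fitted slope.  Requires a maximum above ``threshold``
    (default: background + a quarter of the observed dynamic range) in
    every frame of the window.
    """
    t_lo, t_hi = window
    sel = (field.times >= t_lo) & (field.times <= t_hi)
    if np.count_nonzero(sel) < 2:
        raise MeasurementError(f"window {window} contains fewer than 2 saved frames")
    u = field.u[sel]
    times = field.times[sel]
    x = field.grid.x
    if x_range is not None:
        cols = (x >= x_range[0]) & (x <= x_range[1])
        u = u[:, cols]
        x = x[cols]
    if threshold is None:
        threshold = u.min() + 0.25 * (u.max() - u.min())
    peaks = np.argmax(u, axis=1)
    if np.any(u[np.arange(len(times)), peaks] <= threshold):
        raise MeasurementError("no maximum above threshold in some frames of the window")
    pos = x[peaks].astype(float)
    # periodic unwrap on the full domain circumference
    L = field.grid.length
    jumps = np.diff(pos)
    jumps -= L * np.round(jumps / L)
    pos = pos[0] + np.concatenate(([0.0], np.cumsum(jumps)))
    return float(np.polyfit(times, pos, 1)[0])


def measure_width(
    snapshot: np.ndarray,
    dx: float,
    threshold: float,
    periodic: bool = True,
) -> float:
    """Spatial extent of the widest contiguous super-threshold region.

    Widths are cell counts times dx; on a periodic domain a region
    straddling the boundary is treated as one.
    """
    mask = np.asarray(snapshot) > threshold
    n = mask.size
    if not mask.any():
        raise MeasurementError("nothing above threshold")
    if mask.all():
        return n * dx
    # rotate so position 0 is below threshold, then runs cannot wrap
    if periodic:
        first_off = int(np.argmin(mask))
        mask = np.roll(mask, -first_off)
    padded = np.concatenate(([False], mask, [False]))
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return float((ends - starts).max() * dx)
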