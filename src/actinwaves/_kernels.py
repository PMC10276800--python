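"""Compiled (numba) inner loops for the built-in activator-inhibitor model.

The generic solvers in :mod:`actinwaves.pde` and :mod:`actinwaves.cle`
operate on arbitrary reaction networks in vectorised numpy.  For the
built-in actin network the Euler / Euler-Maruyama time loop is also
available as a numba kernel (~50x faster on the deterministic part), used
automatically.  The kernel evaluates the same update formulas; a
zero-noise kernel run still satisfies the "Langevin at sigma=0 equals the
deterministic trajectory" contract because both solvers dispatch to the
same path for the same network and stepper.

Two steppers are compiled: explicit Euler (diffusion-limited dt) and an
IMEX variant that treats diffusion implicitly through a cyclic
tridiagonal (Thomas + Sherman-Morrison) solve, allowing larger steps for
ensemble work where the per-step noise draws dominate the cost.

Noise draws use numpy's legacy global RNG (the one numba implements),
seeded per run; streams therefore differ from the numpy engine's
``default_rng``, but every run is reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba ships with the environment
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


# noise mode codes
MODE_NONE = -1
MODE_FULL = 0
MODE_REACTION_ONLY = 1
MODE_ADDITIVE_U = 2


@njit(cache=True)
def _cyclic_factor(n, r):
    """Precompute Thomas factors for (I - r L) with periodic corners.

    Matrix: diag 1+2r, off-diagonals -r, corners -r.  Sherman-Morrison
    with u = (gamma, 0, .., -r), v = (1, 0, .., -r/gamma), gamma = -(1+2r).
    Returns (cp, denom, q, sm_denom, gamma).
    """
    gamma = -(1.0 + 2.0 * r)
    b = np.full(n, 1.0 + 2.0 * r)
    b[0] -= gamma
    b[n - 1] -= r * r / gamma
    cp = np.empty(n)
    denom = np.empty(n)
    denom[0] = 1.0 / b[0]
    cp[0] = -r * denom[0]
    for i in range(1, n):
        denom[i] = 1.0 / (b[i] + r * cp[i - 1])
        cp[i] = -r * denom[i]
    # q = A'^{-1} u
    u_vec = np.zeros(n)
    u_vec[0] = gamma
    u_vec[n - 1] = -r
    q = np.empty(n)
    q[0] = u_vec[0] * denom[0]
    for i in range(1, n):
        q[i] = (u_vec[i] + r * q[i - 1]) * denom[i]
    for i in range(n - 2, -1, -1):
        q[i] = q[i] - cp[i] * q[i + 1]
    sm_denom = 1.0 + q[0] - (r / gamma) * q[n - 1]
    return cp, denom, q, sm_denom, gamma


@njit(cache=True)
def _cyclic_solve(d, x, cp, denom, q, sm_denom, gamma, r):
    """Solve the periodic (I - r L) system in place into ``x``."""
    n = d.shape[0]
    x[0] = d[0] * denom[0]
    for i in range(1, n):
        x[i] = (d[i] + r * x[i - 1]) * denom[i]
    for i in range(n - 2, -1, -1):
        x[i] = x[i] - cp[i] * x[i + 1]
    vy = x[0] - (r / gamma) * x[n - 1]
    f = vy / sm_denom
    for i in range(n):
        x[i] = x[i] - f * q[i]


@njit(cache=True)
def _actin_loop(
    u0,
    v0,
    a1,
    a2,
    a3,
    a4,
    a5,
    c1,
    c2,
    eps,
    Du,
    Dv,
    dx,
    dt,
    n_steps,
    save_every,
    sigma,
    mode,
    printed_variance,
    clamp,
    seed,
    imex,
):
    np.random.seed(seed)
    n = u0.shape[0]
    u = u0.copy()
    v = v0.copy()
    n_saves = n_steps // save_every + 1
    u_out = np.empty((n_saves, n))
    v_out = np.empty((n_saves, n))
    u_out[0] = u
    v_out[0] = v

    inv_dx2 = 1.0 / (dx * dx)
    sq = sigma * np.sqrt(dt / dx)  # white-noise scaling per cell per step
    flux_scale = sigma / np.sqrt(dx * dt) * dt / dx
    un = np.empty(n)
    vn = np.empty(n)
    Fu = np.empty(n)
    Fv = np.empty(n)
    n_clamped = 0
    bad_step = -1
    save_idx = 1

    ru = Du * dt * inv_dx2
    rv = Dv * dt * inv_dx2
    if imex:
        cp_u, den_u, q_u, sd_u, g_u = _cyclic_factor(n, ru)
        cp_v, den_v, q_v, sd_v, g_v = _cyclic_factor(n, rv)
    else:
        cp_u = den_u = q_u = np.empty(0)
        cp_v = den_v = q_v = np.empty(0)
        sd_u = g_u = sd_v = g_v = 0.0

    for step in range(1, n_steps + 1):
        # explicit part: reaction kinetics (+ explicit diffusion for euler)
        for k in range(n):
            uk = u[k]
            vk = v[k]
            hill = a3 * uk * uk / (a4 + uk * uk)
            fu = -(a1 + a2 * vk) * uk + hill + a5
            fv = eps * (-c1 * vk + c2 * uk)
            if imex:
                un[k] = uk + dt * fu
                vn[k] = vk + dt * fv
            else:
                km = n - 1 if k == 0 else k - 1
                kp = 0 if k == n - 1 else k + 1
                un[k] = uk + dt * (Du * (u[km] - 2.0 * uk + u[kp]) * inv_dx2 + fu)
                vn[k] = vk + dt * (Dv * (v[km] - 2.0 * vk + v[kp]) * inv_dx2 + fv)

        if sigma > 0.0:
            if mode == MODE_ADDITIVE_U:
                for k in range(n):
                    un[k] += sq * np.random.standard_normal()
            else:
                for k in range(n):
                    uk = u[k]
                    vk = v[k]
                    hill = a3 * uk * uk / (a4 + uk * uk)
                    var_u = (a1 + a2 * vk) * uk + hill + a5
                    if printed_variance:
                        var_v = eps * (-c1 * vk + c2 * uk)
                    else:
                        var_v = eps * (c1 * vk + c2 * uk)
                    if var_u < 0.0:
                        var_u = 0.0
                    if var_v < 0.0:
                        var_v = 0.0
                    un[k] += sq * np.sqrt(var_u) * np.random.standard_normal()
                    vn[k] += sq * np.sqrt(var_v) * np.random.standard_normal()
                if mode == MODE_FULL:
                    # conservative interface fluxes, one normal per interface
                    for k in range(n):
                        kp = 0 if k == n - 1 else k + 1
                        mu = 0.5 * (u[k] + u[kp])
                        mv = 0.5 * (v[k] + v[kp])
                        if mu < 0.0:
                            mu = 0.0
                        if mv < 0.0:
                            mv = 0.0
                        Fu[k] = np.sqrt(2.0 * Du * mu) * np.random.standard_normal()
                        Fv[k] = np.sqrt(2.0 * Dv * mv) * np.random.standard_normal()
                    for k in range(n):
                        km = n - 1 if k == 0 else k - 1
                        un[k] += flux_scale * (Fu[k] - Fu[km])
                        vn[k] += flux_scale * (Fv[k] - Fv[km])

        if imex:
            # implicit diffusion solve; reuse Fu/Fv as work arrays
            _cyclic_solve(un, Fu, cp_u, den_u, q_u, sd_u, g_u, ru)
            _cyclic_solve(vn, Fv, cp_v, den_v, q_v, sd_v, g_v, rv)
            for k in range(n):
                un[k] = Fu[k]
                vn[k] = Fv[k]

        if clamp:
            for k in range(n):
                if un[k] < 0.0:
                    un[k] = 0.0
                    n_clamped += 1
                if vn[k] < 0.0:
                    vn[k] = 0.0
                    n_clamped += 1

        u, un = un, u
        v, vn = vn, v

        if step % save_every == 0:
            ok = True
            for k in range(n):
                if not (np.isfinite(u[k]) and np.isfinite(v[k])):
                    ok = False
                    break
            if not ok:
                bad_step = step
                break
            u_out[save_idx] = u
            v_out[save_idx] = v
            save_idx += 1

    return u_out, v_out, save_idx, n_clamped, bad_step


def run_actin_euler(
    params,
    grid,
    ic,
    T: float,
    dt: float,
    save_every: int,
    sigma: float = 0.0,
    mode: int = MODE_NONE,
    printed_variance: bool = False,
    clamp: bool = False,
    seed: int = 0,
    stepper: str = "euler",
):
    """Run the compiled time loop; mirrors ``pde._integrate``."""
    ic = np.asarray(ic, dtype=float)
    n_steps = int(round(T / dt))
    save_every = max(1, int(save_every))
    u_out, v_out, save_idx, n_clamped, bad_step = _actin_loop(
        np.ascontiguousarray(ic[0]),
        np.ascontiguousarray(ic[1]),
        params.a1,
        params.a2,
        params.a3,
        params.a4,
        params.a5,
        params.c1,
        params.c2,
        params.eps,
        params.Du,
        params.Dv,
        grid.dx,
        dt,
        n_steps,
        save_every,
        float(sigma),
        mode,
        printed_variance,
        clamp,
        int(seed),
        stepper == "imex",
    )
    if bad_step >= 0:
        from .exceptions import IntegrationError

        raise IntegrationError(f"non-finite state at t={bad_step * dt:.6g}", t_bad=bad_step * dt)
    times = np.concatenate(([0.0], np.arange(1, n_steps // save_every + 1) * save_every * dt))
    meta = {
        "dt": dt,
        "stepper": stepper,
        "n_steps": n_steps,
        "n_clamped": n_clamped,
        "backend": "numba",
    }
    if clamp and n_steps:
        meta["clamp_fraction"] = n_clamped / (n_steps * ic.shape[1] * 2)
    return u_out[:save_idx], v_out[:save_idx], times[:save_idx], meta
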