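"""Microscopic exact stochastic simulators (SSA and spatial SSA).

The microscopic description tracks integer molecule counts.  The system
size Omega converts between counts and concentrations: a well-mixed
compartment at concentration u holds Omega*u molecules (Omega*dx*u per
grid cell of width dx in the spatial case).  Count-level reaction rates
follow the standard concentration <-> count conversion: the count rate of
a channel is the compartment size times the concentration propensity
evaluated at counts/size (so linear channels give a*n, the bimolecular
channel a2*n_u*n_v/size, the zeroth-order channel a5*size, and the Hill
channel size*Hill(n/size)).

Diffusion in the spatial simulator (the reaction-diffusion master
equation) is a jump process: each molecule hops to either neighbouring
cell at rate D/dx^2, periodic in x.  Both simulators are exact (Gillespie
direct method): counts never go negative, and in the large-Omega limit
the first moments converge to the deterministic kinetics while the
fluctuations match the Langevin description with sigma = 1/sqrt(Omega).
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .model import ModelParams, ReactionNetwork
from .pde import Grid, SpaceTimeField

__all__ = ["simulate_ssa_wellmixed", "simulate_rdme", "count_rates_wellmixed"]


def count_rates_wellmixed(network: ReactionNetwork, counts, omega: float) -> np.ndarray:
    """Count-level channel rates: omega * R(counts / omega)."""
    counts = np.asarray(counts, dtype=float)
    return omega * network.propensities(counts / omega)


def simulate_ssa_wellmixed(
    network: ReactionNetwork,
    omega: float,
    x0,
    T: float,
    seed: int,
    max_events: int = 1_000_000,
):
    """Exact well-mixed Gillespie trajectory.

    Parameters
    ----------
    x0
        Initial integer molecule counts per species.

    Returns
    -------
    times : (n_events+1,) array
        Event times, starting at 0.
    counts : (n_events+1, M) integer array
        Molecule counts after each event.
    """
    x0 = np.asarray(x0)
    if np.any(x0 < 0) or not np.issubdtype(x0.dtype, np.integer):
        raise ValidationError("x0 must be non-negative integers")
    if network.kind == "actin" and _HAVE_NUMBA:
        p = network.params
        times, nu, nv, n_used = _ssa_actin_loop(
            np.int64(x0[0]),
            np.int64(x0[1]),
            p.a1,
            p.a2,
            p.a3,
            p.a4,
            p.a5,
            p.c1,
            p.c2,
            p.eps,
            float(omega),
            T,
            int(seed),
            max_events,
        )
        return times[:n_used], np.stack([nu[:n_used], nv[:n_used]], axis=1)
    rng = np.random.default_rng(seed)
    S = network.stoich
    counts = x0.astype(np.int64).copy()
    t = 0.0
    times = [0.0]
    states = [counts.copy()]
    for _ in range(max_events):
        rates = count_rates_wellmixed(network, counts, omega)
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > T:
            break
        j = np.searchsorted(np.cumsum(rates), rng.random() * total)
        counts += S[:, j]
        times.append(t)
        states.append(counts.copy())
    return np.array(times), np.array(states)


# ---------------------------------------------------------------------------
# spatial SSA (reaction-diffusion master equation)
# ---------------------------------------------------------------------------

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @njit(cache=True)
    def _ssa_actin_loop(nu0, nv0, a1, a2, a3, a4, a5, c1, c2, eps, omega, T, seed, max_events):
        np.random.seed(seed)
        times = np.empty(max_events + 1)
        nus = np.empty(max_events + 1, dtype=np.int64)
        nvs = np.empty(max_events + 1, dtype=np.int64)
        nu, nv = nu0, nv0
        t = 0.0
        times[0] = 0.0
        nus[0] = nu
        nvs[0] = nv
        idx = 1
        while idx <= max_events:
            u = nu / omega
            v = nv / omega
            r0 = omega * a1 * u
            r1 = omega * a2 * u * v
            r2 = omega * a3 * u * u / (a4 + u * u)
            r3 = omega * a5
            r4 = omega * eps * c1 * v
            r5 = omega * eps * c2 * u
            total = r0 + r1 + r2 + r3 + r4 + r5
            if total <= 0.0:
                break
            t += np.random.exponential(1.0 / total)
            if t > T:
                break
            r = np.random.random() * total
            if r < r0 + r1:
                nu -= 1
            elif r < r0 + r1 + r2 + r3:
                nu += 1
            elif r < r0 + r1 + r2 + r3 + r4:
                nv -= 1
            else:
                nv += 1
            times[idx] = t
            nus[idx] = nu
            nvs[idx] = nv
            idx += 1
        return times, nus, nvs, idx

    @njit(cache=True)
    def _rdme_actin_loop(
        nu, nv, a1, a2, a3, a4, a5, c1, c2, eps, Du, Dv, dx, vol, T, seed, snap_times, react_on
    ):
        """Direct-method spatial SSA for the actin network.

        Per cell: 6 reaction channels (count rates = vol * R(n/vol)) and
        4 diffusion channels (each molecule hops left/right at D/dx^2).
        """
        np.random.seed(seed)
        n = nu.shape[0]
        hop_u = Du / (dx * dx)
        hop_v = Dv / (dx * dx)
        cell_rate = np.empty(n)
        chan = np.empty(10)

        def _cell_total(k):
            u = nu[k] / vol
            v = nv[k] / vol
            r = (
                react_on
                * vol
                * (a1 * u + a2 * u * v + a3 * u * u / (a4 + u * u) + a5 + eps * (c1 * v + c2 * u))
                + 2.0 * hop_u * nu[k]
                + 2.0 * hop_v * nv[k]
            )
            return r

        for k in range(n):
            cell_rate[k] = _cell_total(k)

        n_snaps = snap_times.shape[0]
        u_out = np.empty((n_snaps, n))
        v_out = np.empty((n_snaps, n))
        snap_idx = 0
        t = 0.0
        n_events = 0
        while True:
            total = 0.0
            for k in range(n):
                total += cell_rate[k]
            if total <= 0.0:
                t = T + 1.0
            else:
                t += np.random.exponential(1.0 / total)
            while snap_idx < n_snaps and t > snap_times[snap_idx]:
                for k in range(n):
                    u_out[snap_idx, k] = nu[k] / vol
                    v_out[snap_idx, k] = nv[k] / vol
                snap_idx += 1
            if t > T or snap_idx >= n_snaps:
                break
            # pick cell
            r = np.random.random() * total
            acc = 0.0
            k = n - 1
            for i in range(n):
                acc += cell_rate[i]
                if r < acc:
                    k = i
                    break
            # channel rates within the cell
            u = nu[k] / vol
            v = nv[k] / vol
            chan[0] = react_on * vol * a1 * u
            chan[1] = react_on * vol * a2 * u * v
            chan[2] = react_on * vol * a3 * u * u / (a4 + u * u)
            chan[3] = react_on * vol * a5
            chan[4] = react_on * vol * eps * c1 * v
            chan[5] = react_on * vol * eps * c2 * u
            chan[6] = hop_u * nu[k]  # u hops left
            chan[7] = hop_u * nu[k]  # u hops right
            chan[8] = hop_v * nv[k]
            chan[9] = hop_v * nv[k]
            csum = 0.0
            for j in range(10):
                csum += chan[j]
            r2 = np.random.random() * csum
            acc = 0.0
            j = 9
            for i in range(10):
                acc += chan[i]
                if r2 < acc:
                    j = i
                    break
            km = n - 1 if k == 0 else k - 1
            kp = 0 if k == n - 1 else k + 1
            if j == 0 or j == 1:
                nu[k] -= 1
            elif j == 2 or j == 3:
                nu[k] += 1
            elif j == 4:
                nv[k] -= 1
            elif j == 5:
                nv[k] += 1
            elif j == 6:
                nu[k] -= 1
                nu[km] += 1
                cell_rate[km] = _cell_total(km)
            elif j == 7:
                nu[k] -= 1
                nu[kp] += 1
                cell_rate[kp] = _cell_total(kp)
            elif j == 8:
                nv[k] -= 1
                nv[km] += 1
                cell_rate[km] = _cell_total(km)
            else:
                nv[k] -= 1
                nv[kp] += 1
                cell_rate[kp] = _cell_total(kp)
            cell_rate[k] = _cell_total(k)
            n_events += 1
        return u_out, v_out, n_events


def simulate_rdme(
    network: ReactionNetwork,
    grid: Grid,
    omega: float,
    ic_counts,
    T: float,
    seed: int,
    n_snapshots: int = 101,
    disable_reactions: bool = False,
) -> SpaceTimeField:
    """Exact spatial SSA trajectory, sampled as a concentration kymograph.

    ``ic_counts`` is a (2, n) array of non-negative integer molecule
    counts per cell; cell size is ``omega * grid.dx`` molecules per unit
    concentration.  Snapshots at ``n_snapshots`` equispaced times (from 0
    to T) are returned as concentrations for comparison with the
    continuum solvers.
    """
    ic_counts = np.asarray(ic_counts)
    if ic_counts.shape != (2, grid.n):
        raise ValidationError(f"ic_counts must have shape (2, {grid.n})")
    if np.any(ic_counts < 0) or not np.issubdtype(ic_counts.dtype, np.integer):
        raise ValidationError("ic_counts must be non-negative integers")
    if network.kind != "actin" or not _HAVE_NUMBA:
        raise ValidationError("the spatial SSA is implemented for the built-in actin network")
    p: ModelParams = network.params
    vol = omega * grid.dx
    snap_times = np.linspace(0.0, T, n_snapshots)
    nu = ic_counts[0].astype(np.int64).copy()
    nv = ic_counts[1].astype(np.int64).copy()
    u_out, v_out, n_events = _rdme_actin_loop(
        nu,
        nv,
        p.a1,
        p.a2,
        p.a3,
        p.a4,
        p.a5,
        p.c1,
        p.c2,
        p.eps,
        p.Du,
        p.Dv,
        grid.dx,
        vol,
        T,
        int(seed),
        snap_times,
        0.0 if disable_reactions else 1.0,
    )
    return SpaceTimeField(
        u=u_out,
        v=v_out,
        times=snap_times,
        grid=grid,
        params=p,
        seed=seed,
        noise_mode="rdme",
        meta={"omega": omega, "volume_per_cell": vol, "n_events": n_events},
    )
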