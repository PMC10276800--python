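"""Background states, linear stability and bifurcation scans in c1.

The spatially homogeneous equilibria (u*, v*) of the kinetics satisfy the
u-nullcline and v-nullcline simultaneously; eliminating v* = c2 u*/c1
reduces the problem to the positive real roots of the quartic

    -(a2 c2/c1) u^4 - a1 u^3 + (a3 + a5 - a2 a4 c2/c1) u^2 - a1 a4 u + a4 a5 = 0.

By Descartes' rule of signs there is exactly one positive root when
c1 (a3 + a5) < a2 a4 c2, and one or three otherwise.  Stability follows
from the eigenvalues of the 2x2 Jacobian of the kinetics; increasing c1
first makes the eigenvalues complex (discriminant sign change) and then
drives them across the imaginary axis (Hopf bifurcation), which is where
time-periodic dynamics set in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import BracketingError, ValidationError
from .model import ModelParams

__all__ = [
    "BackgroundState",
    "quartic_coefficients",
    "background_states",
    "descartes_root_bound",
    "jacobian",
    "kinetics_jacobian_entries",
    "eigen_scan",
]

# root classification tolerances (companion-matrix solve)
_REAL_TOL = 1e-9
_POS_TOL = 1e-12


@dataclass(frozen=True)
class BackgroundState:
    """A positive homogeneous equilibrium with its linearisation."""

    u_star: float
    v_star: float
    eigenvalues: tuple[complex, complex]
    stability: str  # "stable" | "unstable"
    is_complex: bool


def quartic_coefficients(params: ModelParams) -> np.ndarray:
    """Coefficients (u^4 ... u^0) of the background-state quartic."""
    a1, a2, a3, a4, a5 = params.a1, params.a2, params.a3, params.a4, params.a5
    c1, c2 = params.c1, params.c2
    return np.array(
        [
            -a2 * c2 / c1,
            -a1,
            a3 + a5 - a2 * a4 * c2 / c1,
            -a1 * a4,
            a5 * a4,
        ]
    )


def background_states(params: ModelParams) -> list[BackgroundState]:
    """All admissible positive background states, sorted by u*.

    Roots of the quartic are taken from the companion-matrix eigenvalues;
    a root is accepted as real if |Im| < 1e-9 * max(1, |Re|) and positive
    if Re > 1e-12.
    """
    roots = np.roots(quartic_coefficients(params))
    out = []
    for r in roots:
        if abs(r.imag) >= _REAL_TOL * max(1.0, abs(r.real)) or r.real <= _POS_TOL:
            continue
        u = float(r.real)
        v = params.c2 * u / params.c1
        J = jacobian(params, (u, v))
        lam = np.linalg.eigvals(J)
        out.append(
            BackgroundState(
                u_star=u,
                v_star=v,
                eigenvalues=(complex(lam[0]), complex(lam[1])),
                stability="stable" if np.all(lam.real < 0) else "unstable",
                is_complex=bool(abs(lam[0].imag) > 0),
            )
        )
    return sorted(out, key=lambda s: s.u_star)


def descartes_root_bound(params: ModelParams) -> str:
    """Sign-rule bound on the number of positive roots of the quartic.

    Returns ``"one"`` iff the strict inequality c1(a3+a5) < a2 a4 c2 holds
    (which guarantees a unique positive root); the boundary case falls in
    the conservative ``"one_or_three"`` branch.
    """
    if params.c1 * (params.a3 + params.a5) < params.a2 * params.a4 * params.c2:
        return "one"
    return "one_or_three"


def kinetics_jacobian_entries(params: ModelParams, u, v):
    """Pointwise Jacobian entries (fu, fv, gu, gv) of the kinetics.

    Vectorised over u, v.  The (1,1) entry is the u-derivative of the full
    u-kinetics, -a1 - a2 v + 2 a3 a4 u/(a4+u^2)^2 (the Hill term's
    derivative enters with a plus sign).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    a4 = params.a4
    fu = -params.a1 - params.a2 * v + 2.0 * params.a3 * a4 * u / (a4 + u * u) ** 2
    fv = -params.a2 * u
    gu = params.eps * params.c2 * np.ones_like(u)
    gv = -params.eps * params.c1 * np.ones_like(u)
    return fu, fv, gu, gv


def jacobian(params: ModelParams, state) -> np.ndarray:
    """2x2 Jacobian of the kinetics at a (background) state (u, v)."""
    u, v = state
    fu, fv, gu, gv = kinetics_jacobian_entries(params, u, v)
    return np.array([[float(fu), float(fv)], [float(gu), float(gv)]])


def _tracked_state(params: ModelParams, u_prev: float | None) -> BackgroundState:
    """Background state continuous in u* along a scan (nearest-neighbour)."""
    states = background_states(params)
    if not states:
        raise ValidationError(f"no positive background state at c1={params.c1}")
    if u_prev is None or len(states) == 1:
        return states[0]
    return min(states, key=lambda s: abs(s.u_star - u_prev))


def eigen_scan(
    params: ModelParams,
    c1_range: tuple[float, float] = (0.18, 0.35),
    tol: float = 1e-6,
    n_coarse: int = 200,
) -> tuple[float, float]:
    """Locate the complex-eigenvalue onset and the Hopf crossing in c1.

    Scans c1 over ``c1_range`` with nearest-neighbour continuation of the
    background state, then bisects (to ``tol`` in c1) the sign changes of
    (i) the Jacobian discriminant (real -> complex eigenvalues) and
    (ii) the maximal real part of the eigenvalues (Hopf).

    Raises
    ------
    BracketingError
        If a transition is not bracketed by the scanned interval.
    """
    c_lo, c_hi = c1_range
    if not (0 < c_lo < c_hi):
        raise ValidationError(f"invalid c1 range {c1_range}")

    grid = np.linspace(c_lo, c_hi, n_coarse)
    disc = np.empty(n_coarse)
    max_re = np.empty(n_coarse)
    u_prev = None
    for i, c1 in enumerate(grid):
        st = _tracked_state(params.with_(c1=float(c1)), u_prev)
        u_prev = st.u_star
        J = jacobian(params.with_(c1=float(c1)), (st.u_star, st.v_star))
        tr = J[0, 0] + J[1, 1]
        det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        disc[i] = tr * tr - 4.0 * det
        max_re[i] = max(lam.real for lam in np.linalg.eigvals(J))

    def _bisect(values: np.ndarray, name: str, fn) -> float:
        sign_change = np.nonzero(np.sign(values[:-1]) != np.sign(values[1:]))[0]
        if sign_change.size == 0:
            raise BracketingError(
                f"{name} transition not bracketed by c1 in [{c_lo}, {c_hi}]"
            )
        k = sign_change[0]
        a, b = float(grid[k]), float(grid[k + 1])
        fa = fn(a)
        while b - a > tol:
            m = 0.5 * (a + b)
            fm = fn(m)
            if np.sign(fm) == np.sign(fa):
                a, fa = m, fm
            else:
                b = m
        return 0.5 * (a + b)

    def disc_at(c1: float) -> float:
        st = _tracked_state(params.with_(c1=c1), None)
        J = jacobian(params.with_(c1=c1), (st.u_star, st.v_star))
        tr = J[0, 0] + J[1, 1]
        det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        return tr * tr - 4.0 * det

    def max_re_at(c1: float) -> float:
        st = _tracked_state(params.with_(c1=c1), None)
        J = jacobian(params.with_(c1=c1), (st.u_star, st.v_star))
        return max(lam.real for lam in np.linalg.eigvals(J))

    c1_complex_onset = _bisect(disc, "complex-eigenvalue onset", disc_at)
    c1_hopf = _bisect(max_re, "Hopf crossing", max_re_at)
    return c1_complex_onset, c1_hopf
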