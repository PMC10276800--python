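"""Reaction-network abstraction and the activator-inhibitor actin-wave model.

The model is an abstraction of Ras-driven actin signalling on a 1-D slice of
the cell membrane: an activator ``u`` (Ras activity, driving protrusion) and
an inhibitor ``v``, coupled through six reaction channels,

====  ==================  ==================
 #    reaction            propensity
====  ==================  ==================
 1    u -> 0              a1*u
 2    u -> 0              a2*u*v
 3    0 -> u              a3*u^2/(a4+u^2)
 4    0 -> u              a5
 5    v -> 0              eps*c1*v
 6    0 -> v              eps*c2*u
====  ==================  ==================

plus Fickian diffusion of both species (Du < Dv).  The deterministic
reaction-rate limit is a FitzHugh-Nagumo-type excitable reaction-diffusion
system; the autocatalytic Hill term (reaction 3) provides the activation
threshold and ``eps`` sets the activator/inhibitor timescale separation.

Propensities are evaluated exactly as written, also for (unphysical)
negative states; positivity enforcement is the solvers' responsibility.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "ModelParams",
    "ReactionNetwork",
    "build_actin_network",
    "drift",
    "get_preset",
    "preset_names",
    "save_params",
    "load_params",
    "ACTIN_STOICH",
]

#: Stoichiometric matrix of the six actin-model reactions (rows: u, v).
ACTIN_STOICH = np.array(
    [
        [-1, -1, 1, 1, 0, 0],
        [0, 0, 0, 0, -1, 1],
    ],
    dtype=int,
)

_RATE_FIELDS = ("a1", "a2", "a3", "a4", "a5", "c1", "c2", "eps", "Du", "Dv")


@dataclass(frozen=True)
class ModelParams:
    """Rate constants, diffusion coefficients and noise strength.

    All quantities are in nondimensional model units.  ``sigma`` is the
    noise strength of the chemical Langevin description and is identified
    with ``1/sqrt(omega)`` where ``omega`` is the system size (molecules
    per unit concentration per unit length); ``omega`` is only needed by
    the microscopic simulators.
    """

    a1: float = 0.167
    a2: float = 16.67
    a3: float = 167.0
    a4: float = 1.44
    a5: float = 1.47
    c1: float = 0.1
    c2: float = 3.9
    eps: float = 0.52
    Du: float = 0.1
    Dv: float = 1.0
    sigma: float = 0.0
    omega: float | None = None

    def __post_init__(self):
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValidationError(f"parameter {name!r} must be strictly positive, got {value}")
        if not (np.isfinite(self.sigma) and self.sigma >= 0):
            raise ValidationError(f"sigma must be >= 0, got {self.sigma}")
        if self.omega is not None:
            if not (np.isfinite(self.omega) and self.omega > 0):
                raise ValidationError(f"omega must be > 0, got {self.omega}")
            if self.sigma > 0 and not math.isclose(self.sigma, 1.0 / math.sqrt(self.omega), rel_tol=1e-8):
                raise ValidationError(
                    f"sigma={self.sigma} and omega={self.omega} are inconsistent with sigma = 1/sqrt(omega)"
                )

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def with_sigma(self, sigma: float) -> "ModelParams":
        """Copy with noise strength ``sigma`` and matching ``omega = 1/sigma**2``."""
        omega = None if sigma == 0 else 1.0 / sigma**2
        return replace(self, sigma=sigma, omega=omega)

    def with_omega(self, omega: float) -> "ModelParams":
        """Copy with system size ``omega`` and matching ``sigma = 1/sqrt(omega)``."""
        return replace(self, omega=omega, sigma=1.0 / math.sqrt(omega))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ReactionNetwork:
    """Species, stoichiometry, propensities and diffusion of a reaction network.

    ``propensities(state)`` evaluates the N reaction rates at ``state``,
    an array of shape ``(M, ...)`` (M species, any trailing shape), and
    returns shape ``(N, ...)``.  The optional ``printed_variance`` hook
    evaluates a model-specific literal variance expression used by the
    ``as_printed`` noise convention of the Langevin solver.
    """

    species_names: tuple[str, ...]
    stoich: np.ndarray
    propensities: callable
    diffusion: np.ndarray
    params: ModelParams
    printed_variance: callable | None = field(default=None, compare=False)
    #: "actin" marks the built-in network, enabling the compiled fast path
    kind: str = "generic"

    @property
    def n_species(self) -> int:
        return self.stoich.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[1]

    def drift(self, state) -> np.ndarray:
        """Reaction part of the rate equation, ``S @ R(state)``."""
        return drift(self, state)


def build_actin_network(params: ModelParams) -> ReactionNetwork:
    """Build the six-reaction activator-inhibitor network for ``params``.

    Propensities are returned in table order:
    ``(a1*u, a2*u*v, a3*u^2/(a4+u^2), a5, eps*c1*v, eps*c2*u)``.
    """
    if not isinstance(params, ModelParams):
        raise ValidationError(f"expected ModelParams, got {type(params).__name__}")
    a1, a2, a3, a4, a5 = params.a1, params.a2, params.a3, params.a4, params.a5
    c1, c2, eps = params.c1, params.c2, params.eps

    def propensities(state):
        state = np.asarray(state, dtype=float)
        u, v = state[0], state[1]
        u2 = u * u
        R = np.empty((6,) + np.shape(u), dtype=float)
        R[0] = a1 * u
        R[1] = a2 * u * v
        R[2] = a3 * u2 / (a4 + u2)
        R[3] = a5
        R[4] = eps * c1 * v
        R[5] = eps * c2 * u
        return R

    def printed_variance(state):
        # Literal per-species noise variances as sometimes printed for this
        # Langevin equation: the v-variance carries a -c1*v term (the systematic
        # S diag(R) S^T construction gives +c1*v; see cle.py).
        state = np.asarray(state, dtype=float)
        u, v = state[0], state[1]
        var = np.empty((2,) + np.shape(u), dtype=float)
        var[0] = (a1 + a2 * v) * u + a3 * u * u / (a4 + u * u) + a5
        var[1] = eps * (-c1 * v + c2 * u)
        return var

    return ReactionNetwork(
        species_names=("u", "v"),
        stoich=ACTIN_STOICH.copy(),
        propensities=propensities,
        diffusion=np.array([params.Du, params.Dv]),
        params=params,
        printed_variance=printed_variance,
        kind="actin",
    )


def drift(network: ReactionNetwork, state) -> np.ndarray:
    """Deterministic reaction term ``S @ R(state)`` of the rate equation."""
    R = network.propensities(state)
    S = network.stoich
    return np.tensordot(S.astype(float), R, axes=(1, 0))


# ---------------------------------------------------------------------------
# Named parameter presets (figure-level parameter sets of the study regimes)
# ---------------------------------------------------------------------------

_PRESETS: dict[str, dict] = {
    # standing-wave regime (stable background, strong inhibitor coupling)
    "fig4_standing": dict(c1=0.1),
    # travelling-wave regime (faster inhibitor decay)
    "fig11_travelling": dict(c1=0.2),
    # oscillatory regime (background unstable past the Hopf point)
    "fig14_oscillatory": dict(c1=0.4),
    # wild-type cell parameterisation
    "fig17a": dict(c1=0.1, eps=0.4, a3=167.0, c2=2.1),
    # PTEN-null cell parameterisation
    "fig17b": dict(c1=0.1, eps=0.4, a3=300.6, c2=3.0),
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def get_preset(name: str, sigma: float = 0.0, **overrides) -> ModelParams:
    """Return a named parameter preset, optionally with noise and overrides."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValidationError(f"unknown preset {name!r}; known: {preset_names()}") from None
    params = ModelParams(**{**base, **overrides})
    if sigma:
        params = params.with_sigma(sigma)
    return params


def save_params(params: ModelParams, path) -> None:
    """Serialise parameters to a JSON file with keys matching field names."""
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def load_params(path) -> ModelParams:
    """Load parameters from a JSON or TOML file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    return ModelParams(**data)
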