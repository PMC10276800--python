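"""Activation-event detection in kymographs and ensemble statistics.

An activation event is a contiguous space-time patch where the activator
exceeds a detection threshold.  Patches are 8-connected components of the
thresholded kymograph lattice, periodic in space (an event straddling the
domain boundary is one event); components smaller than ``min_cells``
cells are discarded as noise specks.  Each event is summarised by its
onset/offset time, duration, spatial width (wrap-aware), peak activator
value and component size.

The default detection threshold adapts to the parameter set:
u* + 0.25 (u_pulse_max - u*), where u_pulse_max is the peak of the
deterministic pulse grown from a centred bump.  Width/duration values
therefore carry the (documented) arbitrariness of this choice.

Ensemble statistics follow the noise-study protocol:
many independent Langevin runs from the homogeneous (u*, 4 v*) state plus
a small seeded perturbation, events pooled per noise level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .cle import NoiseConfig, simulate_cle
from .equilibria import background_states
from .exceptions import MeasurementError, ValidationError
from .model import ModelParams, build_actin_network
from .pde import Grid, SpaceTimeField, simulate_rde

__all__ = [
    "EventRecord",
    "EnsembleStats",
    "detect_events",
    "default_threshold",
    "reference_pulse_max",
    "ensemble_event_stats",
    "estimate_period",
    "event_histograms",
]

logger = logging.getLogger(__name__)

#: default minimum component size (lattice cells)
MIN_CELLS = 8

#: fraction of the pulse height above background used by the default threshold
THRESHOLD_FRACTION = 0.25

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class EventRecord:
    """One detected activation event."""

    t_on: float
    t_off: float
    duration: float
    x_extent: float
    u_max: float
    bbox: tuple[float, float, float, float]  # (t_on, t_off, x_lo, x_hi), wrap-naive
    n_cells: int


@dataclass
class EnsembleStats:
    """Per-noise-level event statistics over an ensemble of runs."""

    sigmas: np.ndarray
    n_runs: int
    base_seed: int
    mean_count: np.ndarray
    std_count: np.ndarray
    mean_width: np.ndarray
    std_width: np.ndarray
    mean_duration: np.ndarray
    std_duration: np.ndarray
    mean_max: np.ndarray
    std_max: np.ndarray
    events: dict = field(default_factory=dict)  # sigma -> list[EventRecord]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sigma": self.sigmas,
                "mean_count": self.mean_count,
                "std_count": self.std_count,
                "mean_width": self.mean_width,
                "std_width": self.std_width,
                "mean_duration": self.mean_duration,
                "std_duration": self.std_duration,
                "mean_max": self.mean_max,
                "std_max": self.std_max,
            }
        )


def _merge_wrapped_labels(labels: np.ndarray) -> np.ndarray:
    """Union labels that touch across the periodic x-boundary (8-conn)."""
    n_lab = labels.max()
    if n_lab == 0:
        return labels
    parent = np.arange(n_lab + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    left = labels[:, 0]
    right = labels[:, -1]
    nt = labels.shape[0]
    for i in range(nt):
        if right[i]:
            for di in (-1, 0, 1):
                j = i + di
                if 0 <= j < nt and left[j]:
                    union(right[i], left[j])
    out = np.array([find(a) for a in range(n_lab + 1)])
    return out[labels]


def detect_events(
    field: SpaceTimeField,
    threshold: float | None = None,
    min_cells: int = MIN_CELLS,
) -> list[EventRecord]:
    """Detect activation events in a kymograph.

    Components of ``u > threshold`` are 8-connected on the (t, x) lattice
    with periodic wrap in x only; components with fewer than ``min_cells``
    cells are discarded.  Deterministic: events are sorted by onset time,
    then bounding-box x.
    """
    if threshold is None:
        threshold = default_threshold(field.params)
    mask = field.u > threshold
    if not mask.any():
        return []
    labels, _ = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    labels = _merge_wrapped_labels(labels)
    dx = field.grid.dx
    nt = len(field.times)
    dt_sample = field.dt_sample if nt > 1 else 1.0
    nx = field.grid.n
    L = field.grid.length

    events = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        n_cells = rows.size
        if n_cells < min_cells:
            continue
        t_on = float(field.times[rows.min()])
        t_off = float(field.times[rows.max()]) + dt_sample
        col_present = np.zeros(nx, dtype=bool)
        col_present[cols] = True
        occupied = int(col_present.sum())
        if col_present[0] and col_present[-1] and not col_present.all():
            # wrapped: domain length minus the longest contiguous empty
            # run of the component's x-projection (cyclic)
            empty = ~col_present
            start = int(np.argmin(empty))  # a present column; runs cannot wrap past it
            empty = np.roll(empty, -start)
            padded = np.concatenate(([False], empty, [False])).astype(int)
            edges = np.diff(padded)
            runs = np.nonzero(edges == -1)[0] - np.nonzero(edges == 1)[0]
            x_extent = L - float(runs.max() * dx)
        else:
            x_extent = float((cols.max() - cols.min() + 1) * dx)
        x_extent = min(x_extent, L)
        events.append(
            EventRecord(
                t_on=t_on,
                t_off=t_off,
                duration=t_off - t_on,
                x_extent=x_extent,
                u_max=float(field.u[rows, cols].max()),
                bbox=(
                    t_on,
                    t_off,
                    float(field.grid.x[cols.min()]),
                    float(field.grid.x[cols.max()]),
                ),
                n_cells=int(n_cells),
            )
        )
    events.sort(key=lambda e: (e.t_on, e.bbox[2]))
    return events


_pulse_max_cache: dict[tuple, float] = {}


def reference_pulse_max(params: ModelParams, grid: Grid | None = None, T: float = 12.0) -> float:
    """Peak activator value of the deterministic pulse for this parameter set.

    Grown from the centred-bump initial condition on a wide domain (so
    counter-propagating pulses do not annihilate through the periodic
    boundary within the run); the maximum is taken over t >= 3, after the
    initial overshoot has settled.
    """
    from .experiments import make_initial_condition

    key = (params.a1, params.a2, params.a3, params.a4, params.a5, params.c1, params.c2,
           params.eps, params.Du, params.Dv)
    if key in _pulse_max_cache:
        return _pulse_max_cache[key]
    if grid is None:
        grid = Grid(-30.0, 30.0, 1200)
    network = build_actin_network(params)
    ic = make_initial_condition("gaussian_bump", params, grid)
    fld = simulate_rde(network, grid, ic, T=T, dt=2e-3, stepper="imex", save_every=50)
    late = fld.times >= 3.0
    value = float(fld.u[late].max())
    _pulse_max_cache[key] = value
    return value


def default_threshold(params: ModelParams) -> float:
    """Parameter-adaptive detection threshold u* + 0.25 (u_pulse_max - u*)."""
    bg = background_states(params)[0]
    return bg.u_star + THRESHOLD_FRACTION * (reference_pulse_max(params) - bg.u_star)


def ensemble_event_stats(
    params: ModelParams,
    sigmas,
    n_runs: int,
    T: float = 100.0,
    base_seed: int = 0,
    grid: Grid | None = None,
    threshold: float | None = None,
    min_cells: int = MIN_CELLS,
    dt: float | None = 2e-3,
    stepper: str = "imex",
    save_every: int = 50,
    mode: str = "full",
    ic_fixture: str = "homog_4v",
) -> EnsembleStats:
    """Event statistics over an ensemble of Langevin runs per noise level.

    Each run i uses seed ``base_seed + i`` for both the initial
    perturbation and the noise path.  Counts are per-run averages; width,
    duration and maximum are averaged over all events pooled across runs.
    """
    from .experiments import make_initial_condition

    if n_runs < 2:
        raise ValidationError("ensemble needs n_runs >= 2")
    if grid is None:
        grid = Grid()
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if threshold is None:
        threshold = default_threshold(params)
    network = build_actin_network(params)

    mean_count = np.empty(sigmas.size)
    std_count = np.empty(sigmas.size)
    agg = {q: (np.full(sigmas.size, np.nan), np.full(sigmas.size, np.nan)) for q in
           ("width", "duration", "max")}
    all_events: dict[float, list[EventRecord]] = {}

    for si, sigma in enumerate(sigmas):
        counts = np.empty(n_runs)
        pooled: list[EventRecord] = []
        for i in range(n_runs):
            seed = int(base_seed + i)
            rng = np.random.default_rng(seed)
            ic = make_initial_condition(ic_fixture, params, grid, rng=rng)
            fld = simulate_cle(
                network,
                grid,
                ic,
                T=T,
                noise=NoiseConfig(sigma=float(sigma), seed=seed, mode=mode),
                dt=dt,
                stepper=stepper,
                save_every=save_every,
            )
            ev = detect_events(fld, threshold=threshold, min_cells=min_cells)
            counts[i] = len(ev)
            pooled.extend(ev)
        mean_count[si] = counts.mean()
        std_count[si] = counts.std(ddof=1)
        for q, attr in (("width", "x_extent"), ("duration", "duration"), ("max", "u_max")):
            vals = np.array([getattr(e, attr) for e in pooled])
            agg[q][0][si] = vals.mean() if vals.size else np.nan
            agg[q][1][si] = vals.std(ddof=1) if vals.size > 1 else np.nan
        all_events[float(sigma)] = pooled
        logger.info(
            "sigma=%.4g: %.2f events/run over %d runs", sigma, mean_count[si], n_runs
        )

    return EnsembleStats(
        sigmas=sigmas,
        n_runs=n_runs,
        base_seed=base_seed,
        mean_count=mean_count,
        std_count=std_count,
        mean_width=agg["width"][0],
        std_width=agg["width"][1],
        mean_duration=agg["duration"][0],
        std_duration=agg["duration"][1],
        mean_max=agg["max"][0],
        std_max=agg["max"][1],
        events=all_events,
    )


def estimate_period(
    field: SpaceTimeField,
    transient: float = 10.0,
    prominence_fraction: float = 0.25,
) -> float:
    """Oscillation period from the spatial mean of the activator.

    Discards ``t < transient``, finds prominence-filtered local maxima of
    <u>(t) and returns the mean spacing between successive maxima.
    Requires at least 3 maxima.
    """
    mean_u = field.u.mean(axis=1)
    keep = field.times >= transient
    series = mean_u[keep]
    times = field.times[keep]
    if series.size < 5:
        raise MeasurementError("too few samples after transient removal")
    prom = prominence_fraction * (series.max() - series.min())
    peaks, _ = signal.find_peaks(series, prominence=prom)
    if peaks.size < 3:
        raise MeasurementError(f"found only {peaks.size} maxima; need >= 3")
    return float(np.mean(np.diff(times[peaks])))


def event_histograms(events, bin_widths: dict | None = None) -> dict:
    """Fixed-bin-width histograms of event width, duration and maximum.

    Returns ``{quantity: (bin_edges, counts)}``; default bin widths are
    0.25 for width and duration and 0.1 for the maximum.
    """
    if not events:
        raise ValidationError("cannot histogram an empty event list")
    widths = {"width": 0.25, "duration": 0.25, "max": 0.1}
    if bin_widths:
        widths.update(bin_widths)
    values = {
        "width": np.array([e.x_extent for e in events]),
        "duration": np.array([e.duration for e in events]),
        "max": np.array([e.u_max for e in events]),
    }
    out = {}
    for q, vals in values.items():
        w = widths[q]
        n_bins = max(1, int(np.ceil(vals.max() / w + 1e-9)))
        edges = np.arange(n_bins + 1) * w
        counts, _ = np.histogram(vals, bins=edges)
        out[q] = (edges, counts)
    return out
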