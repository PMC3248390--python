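"""Stochastic simulator of per-cell DNA replication kinetics.

Space is discretized at 1 kb; time is continuous (minutes).  Each cell draws
potential firing times for a fixed set of origins, and every position is
replicated by the first fork (or origin) to reach it:

    t(x) = min_i ( T_i + |x - x_i| / v )

which encodes passive replication automatically.  Two firing models are
supported:

* ``independent`` -- each origin draws its firing time independently from a
  configurable law (fixed, normal, lognormal or exponential).
* ``domino`` -- an origin can additionally be triggered by an approaching
  fork: its effective firing time is the minimum of its independent draw and
  the time the nearest fork comes within the coupling distance ``d_c`` plus
  a delay ``delta``.  Effective times are resolved with a Dijkstra-style
  relaxation over origins.

The population layer averages many cells into a mean timing profile and the
rightward/leftward fork-polarity fractions (R, L), from which the apparent
replication speed v/(R-L) downstream modules are built on.  The fiber
sampler emulates a dual-pulse (IdU then CldU) molecular-combing experiment
on an asynchronous population, and the FACS sampler draws a DNA-content
histogram from a cytometry forward model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .combing import FiberRecord, Track
from .facs import FACSHistogram, SynthesisRateModel

__all__ = [
    "SimConfig",
    "CellReplication",
    "PopulationKinetics",
    "simulate_cell",
    "simulate_population",
    "sample_fibers",
    "simulate_facs_histogram",
    "evenly_spaced_origins",
    "cell_from_firing_times",
    "sample_fraction_densities",
]

#: single-fork velocity measured by DNA combing in HeLa cells, kb/min
DEFAULT_FORK_VELOCITY = 0.68
#: consecutive labeling pulse durations (IdU then CldU), minutes
DEFAULT_PULSES = (20.0, 20.0)


def evenly_spaced_origins(genome_length: float, spacing: float, offset: float = 0.0) -> np.ndarray:
    """Origin positions every ``spacing`` kb starting at ``offset``."""
    return np.arange(offset, genome_length, spacing, dtype=float)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a replication-kinetics simulation.

    Parameters
    ----------
    genome_length:
        Genome (or region) length in kb; positions live on a 1-kb grid.
    origin_positions:
        Origin coordinates in kb, each in ``[0, genome_length)``.  They are
        snapped to the 1-kb grid.
    firing_model:
        ``"independent"`` or ``"domino"``.
    firing_law:
        ``("fixed", t)``, ``("normal", mean, sd)``, ``("lognormal", mean, sd)``
        (mean/sd of the distribution itself) or ``("exponential", mean)``;
        minutes.  For the domino model this is the law of the independent
        (fork-free) component.
    fork_velocity:
        Single-fork velocity v, kb/min.
    coupling_distance, coupling_delay:
        Domino parameters: an unfired origin fires ``coupling_delay`` minutes
        after the nearest approaching fork comes within
        ``coupling_distance`` kb of it (if earlier than its own draw).
    pulse_scheme:
        (IdU duration, CldU duration), minutes.
    fiber_length_law:
        ``("lognormal", median_kb, sigma_log)`` for combed-fiber lengths.
    origin_time_offsets:
        Optional per-origin deterministic offsets (minutes) added to the
        drawn firing times; encodes a reproducible replication-timing
        landscape (efficient early origins vs late ones).
    """

    genome_length: float
    origin_positions: tuple[float, ...]
    firing_model: str = "independent"
    firing_law: tuple = ("lognormal", 120.0, 60.0)
    fork_velocity: float = DEFAULT_FORK_VELOCITY
    n_cells: int = 100
    pulse_scheme: tuple[float, float] = DEFAULT_PULSES
    fiber_length_law: tuple = ("lognormal", 200.0, 0.6)
    origin_time_offsets: tuple[float, ...] | None = None
    s_phase_compartments: int = 4
    coupling_distance: float = 36.0
    coupling_delay: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.fork_velocity <= 0:
            raise ValueError("fork_velocity must be positive")
        if len(self.origin_positions) == 0:
            raise ValueError("at least one origin is required: genome cannot replicate")
        pos = np.asarray(self.origin_positions, dtype=float)
        if np.any(pos < 0) or np.any(pos >= self.genome_length):
            raise ValueError("origin positions must lie in [0, genome_length)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.firing_model not in ("independent", "domino"):
            raise ValueError(f"unknown firing model {self.firing_model!r}")
        if (self.origin_time_offsets is not None
                and len(self.origin_time_offsets) != len(self.origin_positions)):
            raise ValueError("origin_time_offsets must match origin_positions")

    @property
    def n_positions(self) -> int:
        return int(round(self.genome_length))

    @property
    def origin_indices(self) -> np.ndarray:
        """Origin positions snapped to the 1-kb grid."""
        idx = np.round(np.asarray(self.origin_positions, dtype=float)).astype(int)
        return np.clip(idx, 0, self.n_positions - 1)

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class CellReplication:
    """Replication program of one cell on the 1-kb grid."""

    firing_times: np.ndarray  # per origin, min; +inf if passively replicated
    t_of_x: np.ndarray        # replication time per position, min
    polarity_of_x: np.ndarray # +1 rightward fork, -1 leftward fork

    @property
    def s_phase_end(self) -> float:
        return float(self.t_of_x.max())


@dataclass
class PopulationKinetics:
    """Ensemble averages over many simulated cells."""

    mean_timing: np.ndarray  # per position, min
    R_of_x: np.ndarray       # fraction of cells replicated by a rightward fork
    L_of_x: np.ndarray       # fraction replicated by a leftward fork

    def apparent_speed_identity(self, v: float) -> np.ndarray:
        """Predicted timing slope (R - L)/v, min/kb, per position."""
        return (self.R_of_x - self.L_of_x) / v


# ---------------------------------------------------------------------------
# firing-time draws


def _draw_firing_times(law: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "fixed":
        return np.full(n, float(law[1]))
    if kind == "normal":
        mean, sd = float(law[1]), float(law[2])
        return np.maximum(rng.normal(mean, sd, size=n), 0.0)
    if kind == "lognormal":
        mean, sd = float(law[1]), float(law[2])
        # convert distribution mean/sd to the underlying normal parameters
        sigma2 = np.log(1.0 + (sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=n)
    if kind == "exponential":
        return rng.exponential(float(law[1]), size=n)
    raise ValueError(f"unknown firing law {kind!r}")


def _domino_effective_times(
    draws: np.ndarray, positions: np.ndarray, v: float, d_c: float, delta: float
) -> np.ndarray:
    """Resolve domino coupling into effective firing times.

    T_i = min(draw_i, min_j T_j + max(0, |x_i - x_j| - d_c)/v + delta), solved
    exactly with a Dijkstra-style relaxation (trigger times never decrease
    along a cascade because the added cost is non-negative).
    """
    import heapq

    n = len(draws)
    eff = draws.astype(float).copy()
    done = np.zeros(n, dtype=bool)
    heap = [(eff[i], i) for i in range(n)]
    heapq.heapify(heap)
    while heap:
        t, i = heapq.heappop(heap)
        if done[i] or t > eff[i]:
            continue
        done[i] = True
        gaps = np.abs(positions - positions[i])
        trig = t + np.maximum(0.0, gaps - d_c) / v + delta
        better = (~done) & (trig < eff)
        for j in np.nonzero(better)[0]:
            eff[j] = trig[j]
            heapq.heappush(heap, (eff[j], j))
    return eff


# ---------------------------------------------------------------------------
# single cell


def cell_from_firing_times(origin_indices: np.ndarray, firing_times: np.ndarray,
                           fork_velocity: float, n_positions: int) -> CellReplication:
    """Replication program for explicit origin firing times.

    ``t(x) = min_i(T_i + |x - x_i|/v)`` evaluated with two linear sweeps
    (rightward and leftward lower envelopes); passive replication of late
    origins is automatic.  Polarity is the direction of the winning fork;
    exact ties (origins, termination midpoints) are assigned rightward.
    """
    idx = np.asarray(origin_indices, dtype=int)
    eff = np.asarray(firing_times, dtype=float)
    v = float(fork_velocity)
    grid = np.arange(n_positions, dtype=float)
    seed_t = np.full(n_positions, np.inf)
    np.minimum.at(seed_t, idx, eff)

    # rightward envelope: min_{i<=x} (T_i + (x - x_i)/v)
    t_right = np.minimum.accumulate(seed_t - grid / v) + grid / v
    # leftward envelope
    t_left = (np.minimum.accumulate((seed_t + grid / v)[::-1]) - (grid / v)[::-1])[::-1]

    t = np.minimum(t_right, t_left)
    polarity = np.where(t_right <= t_left, 1, -1).astype(np.int8)

    # an origin fired iff its draw beat every incoming fork
    fired = eff <= t[idx] + 1e-9
    firing = np.where(fired, eff, np.inf)
    return CellReplication(firing_times=firing, t_of_x=t, polarity_of_x=polarity)


def simulate_cell(config: SimConfig, cell_seed: int) -> CellReplication:
    """Simulate one cell's replication program.

    Every position takes the time of the first arriving fork,
    ``t(x) = min_i(T_i + |x - x_i|/v)``, computed with two linear sweeps
    (rightward and leftward lower envelopes).  Polarity is the direction of
    the winning fork; exact ties (origins themselves, termination midpoints)
    are assigned rightward.
    """
    rng = np.random.default_rng(cell_seed)
    idx = config.origin_indices
    draws = _draw_firing_times(config.firing_law, len(idx), rng)
    if config.origin_time_offsets is not None:
        draws = draws + np.asarray(config.origin_time_offsets, dtype=float)
    v = config.fork_velocity

    if config.firing_model == "domino":
        order = np.argsort(idx)
        eff = np.empty_like(draws)
        eff[order] = _domino_effective_times(
            draws[order], idx[order].astype(float), v,
            config.coupling_distance, config.coupling_delay,
        )
    else:
        eff = draws

    return cell_from_firing_times(idx, eff, v, config.n_positions)


def simulate_population(config: SimConfig) -> PopulationKinetics:
    """Ensemble mean timing and fork-polarity fractions over ``n_cells``."""
    if config.n_cells < 2:
        raise ValueError("population statistics require n_cells >= 2")
    cells = _cell_seeds(config)
    n = config.n_positions
    t_sum = np.zeros(n)
    right = np.zeros(n)
    for s in cells:
        cell = simulate_cell(config, s)
        t_sum += cell.t_of_x
        right += cell.polarity_of_x > 0
    R = right / config.n_cells
    return PopulationKinetics(mean_timing=t_sum / config.n_cells, R_of_x=R, L_of_x=1.0 - R)


def _cell_seeds(config: SimConfig) -> np.ndarray:
    ss = np.random.SeedSequence(config.seed)
    return ss.generate_state(config.n_cells).astype(np.int64)


# ---------------------------------------------------------------------------
# combed fibers


def _label_positions(t: np.ndarray, t0: float, p1: float, p2: float) -> np.ndarray:
    """0 unlabeled, 1 IdU, 2 CldU, for a pulse starting at absolute time t0."""
    lab = np.zeros(len(t), dtype=np.int8)
    lab[(t >= t0) & (t < t0 + p1)] = 1
    lab[(t >= t0 + p1) & (t < t0 + p1 + p2)] = 2
    return lab


def _runs(values: np.ndarray):
    """Yield (value, start, end) runs over an integer array."""
    if len(values) == 0:
        return
    change = np.nonzero(np.diff(values))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    for s, e in zip(starts, ends):
        yield int(values[s]), int(s), int(e)


def sample_fibers(config: SimConfig, n_fibers: int, seed: int | None = None) -> list[FiberRecord]:
    """Sample labeled combed fibers from an asynchronous population.

    Each fiber is a random window of a random cell observed at the end of the
    second pulse.  The cell's pulse start time is uniform over its S phase,
    emulating asynchronous growth; positions replicated during pulse 1 carry
    IdU, during pulse 2 CldU, and all others are unlabeled.  Cells are
    assigned to S-phase compartments by the fraction of the genome replicated
    at the end of labeling (equal-width windows; quartiles for 4
    compartments).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p1, p2 = config.pulse_scheme
    law = config.fiber_length_law
    if law[0] != "lognormal":
        raise ValueError("fiber_length_law must be ('lognormal', median_kb, sigma)")
    median, sigma = float(law[1]), float(law[2])

    cells = [simulate_cell(config, s) for s in _cell_seeds(config)]
    ncomp = config.s_phase_compartments
    fibers: list[FiberRecord] = []
    for k in range(n_fibers):
        cell = cells[rng.integers(len(cells))]
        t_end = cell.s_phase_end
        t0 = rng.uniform(0.0, t_end)
        length = float(np.round(median * np.exp(sigma * rng.normal())))
        length = max(length, 1.0)
        if length > config.genome_length:
            raise ValueError("drawn fiber longer than the genome")
        start = int(rng.integers(0, config.n_positions - int(length) + 1))
        window = cell.t_of_x[start:start + int(length)]
        labels = _label_positions(window, t0, p1, p2)
        frac = float(np.mean(cell.t_of_x <= t0 + p1 + p2))
        comp = min(int(frac * ncomp), ncomp - 1)
        tracks = [
            Track(label=("unlabeled", "IdU", "CldU")[val], start=float(s), end=float(e))
            for val, s, e in _runs(labels)
        ]
        fibers.append(FiberRecord(
            fiber_id=f"fiber{k:05d}",
            compartment=f"S{comp + 1}",
            length=float(len(labels)),
            tracks=tracks,
        ))
    return fibers


# ---------------------------------------------------------------------------
# per-fraction tag densities (Repli-seq emulation)


def sample_fraction_densities(
    config: SimConfig,
    n_fractions: int = 4,
    mean_depth: float | None = None,
    background_rate: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Per-kb nascent-DNA tag counts for each S-phase fraction.

    Each cell's S phase is divided into ``n_fractions`` intervals of equal
    replicated-fraction width (the sorting is by DNA content); a position
    contributes a tag to the fraction during which it replicates in that
    cell.  With ``mean_depth`` set, counts are Poisson-sampled at that mean
    coverage per kb per fraction, optionally over a uniform background of
    ``background_rate`` expected tags per kb per fraction (sequencing
    noise); otherwise the deterministic expected counts are returned.

    Returns an (n_positions, n_fractions) array.
    """
    counts = np.zeros((config.n_positions, n_fractions))
    for s in _cell_seeds(config):
        cell = simulate_cell(config, s)
        t = cell.t_of_x
        bounds = np.quantile(t, np.arange(1, n_fractions) / n_fractions)
        frac = np.searchsorted(bounds, t, side="left")
        np.add.at(counts, (np.arange(len(t)), frac), 1.0)
    if mean_depth is None:
        return counts
    rng = np.random.default_rng(config.seed if seed is None else seed)
    expected = counts / counts.mean() * mean_depth + background_rate
    return rng.poisson(expected).astype(float)


# ---------------------------------------------------------------------------
# FACS forward model


def simulate_facs_histogram(
    model: SynthesisRateModel,
    theta1: float,
    theta2: float,
    cv: float,
    n_cells: int,
    seed: int,
    bins: np.ndarray | None = None,
) -> FACSHistogram:
    """Draw a DNA-content histogram from the cytometry forward model.

    Cells are G1 (content 1) with probability ``theta1``, G2/M (content 2)
    with probability ``theta2``, otherwise in S phase with content drawn from
    the steady-state S-phase density implied by the synthesis rate phi(x).
    Measured fluorescence is the true content perturbed by multiplicative
    Gaussian error of coefficient of variation ``cv``.
    """
    if theta1 + theta2 > 1 + 1e-12:
        raise ValueError("theta1 + theta2 must be <= 1")
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = np.random.default_rng(seed)
    x_grid, dens = model.s_phase_density_grid()
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]

    u = rng.random(n_cells)
    content = np.empty(n_cells)
    g1 = u < theta1
    g2 = (u >= theta1) & (u < theta1 + theta2)
    s = ~(g1 | g2)
    content[g1] = 1.0
    content[g2] = 2.0
    content[s] = np.interp(rng.random(int(s.sum())), cdf, x_grid)
    measured = content * (1.0 + cv * rng.normal(size=n_cells))

    if bins is None:
        bins = np.linspace(1.0 - 6 * cv, 2.0 + 12 * cv, 201)
    counts, edges = np.histogram(measured, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FACSHistogram(bin_centers=centers, counts=counts.astype(float),
                         theta1=theta1, theta2=theta2)
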