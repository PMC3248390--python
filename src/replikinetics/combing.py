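"""Single-molecule (DNA combing) replication statistics.

Fibers arrive as digitized, ordered runs of labeled tracks from a dual-pulse
experiment (IdU for the first pulse, CldU for the second).  The label
transitions on a fiber encode the replication state at the moment the second
pulse began:

* an adjacent IdU->CldU boundary is a moving fork (orientation from the IdU
  side toward the CldU side);
* a central IdU tract flanked by CldU on both sides is an origin that fired
  before CldU addition (type 1);
* an isolated CldU-only tract is an origin that fired after CldU addition
  (type 2);
* a central CldU tract flanked by IdU on both sides is a termination event.

A tract measures single-fork velocity only when it is delimited on both
sides inside the fiber and carries exactly one complementary-label
neighbour, so that it spans one full labeling pulse.

This module also provides the aggregate statistics built on those calls:
corrected DNA lengths, fork densities and global fork-to-fork distances
(FTFD), intra-fiber distance lists, a Monte-Carlo test of fork clustering
against a uniform (Poisson) initiation null, a chi-square homogeneity test
of adjacent origin types, mean inter-cluster distances, and the total genome
duplication time implied by per-compartment fork densities and velocities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Track",
    "FiberRecord",
    "ForkEvent",
    "OriginCall",
    "TerminusCall",
    "ClassifiedFiber",
    "CompartmentSummary",
    "DuplicationTimeInputs",
    "ClusteringTestResult",
    "classify_tracks",
    "fork_velocity",
    "corrected_dna_length",
    "fork_density_and_ftfd",
    "pairwise_distances",
    "clustering_null",
    "adjacent_type_homogeneity",
    "intercluster_distance",
    "genome_duplication_time",
    "summarize_compartment",
    "adjacent_origin_pair_counts",
]

LABELS = ("IdU", "CldU", "unlabeled")


@dataclass(frozen=True)
class Track:
    label: str
    start: float  # kb, fiber-local
    end: float

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.end <= self.start:
            raise ValueError("track end must exceed start")

    @property
    def length(self) -> float:
        return self.end - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class FiberRecord:
    fiber_id: str
    compartment: str
    length: float  # kb
    tracks: list[Track]

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"fiber {self.fiber_id}: non-positive length")
        pos = 0.0
        for tr in self.tracks:
            if tr.start < pos - 1e-9:
                raise ValueError(f"fiber {self.fiber_id}: overlapping or unordered tracks")
            pos = tr.end
        if pos > self.length + 1e-9:
            raise ValueError(f"fiber {self.fiber_id}: tracks exceed fiber length")

    def labeled_runs(self) -> list[Track]:
        """Tracks with explicit unlabeled gaps filled in, tiling [0, length]."""
        runs: list[Track] = []
        pos = 0.0
        for tr in self.tracks:
            if tr.start > pos + 1e-9:
                runs.append(Track("unlabeled", pos, tr.start))
            runs.append(tr)
            pos = tr.end
        if pos < self.length - 1e-9:
            runs.append(Track("unlabeled", pos, self.length))
        # merge consecutive runs with the same label
        merged: list[Track] = []
        for tr in runs:
            if merged and merged[-1].label == tr.label:
                merged[-1] = Track(tr.label, merged[-1].start, tr.end)
            else:
                merged.append(tr)
        return merged


@dataclass(frozen=True)
class ForkEvent:
    position: float           # kb, transition point at the time of CldU addition
    direction: str            # "right" or "left"
    velocity: float = np.nan  # kb/min when measurable


@dataclass(frozen=True)
class OriginCall:
    position: float
    origin_type: int  # 1 fired during pulse 1, 2 fired during pulse 2


@dataclass(frozen=True)
class TerminusCall:
    position: float


@dataclass
class ClassifiedFiber:
    forks: list[ForkEvent]
    origins: list[OriginCall]
    termini: list[TerminusCall]
    velocities: list[float]  # one entry per velocity-eligible tract


def fork_velocity(track_length: float, pulse: float) -> float:
    """Single-fork velocity from a full-pulse tract, kb/min."""
    if pulse <= 0:
        raise ValueError("pulse duration must be positive")
    if track_length < 0:
        raise ValueError("track length must be non-negative")
    return track_length / pulse


def _velocity_eligible(runs: list[Track], i: int, fiber_length: float) -> bool:
    """A labeled tract spans one full pulse iff it is delimited inside the
    fiber on both sides and has exactly one complementary-label neighbour."""
    tr = runs[i]
    if tr.start <= 1e-9 or tr.end >= fiber_length - 1e-9:
        return False
    other = "CldU" if tr.label == "IdU" else "IdU"
    left = runs[i - 1].label if i > 0 else None
    right = runs[i + 1].label if i < len(runs) - 1 else None
    return (left == other) != (right == other)  # exactly one complementary side


def classify_tracks(
    fiber: FiberRecord, pulse_durations: tuple[float, float] = (20.0, 20.0)
) -> ClassifiedFiber:
    """Call forks, origins and termini from the label pattern of one fiber."""
    p1, p2 = pulse_durations
    runs = [r for r in fiber.labeled_runs()]
    forks: list[ForkEvent] = []
    origins: list[OriginCall] = []
    termini: list[TerminusCall] = []
    velocities: list[float] = []

    # per-transition forks and per-tract velocities
    tract_v: dict[int, float] = {}
    for i, tr in enumerate(runs):
        if tr.label == "unlabeled":
            continue
        if _velocity_eligible(runs, i, fiber.length):
            pulse = p1 if tr.label == "IdU" else p2
            v = fork_velocity(tr.length, pulse)
            velocities.append(v)
            tract_v[i] = v

    for i in range(len(runs) - 1):
        a, b = runs[i], runs[i + 1]
        pair = (a.label, b.label)
        if pair == ("IdU", "CldU"):
            direction = "right"
        elif pair == ("CldU", "IdU"):
            direction = "left"
        else:
            continue
        vs = [tract_v[j] for j in (i, i + 1) if j in tract_v]
        forks.append(ForkEvent(
            position=a.end, direction=direction,
            velocity=float(np.mean(vs)) if vs else np.nan,
        ))

    for i, tr in enumerate(runs):
        left = runs[i - 1].label if i > 0 else None
        right = runs[i + 1].label if i < len(runs) - 1 else None
        if tr.label == "IdU" and left == "CldU" and right == "CldU":
            origins.append(OriginCall(position=tr.center, origin_type=1))
        elif tr.label == "CldU" and left == "IdU" and right == "IdU":
            termini.append(TerminusCall(position=tr.center))
        elif tr.label == "CldU" and left != "IdU" and right != "IdU":
            # isolated CldU-only tract: origin fired after CldU addition
            origins.append(OriginCall(position=tr.center, origin_type=2))

    return ClassifiedFiber(forks=forks, origins=origins, termini=termini,
                           velocities=velocities)


# ---------------------------------------------------------------------------
# scalar corrections and densities


def corrected_dna_length(raw_length: float, frac_nonreplicating: float,
                         mean_dna_content: float) -> float:
    """Correct combed DNA length for non-replicating cells and ploidy.

    ``raw * (1 - frac_nonreplicating) / mean_dna_content`` -- the first factor
    removes DNA contributed by contaminating G1/G2 cells, the second divides
    out the already-synthesized DNA of the compartment (mean content relative
    to G1 = 1).
    """
    if not 0.0 <= frac_nonreplicating <= 1.0:
        raise ValueError("frac_nonreplicating must be in [0, 1]")
    if mean_dna_content < 1.0:
        raise ValueError("mean DNA content is relative to G1 and must be >= 1")
    return raw_length * (1.0 - frac_nonreplicating) / mean_dna_content


def fork_density_and_ftfd(n_forks: int, corrected_length_mb: float) -> tuple[float, float]:
    """Global fork density (forks/Mb) and global fork-to-fork distance (kb).

    The global FTFD is the reciprocal of the density, 1000/density kb; it is
    NaN (flagged undefined) when no forks were observed.
    """
    if corrected_length_mb <= 0:
        raise ValueError("corrected DNA length must be positive")
    density = n_forks / corrected_length_mb
    ftfd = 1000.0 / density if density > 0 else np.nan
    return density, ftfd


def pairwise_distances(positions) -> np.ndarray:
    """Consecutive center-to-center distances of sorted same-kind events, kb."""
    pos = np.sort(np.asarray([p for p in positions], dtype=float))
    if len(pos) < 2:
        return np.empty(0)
    return np.diff(pos)


def intercluster_distance(total_corrected_length: float, sum_intrafiber_ftfd: float,
                          n_fork_fibers: int) -> float:
    """Mean distance between origin clusters, kb.

    ``(total - sum of intra-fiber FTFDs) / number of fork-containing fibers``,
    assuming at most one cluster per fiber.
    """
    if n_fork_fibers <= 0:
        raise ValueError("need at least one fork-containing fiber")
    if sum_intrafiber_ftfd > total_corrected_length:
        raise ValueError("intra-fiber FTFD total exceeds the DNA length")
    return (total_corrected_length - sum_intrafiber_ftfd) / n_fork_fibers


# ---------------------------------------------------------------------------
# clustering test


@dataclass
class ClusteringTestResult:
    observed_props: np.ndarray   # P(0), P(1), P(>=2) forks per fiber, observed
    expected_props: np.ndarray   # same under the uniform-initiation null
    statistic: float
    p_value: float
    null_statistics: np.ndarray


def _fork_count_bins(counts: np.ndarray) -> np.ndarray:
    return np.array([np.sum(counts == 0), np.sum(counts == 1), np.sum(counts >= 2)],
                    dtype=float)


def clustering_null(fiber_lengths, density: float, observed_counts,
                    n_reps: int = 1000, seed: int = 0) -> ClusteringTestResult:
    """Monte-Carlo test of fork clustering against uniform initiation.

    Under the null, forks fall on each fiber as a uniform point process at
    the global density, so the forks-per-fiber count of a fiber of length
    ``l`` kb is Poisson(density * l / 1000).  The discrepancy statistic is a
    chi-square over the {0, 1, >=2}-fork bins; its tail probability is
    estimated by simulation rather than asymptotics because expected counts
    can be small.  Ties between the observed and simulated statistics (the
    statistic is discrete) are broken uniformly at random, which makes the
    p-value exactly uniform under the null.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    lengths = np.asarray(fiber_lengths, dtype=float)
    observed = np.asarray(observed_counts)
    if len(lengths) != len(observed):
        raise ValueError("one observed fork count per fiber is required")
    lam = density * lengths / 1000.0

    p0 = np.exp(-lam)
    p1 = lam * p0
    expected = np.array([p0.sum(), p1.sum(), len(lam) - p0.sum() - p1.sum()])
    safe = np.where(expected > 0, expected, 1.0)

    def stat(binned):
        return np.sum(np.where(expected > 0, (binned - expected) ** 2 / safe, 0.0),
                      axis=-1)

    obs_stat = float(stat(_fork_count_bins(observed)))
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=(n_reps, len(lam)))
    binned = np.stack([
        (counts == 0).sum(axis=1),
        (counts == 1).sum(axis=1),
        (counts >= 2).sum(axis=1),
    ], axis=1).astype(float)
    null_stats = stat(binned)
    n_gt = int(np.sum(null_stats > obs_stat + 1e-12))
    n_eq = int(np.sum(np.abs(null_stats - obs_stat) <= 1e-12))
    p = (n_gt + rng.random() * (n_eq + 1)) / (n_reps + 1.0)
    n = len(lengths)
    return ClusteringTestResult(
        observed_props=_fork_count_bins(observed) / n,
        expected_props=expected / n,
        statistic=obs_stat,
        p_value=float(p),
        null_statistics=null_stats,
    )


# ---------------------------------------------------------------------------
# adjacent origin-type homogeneity


def adjacent_type_homogeneity(n11: int, n22: int, n12: int,
                              n_reps: int = 100_000, seed: int = 0):
    """Chi-square test of whether adjacent origin types mix at random.

    Under random interspersion the pair proportions are (p1^2, p2^2, 2 p1 p2)
    with p1 estimated from pair slots, p1 = (2 n11 + n12) / (2 N).  One
    parameter is estimated from 3 categories, so df = 1.  If any expected
    count falls below 1, a Monte-Carlo multinomial p-value is substituted.

    Returns ``(chi2, df, p)``.
    """
    total = n11 + n22 + n12
    if total <= 0:
        raise ValueError("at least one adjacent pair is required")
    p1 = (2 * n11 + n12) / (2 * total)
    p2 = 1.0 - p1
    probs = np.array([p1 ** 2, p2 ** 2, 2 * p1 * p2])
    expected = total * probs
    observed = np.array([n11, n22, n12], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float(np.nansum(np.where(expected > 0,
                                        (observed - expected) ** 2 / expected, 0.0)))
    df = 1
    if np.any(expected < 1.0):
        rng = np.random.default_rng(seed)
        sims = rng.multinomial(total, probs, size=n_reps).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = (sims - expected) ** 2 / expected
        null = np.nansum(np.where(expected > 0, contrib, 0.0), axis=1)
        p = float((1.0 + np.sum(null >= chi2 - 1e-12)) / (n_reps + 1.0))
    else:
        p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def adjacent_origin_pair_counts(classified: list[ClassifiedFiber]) -> tuple[int, int, int]:
    """(n11, n22, n12) counts of adjacent origin-type pairs across fibers."""
    n11 = n22 = n12 = 0
    for cf in classified:
        types = [o.origin_type for o in sorted(cf.origins, key=lambda o: o.position)]
        for a, b in zip(types, types[1:]):
            if a == b == 1:
                n11 += 1
            elif a == b == 2:
                n22 += 1
            else:
                n12 += 1
    return n11, n22, n12


# ---------------------------------------------------------------------------
# genome duplication time


@dataclass
class DuplicationTimeInputs:
    """Per-compartment inputs for the genome duplication time.

    P_Si is the fraction of the genome replicated during compartment i (from
    FACS profiles), density_i the global fork density (forks/Mb) and v_i the
    fork velocity (kb/min).  The genome size cancels: the global synthesis
    rate per compartment is density_i * v_i * 1e-3 genome fractions per
    minute.
    """

    p_si: np.ndarray       # replicated genome fraction per compartment
    density: np.ndarray    # forks/Mb
    velocity: np.ndarray   # kb/min

    def __post_init__(self):
        self.p_si = np.asarray(self.p_si, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not (len(self.p_si) == len(self.density) == len(self.velocity)):
            raise ValueError("per-compartment arrays must have equal length")
        if np.any(self.p_si <= 0) or np.any(self.density <= 0) or np.any(self.velocity <= 0):
            raise ValueError("all duplication-time inputs must be positive")
        if self.p_si.sum() > 1 + 1e-9:
            raise ValueError("replicated fractions sum above 1")

    @property
    def t_si(self) -> np.ndarray:
        """Time spent in each compartment, minutes."""
        return self.p_si / (self.density * self.velocity * 1e-3)


def genome_duplication_time(inputs: DuplicationTimeInputs) -> float:
    """Total time to duplicate the genome, minutes.

    Sum of per-compartment durations T_Si = P_Si / (density_i v_i 1e-3),
    corrected by the total genome fraction the compartments cover.
    """
    total_p = inputs.p_si.sum()
    if total_p <= 0:
        raise ValueError("total replicated fraction must be positive")
    return float(inputs.t_si.sum() / total_p)


# ---------------------------------------------------------------------------
# per-compartment summary (Table-2 style)


@dataclass
class CompartmentSummary:
    compartment: str
    n_fibers: int
    n_forks: int
    dna_length_raw: float        # Mb
    dna_length_corrected: float  # Mb
    fork_density: float          # forks/Mb
    global_ftfd: float           # kb
    velocities: np.ndarray       # kb/min, one per eligible tract
    local_ftfds: np.ndarray      # kb, intra-fiber fork-to-fork distances
    inter_origin: np.ndarray     # kb
    inter_termini: np.ndarray    # kb
    forks_per_fiber: np.ndarray  # counts over fork-containing fibers
    idu_fraction: np.ndarray     # IdU-labeled length fraction per labeled fiber


def summarize_compartment(
    fibers: list[FiberRecord],
    compartment: str,
    pulse_durations: tuple[float, float] = (20.0, 20.0),
    frac_nonreplicating: float = 0.0,
    mean_dna_content: float = 1.0,
) -> CompartmentSummary:
    """Aggregate single-fiber calls of one S-phase compartment."""
    sub = [f for f in fibers if f.compartment == compartment]
    velocities: list[float] = []
    local_ftfds: list[float] = []
    inter_origin: list[float] = []
    inter_termini: list[float] = []
    forks_per_fiber: list[int] = []
    idu_fraction: list[float] = []
    n_forks = 0
    raw_kb = 0.0
    for f in sub:
        raw_kb += f.length
        cf = classify_tracks(f, pulse_durations)
        velocities.extend(cf.velocities)
        n_forks += len(cf.forks)
        if cf.forks:
            forks_per_fiber.append(len(cf.forks))
        local_ftfds.extend(pairwise_distances([fk.position for fk in cf.forks]))
        inter_origin.extend(pairwise_distances([o.position for o in cf.origins]))
        inter_termini.extend(pairwise_distances([t.position for t in cf.termini]))
        idu_len = sum(tr.length for tr in f.tracks if tr.label == "IdU")
        if idu_len > 0:
            idu_fraction.append(idu_len / f.length)
    raw_mb = raw_kb / 1000.0
    corrected = corrected_dna_length(raw_mb, frac_nonreplicating, mean_dna_content)
    if corrected > 0:
        density, gftfd = fork_density_and_ftfd(n_forks, corrected)
    else:
        density, gftfd = 0.0, np.nan
    return CompartmentSummary(
        compartment=compartment,
        n_fibers=len(sub),
        n_forks=n_forks,
        dna_length_raw=raw_mb,
        dna_length_corrected=corrected,
        fork_density=density,
        global_ftfd=gftfd,
        velocities=np.asarray(velocities),
        local_ftfds=np.asarray(local_ftfds),
        inter_origin=np.asarray(inter_origin),
        inter_termini=np.asarray(inter_termini),
        forks_per_fiber=np.asarray(forks_per_fiber),
        idu_fraction=np.asarray(idu_fraction),
    )
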