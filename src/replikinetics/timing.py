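"""Replication timing profiles from per-fraction tag densities.

A Repli-seq style experiment sorts S-phase cells into ``n`` fractions by DNA
content and sequences the nascent DNA of each fraction.  After binning, the
per-bin vector of fraction enrichments describes when in S phase the bin
replicates.  This module normalizes those vectors, removes background noise,
computes S50 (the fraction of S phase at which half the cells have
replicated the bin) by piecewise-linear interpolation of the cumulative
enrichment, and converts S50 to a clock time TR50 either linearly (fixed
S-phase length) or through a FACS-calibrated DNA-content -> time map.

Coordinates are 0-based half-open (BED convention) in base pairs; window and
step sizes are given in kb.  Fraction ``i`` (1-based) is mapped to the
S-phase interval ``((i-1)/n, i/n]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .facs import SynthesisRateModel

__all__ = [
    "FractionDensities",
    "TimingProfile",
    "normalize_fractions",
    "denoise_4m",
    "s50",
    "s50_to_tr50",
    "make_timing_profile",
    "bin_counts",
    "estimate_density_mode",
]


@dataclass
class FractionDensities:
    """Binned per-fraction tag densities.

    ``values`` is (n_bins, n_fractions); ``mask`` marks bins with no usable
    signal.  Bins are 0-based half-open bp intervals.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    mask: np.ndarray = None  # True where the bin is missing/unusable
    window_kb: float = 100.0
    step_kb: float = 100.0

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_bins, n_fractions)")
        if np.any(self.values < 0):
            raise ValueError("densities must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(len(self.starts), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_fractions(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray, mask: np.ndarray) -> "FractionDensities":
        return FractionDensities(self.chroms, self.starts, self.ends, values,
                                 mask, self.window_kb, self.step_kb)


@dataclass
class TimingProfile:
    """Per-bin S50 (fraction of S phase) and TR50 (hours)."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    s50: np.ndarray
    tr50: np.ndarray
    mask: np.ndarray
    step_kb: float = 100.0
    window_kb: float = None  # defaults to step_kb (tiled windows)

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.s50 = np.asarray(self.s50, dtype=float)
        self.tr50 = np.asarray(self.tr50, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.window_kb is None:
            self.window_kb = self.step_kb


# ---------------------------------------------------------------------------


def normalize_fractions(raw: FractionDensities) -> FractionDensities:
    """Equalize genome-wide totals across fractions, then scale each covered
    bin so its enrichments sum to one.  Bins that are zero in every fraction
    are masked."""
    if raw.n_fractions < 2:
        raise ValueError("need at least two S-phase fractions")
    totals = raw.values.sum(axis=0)
    if np.any(totals <= 0):
        bad = int(np.argmin(totals))
        raise ValueError(f"fraction {bad} has zero total tag count")
    scaled = raw.values * (totals.mean() / totals)
    sums = scaled.sum(axis=1)
    mask = raw.mask | (sums <= 0)
    out = np.zeros_like(scaled)
    ok = ~mask
    out[ok] = scaled[ok] / sums[ok, None]
    return raw.copy_with(out, mask)


def estimate_density_mode(norm: FractionDensities) -> float:
    """Mode of the genome-wide normalized density distribution.

    Estimated as the peak of a Freedman-Diaconis histogram over the positive
    normalized densities of all fractions pooled.
    """
    vals = norm.values[~norm.mask].ravel()
    vals = vals[vals > 0]
    if len(vals) == 0:
        raise ValueError("no positive densities to estimate a mode from")
    counts, edges = np.histogram(vals, bins="fd")
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def denoise_4m(norm: FractionDensities, mode: float | None = None) -> FractionDensities:
    """Zero normalized densities below 4x the background mode, renormalize.

    The genome-wide distribution of normalized densities has a low mode
    produced mostly by noise; values under four times that mode are set to
    zero fraction-wise and each bin is rescaled to sum to one again.  Bins
    zeroed in every fraction become masked.
    """
    m = estimate_density_mode(norm) if mode is None else float(mode)
    if not (0.001 <= m <= 0.2):
        warnings.warn(f"density mode {m:.4g} outside the plausible range; proceeding")
    vals = np.where(norm.values < 4.0 * m, 0.0, norm.values)
    sums = vals.sum(axis=1)
    mask = norm.mask | (sums <= 0)
    out = np.zeros_like(vals)
    ok = ~mask
    out[ok] = vals[ok] / sums[ok, None]
    return norm.copy_with(out, mask)


def s50(norm: FractionDensities) -> np.ndarray:
    """Per-bin S50 by linear interpolation of the cumulative enrichment.

    Fraction ``i`` occupies the S-phase interval ``((i-1)/n, i/n]``; the
    cumulative replicated fraction is piecewise linear through (0, 0) and
    (i/n, sum_{j<=i} w_j), and S50 is the abscissa of the first crossing of
    one half.  Masked bins yield NaN.
    """
    n = norm.n_fractions
    w = norm.values
    cum = np.concatenate([np.zeros((len(w), 1)), np.cumsum(w, axis=1)], axis=1)
    xs = np.arange(n + 1) / n
    out = np.full(len(w), np.nan)
    ok = ~norm.mask
    if not np.any(ok):
        return out
    c = cum[ok]
    # first segment whose right endpoint reaches 0.5
    k = np.argmax(c[:, 1:] >= 0.5, axis=1)
    c0 = np.take_along_axis(c, k[:, None], axis=1)[:, 0]
    c1 = np.take_along_axis(c, k[:, None] + 1, axis=1)[:, 0]
    frac = np.where(c1 > c0, (0.5 - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.0)
    out[ok] = xs[k] + frac / n
    return out


def s50_to_tr50(s50_values, mode: str = "linear", s_length_h: float = 8.0,
                model: SynthesisRateModel | None = None) -> np.ndarray:
    """Convert S50 (fraction of S phase) to TR50 (hours).

    ``linear``: TR50 = s_length_h * S50, a uniform DNA-content -> time map.
    ``facs``: TR50 = t(1 + S50) through a fitted synthesis-rate model, which
    accounts for the varying speed at which cells traverse DNA contents.
    """
    s = np.asarray(s50_values, dtype=float)
    if mode == "linear":
        return s_length_h * s
    if mode == "facs":
        if model is None:
            raise ValueError("facs mode requires a SynthesisRateModel")
        _, t = model.time_grid()
        if np.any(np.diff(t) < 0):
            raise ValueError("content -> time map must be monotone")
        return model.time_at_content(1.0 + s)
    raise ValueError(f"unknown conversion mode {mode!r}")


def make_timing_profile(norm: FractionDensities, mode: str = "linear",
                        s_length_h: float = 8.0,
                        model: SynthesisRateModel | None = None) -> TimingProfile:
    """S50 + TR50 profile from normalized fraction densities."""
    s = s50(norm)
    tr = np.full_like(s, np.nan)
    ok = ~norm.mask
    tr[ok] = s50_to_tr50(s[ok], mode=mode, s_length_h=s_length_h, model=model)
    return TimingProfile(norm.chroms, norm.starts, norm.ends, s, tr, norm.mask,
                         step_kb=norm.step_kb, window_kb=norm.window_kb)


# ---------------------------------------------------------------------------


def profile_from_mean_timing(mean_timing_min: np.ndarray, window_kb: int = 100,
                             step_kb: int = 10, chrom: str = "chr1") -> TimingProfile:
    """Windowed TR50 profile straight from simulated per-kb mean timing.

    Averages the per-kb population mean replication time (minutes) over
    (sliding) windows; S50 is the corresponding rank within the cell's S
    phase, mean/max.  Bypasses the fraction-density route when the simulator
    has already produced exact ensemble timing.
    """
    t = np.asarray(mean_timing_min, dtype=float)
    if len(t) < window_kb:
        raise ValueError("genome shorter than one window")
    cum = np.concatenate([[0.0], np.cumsum(t)])
    starts_kb = np.arange(0, len(t) - window_kb + 1, step_kb)
    mean = (cum[starts_kb + window_kb] - cum[starts_kb]) / window_kb
    starts = starts_kb * 1000
    ends = starts + window_kb * 1000
    chroms = np.full(len(starts), chrom)
    tmax = t.max()
    return TimingProfile(chroms, starts, ends, mean / tmax if tmax > 0 else mean,
                         mean / 60.0, np.zeros(len(starts), dtype=bool),
                         step_kb=float(step_kb), window_kb=float(window_kb))


def bin_counts(counts_per_kb: np.ndarray, window_kb: int = 100, step_kb: int = 100,
               chrom: str = "chr1") -> FractionDensities:
    """Aggregate per-kb, per-fraction counts into (sliding) windows.

    ``counts_per_kb`` is (n_positions, n_fractions) at 1-kb resolution.
    Windows of ``window_kb`` are placed every ``step_kb`` (tiled when equal,
    sliding when step < window), dropping any final partial window.
    """
    counts = np.asarray(counts_per_kb, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts_per_kb must be (n_positions, n_fractions)")
    n_pos = counts.shape[0]
    if n_pos < window_kb:
        raise ValueError("genome shorter than one window")
    cum = np.concatenate([np.zeros((1, counts.shape[1])), np.cumsum(counts, axis=0)])
    starts_kb = np.arange(0, n_pos - window_kb + 1, step_kb)
    vals = cum[starts_kb + window_kb] - cum[starts_kb]
    starts = starts_kb * 1000
    ends = starts + window_kb * 1000
    chroms = np.full(len(starts), chrom)
    return FractionDensities(chroms, starts, ends, vals,
                             window_kb=float(window_kb), step_kb=float(step_kb))
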