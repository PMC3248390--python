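"""Multiscale apparent replication speed and CTR/TTR segmentation.

The population timing profile t(x) has slope dt/dx = (R - L)/v, where v is
the single-fork velocity and R, L are the fractions of cells in which the
locus is replicated by a rightward or leftward fork.  The apparent
replication speed is the inverse of that slope, v/(R - L): it equals v only
where all forks move one way and diverges where forks move equally in both
directions.

Because the measured profile is noisy, the slope is estimated at a chosen
length scale by correlation with a first-derivative-of-Gaussian kernel (a
continuous-wavelet-style smoothed differentiator).  The kernel standard
deviation is scale/2, so roughly 95% of its mass spans the nominal scale,
and its weights are normalized so an exactly affine profile returns its
exact slope at machine precision.  The genome is then segmented, per scale,
into constant timing regions (CTR, |apparent speed| above a threshold,
default 10 kb/min) and timing transition regions (TTR, at or below it),
with ties going to TTR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timing import TimingProfile

__all__ = [
    "SpeedMap",
    "Segment",
    "SegmentSet",
    "TTRStats",
    "wt_slope",
    "build_speed_map",
    "speed_classes",
    "segment_ctr_ttr",
    "ttr_stats",
    "unidirectional_compatibility",
    "SPEED_CAP",
]

#: reported speed for numerically flat profiles (|slope| < 1e-6 min/kb)
SPEED_CAP = 1e3
DEFAULT_SCALES = (100.0, 200.0, 500.0)
DEFAULT_THRESHOLD = 10.0  # kb/min


def _dog_kernel(sd_bins: float) -> np.ndarray:
    """First-derivative-of-Gaussian weights, normalized so that correlating
    with a linear ramp of unit slope (per bin) returns exactly 1."""
    half = max(int(np.ceil(4.0 * sd_bins)), 1)
    j = np.arange(-half, half + 1, dtype=float)
    w = j * np.exp(-0.5 * (j / sd_bins) ** 2)
    return w / np.sum(j * w)


def _contiguous_runs(chroms: np.ndarray, starts: np.ndarray, mask: np.ndarray,
                     step_bp: int):
    """Yield (i0, i1) slices of unmasked, same-chromosome, contiguous bins."""
    n = len(starts)
    i = 0
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i + 1
        while (j < n and not mask[j] and chroms[j] == chroms[i]
               and starts[j] - starts[j - 1] == step_bp):
            j += 1
        yield i, j
        i = j


def wt_slope(profile: TimingProfile, scale_kb: float) -> tuple[np.ndarray, np.ndarray]:
    """Timing slope dt/dx (min/kb) per bin at one scale.

    Returns ``(slope, mask)``; bins within half a kernel of a profile edge
    or gap are masked, as are bins masked in the profile itself.
    """
    if np.all(profile.mask):
        raise ValueError("profile is entirely masked")
    step_kb = profile.step_kb
    sd_bins = (scale_kb / 2.0) / step_kb
    kernel = _dog_kernel(sd_bins)
    half = (len(kernel) - 1) // 2
    t_min = profile.tr50 * 60.0  # hours -> minutes

    slope = np.full(len(t_min), np.nan)
    out_mask = np.ones(len(t_min), dtype=bool)
    step_bp = int(round(step_kb * 1000))
    for i0, i1 in _contiguous_runs(profile.chroms, profile.starts, profile.mask, step_bp):
        seg = t_min[i0:i1]
        if len(seg) < len(kernel):
            continue
        # correlation: slope[i] = sum_j w_j * t[i+j]
        vals = np.convolve(seg, kernel[::-1], mode="valid") / step_kb
        slope[i0 + half:i1 - half] = vals
        out_mask[i0 + half:i1 - half] = False
    return slope, out_mask


@dataclass
class SpeedMap:
    """Signed apparent replication speed per bin per scale."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    scales: tuple[float, ...]          # kb
    slope: np.ndarray                  # (n_scales, n_bins), min/kb
    mask: np.ndarray                   # (n_scales, n_bins)
    step_kb: float
    window_kb: float = None

    def __post_init__(self):
        if self.window_kb is None:
            self.window_kb = self.step_kb

    def scale_index(self, scale_kb: float) -> int:
        for i, s in enumerate(self.scales):
            if np.isclose(s, scale_kb):
                return i
        raise KeyError(f"scale {scale_kb} kb not in map (have {self.scales})")

    def apparent_speed(self, scale_kb: float) -> np.ndarray:
        """Signed speed 1/slope, kb/min, capped at +/-SPEED_CAP on flats."""
        sl = self.slope[self.scale_index(scale_kb)]
        with np.errstate(divide="ignore", invalid="ignore"):
            speed = np.where(np.abs(sl) < 1e-6, np.sign(sl) * SPEED_CAP +
                             np.where(sl == 0, SPEED_CAP, 0.0), 1.0 / sl)
        # sign(0) = 0 would zero the cap; make flat bins +cap
        speed = np.where(np.abs(sl) < 1e-6, np.where(sl < 0, -SPEED_CAP, SPEED_CAP), speed)
        return speed


def build_speed_map(profile: TimingProfile,
                    scales: tuple[float, ...] = DEFAULT_SCALES) -> SpeedMap:
    """Slope and apparent speed at each requested scale."""
    slopes = []
    masks = []
    for sc in scales:
        sl, mk = wt_slope(profile, sc)
        slopes.append(sl)
        masks.append(mk)
    return SpeedMap(profile.chroms, profile.starts, profile.ends, tuple(scales),
                    np.vstack(slopes), np.vstack(masks), profile.step_kb,
                    getattr(profile, "window_kb", profile.step_kb))


def speed_classes(speed_map: SpeedMap, scale_kb: float,
                  bounds: tuple[float, float] = (2.0, 10.0)) -> tuple[float, float, float]:
    """Fractions of unmasked bins with |speed| <=2, 2-10 and >10 kb/min."""
    i = speed_map.scale_index(scale_kb)
    speed = np.abs(speed_map.apparent_speed(scale_kb)[~speed_map.mask[i]])
    if len(speed) == 0:
        return (np.nan, np.nan, np.nan)
    lo, hi = bounds
    slow = np.mean(speed <= lo)
    mid = np.mean((speed > lo) & (speed <= hi))
    fast = np.mean(speed > hi)
    return float(slow), float(mid), float(fast)


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class Segment:
    chrom: str
    start: int     # bp
    end: int       # bp
    klass: str     # "CTR" or "TTR"
    bin_slice: tuple[int, int] = None  # bin index range in the source profile

    @property
    def length_kb(self) -> float:
        return (self.end - self.start) / 1000.0


@dataclass
class SegmentSet:
    scale_kb: float
    threshold: float
    segments: list[Segment]

    def of_class(self, klass: str) -> list[Segment]:
        return [s for s in self.segments if s.klass == klass]


def segment_ctr_ttr(speed_map: SpeedMap, scale_kb: float,
                    threshold: float = DEFAULT_THRESHOLD) -> SegmentSet:
    """Partition the unmasked support into CTRs and TTRs at one scale.

    Maximal runs with |apparent speed| > threshold become CTRs, runs at or
    below the threshold become TTRs; runs are split at masked gaps and
    chromosome boundaries.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    i = speed_map.scale_index(scale_kb)
    speed = np.abs(speed_map.apparent_speed(scale_kb))
    mask = speed_map.mask[i]
    is_ttr = speed <= threshold * (1.0 + 1e-9)  # ties to TTR
    segments: list[Segment] = []
    step_bp = int(round(speed_map.step_kb * 1000))
    # with sliding windows each bin stands for the step-sized interval at
    # its window center, so that segments tile the support without overlap
    off_bp = int(round((speed_map.window_kb - speed_map.step_kb) * 500))
    for i0, i1 in _contiguous_runs(speed_map.chroms, speed_map.starts, mask, step_bp):
        k = i0
        while k < i1:
            j = k + 1
            while j < i1 and is_ttr[j] == is_ttr[k]:
                j += 1
            segments.append(Segment(
                chrom=str(speed_map.chroms[k]),
                start=int(speed_map.starts[k]) + off_bp,
                end=int(speed_map.starts[j - 1]) + off_bp + step_bp,
                klass="TTR" if is_ttr[k] else "CTR",
                bin_slice=(k, j),
            ))
            k = j
    return SegmentSet(scale_kb=scale_kb, threshold=threshold, segments=segments)


@dataclass
class TTRStats:
    segment: Segment
    dx_kb: float
    dt_min: float
    orientation: str               # "left" if the early edge is the left end
    mean_speed: float              # Dx/Dt, kb/min
    offset_speeds: dict[float, float]  # |speed| at distances from the early edge
    degenerate: bool = False       # Dt == 0 (mislabeled TTR)


def ttr_stats(segment: Segment, profile: TimingProfile, speed_map: SpeedMap,
              scale_kb: float,
              offsets_kb: tuple[float, ...] = (100.0, 200.0, 300.0, 400.0)) -> TTRStats:
    """Per-TTR size, time span, mean speed and along-gradient speeds.

    Dt is the TR50 difference across the segment; profile values sit at
    window centers, so the edge-bin difference (which spans Dx minus one
    step) is linearly extrapolated to the full segment extent.  The early
    edge is the one with the smaller TR50.  Offset speeds are read from the
    speed map at the bins ``offset`` kb from the early edge (missing when
    the offset exceeds the TTR length).
    """
    if segment.klass != "TTR":
        raise ValueError("ttr_stats expects a TTR segment")
    k0, k1 = segment.bin_slice
    tr = profile.tr50 * 60.0
    t_left, t_right = tr[k0], tr[k1 - 1]
    dx = segment.length_kb
    dt = abs(t_right - t_left)
    if k1 - k0 >= 2 and dx > speed_map.step_kb:
        dt *= dx / (dx - speed_map.step_kb)
    orientation = "left" if t_left <= t_right else "right"
    i = speed_map.scale_index(scale_kb)
    speed = np.abs(speed_map.apparent_speed(scale_kb))
    step = speed_map.step_kb
    offset_speeds: dict[float, float] = {}
    for off in offsets_kb:
        if off > dx:
            offset_speeds[off] = np.nan
            continue
        nb = int(round(off / step))
        idx = k0 + nb if orientation == "left" else k1 - 1 - nb
        idx = min(max(idx, k0), k1 - 1)
        offset_speeds[off] = float(speed[idx]) if not speed_map.mask[i, idx] else np.nan
    degenerate = dt <= 0
    return TTRStats(
        segment=segment, dx_kb=dx, dt_min=dt, orientation=orientation,
        mean_speed=dx / dt if dt > 0 else np.inf,
        offset_speeds=offset_speeds, degenerate=degenerate,
    )


def unidirectional_compatibility(stats: TTRStats, v_max: float = 2.0) -> bool:
    """True iff the TTR could be replicated by one fork at <= v_max kb/min."""
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    return bool(stats.mean_speed <= v_max)
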