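"""Interval-feature analytics over CTRs/TTRs and timing profiles.

Coverage of replication segments by origin-mapping signals (replication
bubbles, lambda-exonuclease-resistant short nascent strands) and open
chromatin markers (DNase I hypersensitive sites, CpG islands), coverage as
a function of replication time, and feature gradients measured along TTRs
from their early border.

All intervals are 0-based half-open (BED convention).  Features are merged
before any coverage computation so overlapping annotations are never double
counted; interval algebra is delegated to pyranges.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import pyranges as pr

from .speedscale import Segment, TTRStats
from .timing import TimingProfile

__all__ = [
    "FeatureSet",
    "enlarge",
    "coverage",
    "coverage_by_timing",
    "profile_along_ttrs",
    "DEFAULT_SIZE_CLASSES",
]

#: TTR size classes (kb) used for along-TTR feature gradients
DEFAULT_SIZE_CLASSES = ((0.0, 200.0), (200.0, 360.0), (360.0, np.inf))


@dataclass
class FeatureSet:
    """A sorted, per-chromosome set of genomic intervals."""

    ranges: pr.PyRanges

    @classmethod
    def from_arrays(cls, chroms, starts, ends) -> "FeatureSet":
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(starts >= ends):
            raise ValueError("feature starts must be < ends")
        df = pd.DataFrame({"Chromosome": np.asarray(chroms), "Start": starts,
                           "End": ends})
        return cls(pr.PyRanges(df).sort())

    @property
    def df(self) -> pd.DataFrame:
        return self.ranges.df

    def __len__(self) -> int:
        return len(self.ranges)

    def merged(self) -> "FeatureSet":
        return FeatureSet(self.ranges.merge())

    def total_length(self) -> int:
        m = self.merged().df
        return int((m.End - m.Start).sum()) if len(m) else 0


def enlarge(features: FeatureSet, pad_kb: float, chrom_sizes: dict[str, int]) -> FeatureSet:
    """Extend every interval by ``pad_kb`` on both sides, clip to chromosome
    bounds, and merge the result."""
    if pad_kb < 0:
        raise ValueError("pad must be non-negative")
    pad = int(round(pad_kb * 1000))
    df = features.df.copy()
    for chrom in df.Chromosome.unique():
        if str(chrom) not in chrom_sizes:
            raise KeyError(f"no chromosome size for {chrom!r}")
    sizes = df.Chromosome.astype(str).map(chrom_sizes).to_numpy()
    df["Start"] = np.maximum(df.Start.to_numpy() - pad, 0)
    df["End"] = np.minimum(df.End.to_numpy() + pad, sizes)
    return FeatureSet(pr.PyRanges(df).merge())


def _overlap_lengths(features: FeatureSet, chroms, starts, ends) -> np.ndarray:
    """Merged-feature overlap length (bp) for each target interval."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    targets = pd.DataFrame({
        "Chromosome": np.asarray(chroms), "Start": starts, "End": ends,
        "_idx": np.arange(len(starts)),
    })
    joined = pr.PyRanges(targets).join(features.merged().ranges)
    out = np.zeros(len(starts))
    if len(joined) == 0:
        return out
    j = joined.df
    ov = (np.minimum(j.End, j.End_b) - np.maximum(j.Start, j.Start_b)).to_numpy()
    np.add.at(out, j["_idx"].to_numpy(), np.maximum(ov, 0))
    return out


def coverage(features: FeatureSet, chroms, starts, ends) -> np.ndarray:
    """Fraction of each target interval covered by the merged features."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    lengths = ends - starts
    if np.any(lengths <= 0):
        raise ValueError("zero-length target interval")
    return _overlap_lengths(features, chroms, starts, ends) / lengths


def segment_coverage(features: FeatureSet, segments: list[Segment]) -> np.ndarray:
    """Feature coverage fraction of each CTR/TTR segment."""
    return coverage(features,
                    [s.chrom for s in segments],
                    [s.start for s in segments],
                    [s.end for s in segments])


def coverage_by_timing(features: FeatureSet, profile: TimingProfile) -> pd.DataFrame:
    """(TR50, coverage) per unmasked profile window."""
    ok = ~profile.mask
    cov = coverage(features, profile.chroms[ok], profile.starts[ok], profile.ends[ok])
    return pd.DataFrame({
        "chrom": profile.chroms[ok], "start": profile.starts[ok],
        "end": profile.ends[ok], "tr50_h": profile.tr50[ok], "coverage": cov,
    })


def profile_along_ttrs(
    features: FeatureSet,
    ttrs: list[TTRStats],
    genome_coverage: float,
    size_classes: tuple[tuple[float, float], ...] = DEFAULT_SIZE_CLASSES,
    bin_kb: float = 20.0,
    max_distance_kb: float | None = None,
) -> pd.DataFrame:
    """Mean relative feature coverage vs distance from each TTR's early edge.

    Each TTR is traversed from its early border toward its late border in
    ``bin_kb`` windows (bins beyond a TTR's own length contribute nothing);
    coverage per distance bin is averaged over the TTRs of each size class
    and divided by the genome-wide average coverage.  Empty size classes are
    omitted with a warning.
    """
    if genome_coverage <= 0:
        raise ValueError("genome-wide coverage must be positive")
    if max_distance_kb is None:
        max_distance_kb = max((t.dx_kb for t in ttrs), default=0.0)
    n_bins = int(np.ceil(max_distance_kb / bin_kb))
    rows = []
    for lo, hi in size_classes:
        members = [t for t in ttrs if lo <= t.dx_kb < hi]
        if not members:
            warnings.warn(f"no TTRs in size class [{lo}, {hi}) kb; omitted")
            continue
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        chroms, starts, ends, which = [], [], [], []
        for t in members:
            seg = t.segment
            k = int(np.ceil(t.dx_kb / bin_kb))
            for b in range(min(k, n_bins)):
                d0, d1 = b * bin_kb, min((b + 1) * bin_kb, t.dx_kb)
                if d1 <= d0:
                    continue
                if t.orientation == "left":
                    s = seg.start + int(round(d0 * 1000))
                    e = seg.start + int(round(d1 * 1000))
                else:
                    e = seg.end - int(round(d0 * 1000))
                    s = seg.end - int(round(d1 * 1000))
                chroms.append(seg.chrom)
                starts.append(s)
                ends.append(e)
                which.append(b)
        if chroms:
            cov = coverage(features, chroms, starts, ends)
            np.add.at(sums, which, cov)
            np.add.at(counts, which, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(counts > 0, sums / np.maximum(counts, 1) / genome_coverage,
                           np.nan)
        for b in range(n_bins):
            if counts[b] > 0:
                rows.append({
                    "size_class": f"[{lo:g},{hi:g}) kb",
                    "distance_kb": (b + 0.5) * bin_kb,
                    "relative_coverage": rel[b],
                    "n_ttrs": int(counts[b]),
                })
    return pd.DataFrame(rows)
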