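"""File formats: bedGraph/BED for profiles and intervals, TSV for fibers,
CSV for FACS histograms.

All genomic coordinates on disk are 0-based half-open.  Output files carry a
one-line provenance header (``# replikinetics ... seed=... config=...``);
comment lines beginning with ``#`` and bedGraph ``track`` lines are ignored
on input.  Malformed lines raise with their line number.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
import pandas as pd

from . import __version__
from .annotate import FeatureSet
from .combing import FiberRecord, Track
from .facs import FACSHistogram
from .timing import FractionDensities, TimingProfile

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_fraction_table",
    "write_fraction_table",
    "read_timing_profile",
    "write_timing_profile",
    "read_fibers",
    "write_fibers",
    "read_facs",
    "write_facs",
    "read_bed",
    "write_segments_bed",
    "provenance_header",
]


def provenance_header(stage: str, seed=None, config_text: str | None = None) -> str:
    parts = [f"# replikinetics {__version__}", f"stage={stage}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_text is not None:
        parts.append(f"config_sha1={hashlib.sha1(config_text.encode()).hexdigest()[:12]}")
    return " ".join(parts)


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def _warn_if_one_based(starts: np.ndarray, ends: np.ndarray, chroms: np.ndarray,
                       path) -> None:
    """Heuristic flag for 1-based, fully-closed coordinates.

    0-based half-open tiled bins abut exactly (next start == previous end);
    1-based closed intervals read naively leave systematic 1-bp gaps and
    never start at 0.
    """
    if len(starts) < 3 or starts.min() == 0:
        return
    order = np.lexsort((starts, chroms))
    s, e, c = starts[order], ends[order], chroms[order]
    same = c[1:] == c[:-1]
    gaps = (s[1:] - e[:-1])[same]
    if len(gaps) and np.mean(gaps == 1) > 0.9:
        warnings.warn(f"{path}: intervals look 1-based fully-closed "
                      "(systematic 1-bp gaps); expected 0-based half-open")


def read_bedgraph(path) -> pd.DataFrame:
    """Four-column numeric bedGraph -> DataFrame(chrom, start, end, value)."""
    rows = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    if len(df):
        if np.any(df.start.to_numpy() >= df.end.to_numpy()):
            bad = int(np.argmax(df.start.to_numpy() >= df.end.to_numpy()))
            raise ValueError(f"{path}: interval {bad} has start >= end")
        _warn_if_one_based(df.start.to_numpy(), df.end.to_numpy(),
                           df.chrom.to_numpy(), path)
    return df


def write_bedgraph(path, chroms, starts, ends, values, stage: str = "export",
                   seed=None, precision: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, seed=seed) + "\n")
        for c, s, e, v in zip(chroms, starts, ends, values):
            fh.write(f"{c}\t{int(s)}\t{int(e)}\t{v:.{precision}g}\n")


# ---------------------------------------------------------------------------
# fraction densities


def write_fraction_table(path, fd: FractionDensities, stage: str = "simulate",
                         seed=None) -> None:
    n = fd.n_fractions
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, seed=seed) +
                 f" window_kb={fd.window_kb:g} step_kb={fd.step_kb:g}\n")
        fh.write("chrom\tstart\tend\t" + "\t".join(f"S{i+1}" for i in range(n)) + "\n")
        ok = ~fd.mask
        for c, s, e, row in zip(fd.chroms[ok], fd.starts[ok], fd.ends[ok], fd.values[ok]):
            fh.write(f"{c}\t{int(s)}\t{int(e)}\t" +
                     "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_fraction_table(path) -> FractionDensities:
    """TSV with header chrom/start/end/S1..Sn -> FractionDensities."""
    window_kb = step_kb = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.split():
            if tok.startswith("window_kb="):
                window_kb = float(tok.split("=", 1)[1])
            elif tok.startswith("step_kb="):
                step_kb = float(tok.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    frac_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    if not frac_cols:
        raise ValueError(f"{path}: no fraction columns found")
    starts = df.start.to_numpy(np.int64)
    ends = df.end.to_numpy(np.int64)
    if window_kb is None and len(df):
        window_kb = float((ends[0] - starts[0]) / 1000)
    if step_kb is None and len(df) > 1:
        step_kb = float((starts[1] - starts[0]) / 1000)
    _warn_if_one_based(starts, ends, df.chrom.to_numpy(), path)
    return FractionDensities(df.chrom.to_numpy(), starts, ends,
                             df[frac_cols].to_numpy(float),
                             window_kb=window_kb or 100.0, step_kb=step_kb or 100.0)


# ---------------------------------------------------------------------------
# timing profiles


def write_timing_profile(path, profile: TimingProfile, stage: str = "timing",
                         seed=None) -> None:
    """TSV with S50 and TR50 columns; masked bins are omitted."""
    ok = ~profile.mask
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, seed=seed) +
                 f" step_kb={profile.step_kb:g}\n")
        fh.write("chrom\tstart\tend\ts50\ttr50_h\n")
        for c, s, e, s5, tr in zip(profile.chroms[ok], profile.starts[ok],
                                   profile.ends[ok], profile.s50[ok], profile.tr50[ok]):
            fh.write(f"{c}\t{int(s)}\t{int(e)}\t{s5:.6g}\t{tr:.6g}\n")


def read_timing_profile(path) -> TimingProfile:
    step_kb = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.split():
            if tok.startswith("step_kb="):
                step_kb = float(tok.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    if step_kb is None and len(df) > 1:
        step_kb = float((df.start.iloc[1] - df.start.iloc[0]) / 1000)
    return TimingProfile(df.chrom.to_numpy(), df.start.to_numpy(np.int64),
                         df.end.to_numpy(np.int64), df.s50.to_numpy(float),
                         df.tr50_h.to_numpy(float),
                         np.zeros(len(df), dtype=bool), step_kb=step_kb or 100.0)


# ---------------------------------------------------------------------------
# fibers


FIBER_COLUMNS = ("fiber_id", "compartment", "fiber_length_kb", "track_index",
                 "label", "start_kb", "end_kb")


def write_fibers(path, fibers: list[FiberRecord], stage: str = "simulate",
                 seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, seed=seed) + "\n")
        fh.write("\t".join(FIBER_COLUMNS) + "\n")
        for f in fibers:
            for i, tr in enumerate(f.tracks):
                fh.write(f"{f.fiber_id}\t{f.compartment}\t{f.length:g}\t{i}\t"
                         f"{tr.label}\t{tr.start:g}\t{tr.end:g}\n")


def read_fibers(path) -> list[FiberRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(FIBER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing fiber columns {sorted(missing)}")
    fibers = []
    for fid, group in df.groupby("fiber_id", sort=False):
        group = group.sort_values("track_index")
        tracks = [Track(label=r.label, start=float(r.start_kb), end=float(r.end_kb))
                  for r in group.itertuples()]
        try:
            fibers.append(FiberRecord(
                fiber_id=str(fid),
                compartment=str(group.compartment.iloc[0]),
                length=float(group.fiber_length_kb.iloc[0]),
                tracks=tracks,
            ))
        except ValueError as exc:
            raise ValueError(f"{path}: fiber {fid}: {exc}") from None
    return fibers


# ---------------------------------------------------------------------------
# FACS histograms


def write_facs(path, hist: FACSHistogram, stage: str = "simulate", seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, seed=seed) +
                 f" theta1={hist.theta1:g} theta2={hist.theta2:g}\n")
        fh.write("bin_center,count\n")
        for c, n in zip(hist.bin_centers, hist.counts):
            fh.write(f"{c:.6g},{n:g}\n")


def read_facs(path) -> FACSHistogram:
    theta1 = theta2 = np.nan
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.split():
            if tok.startswith("theta1="):
                theta1 = float(tok.split("=", 1)[1])
            elif tok.startswith("theta2="):
                theta2 = float(tok.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    if not {"bin_center", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns bin_center,count")
    return FACSHistogram(df.bin_center.to_numpy(float), df["count"].to_numpy(float),
                         theta1=theta1, theta2=theta2)


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> FeatureSet:
    rows = []
    for lineno, line in _data_lines(path):
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
        try:
            rows.append((parts[0], int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        return FeatureSet.from_arrays(np.array([], dtype=str),
                                      np.array([], dtype=np.int64),
                                      np.array([], dtype=np.int64))
    chroms, starts, ends = zip(*rows)
    return FeatureSet.from_arrays(np.array(chroms), np.array(starts), np.array(ends))


def write_segments_bed(path, segset, stage: str = "segment", seed=None) -> None:
    """CTR/TTR intervals as BED with the class in the name field."""
    with open(path, "w") as fh:
        fh.write(provenance_header(stage, seed=seed) +
                 f" scale_kb={segset.scale_kb:g} threshold={segset.threshold:g}\n")
        for seg in segset.segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.klass}\n")
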