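"""Depth-table IO, window aggregation, breadth of coverage, iterative
normalization and contig split-point detection."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DepthTrack, Sex

__all__ = [
    "CoverageSummary",
    "SplitPoint",
    "read_depth",
    "write_depth",
    "breadth_coverage",
    "iterative_normalize",
    "find_split_points",
]


@dataclass(frozen=True)
class CoverageSummary:
    """Breadth of coverage of a region: fraction of sites covered at all."""

    region_id: str
    covered_sites: int
    region_length: int

    @property
    def coverage(self) -> float:
        return breadth_coverage(self.covered_sites, self.region_length)


@dataclass(frozen=True)
class SplitPoint:
    """Candidate assembly split: a sub-threshold depth trough between two
    regions that both exceed the threshold."""

    contig_id: str
    position: int  # 1-based first base of the first sub-threshold window
    left_depth: float
    trough_depth: float
    right_depth: float


def breadth_coverage(covered_sites: int, region_length: int) -> float:
    """Breadth of coverage N/G: covered sites over region length."""
    if region_length <= 0:
        raise ValueError("region length G must be > 0")
    if not 0 <= covered_sites <= region_length:
        raise ValueError("covered sites N must satisfy 0 <= N <= G")
    return covered_sites / region_length


def read_depth(
    path,
    window_size: int = 10_000,
    sex: Sex = Sex.MALE,
    base_depth: float = 100.0,
) -> list[DepthTrack]:
    """Read a depth TSV and aggregate to fixed windows.

    Accepts samtools-depth-style 3-column per-base rows (contig, 1-based
    position, depth) or 3-column windowed rows where positions step by
    ``window_size`` (window start positions); 4-column rows (contig, start,
    end, depth) are treated as windowed. Per-base rows are averaged per
    window with missing positions counted as depth 0; a short terminal
    window is averaged over its own length (to the last observed position).
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] == 4:
        df.columns = ["contig", "start", "end", "depth"]
        windowed = True
    elif df.shape[1] == 3:
        df.columns = ["contig", "start", "depth"]
        # windowed rows sit exactly on the window grid; per-base rows do not
        windowed = bool(((df["start"] - 1) % window_size == 0).all())
    else:
        raise ValueError(f"expected 3 or 4 columns, got {df.shape[1]}")

    if (df["depth"] < 0).any():
        row = int(np.argmax(df["depth"].to_numpy() < 0))
        raise ValueError(f"negative depth at row {row + 1}")
    # sortedness: within each contig, positions strictly increasing
    for _, grp in df.groupby("contig", sort=False):
        pos = grp["start"].to_numpy()
        bad = np.diff(pos) <= 0
        if bad.any():
            row = int(grp.index[int(np.argmax(bad)) + 1])
            raise ValueError(f"unsorted positions at row {row + 1}")

    tracks: list[DepthTrack] = []
    for cid, grp in df.groupby("contig", sort=False):
        if windowed:
            depths = grp["depth"].to_numpy(dtype=float)
        else:
            pos = grp["start"].to_numpy(dtype=np.int64)
            dep = grp["depth"].to_numpy(dtype=float)
            last = int(pos[-1])
            nw = math.ceil(last / window_size)
            sums = np.zeros(nw)
            np.add.at(sums, (pos - 1) // window_size, dep)
            lens = np.full(nw, window_size, dtype=float)
            lens[-1] = last - (nw - 1) * window_size
            depths = sums / lens
        tracks.append(
            DepthTrack(
                contig_id=str(cid),
                sex=sex,
                window_size=window_size,
                depths=depths,
                base_depth=base_depth,
            )
        )
    return tracks


def write_depth(tracks: list[DepthTrack], path) -> None:
    """Write windowed depth as 3-column TSV (contig, 1-based window start, depth)."""
    from .synthetic_data import write_depth_tsv

    write_depth_tsv(tracks, path)


def _trimmed_mean(x: np.ndarray, trim: float) -> float:
    lo, hi = np.quantile(x, [trim, 1 - trim])
    sel = x[(x >= lo) & (x <= hi)]
    return float(sel.mean()) if sel.size else float(x.mean())


def iterative_normalize(
    track: DepthTrack,
    mappability_bias: np.ndarray | None = None,
    rounds: int = 3,
    trim: float = 0.1,
) -> DepthTrack:
    """Iterative proportional bias correction of a 1-D depth track.

    Each round divides every window by its current bias estimate — the
    provided mappability bias on the first round if given, otherwise the
    window's depth relative to the trimmed track mean — and rescales so the
    global mean is preserved. Three rounds reach convergence (subsequent
    rounds change windows by < 1e-6 relative). Assumes the underlying signal
    is uniform apart from multiplicative window biases; copy-number signal
    should not be normalized this way.

    An all-zero track is returned unchanged with a warning.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    d = track.depths.astype(float).copy()
    if not np.any(d > 0):
        warnings.warn(f"{track.contig_id}: all-zero depth track left unnormalized")
        return DepthTrack(track.contig_id, track.sex, track.window_size, d, track.base_depth)
    target_mean = d.mean()
    if mappability_bias is not None:
        bias = np.asarray(mappability_bias, dtype=float)
        if bias.shape != d.shape or np.any(bias <= 0):
            raise ValueError("mappability_bias must be positive and match the track")
        d = d / bias
        d *= target_mean / d.mean()
        rounds -= 1
    for _ in range(rounds):
        center = _trimmed_mean(d, trim)
        if center <= 0:
            break
        bias = np.where(d > 0, d / center, 1.0)
        d = d / bias
        d *= target_mean / d.mean()
    return DepthTrack(track.contig_id, track.sex, track.window_size, d, track.base_depth)


def find_split_points(
    track: DepthTrack, threshold: float = 30.0, min_flank_windows: int = 1
) -> list[SplitPoint]:
    """Detect depth troughs where a contig should be split.

    Emits one split per maximal run of windows with depth < ``threshold``
    that is flanked on both sides by at least ``min_flank_windows`` windows
    with depth >= threshold (a depth drop between two well-covered regions).
    Runs touching a contig edge are not splits. The reported position is the
    1-based first base of the first sub-threshold window.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    d = track.depths
    below = d < threshold
    splits: list[SplitPoint] = []
    i = 0
    n = d.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        # run [i, j); flanks must exist and be long enough
        left_ok = i >= min_flank_windows and not below[i - min_flank_windows : i].any()
        right_ok = j + min_flank_windows <= n and not below[j : j + min_flank_windows].any()
        if left_ok and right_ok:
            splits.append(
                SplitPoint(
                    contig_id=track.contig_id,
                    position=track.window_start(i),
                    left_depth=float(d[i - 1]),
                    trough_depth=float(d[i:j].min()),
                    right_depth=float(d[j]),
                )
            )
        i = j
    return splits


def write_split_bed(splits: list[SplitPoint], window_size: int, path) -> None:
    """Write split windows as BED (0-based half-open, one window per split)."""
    with open(path, "w") as fh:
        for s in splits:
            start0 = s.position - 1
            fh.write(f"{s.contig_id}\t{start0}\t{start0 + window_size}\tsplit\n")
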