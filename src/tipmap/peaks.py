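"""Ranked peak calling on probe intensity tracks.

A descending sequence of percentile thresholds is applied to the track's
unmasked log2-ratio distribution.  At any level, a candidate peak is a
maximal run of unmasked probes in which every probe exceeds an absolute
floor, consecutive probes lie within ``window_bp`` of each other, and at
least ``min_probes_above`` probes exceed the level's percentile threshold.
Because run segmentation depends only on the floor and the window, a peak
is reported once, with ``rank_threshold`` equal to the highest percentile
at which it qualifies; candidate detections at lower levels that overlap an
existing call merge into it.

The window constrains the gap between *consecutive supporting probes*
(start-to-start distance), which reproduces sliding-window behaviour
without an explicit step size.  "min probes > 4, all probes > 2" is read
as: >= ``min_probes_above`` probes above the percentile threshold AND every
probe in the run above the absolute ``floor_value``; both are parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["chrom", "start", "end", "intensity", "masked"]


@dataclass
class ProbeTrack:
    """Ordered genomic probes with log2-ratio intensities for one array channel.

    ``probes`` columns: chrom, start, end, intensity, masked.  Must be
    sorted by (chrom, start) with start < end and no duplicate (chrom,
    start) pairs.
    """

    probes: pd.DataFrame
    cell_line: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        df = self.probes
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"probe table missing columns {missing}")
        if not (df["start"] < df["end"]).all():
            raise ValueError("probe intervals must satisfy start < end")
        key = df[["chrom", "start"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, start) probes")
        order = df.sort_values(["chrom", "start"], kind="mergesort")
        if not (order.index == df.index).all():
            raise ValueError("probes must be sorted by (chrom, start)")

    def unmasked(self) -> pd.DataFrame:
        return self.probes.loc[~self.probes["masked"].astype(bool)]


@dataclass
class PeakParams:
    """Descending-threshold sliding-window settings.

    Defaults follow the published run settings: percent start 90, step 1,
    76 steps, 1500 bp window, >= 4 probes above threshold, absolute floor 2
    (log2-ratio), top 5000 peaks kept.
    """

    p_start: float = 90.0
    p_step: float = 1.0
    n_steps: int = 76
    window_bp: int = 1500
    min_probes_above: int = 4
    floor_value: float = 2.0
    max_peaks: int = 5000

    def __post_init__(self) -> None:
        if self.p_start - self.p_step * self.n_steps < 0:
            raise ValueError("p_start - p_step * n_steps must be >= 0")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if self.min_probes_above < 1:
            raise ValueError("min_probes_above must be >= 1")

    @property
    def levels(self) -> np.ndarray:
        """Percentile levels, descending: p_start, p_start - p_step, ..."""
        return self.p_start - self.p_step * np.arange(self.n_steps + 1)


@dataclass
class PeakCall:
    chrom: str
    start: int
    end: int
    rank_threshold: float
    n_probes: int
    max_intensity: float
    cell_line: str = ""
    family: str = ""
    peak_id: str = ""

    def overlaps(self, other: "PeakCall") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def mask_probes(
    track: ProbeTrack, repeat_intervals: list[tuple[str, int, int]]
) -> ProbeTrack:
    """Flag probes overlapping any repeat interval as masked.

    Masked probes are excluded from threshold statistics and peak support.
    An empty interval set returns the track unchanged.
    """
    if not repeat_intervals:
        return track
    df = track.probes.copy()
    masked = df["masked"].to_numpy(dtype=bool).copy()
    for chrom, iv_start, iv_end in repeat_intervals:
        sel = (
            (df["chrom"] == chrom)
            & (df["start"] < iv_end)
            & (df["end"] > iv_start)
        )
        masked |= sel.to_numpy()
    df["masked"] = masked
    return replace(track, probes=df)


def _runs(
    starts: np.ndarray, above_floor: np.ndarray, window_bp: int
) -> list[tuple[int, int]]:
    """Maximal runs (half-open index ranges) of above-floor probes whose
    consecutive start coordinates are within window_bp."""
    runs: list[tuple[int, int]] = []
    n = len(starts)
    i = 0
    while i < n:
        if not above_floor[i]:
            i += 1
            continue
        j = i + 1
        while (
            j < n
            and above_floor[j]
            and starts[j] - starts[j - 1] <= window_bp
        ):
            j += 1
        runs.append((i, j))
        i = j
    return runs


def call_peaks(track: ProbeTrack, params: PeakParams) -> list[PeakCall]:
    """Call ranked peaks on one track.

    Returns peaks sorted by descending ``rank_threshold``, then descending
    ``max_intensity``, then genome position, truncated to
    ``params.max_peaks``.  A track with fewer unmasked probes than
    ``min_probes_above`` yields an empty list.
    """
    um = track.unmasked()
    if len(um) < params.min_probes_above:
        logger.warning(
            "track %s/%s: %d unmasked probes < min_probes_above=%d; no peaks",
            track.cell_line, track.family, len(um), params.min_probes_above,
        )
        return []
    values = um["intensity"].to_numpy(dtype=float)
    levels = params.levels
    thresholds = np.percentile(values, levels)

    calls: list[PeakCall] = []
    for chrom, sub in um.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["intensity"].to_numpy(dtype=float)
        above_floor = vals > params.floor_value
        for i, j in _runs(starts, above_floor, params.window_bp):
            rv = vals[i:j]
            counts = (rv[:, None] > thresholds[None, :]).sum(axis=0)
            qual = counts >= params.min_probes_above
            if not qual.any():
                continue
            rank = float(levels[int(np.argmax(qual))])
            calls.append(
                PeakCall(
                    chrom=str(chrom),
                    start=int(starts[i]),
                    end=int(ends[j - 1]),
                    rank_threshold=rank,
                    n_probes=j - i,
                    max_intensity=float(rv.max()),
                    cell_line=track.cell_line,
                    family=track.family,
                )
            )
    calls = peak_overlap_merge(calls)
    calls.sort(key=lambda c: (-c.rank_threshold, -c.max_intensity, c.chrom, c.start))
    calls = calls[: params.max_peaks]
    for k, c in enumerate(calls):
        c.peak_id = f"{track.cell_line}_{track.family}_pk{k:05d}"
    return calls


def peak_overlap_merge(calls: list[PeakCall]) -> list[PeakCall]:
    """Deduplicate calls from one track across threshold levels.

    Overlapping calls merge transitively: coordinates extend to the union,
    the maximum rank_threshold is kept, and n_probes/max_intensity take the
    member maxima.  Output contains no two overlapping peaks.
    """
    out: list[PeakCall] = []
    for call in sorted(calls, key=lambda c: (c.chrom, c.start, c.end)):
        if out and out[-1].overlaps(call):
            prev = out[-1]
            out[-1] = replace(
                prev,
                start=min(prev.start, call.start),
                end=max(prev.end, call.end),
                rank_threshold=max(prev.rank_threshold, call.rank_threshold),
                n_probes=max(prev.n_probes, call.n_probes),
                max_intensity=max(prev.max_intensity, call.max_intensity),
            )
        else:
            out.append(replace(call))
    return out


def two_channel_log_ratio(
    red: np.ndarray, green: np.ndarray, family: str, eps: float = 1e-9
) -> np.ndarray:
    """Signed per-family intensity from raw two-channel values.

    Alu families are dye-labelled on the red channel and L1 on the green,
    so the track to call is log2(red/green) for Alu and the reciprocal for
    L1.
    """
    red = np.maximum(np.asarray(red, dtype=float), eps)
    green = np.maximum(np.asarray(green, dtype=float), eps)
    ratio = red / green if family.startswith("Alu") else green / red
    return np.log2(ratio)
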