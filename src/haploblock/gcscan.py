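"""Windowed GC-content profiling and z-score anomaly flagging.

GC-biased gene conversion preferentially fixes G/C alleles, so conversion
hotspots show locally elevated GC.  The scan profiles GC in a sliding
window (default 100 bp, 1-bp step), flags maximal runs of windows beyond a
z-score cut-off (default 2.5 SD above the per-gene mean) and associates
flagged intervals with nearby exon boundaries.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np

from .seq_core import Feature, SequenceRecord


@dataclass
class GCWindowScan:
    seq_id: str
    interval: tuple[int, int]
    window: int
    step: int
    gc: np.ndarray  # fraction per window; NaN where the window had no valid bases
    mean: float
    sd: float

    def window_start(self, i: int) -> int:
        return self.interval[0] + i * self.step


@dataclass
class GCAnomaly:
    interval: tuple[int, int]
    peak_z: float
    peak_gc: float
    nearest_boundary: tuple[str, int, int] | None = None  # (name, position, distance)


def gc_profile(
    seq: SequenceRecord,
    interval: tuple[int, int] | None = None,
    window: int = 100,
    step: int = 1,
) -> GCWindowScan:
    """GC fraction per sliding window over an interval.

    gc[i] = (G+C) / (A+C+G+T) in window i; N bases are excluded from the
    denominator, and an all-N window is recorded as NaN and excluded from
    the mean/sd baseline.
    """
    start, end = interval if interval is not None else (0, len(seq))
    if window > end - start:
        raise ValueError("window larger than scanned interval")
    sub = seq.seq[start:end]
    arr = np.frombuffer(sub.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_valid = arr != ord("N")
    gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
    valid_cum = np.concatenate([[0], np.cumsum(is_valid)])
    starts = np.arange(0, len(sub) - window + 1, step)
    gc_counts = gc_cum[starts + window] - gc_cum[starts]
    valid_counts = valid_cum[starts + window] - valid_cum[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(valid_counts > 0, gc_counts / np.maximum(valid_counts, 1), np.nan)
    finite = gc[np.isfinite(gc)]
    mean = float(finite.mean()) if finite.size else float("nan")
    sd = float(finite.std(ddof=0)) if finite.size else float("nan")
    return GCWindowScan(
        seq_id=seq.id, interval=(start, end), window=window, step=step,
        gc=gc, mean=mean, sd=sd,
    )


def flag_anomalies(
    scan: GCWindowScan, z_cutoff: float = 2.5, direction: str = "high"
) -> list[GCAnomaly]:
    """Merge windows beyond the z cut-off into maximal anomaly intervals.

    The interval of an anomaly is the union of its qualifying window spans.
    With sd == 0 there is no variation to flag; an empty list is returned
    with a warning.
    """
    if direction not in ("high", "low", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if not np.isfinite(scan.sd) or scan.sd == 0:
        print(f"warning: {scan.seq_id}: GC scan has no variation (sd=0)", file=sys.stderr)
        return []
    z = (scan.gc - scan.mean) / scan.sd
    if direction == "high":
        hit = z >= z_cutoff
    elif direction == "low":
        hit = z <= -z_cutoff
    else:
        hit = np.abs(z) >= z_cutoff
    hit = np.nan_to_num(hit, nan=False) if hit.dtype != bool else np.where(np.isfinite(z), hit, False)
    anomalies: list[GCAnomaly] = []
    i = 0
    n = len(hit)
    while i < n:
        if not hit[i]:
            i += 1
            continue
        j = i
        while j < n and hit[j]:
            j += 1
        lo = scan.window_start(i)
        hi = scan.window_start(j - 1) + scan.window
        zseg = z[i:j]
        peak = int(np.nanargmax(np.abs(zseg)))
        anomaly = GCAnomaly(
            interval=(lo, hi),
            peak_z=float(zseg[peak]),
            peak_gc=float(scan.gc[i + peak]),
        )
        # window spans are wider than the step, so nearby runs can overlap
        # in bp; merge them to keep anomaly intervals disjoint and maximal
        if anomalies and lo <= anomalies[-1].interval[1]:
            prev = anomalies[-1]
            keep = prev if abs(prev.peak_z) >= abs(anomaly.peak_z) else anomaly
            anomalies[-1] = GCAnomaly(
                interval=(prev.interval[0], max(prev.interval[1], hi)),
                peak_z=keep.peak_z,
                peak_gc=keep.peak_gc,
            )
        else:
            anomalies.append(anomaly)
        i = j
    return anomalies


def associate_boundaries(
    anomalies: list[GCAnomaly],
    features: list[Feature],
    max_dist: int = 200,
) -> list[GCAnomaly]:
    """Attach the closest exon boundary within ``max_dist`` to each anomaly.

    Distance is measured from the anomaly interval (0 if the boundary falls
    inside it).  Returns the same anomaly objects with ``nearest_boundary``
    filled in (or None).
    """
    boundaries: list[tuple[str, int]] = []
    for f in features:
        if f.kind == "exon":
            boundaries.append((f"{f.name}_start", f.start))
            boundaries.append((f"{f.name}_end", f.end))
    for a in anomalies:
        lo, hi = a.interval
        best = None
        for name, pos in boundaries:
            d = 0 if lo <= pos <= hi else min(abs(pos - lo), abs(pos - hi))
            if best is None or d < best[2]:
                best = (name, pos, d)
        a.nearest_boundary = best if best is not None and best[2] <= max_dist else None
    return anomalies


def write_anomalies_bed(anomalies: list[GCAnomaly], seq_id: str, path) -> None:
    """BED (0-based half-open) with z-score x100 in the score column."""
    with open(path, "w") as fh:
        for i, a in enumerate(anomalies):
            name = a.nearest_boundary[0] if a.nearest_boundary else f"anomaly{i + 1}"
            fh.write(
                f"{seq_id}\t{a.interval[0]}\t{a.interval[1]}\t{name}\t{int(round(a.peak_z * 100))}\t.\n"
            )


def write_profile_bedgraph(scan: GCWindowScan, path) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="GC_{scan.seq_id}"\n')
        for i, val in enumerate(scan.gc):
            if np.isfinite(val):
                s = scan.window_start(i)
                fh.write(f"{scan.seq_id}\t{s}\t{s + scan.step}\t{val:.4f}\n")
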