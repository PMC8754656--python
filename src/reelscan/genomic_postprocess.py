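"""Genomic-context statistics for called candidates.

Two summaries of how candidates sit in the genome:

* **window clustering** — enhancers typically span several protein
  footprints, so nearby candidate tiles are grouped: two candidates belong
  together when a single window (default 140 bp, four tile lengths) covers
  both entirely, chained by single linkage into clusters;
* **annotation density** — the number of candidates falling (>= 1 bp
  overlap) in each interval of an external annotation set (e.g. predicted
  enhancers), summarized as the mean count over non-empty intervals.

Plus BED interchange for candidates (absolute coordinates, BED6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "ClusterResult",
    "DensityResult",
    "cluster_candidates",
    "annotate_density",
    "export_candidates",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    source: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.name}: start must precede end")


@dataclass
class ClusterResult:
    window_bp: int
    clusters: list[list[str]]  # candidate names per cluster
    cluster_id: dict[str, int]
    fraction_clustered: float  # candidates in clusters of size >= 2


@dataclass
class DensityResult:
    per_interval: pd.DataFrame  # chrom, start, end, name, n_candidates
    mean_per_nonempty: float
    n_empty: int
    flags: list[str] = field(default_factory=list)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def cluster_candidates(
    candidates: list[Interval], window_bp: int = 140
) -> ClusterResult:
    """Single-linkage clustering by pairwise co-occupancy of a window.

    Two candidates are linked iff some window of ``window_bp`` contains
    both entirely, i.e. their joint span max(end) - min(start) is at most
    ``window_bp``; clusters are the connected components of that graph.
    """
    if candidates and window_bp < max(c.end - c.start for c in candidates):
        raise ValueError("window_bp must be at least the longest candidate length")
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i].chrom, candidates[i].start))
    uf = _UnionFind(len(candidates))
    for a_pos, i in enumerate(order):
        ci = candidates[i]
        for j in order[a_pos + 1 :]:
            cj = candidates[j]
            if cj.chrom != ci.chrom or cj.start > ci.start + window_bp:
                break
            if max(ci.end, cj.end) - min(ci.start, cj.start) <= window_bp:
                uf.union(i, j)
    groups: dict[int, list[str]] = {}
    for i, c in enumerate(candidates):
        groups.setdefault(uf.find(i), []).append(c.name)
    clusters = sorted(groups.values(), key=lambda g: g[0])
    cluster_id = {name: k for k, grp in enumerate(clusters) for name in grp}
    n = len(candidates)
    n_clustered = sum(len(g) for g in clusters if len(g) >= 2)
    return ClusterResult(
        window_bp=window_bp,
        clusters=clusters,
        cluster_id=cluster_id,
        fraction_clustered=n_clustered / n if n else float("nan"),
    )


def annotate_density(
    candidates: list[Interval], annotations: list[Interval]
) -> DensityResult:
    """Count candidates overlapping (>= 1 bp) each annotation interval.

    A candidate straddling two intervals is counted in both.  The summary
    mean is taken over intervals containing at least one candidate.
    """
    flags: list[str] = []
    if annotations and candidates:
        if not ({c.chrom for c in candidates} & {a.chrom for a in annotations}):
            flags.append("no shared chromosomes")
    rows = []
    for a in annotations:
        n = sum(
            1
            for c in candidates
            if c.chrom == a.chrom and c.start < a.end and c.end > a.start
        )
        rows.append(
            {"chrom": a.chrom, "start": a.start, "end": a.end, "name": a.name,
             "n_candidates": n}
        )
    per_interval = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "n_candidates"]
    )
    nonempty = per_interval[per_interval["n_candidates"] > 0] if rows else per_interval
    mean = float(nonempty["n_candidates"].mean()) if len(nonempty) else float("nan")
    n_empty = int(len(per_interval) - len(nonempty)) if rows else 0
    return DensityResult(
        per_interval=per_interval, mean_per_nonempty=mean, n_empty=n_empty, flags=flags
    )


def export_candidates(
    records: pd.DataFrame,
    chrom: str,
    region_start: int,
    region_end: int,
    coords: pd.DataFrame,
    bed_path: str | Path,
    tsv_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write candidate tiles as BED6 (absolute coordinates) plus a full TSV.

    ``records`` is the calling output indexed by tile_id (needs ``slope``
    and ``is_candidate``); ``coords`` maps tile_id to region-relative
    ``start``/``end``.  BED score = -slope min-max scaled to [0, 1000]
    over the exported candidates.  Returns the BED table.
    """
    cand = records[records["is_candidate"]].join(coords, how="left")
    if cand[["start", "end"]].isna().any().any():
        missing = cand.index[cand["start"].isna()].tolist()
        raise ValueError(f"no coordinates for candidate tiles {missing}")
    abs_start = cand["start"].astype(int) + region_start
    abs_end = cand["end"].astype(int) + region_start
    if (abs_end > region_end).any():
        raise ValueError("candidate coordinates overflow past the region end")
    neg = -cand["slope"].to_numpy(dtype=float)
    if len(neg) and np.ptp(neg) > 0:
        score = np.round((neg - neg.min()) / np.ptp(neg) * 1000).astype(int)
    else:
        score = np.full(len(neg), 1000, dtype=int)
    bed = pd.DataFrame(
        {
            "chrom": chrom,
            "start": abs_start.to_numpy(),
            "end": abs_end.to_numpy(),
            "name": cand.index,
            "score": score,
            "strand": "+",
        }
    )
    bed.to_csv(bed_path, sep="\t", index=False, header=False)
    if tsv_path is not None:
        records.join(coords, how="left").to_csv(tsv_path, sep="\t")
    return bed


def read_bed(path: str | Path, source: str = ".") -> list[Interval]:
    """Load a BED3+ file as a list of intervals (extra columns ignored)."""
    out: list[Interval] = []
    with open(path) as fh:
        for k, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{k}: malformed BED line {line!r}")
            name = parts[3] if len(parts) > 3 else f"interval_{k}"
            out.append(
                Interval(
                    chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                    name=name, source=source,
                )
            )
    return out


def write_bed(intervals: list[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
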