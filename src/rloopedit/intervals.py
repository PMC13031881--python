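"""Stranded genomic intervals and the overlap/proximity primitives built on them.

All coordinates are 0-based half-open, matching BED on disk.  A ``PeakSet``
wraps a pandas DataFrame with the BED6 columns (``contig``, ``start``,
``end``, ``name``, ``score``, ``strand``) and is the currency of every
integration step in the package.  Strand is ``'+'``, ``'-'`` or ``'.'``
(unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ["contig", "start", "end", "name", "score", "strand"]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class StrandedInterval:
    """A single half-open genomic interval with strand."""

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """A set of stranded intervals, stored as a BED6-shaped DataFrame.

    ``provenance`` optionally records, per peak, which replicate sets
    supported it (used by consensus construction).
    """

    df: pd.DataFrame
    provenance: list[set[str]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[BED_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"interval at row {bad} has start >= end")
        if len(df) and not df["strand"].isin(STRANDS).all():
            raise ValueError("strand column must be one of + - .")
        df = df.sort_values(["contig", "start", "end"], kind="stable").reset_index(
            drop=True
        )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield StrandedInterval(
                row.contig, int(row.start), int(row.end), row.strand, str(row.name), float(row.score)
            )

    @classmethod
    def from_intervals(cls, intervals: Iterable[StrandedInterval]) -> "PeakSet":
        rows = [
            (iv.contig, iv.start, iv.end, iv.name, iv.score, iv.strand)
            for iv in intervals
        ]
        return cls(pd.DataFrame(rows, columns=BED_COLUMNS))

    @classmethod
    def read_bed(cls, path: str | Path) -> "PeakSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=BED_COLUMNS,
            usecols=range(6),
            dtype={"contig": str, "name": str, "strand": str},
        )
        return cls(df)

    def write_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def subset(self, mask) -> "PeakSet":
        return PeakSet(self.df[np.asarray(mask)].reset_index(drop=True))

    def midpoints(self) -> pd.DataFrame:
        out = self.df.copy()
        out["midpoint"] = (out["start"] + out["end"]) // 2
        return out

    def validate_against(self, contig_lengths: dict[str, int]) -> None:
        """Raise if any interval falls outside its contig."""
        for contig, grp in self.df.groupby("contig"):
            if contig not in contig_lengths:
                raise ValueError(f"unknown contig {contig!r}")
            if int(grp["end"].max()) > contig_lengths[contig]:
                raise ValueError(f"interval exceeds length of contig {contig!r}")


# ---------------------------------------------------------------------------
# vectorised primitives
# ---------------------------------------------------------------------------


def _per_contig(df: pd.DataFrame):
    return {contig: grp for contig, grp in df.groupby("contig", sort=False)}


def gap_to_nearest(
    query: PeakSet, reference: PeakSet, stranded: bool = False
) -> np.ndarray:
    """Signed gap from each query interval to its nearest reference interval.

    Returns, per query, the end-to-end gap in bp to the closest reference
    on the same contig (and same strand in stranded mode): negative values
    mean the intervals share at least one base, 0 means they abut, and
    ``inf`` means no reference exists on that contig/strand.
    """
    out = np.full(len(query), np.inf)
    qdf = query.df
    rdf = reference.df
    for key, ridx in _reference_groups(rdf, stranded):
        r = rdf.loc[ridx]
        starts = r["start"].to_numpy()
        ends = r["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts = starts[order]
        # running max of ends in start order gives the nearest left edge
        cummax_end = np.maximum.accumulate(ends[order])
        qmask = _query_mask(qdf, key, stranded)
        if not qmask.any():
            continue
        qs = qdf.loc[qmask, "start"].to_numpy()
        qe = qdf.loc[qmask, "end"].to_numpy()
        idx = np.searchsorted(starts, qe, side="left")
        left = np.full(len(qs), np.inf)
        has_left = idx > 0
        left[has_left] = qs[has_left] - cummax_end[idx[has_left] - 1]
        right = np.full(len(qs), np.inf)
        has_right = idx < len(starts)
        right[has_right] = starts[idx[has_right]] - qe[has_right]
        out[np.flatnonzero(qmask)] = np.minimum(
            np.minimum(left, right), out[np.flatnonzero(qmask)]
        )
    return out


def _reference_groups(rdf: pd.DataFrame, stranded: bool):
    if stranded:
        for (contig, strand), grp in rdf.groupby(["contig", "strand"], sort=False):
            yield (contig, strand), grp.index
    else:
        for contig, grp in rdf.groupby("contig", sort=False):
            yield (contig, None), grp.index


def _query_mask(qdf: pd.DataFrame, key, stranded: bool) -> np.ndarray:
    contig, strand = key
    mask = (qdf["contig"] == contig).to_numpy()
    if stranded and strand is not None:
        mask &= (qdf["strand"] == strand).to_numpy()
    return mask


def overlaps_any(
    query: PeakSet, reference: PeakSet, stranded: bool = False
) -> np.ndarray:
    """Boolean per query: does it intersect (>=1 bp) any reference interval."""
    gaps = gap_to_nearest(query, reference, stranded=stranded)
    return gaps < 0


def count_overlapping(query: PeakSet, reference: PeakSet) -> np.ndarray:
    """Number of reference intervals each query interval intersects."""
    out = np.zeros(len(query), dtype=int)
    rgroups = _per_contig(reference.df)
    for contig, qgrp in query.df.groupby("contig", sort=False):
        if contig not in rgroups:
            continue
        r = rgroups[contig]
        rs = np.sort(r["start"].to_numpy())
        re = np.sort(r["end"].to_numpy())
        qs = qgrp["start"].to_numpy()
        qe = qgrp["end"].to_numpy()
        # refs with start < q.end, minus refs with end <= q.start
        n = np.searchsorted(rs, qe, side="left") - np.searchsorted(
            re, qs, side="right"
        )
        out[qgrp.index.to_numpy()] = n
    return out


def overlap_bases(query: PeakSet, reference: PeakSet) -> np.ndarray:
    """Bases of each query interval covered by the (merged) reference set."""
    merged = merge_intervals(reference, gap=0, per_strand=False)
    out = np.zeros(len(query), dtype=np.int64)
    rgroups = _per_contig(merged.df)
    for contig, qgrp in query.df.groupby("contig", sort=False):
        if contig not in rgroups:
            continue
        r = rgroups[contig]
        rs = r["start"].to_numpy()
        re = r["end"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(re - rs)])
        for i, (qs, qe) in zip(
            qgrp.index.to_numpy(), qgrp[["start", "end"]].to_numpy()
        ):
            lo = np.searchsorted(re, qs, side="right")
            hi = np.searchsorted(rs, qe, side="left")
            if hi <= lo:
                continue
            total = cum[hi] - cum[lo]
            total -= max(0, qs - rs[lo])
            total -= max(0, re[hi - 1] - qe)
            out[i] = total
    return out


def merge_intervals(
    peaks: PeakSet, gap: int = 0, per_strand: bool = True
) -> PeakSet:
    """Merge intervals whose end-to-end gap is <= ``gap``.

    With ``per_strand`` intervals on different strands are never merged
    (the same-strand merge rule used for consensus R-loop peaks).
    """
    if len(peaks) == 0:
        return PeakSet(pd.DataFrame(columns=BED_COLUMNS))
    rows = []
    keys = ["contig", "strand"] if per_strand else ["contig"]
    for key, grp in peaks.df.groupby(keys, sort=False):
        contig = key[0] if isinstance(key, tuple) else key
        strand = key[1] if per_strand and isinstance(key, tuple) else "."
        grp = grp.sort_values(["start", "end"], kind="stable")
        cur_s, cur_e = None, None
        for s, e in grp[["start", "end"]].to_numpy():
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s - cur_e <= gap:
                cur_e = max(cur_e, e)
            else:
                rows.append((contig, cur_s, cur_e, ".", 0.0, strand))
                cur_s, cur_e = s, e
        rows.append((contig, cur_s, cur_e, ".", 0.0, strand))
    return PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS))


def total_bases(peaks: PeakSet) -> int:
    return int((peaks.df["end"] - peaks.df["start"]).sum())


def points_to_peakset(
    contigs: Sequence[str],
    positions: Sequence[int],
    flank: int = 0,
    contig_lengths: dict[str, int] | None = None,
    strands: Sequence[str] | None = None,
) -> PeakSet:
    """Expand point positions (0-based) by +-flank into intervals, clipped to contigs."""
    positions = np.asarray(positions, dtype=np.int64)
    starts = np.maximum(positions - flank, 0)
    ends = positions + flank + 1
    if contig_lengths is not None:
        lens = np.array([contig_lengths[c] for c in contigs], dtype=np.int64)
        ends = np.minimum(ends, lens)
    df = pd.DataFrame(
        {
            "contig": list(contigs),
            "start": starts,
            "end": ends,
            "name": ".",
            "score": 0.0,
            "strand": list(strands) if strands is not None else ".",
        }
    )
    return PeakSet(df)
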