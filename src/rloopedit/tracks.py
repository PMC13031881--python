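"""Fixed-bin numeric signal tracks (GC-skew, G4 density, replication timing).

A :class:`SignalTrack` holds one float array per contig at a fixed bin
width.  Bins are left-aligned and 0-based; the last partial bin is kept.
Missing values are ``NaN`` and are skipped on bedGraph output and excluded
from profile means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class SignalTrack:
    bin_width: int
    contig_lengths: dict[str, int]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        for contig, length in self.contig_lengths.items():
            n = self.n_bins(contig)
            if contig not in self.values:
                self.values[contig] = np.full(n, np.nan)
            elif len(self.values[contig]) != n:
                raise ValueError(
                    f"track for {contig!r} has {len(self.values[contig])} bins, "
                    f"expected {n}"
                )

    def n_bins(self, contig: str) -> int:
        return math.ceil(self.contig_lengths[contig] / self.bin_width)

    def bin_of(self, position: int) -> int:
        return position // self.bin_width

    def value_at(self, contig: str, position: int) -> float:
        return float(self.values[contig][self.bin_of(position)])

    def global_mean(self) -> float:
        parts = [v[~np.isnan(v)] for v in self.values.values()]
        allv = np.concatenate(parts) if parts else np.array([])
        return float(np.mean(allv)) if allv.size else float("nan")

    def negated(self) -> "SignalTrack":
        return SignalTrack(
            self.bin_width,
            dict(self.contig_lengths),
            {c: -v for c, v in self.values.items()},
        )

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig in self.contig_lengths:
                vals = self.values[contig]
                length = self.contig_lengths[contig]
                for i, v in enumerate(vals):
                    if np.isnan(v):
                        continue
                    start = i * self.bin_width
                    end = min(start + self.bin_width, length)
                    fh.write(f"{contig}\t{start}\t{end}\t{v:.6g}\n")

    @classmethod
    def read_bedgraph(
        cls, path: str | Path, bin_width: int, contig_lengths: dict[str, int]
    ) -> "SignalTrack":
        track = cls(bin_width, dict(contig_lengths))
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                contig, start, _end, value = line.rstrip("\n").split("\t")[:4]
                start = int(start)
                if start % bin_width:
                    raise ValueError(
                        f"bedGraph line not aligned to {bin_width} bp bins: "
                        f"{line.rstrip()}"
                    )
                track.values[contig][start // bin_width] = float(value)
        return track
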