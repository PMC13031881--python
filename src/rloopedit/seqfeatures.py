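"""GC-skew and G4Hunter tracks plus strand-aware metaprofiles.

GC-skew of a window is (G - C) / (G + C) counted on the + strand; the
- strand value is its negation.  G4Hunter scores each base by the length of
the homopolymer G/C run containing it (capped at 4, C runs negative) and a
window's score is the arithmetic mean; |score| >= threshold windows are
merged into candidate G4 intervals whose sign gives the G-rich strand.

``profile_around`` aggregates any fixed-bin track around a set of anchor
midpoints into a mean profile with a 95% confidence band, optionally
reversing (and sign-flipping, for strand-antisymmetric tracks like GC-skew)
the window of minus-strand anchors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import BED_COLUMNS, PeakSet
from .tracks import SignalTrack

_BASE_CODE = {"G": 1, "C": -1}


def gc_skew_track(
    genome: dict[str, str], window: int = 200
) -> tuple[SignalTrack, SignalTrack]:
    """Windowed GC-skew for both strands; windows without G or C are missing.

    Returns ``(plus, minus)`` tracks; the minus track is the negation of the
    plus track (skew is antisymmetric under reverse complement).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    lengths = {c: len(s) for c, s in genome.items()}
    plus = SignalTrack(window, lengths)
    for contig, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode(), dtype="S1")
        is_g = arr == b"G"
        is_c = arr == b"C"
        n_bins = plus.n_bins(contig)
        g = np.zeros(n_bins)
        c = np.zeros(n_bins)
        bins = np.arange(len(seq)) // window
        np.add.at(g, bins, is_g)
        np.add.at(c, bins, is_c)
        with np.errstate(invalid="ignore", divide="ignore"):
            skew = (g - c) / (g + c)
        plus.values[contig] = skew  # NaN where G + C == 0
    return plus, plus.negated()


def g4hunter_base_scores(sequence: str) -> np.ndarray:
    """Per-base G4Hunter scores: run of G of length L scores +min(L, 4) per base."""
    seq = sequence.upper()
    scores = np.zeros(len(seq))
    i = 0
    while i < len(seq):
        base = seq[i]
        j = i
        while j < len(seq) and seq[j] == base:
            j += 1
        code = _BASE_CODE.get(base, 0)
        if code:
            scores[i:j] = code * min(j - i, 4)
        i = j
    return scores


def g4hunter_score(sequence: str) -> float:
    """Mean G4Hunter score of a sequence; in [-4, 4]."""
    if len(sequence) == 0:
        raise ValueError("cannot score an empty sequence")
    return float(g4hunter_base_scores(sequence).mean())


def g4hunter_scan(
    genome: dict[str, str],
    window: int = 25,
    threshold: float = 1.2,
    density_bin: int = 100,
) -> tuple[PeakSet, SignalTrack]:
    """Genome-wide G4 candidate intervals plus a motif-density track.

    Sliding windows (step 1) with |mean score| >= threshold are merged into
    maximal intervals when they overlap or abut and carry the same sign;
    the interval strand is '+' for G-rich, '-' for C-rich.  The density
    track counts G4 intervals overlapping each ``density_bin`` bp bin.
    """
    if window < 1 or density_bin < 1:
        raise ValueError("window and density_bin must be >= 1")
    rows = []
    lengths = {c: len(s) for c, s in genome.items()}
    for contig, seq in genome.items():
        if len(seq) < window:
            continue
        base = g4hunter_base_scores(seq)
        csum = np.concatenate([[0.0], np.cumsum(base)])
        means = (csum[window:] - csum[:-window]) / window
        qualifying = np.flatnonzero(np.abs(means) >= threshold)
        # merge overlapping-or-abutting qualifying window extents of equal sign
        start = end = None
        cur_sign = 0.0
        for k in qualifying:
            s = 1.0 if means[k] > 0 else -1.0
            if start is not None and s == cur_sign and k <= end:
                end = k + window
            else:
                if start is not None:
                    rows.append(
                        (contig, start, end, ".", 0.0, "+" if cur_sign > 0 else "-")
                    )
                start, end, cur_sign = k, k + window, s
        if start is not None:
            rows.append((contig, start, end, ".", 0.0, "+" if cur_sign > 0 else "-"))
    intervals = PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS))

    density = SignalTrack(density_bin, lengths)
    for contig in genome:
        density.values[contig] = np.zeros(density.n_bins(contig))
    for row in intervals.df.itertuples(index=False):
        first = row.start // density_bin
        last = (row.end - 1) // density_bin
        density.values[row.contig][first : last + 1] += 1
    return intervals, density


def profile_around(
    anchors: PeakSet,
    track: SignalTrack,
    flank: int,
    strand_aware: bool = False,
    antisymmetric: bool = False,
) -> pd.DataFrame:
    """Mean track profile around anchor midpoints with a 95% CI band.

    Columns: ``rel_pos`` (bin-centre offset from the anchor midpoint),
    ``mean``, ``ci95`` (1.96 x SEM) and ``n`` (anchors contributing a
    defined value at that position).  With ``strand_aware``, minus-strand
    anchor windows are reversed; with ``antisymmetric`` additionally
    sign-flipped (GC-skew-like tracks).  Missing bins and positions hanging
    off contig ends are excluded, not imputed.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors given")
    b = track.bin_width
    if flank % b:
        raise ValueError(f"flank must be a multiple of the bin width ({b})")
    n_pos = 2 * flank // b
    rel_pos = -flank + b * np.arange(n_pos) + b / 2
    rows = []
    for row in anchors.midpoints().itertuples(index=False):
        vals = np.full(n_pos, np.nan)
        mid_bin = row.midpoint // b
        lo = mid_bin - flank // b
        contig_vals = track.values[row.contig]
        for k in range(n_pos):
            j = lo + k
            if 0 <= j < len(contig_vals):
                vals[k] = contig_vals[j]
        if strand_aware and row.strand == "-":
            vals = vals[::-1]
            if antisymmetric:
                vals = -vals
        rows.append(vals)
    mat = np.vstack(rows)
    n = np.sum(~np.isnan(mat), axis=0)
    if n.sum() == 0:
        raise ValueError("no anchor produced any defined track value")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0, ddof=1)
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
    ci95 = np.where(n > 1, 1.96 * sem, 0.0)
    return pd.DataFrame({"rel_pos": rel_pos, "mean": mean, "ci95": ci95, "n": n})
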