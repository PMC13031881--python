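"""Shared helpers and independent brute-force oracles for the test suite."""

import numpy as np
import pandas as pd

from rloopedit.intervals import BED_COLUMNS, PeakSet


def make_peakset(rows):
    """rows: iterable of (contig, start, end[, strand])."""
    full = []
    for r in rows:
        contig, start, end = r[:3]
        strand = r[3] if len(r) > 3 else "."
        full.append((contig, start, end, ".", 0.0, strand))
    return PeakSet(pd.DataFrame(full, columns=BED_COLUMNS))


def brute_force_clusters(positions, d_max):
    """O(n^2)-style exhaustive cluster enumeration on sorted positions."""
    positions = sorted(positions)
    clusters = []
    current = [positions[0]] if positions else []
    for p in positions[1:]:
        if p - current[-1] <= d_max:
            current.append(p)
        else:
            if len(current) >= 2:
                clusters.append(list(current))
            current = [p]
    if len(current) >= 2:
        clusters.append(list(current))
    return clusters


def brute_force_g4_scan(seq, base_scores, window, threshold):
    """Exhaustive sliding-window qualification + same-sign extent merging."""
    hits = []
    for k in range(len(seq) - window + 1):
        m = base_scores[k : k + window].mean()
        if abs(m) >= threshold:
            hits.append((k, k + window, 1.0 if m > 0 else -1.0))
    merged = []
    for s, e, sign in hits:
        if merged and sign == merged[-1][2] and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], e, sign)
        else:
            merged.append((s, e, sign))
    return merged


def random_genome(rng, length, gc=0.41):
    return "".join(
        rng.choice(list("ACGT"), size=length, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    )
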