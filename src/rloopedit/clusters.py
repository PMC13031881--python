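"""Clustered hypermutation (omikli / kataegis) and intermutation distance.

A cluster is a maximal run of consecutive same-sample mutations on one
contig whose adjacent intermutation distances are all <= ``d_max``
(default 1000 bp).  Runs of 2-4 mutations are called omikli (small, fog-like
clusters); runs of >= 5 are kataegis.  Per-sample significance comes from a
permutation null: mutation positions are re-drawn uniformly within the
callable regions and the total cluster count compared with the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import PeakSet

OMIKLI_MAX_SIZE = 4  # 2..4 omikli, >=5 kataegis
KATAEGIS_MIN_SIZE = 5


@dataclass
class MutationCluster:
    contig: str
    sample: str
    positions: list[int]  # sorted, 0-based
    klass: str = field(init=False)

    def __post_init__(self) -> None:
        self.positions = sorted(self.positions)
        if len(self.positions) < 2:
            raise ValueError("a cluster needs at least two mutations")
        self.klass = (
            "kataegis" if len(self.positions) >= KATAEGIS_MIN_SIZE else "omikli"
        )

    @property
    def size(self) -> int:
        return len(self.positions)

    @property
    def span(self) -> int:
        return self.positions[-1] - self.positions[0]


def intermutation_distance(mutations: pd.DataFrame) -> pd.Series:
    """Per-mutation distance to the nearest preceding mutation (same sample+contig).

    The first mutation of each sample/contig group has no predecessor and
    gets ``NaN``.  Input is sorted internally; the result is aligned to the
    input index.
    """
    out = pd.Series(np.nan, index=mutations.index, dtype=float)
    for _, grp in mutations.groupby(["sample", "contig"], sort=False):
        ordered = grp.sort_values("position", kind="stable")
        imd = ordered["position"].diff()
        out.loc[ordered.index] = imd.to_numpy(dtype=float)
    return out


def _runs(positions: np.ndarray, d_max: int) -> list[tuple[int, int]]:
    """Maximal [i, j) index runs with adjacent gaps <= d_max."""
    runs = []
    start = 0
    for k in range(1, len(positions) + 1):
        if k == len(positions) or positions[k] - positions[k - 1] > d_max:
            if k - start >= 2:
                runs.append((start, k))
            start = k
    return runs


def _count_clusters(positions: np.ndarray, d_max: int) -> int:
    return len(_runs(np.sort(positions), d_max))


def detect_clusters(
    mutations: pd.DataFrame,
    callable_regions: PeakSet,
    d_max: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[list[MutationCluster], pd.DataFrame]:
    """Find omikli/kataegis clusters and per-sample permutation p-values.

    Returns the cluster list and a per-sample summary with omikli and
    kataegis counts and the empirical p-value
    ``(1 + #permutations with >= observed cluster count) / (1 + n_perm)``,
    positions re-drawn uniformly within the callable regions.
    """
    if len(mutations) == 0:
        return [], pd.DataFrame(
            columns=["sample", "n_mutations", "omikli", "kataegis", "p_value"]
        )
    cr = callable_regions.df
    region_lengths = (cr["end"] - cr["start"]).to_numpy()
    cum = np.concatenate([[0], np.cumsum(region_lengths)])
    total_callable = int(cum[-1])
    if total_callable == 0:
        raise ValueError("callable regions are empty")

    clusters: list[MutationCluster] = []
    summary_rows = []
    rng = np.random.default_rng(seed)
    for sample, sgrp in mutations.groupby("sample", sort=False):
        observed = 0
        for contig, grp in sgrp.groupby("contig", sort=False):
            pos = np.sort(grp["position"].to_numpy())
            if not np.array_equal(pos, grp["position"].to_numpy()):
                warnings.warn(
                    f"mutations for {sample}/{contig} were not sorted; sorting",
                    stacklevel=2,
                )
            for i, j in _runs(pos, d_max):
                clusters.append(MutationCluster(contig, sample, list(pos[i:j])))
                observed += 1
        n_mut = len(sgrp)
        exceed = 0
        for _ in range(n_perm):
            draws = rng.integers(0, total_callable, size=n_mut)
            ridx = np.searchsorted(cum, draws, side="right") - 1
            offsets = draws - cum[ridx]
            perm_pos = cr["start"].to_numpy()[ridx] + offsets
            # count clusters per contig of the callable regions
            count = 0
            for contig in np.unique(cr["contig"].to_numpy()[ridx]):
                mask = cr["contig"].to_numpy()[ridx] == contig
                count += _count_clusters(perm_pos[mask], d_max)
            exceed += count >= observed
        p = (1 + exceed) / (1 + n_perm)
        n_omikli = sum(
            1 for c in clusters if c.sample == sample and c.klass == "omikli"
        )
        n_kataegis = sum(
            1 for c in clusters if c.sample == sample and c.klass == "kataegis"
        )
        summary_rows.append((sample, n_mut, n_omikli, n_kataegis, p))
    summary = pd.DataFrame(
        summary_rows, columns=["sample", "n_mutations", "omikli", "kataegis", "p_value"]
    )
    return clusters, summary


def clusters_to_tsv(clusters: list[MutationCluster], path) -> None:
    rows = [
        (c.contig, c.positions[0], c.positions[-1] + 1, c.sample, c.size, c.span, c.klass)
        for c in clusters
    ]
    pd.DataFrame(
        rows, columns=["contig", "start", "end", "sample", "size", "span", "class"]
    ).to_csv(path, sep="\t", index=False)
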