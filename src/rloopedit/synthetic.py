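"""Synthetic dataset generator planting the structures the pipeline assumes.

The generator emulates the processed forms of a strand-resolved R-loop /
APOBEC editing study: a small genome with stranded R-loop intervals whose
displaced strand carries planted GC-skew and G-quadruplex motifs; TCW C>T
mutations concentrated on the displaced strand at a configurable
concordance; diffuse background mutations and planted omikli-like clusters;
replicate negative-binomial peak count matrices with a condition-induced
subset; and DSB peaks whose knockdown response is conditional on sitting at
an A3B-binding/R-loop intersection.

Every random draw flows from the single config seed through named
sub-streams, so identical configs give byte-identical fixture bundles and
individual artefacts can be regenerated in isolation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import contig_lengths as _contig_lengths
from .genome import reverse_complement, write_fasta
from .intervals import BED_COLUMNS, PeakSet, gap_to_nearest
from .mutations import MUTATION_COLUMNS, write_vcf
from .tracks import SignalTrack

G4_MOTIF = "GGGTGGGTGGGTGGG"  # four G3 runs; G4Hunter-positive on its own strand

_SUBSTREAMS = [
    "genome",
    "rloops",
    "mutations",
    "a3b",
    "counts",
    "dsb",
    "timing",
    "states",
]


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic dataset; defaults are the study conditions."""

    seed: int = 0
    contigs: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 600_000), ("chr2", 400_000)]
    )
    gc_content: float = 0.41
    # R-loops
    n_rloops: int = 200
    rloop_length: tuple[int, int] = (800, 1600)
    skew_strength: float = 0.9
    g4_plant_rate: float = 0.8
    # mutations
    n_background_mut: int = 300
    n_rloop_mut: int = 1000
    concordance: float = 0.8
    n_clusters: int = 10
    cluster_size: int = 3
    cluster_span: int = 900
    timing_mut_bias: float = 1.0  # rate multiplier in the earliest quartile
    # peak count matrices
    n_peaks: int = 2000
    n_replicates: int = 3
    frac_induced: float = 0.2
    induced_fc: float = 3.0
    nb_dispersion: float = 0.1
    mean_count: int = 50
    # A3B binding peaks
    n_a3b_peaks: int = 150
    a3b_peak_length: int = 600
    frac_a3b_in_rloop: float = 0.5
    # DSB peaks
    n_dsb_peaks: int = 400
    dsb_peak_length: int = 500
    frac_dsb_both: float = 0.4
    frac_dsb_a3b_only: float = 0.1
    frac_dsb_rloop_only: float = 0.1
    frac_dsb_e2_induced: float = 0.3
    dsb_dependence_ratio: float = 0.4
    # tracks
    timing_bin: int = 2000
    state_mean_length: int = 5000

    def __post_init__(self) -> None:
        for name in (
            "gc_content",
            "g4_plant_rate",
            "concordance",
            "frac_induced",
            "frac_a3b_in_rloop",
            "frac_dsb_both",
            "frac_dsb_a3b_only",
            "frac_dsb_rloop_only",
            "frac_dsb_e2_induced",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.5 <= self.skew_strength <= 1.0:
            raise ValueError("skew_strength must be in [0.5, 1]")
        if self.rloop_length[0] <= 0 or self.rloop_length[0] > self.rloop_length[1]:
            raise ValueError("rloop_length must be a positive (min, max) pair")
        if self.mean_count <= 0:
            raise ValueError("mean_count must be positive")
        for name in ("timing_bin", "state_mean_length", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_rloops < 0:
            raise ValueError("n_rloops must be non-negative")
        if self.frac_dsb_both + self.frac_dsb_a3b_only + self.frac_dsb_rloop_only > 1:
            raise ValueError("DSB placement fractions exceed 1")

    def rng(self, stream: str) -> np.random.Generator:
        """Named child RNG; streams are independent and reproducible."""
        idx = _SUBSTREAMS.index(stream)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(len(_SUBSTREAMS))[idx]
        )

    @property
    def contig_lengths(self) -> dict[str, int]:
        return dict(self.contigs)


@dataclass
class FixtureBundle:
    """Paths of a written synthetic dataset plus the planted-truth tables."""

    directory: Path
    genome_fasta: Path
    mutations_vcf: Path
    rloops_bed: Path
    a3b_bed: Path
    dsb_bed: Path
    counts_tsv: dict[str, Path]
    timing_bedgraph: Path
    states_bed: Path
    truth_tsv: Path
    config_json: Path


# ---------------------------------------------------------------------------
# genome and R-loops
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _place_nonoverlapping(
    rng: np.random.Generator,
    contigs: list[tuple[str, int]],
    n: int,
    length_range: tuple[int, int],
    max_retries: int = 1000,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
) -> list[tuple[str, int, int]]:
    """Rejection-sample n non-overlapping intervals across contigs."""
    occupied = {c: list(occupied.get(c, [])) if occupied else [] for c, _ in contigs}
    total = sum(l for _, l in contigs)
    weights = np.array([l / total for _, l in contigs])
    out = []
    for _ in range(n):
        for attempt in range(max_retries):
            ci = rng.choice(len(contigs), p=weights)
            cname, clen = contigs[ci]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            if clen <= length:
                continue
            start = int(rng.integers(0, clen - length))
            end = start + length
            if all(e <= start or end <= s for s, e in occupied[cname]):
                occupied[cname].append((start, end))
                out.append((cname, start, end))
                break
        else:
            raise RuntimeError(
                f"could not place interval {len(out) + 1}/{n} after "
                f"{max_retries} retries; the configuration is overcrowded"
            )
    return out


def generate_genome(config: SyntheticConfig) -> tuple[dict[str, str], PeakSet]:
    """Background genome plus stranded R-loops with planted skew and G4 motifs.

    Background bases are i.i.d. at the configured GC content.  Inside each
    R-loop, strong (G/C) positions carry G on the displaced strand with
    probability ``skew_strength``; the BED strand column names the displaced
    strand.  A G4 motif is written at the 5' end of the displaced strand
    with probability ``g4_plant_rate``.
    """
    rng = config.rng("genome")
    genome_arrays = {
        name: _random_sequence(rng, length, config.gc_content)
        for name, length in config.contigs
    }
    rng_r = config.rng("rloops")
    placements = _place_nonoverlapping(
        rng_r, config.contigs, config.n_rloops, config.rloop_length
    )
    rows = []
    for i, (contig, start, end) in enumerate(placements):
        strand = "+" if rng_r.random() < 0.5 else "-"
        arr = genome_arrays[contig]
        span = end - start
        strong = rng_r.random(span) < config.gc_content
        g_on_displaced = rng_r.random(span) < config.skew_strength
        weak_is_a = rng_r.random(span) < 0.5
        for k in range(span):
            if strong[k]:
                disp_base = b"G" if g_on_displaced[k] else b"C"
                arr[start + k] = (
                    disp_base
                    if strand == "+"
                    else (b"C" if disp_base == b"G" else b"G")
                )
            else:
                arr[start + k] = b"A" if weak_is_a[k] else b"T"
        if rng_r.random() < config.g4_plant_rate:
            motif = G4_MOTIF if strand == "+" else reverse_complement(G4_MOTIF)
            pos = start if strand == "+" else end - len(motif)
            arr[pos : pos + len(motif)] = np.frombuffer(motif.encode(), dtype="S1")
        rows.append((contig, start, end, f"rloop_{i}", 0.0, strand))
    genome = {name: arr.tobytes().decode() for name, arr in genome_arrays.items()}
    rloops = PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS))
    return genome, rloops


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------


def _tcw_sites(seq: str, start: int, end: int) -> tuple[list[int], list[int]]:
    """Positions of TCW motifs (pyrimidine strand +) and their - strand mirror."""
    plus, minus = [], []
    lo = max(start, 1)
    hi = min(end, len(seq) - 1)
    for i in range(lo, hi):
        tri = seq[i - 1 : i + 2]
        if tri[1] == "C" and tri[0] == "T" and tri[2] in "AT":
            plus.append(i)
        elif tri[1] == "G" and tri[2] == "A" and tri[0] in "AT":
            minus.append(i)
    return plus, minus


def plant_mutations(
    genome: dict[str, str],
    rloops: PeakSet,
    config: SyntheticConfig,
    timing: SignalTrack | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant R-loop TCW mutations, uniform background and omikli clusters.

    Returns ``(mutations, truth)``: mutations in the in-memory 0-based
    representation (single sample ``synthetic``), truth with one row per
    mutation carrying the planted label.  Raises when the genome lacks
    enough TCW sites for the requested counts, naming the shortfall.
    """
    rng = config.rng("mutations")
    lengths = _contig_lengths(genome)
    used: set[tuple[str, int]] = set()
    mut_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    conc_pool: list[tuple[str, int, str]] = []  # (contig, pos, rloop strand)
    disc_pool: list[tuple[str, int, str]] = []
    for row in rloops.df.itertuples(index=False):
        plus, minus = _tcw_sites(genome[row.contig], int(row.start), int(row.end))
        conc, disc = (plus, minus) if row.strand == "+" else (minus, plus)
        conc_pool += [(row.contig, p, row.strand) for p in conc]
        disc_pool += [(row.contig, p, row.strand) for p in disc]

    want_conc = int(rng.binomial(config.n_rloop_mut, config.concordance))
    want_disc = config.n_rloop_mut - want_conc
    for want, pool, label in (
        (want_conc, conc_pool, True),
        (want_disc, disc_pool, False),
    ):
        if want > len(pool):
            raise RuntimeError(
                f"not enough TCW sites: requested {want} "
                f"{'concordant' if label else 'discordant'} R-loop mutations but "
                f"only {len(pool)} sites are available"
            )
        picks = rng.choice(len(pool), size=want, replace=False)
        for k in picks:
            contig, pos, strand = pool[k]
            if (contig, pos) in used:
                continue
            used.add((contig, pos))
            base = genome[contig][pos]
            ref, alt = ("C", "T") if base == "C" else ("G", "A")
            mut_rows.append((contig, pos, ref, alt, "synthetic"))
            truth_rows.append((contig, pos, "rloop", strand, label, ""))

    # background: uniform outside R-loops, optionally biased by timing quartile
    rdf = rloops.df
    in_rloop = {
        c: list(zip(g["start"], g["end"])) for c, g in rdf.groupby("contig", sort=False)
    }
    quartile_weight = _timing_weights(timing, config) if timing is not None else None
    total = sum(lengths.values())
    names = list(lengths)
    probs = np.array([lengths[c] / total for c in names])
    placed = 0
    attempts = 0
    while placed < config.n_background_mut:
        attempts += 1
        if attempts > 200 * max(config.n_background_mut, 1):
            raise RuntimeError("could not place background mutations (overcrowded)")
        contig = names[rng.choice(len(names), p=probs)]
        pos = int(rng.integers(1, lengths[contig] - 1))
        if (contig, pos) in used:
            continue
        if any(s <= pos < e for s, e in in_rloop.get(contig, [])):
            continue
        if quartile_weight is not None:
            if rng.random() > quartile_weight(contig, pos):
                continue
        used.add((contig, pos))
        ref = genome[contig][pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        mut_rows.append((contig, pos, ref, str(alt), "synthetic"))
        truth_rows.append((contig, pos, "background", ".", "", ""))
        placed += 1

    # clusters: evenly spaced within the span, kept far enough (> d_max) from
    # every other mutation that they are recovered exactly
    margin = 1500
    for ci in range(config.n_clusters):
        for attempt in range(1000):
            contig = names[rng.choice(len(names), p=probs)]
            clen = lengths[contig]
            if clen < config.cluster_span + 2 * margin:
                continue
            start = int(rng.integers(margin, clen - config.cluster_span - margin))
            span_ok = not any(
                s - margin <= start + config.cluster_span and start - margin <= e
                for s, e in in_rloop.get(contig, [])
            )
            near_mut = any(
                c == contig and abs(p - (start + config.cluster_span // 2)) < margin + config.cluster_span
                for c, p in used
            )
            if span_ok and not near_mut:
                break
        else:
            raise RuntimeError(f"could not place cluster {ci} (overcrowded)")
        step = config.cluster_span // max(config.cluster_size - 1, 1)
        positions = [start + k * step for k in range(config.cluster_size)]
        for pos in positions:
            used.add((contig, pos))
            ref = genome[contig][pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            mut_rows.append((contig, pos, ref, str(alt), "synthetic"))
            truth_rows.append((contig, pos, "cluster", ".", "", f"cluster_{ci}"))

    mutations = pd.DataFrame(mut_rows, columns=MUTATION_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["contig", "position", "kind", "rloop_strand", "concordant", "cluster_id"],
    )
    order = np.lexsort((mutations["position"], mutations["contig"]))
    return (
        mutations.iloc[order].reset_index(drop=True),
        truth.iloc[order].reset_index(drop=True),
    )


def _timing_weights(timing: SignalTrack, config: SyntheticConfig):
    """Acceptance weight per position: timing_mut_bias in the earliest quartile."""
    if config.timing_mut_bias == 1.0:
        return None
    values = np.concatenate([v[~np.isnan(v)] for v in timing.values.values()])
    cutoff = np.quantile(values, 0.75)
    hi = max(config.timing_mut_bias, 1.0)

    def weight(contig: str, pos: int) -> float:
        v = timing.value_at(contig, pos)
        w = config.timing_mut_bias if v >= cutoff else 1.0
        return w / hi

    return weight


# ---------------------------------------------------------------------------
# peaks and counts
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_peak_counts(
    peaks: PeakSet,
    config: SyntheticConfig,
    stream: str = "counts",
    frac_induced: float | None = None,
    induced_fc: float | None = None,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Replicate NB count matrix with a condition-induced subset.

    Returns ``(counts, condition, induced_truth)``: columns are
    ``ctrl_1..n`` and ``treat_1..n``; induced features have their treated
    mean multiplied by ``induced_fc``.  Per-sample size factors are drawn
    log-normally and folded into the means.
    """
    if len(peaks) == 0:
        raise ValueError("peak set is empty")
    frac = config.frac_induced if frac_induced is None else frac_induced
    fc = config.induced_fc if induced_fc is None else induced_fc
    if frac > 0 and frac * len(peaks) < 1:
        raise ValueError("frac_induced * n_peaks must be >= 1 (or 0)")
    rng = config.rng(stream)
    n = len(peaks)
    n_ind = int(round(frac * n))
    induced = np.zeros(n, dtype=bool)
    induced[rng.choice(n, size=n_ind, replace=False)] = True

    samples = [f"ctrl_{i + 1}" for i in range(config.n_replicates)] + [
        f"treat_{i + 1}" for i in range(config.n_replicates)
    ]
    condition = pd.Series(
        ["control"] * config.n_replicates + ["treated"] * config.n_replicates,
        index=samples,
    )
    size_factors = np.exp(rng.normal(0.0, 0.15, size=len(samples)))
    base_mean = config.mean_count * np.exp(rng.normal(0.0, 0.5, size=n))
    counts = {}
    for j, s in enumerate(samples):
        mu = base_mean * size_factors[j]
        if condition[s] == "treated":
            mu = np.where(induced, mu * fc, mu)
        counts[s] = _nb_draw(rng, mu, config.nb_dispersion)
    names = (
        peaks.df["name"].tolist()
        if (peaks.df["name"] != ".").any()
        else [f"peak_{i}" for i in range(n)]
    )
    df = pd.DataFrame(counts, index=names)
    df.index.name = "feature"
    return df, condition, induced


def generate_a3b_peaks(rloops: PeakSet, config: SyntheticConfig) -> PeakSet:
    """A3B binding peaks, a configured fraction placed inside R-loops."""
    rng = config.rng("a3b")
    n_in = int(round(config.frac_a3b_in_rloop * config.n_a3b_peaks))
    rows = []
    rdf = rloops.df
    lengths = config.contig_lengths
    for i in range(config.n_a3b_peaks):
        if i < n_in and len(rdf):
            r = rdf.iloc[int(rng.integers(0, len(rdf)))]
            center = int(rng.integers(r["start"], r["end"]))
            contig = r["contig"]
        else:
            names = list(lengths)
            total = sum(lengths.values())
            contig = names[rng.choice(len(names), p=[lengths[c] / total for c in names])]
            center = int(rng.integers(0, lengths[contig]))
        half = config.a3b_peak_length // 2
        start = max(0, center - half)
        end = min(lengths[contig], center + half)
        if end - start < 10:
            continue
        rows.append((contig, start, end, f"a3b_{i}", 0.0, "."))
    return PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS))


def simulate_dsb_peaks(
    a3b_peaks: PeakSet,
    rloops: PeakSet,
    config: SyntheticConfig,
    proximity_d: int = 1500,
) -> tuple[PeakSet, dict[str, pd.DataFrame], dict[str, pd.Series], pd.DataFrame]:
    """DSB peaks with class-conditional knockdown dependence.

    Places DSB peaks in four target classes (A3B-and-R-loop intersections,
    A3B-only, R-loop-only, neither) and simulates two count matrices over
    them: an E2-induction contrast (DMSO vs E2) and a knockdown contrast
    (NT vs siA3B under E2) in which only the A3B-and-R-loop peaks have
    their siA3B mean scaled by ``dsb_dependence_ratio``.

    Returns ``(dsb_peaks, counts, conditions, truth)`` where ``counts`` and
    ``conditions`` are keyed ``'e2'`` and ``'knockdown'``.
    """
    rng = config.rng("dsb")
    lengths = config.contig_lengths
    margin = proximity_d + 500

    both_targets = _intersections(a3b_peaks, rloops)
    a3b_only = _distal_subset(a3b_peaks, rloops, margin)
    rloop_only = _distal_subset(rloops, a3b_peaks, margin)

    n = config.n_dsb_peaks
    n_both = int(round(config.frac_dsb_both * n))
    n_a3b = int(round(config.frac_dsb_a3b_only * n))
    n_rl = int(round(config.frac_dsb_rloop_only * n))
    n_neither = n - n_both - n_a3b - n_rl

    rows, classes = [], []
    half = config.dsb_peak_length // 2

    def place_in(targets: pd.DataFrame, label: str, count: int) -> int:
        """Returns the number of peaks that could not be placed."""
        if count == 0:
            return 0
        if len(targets) == 0:
            if label == "A3B_and_Rloop":
                raise RuntimeError(
                    "frac_dsb_both > 0 but A3B peaks and R-loops never intersect"
                )
            warnings.warn(
                f"no placement target for DSB class {label!r}; "
                "re-assigning to 'neither'",
                stacklevel=2,
            )
            return count
        for _ in range(count):
            t = targets.iloc[int(rng.integers(0, len(targets)))]
            center = int(rng.integers(t["start"], t["end"]))
            start = max(0, center - half)
            end = min(lengths[t["contig"]], center + half)
            rows.append((t["contig"], start, end, f"dsb_{len(rows)}", 0.0, "."))
            classes.append(label)
        return 0

    n_neither += place_in(both_targets, "A3B_and_Rloop", n_both)
    n_neither += place_in(a3b_only, "A3B_only", n_a3b)
    n_neither += place_in(rloop_only, "Rloop_only", n_rl)

    exclusion = pd.concat([a3b_peaks.df, rloops.df], ignore_index=True)
    excl_by_contig = {
        c: g[["start", "end"]].to_numpy()
        for c, g in exclusion.groupby("contig", sort=False)
    }
    names = list(lengths)
    total = sum(lengths.values())
    probs = [lengths[c] / total for c in names]
    placed = 0
    attempts = 0
    while placed < n_neither:
        attempts += 1
        if attempts > 1000 * max(n_neither, 1):
            raise RuntimeError("could not place 'neither' DSB peaks (overcrowded)")
        contig = names[rng.choice(len(names), p=probs)]
        center = int(rng.integers(margin, lengths[contig] - margin))
        start, end = center - half, center + half
        near = excl_by_contig.get(contig)
        if near is not None and np.any(
            (near[:, 0] - margin < end) & (start < near[:, 1] + margin)
        ):
            continue
        rows.append((contig, start, end, f"dsb_{len(rows)}", 0.0, "."))
        classes.append("neither")
        placed += 1

    dsb = PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS))
    # PeakSet sorting reorders rows: recover class by name
    name_to_class = {rows[i][3]: classes[i] for i in range(len(rows))}
    ordered_classes = [name_to_class[nm] for nm in dsb.df["name"]]
    dependent = np.array([c == "A3B_and_Rloop" for c in ordered_classes])
    e2_induced = rng.random(len(dsb)) < config.frac_dsb_e2_induced

    # full 2x2 design: (DMSO, E2) x (NT, siA3B); the knockdown effect on
    # dependent peaks applies under E2 only, so it appears as an interaction
    base_mean = config.mean_count * np.exp(rng.normal(0.0, 0.5, size=len(dsb)))
    reps = config.n_replicates
    samples, cond_lab, geno_lab = [], [], []
    for cond in ("DMSO", "E2"):
        for geno in ("NT", "siA3B"):
            for i in range(reps):
                samples.append(f"{cond}_{geno}_{i + 1}")
                cond_lab.append(cond)
                geno_lab.append(geno)
    condition = pd.Series(cond_lab, index=samples)
    genotype = pd.Series(geno_lab, index=samples)
    sf = np.exp(rng.normal(0.0, 0.15, size=len(samples)))
    mat = {}
    for j, s in enumerate(samples):
        mu = base_mean * sf[j]
        if condition[s] == "E2":
            mu = np.where(e2_induced, mu * config.induced_fc, mu)
            if genotype[s] == "siA3B":
                mu = np.where(dependent, mu * config.dsb_dependence_ratio, mu)
        mat[s] = _nb_draw(rng, mu, config.nb_dispersion)
    full = pd.DataFrame(mat, index=dsb.df["name"].tolist())
    full.index.name = "feature"

    nt_cols = [s for s in samples if genotype[s] == "NT"]
    e2_cols = [s for s in samples if condition[s] == "E2"]
    counts: dict[str, pd.DataFrame] = {
        "full": full,
        "e2": full[nt_cols],  # DMSO vs E2 in the non-targeting background
        "knockdown": full[e2_cols],  # NT vs siA3B under E2
    }
    conditions: dict[str, pd.Series] = {
        "condition": condition,
        "genotype": genotype,
        "e2": condition[nt_cols],
        "knockdown": genotype[e2_cols],
    }

    truth = pd.DataFrame(
        {
            "feature": dsb.df["name"].tolist(),
            "placement_class": ordered_classes,
            "dependent": dependent,
            "e2_induced": e2_induced,
        }
    )
    return dsb, counts, conditions, truth


def _intersections(a: PeakSet, b: PeakSet) -> pd.DataFrame:
    rows = []
    bdf_by_contig = {c: g for c, g in b.df.groupby("contig", sort=False)}
    for row in a.df.itertuples(index=False):
        grp = bdf_by_contig.get(row.contig)
        if grp is None:
            continue
        s = np.maximum(grp["start"].to_numpy(), row.start)
        e = np.minimum(grp["end"].to_numpy(), row.end)
        for ss, ee in zip(s, e):
            if ss < ee:
                rows.append((row.contig, int(ss), int(ee)))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def _distal_subset(query: PeakSet, reference: PeakSet, margin: int) -> pd.DataFrame:
    if len(query) == 0:
        return pd.DataFrame(columns=["contig", "start", "end"])
    gaps = gap_to_nearest(query, reference)
    keep = query.df[gaps > margin]
    return keep[["contig", "start", "end"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# tracks and segmentation
# ---------------------------------------------------------------------------


def generate_timing_track(config: SyntheticConfig) -> SignalTrack:
    """Smooth replication-timing surrogate: sinusoid along each contig plus noise."""
    rng = config.rng("timing")
    track = SignalTrack(config.timing_bin, config.contig_lengths)
    for contig, length in config.contigs:
        n = track.n_bins(contig)
        x = np.arange(n) * config.timing_bin / length
        phase = rng.uniform(0, 2 * np.pi)
        track.values[contig] = np.sin(4 * np.pi * x + phase) + rng.normal(0, 0.05, n)
    return track


STATE_LABELS = ["Promoter", "Enhancer", "Transcribed", "Heterochromatin", "Quiescent"]
_STATE_PROBS = [0.05, 0.1, 0.25, 0.25, 0.35]


def generate_state_segmentation(config: SyntheticConfig) -> PeakSet:
    """Random chromatin-state partition with exponential segment lengths."""
    rng = config.rng("states")
    rows = []
    for contig, length in config.contigs:
        pos = 0
        while pos < length:
            seg = max(200, int(rng.exponential(config.state_mean_length)))
            end = min(pos + seg, length)
            label = rng.choice(STATE_LABELS, p=_STATE_PROBS)
            rows.append((contig, pos, end, str(label), 0.0, "."))
            pos = end
    return PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS))


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.rename_axis("feature").to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature")


def generate_all(config: SyntheticConfig) -> dict:
    """Run every generator stage; returns a dict of in-memory artefacts."""
    genome, rloops = generate_genome(config)
    timing = generate_timing_track(config)
    mutations, mut_truth = plant_mutations(genome, rloops, config, timing=timing)
    a3b = generate_a3b_peaks(rloops, config)
    counts, condition, induced = simulate_peak_counts(rloops, config)
    dsb, dsb_counts, dsb_conditions, dsb_truth = simulate_dsb_peaks(
        a3b, rloops, config
    )
    states = generate_state_segmentation(config)
    return {
        "genome": genome,
        "rloops": rloops,
        "timing": timing,
        "mutations": mutations,
        "mutation_truth": mut_truth,
        "a3b": a3b,
        "spi_counts": counts,
        "spi_condition": condition,
        "spi_induced": induced,
        "dsb": dsb,
        "dsb_counts": dsb_counts,
        "dsb_conditions": dsb_conditions,
        "dsb_truth": dsb_truth,
        "states": states,
    }


def write_fixture_bundle(config: SyntheticConfig, directory: str | Path) -> FixtureBundle:
    """Generate everything and write it as standard text formats.

    The bundle round-trips through the package readers without loss; the
    truth TSV covers every planted mutation and DSB peak.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    art = generate_all(config)

    paths = FixtureBundle(
        directory=directory,
        genome_fasta=directory / "genome.fa",
        mutations_vcf=directory / "mutations.vcf",
        rloops_bed=directory / "rloops.bed",
        a3b_bed=directory / "a3b_peaks.bed",
        dsb_bed=directory / "dsb_peaks.bed",
        counts_tsv={
            "spi": directory / "spi_counts.tsv",
            "dsb_full": directory / "dsb_counts_full.tsv",
        },
        timing_bedgraph=directory / "replication_timing.bedGraph",
        states_bed=directory / "chromatin_states.bed",
        truth_tsv=directory / "truth.tsv",
        config_json=directory / "config.json",
    )
    write_fasta(art["genome"], paths.genome_fasta)
    write_vcf(art["mutations"], paths.mutations_vcf, config.contig_lengths)
    art["rloops"].write_bed(paths.rloops_bed)
    art["a3b"].write_bed(paths.a3b_bed)
    art["dsb"].write_bed(paths.dsb_bed)
    write_counts_tsv(art["spi_counts"], paths.counts_tsv["spi"])
    write_counts_tsv(art["dsb_counts"]["full"], paths.counts_tsv["dsb_full"])
    art["timing"].write_bedgraph(paths.timing_bedgraph)
    art["states"].write_bed(paths.states_bed)

    mt = art["mutation_truth"].copy()
    mt.insert(0, "record", "mutation")
    dt = art["dsb_truth"].copy()
    dt.insert(0, "record", "dsb_peak")
    spi_truth = pd.DataFrame(
        {
            "record": "spi_peak",
            "feature": art["spi_counts"].index,
            "induced": art["spi_induced"],
        }
    )
    truth = pd.concat([mt, dt, spi_truth], ignore_index=True)
    truth.to_csv(paths.truth_tsv, sep="\t", index=False)

    with open(paths.config_json, "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
    return paths
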