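"""Strand-aware integration statistics over genomic intervals.

Covers: proximity classification of one peak set against another
(overlapping / proximal within +-d / distal), strand concordance of
pyrimidine-strand mutations with the displaced strand of R-loops,
uniform random genomic site sampling, consequence-category enrichment
against random sites, chromatin-state fold enrichment, replication-timing
quartile mutation rates, GREAT-style region-to-gene assignment and the
closed-form 2x2 chi-square test.

The strand column of a stranded R-loop record is interpreted, by default,
as naming the displaced single-stranded DNA strand; pass
``rloop_strand_means='hybrid'`` where the upstream convention is the
opposite, which flips the comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .intervals import (
    PeakSet,
    gap_to_nearest,
    merge_intervals,
    overlap_bases,
    overlaps_any,
    points_to_peakset,
    total_bases,
)
from .tracks import SignalTrack

PROXIMITY_DEFAULT = 1500  # bp, "+- 1.5 kb"


# ---------------------------------------------------------------------------
# proximity
# ---------------------------------------------------------------------------


def classify_proximity(
    query: PeakSet,
    reference: PeakSet,
    d: int = PROXIMITY_DEFAULT,
    stranded: bool = False,
) -> tuple[pd.Series, pd.Series]:
    """Label each query interval overlapping / proximal / distal to a reference set.

    Overlapping means >= 1 bp intersection; proximal means an end-to-end gap
    of at most ``d`` bp; otherwise distal.  In stranded mode only
    same-strand references count.  Returns per-query labels and the summary
    fractions.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if len(reference) == 0:
        warnings.warn("empty reference set: every query is distal", stacklevel=2)
        labels = pd.Series("distal", index=query.df.index)
    else:
        gaps = gap_to_nearest(query, reference, stranded=stranded)
        labels = pd.Series(
            np.where(gaps < 0, "overlapping", np.where(gaps <= d, "proximal", "distal")),
            index=query.df.index,
        )
    fractions = labels.value_counts(normalize=True).reindex(
        ["overlapping", "proximal", "distal"], fill_value=0.0
    )
    return labels, fractions


# ---------------------------------------------------------------------------
# strand concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    n_in_rloop: int
    n_concordant: int
    n_excluded_ambiguous: int
    fraction: float | None
    ci_low: float | None
    ci_high: float | None
    table: np.ndarray | None  # 2x2: (in/out R-loop) x (matches nearest strand)
    chi2: float | None
    p_value: float | None


def strand_concordance(
    classified_mutations: pd.DataFrame,
    rloops: PeakSet,
    rloop_strand_means: str = "displaced",
) -> ConcordanceResult:
    """Fraction of R-loop mutations whose pyrimidine strand is the displaced strand.

    ``classified_mutations`` must carry the ``pyrimidine_strand`` column
    from spectrum classification.  Mutations inside two opposite-strand
    R-loops are excluded and counted.  The exact (Clopper-Pearson) binomial
    95% CI accompanies the fraction.  The contingency table contrasts
    mutations inside vs outside R-loops by whether the pyrimidine strand
    matches the (nearest) R-loop's displaced strand, with a chi-square test.
    """
    if rloop_strand_means not in ("displaced", "hybrid"):
        raise ValueError("rloop_strand_means must be 'displaced' or 'hybrid'")

    muts = classified_mutations.reset_index(drop=True)
    rdf = rloops.df
    flip = rloop_strand_means == "hybrid"

    def displaced(strand: str) -> str:
        if flip:
            return "-" if strand == "+" else "+"
        return strand

    inside_strands: list[set[str]] = []
    nearest_strand: list[str | None] = []
    inside_mask = np.zeros(len(muts), dtype=bool)
    for i, row in enumerate(muts.itertuples(index=False)):
        on_contig = rdf[rdf["contig"] == row.contig]
        hit = on_contig[
            (on_contig["start"] <= row.position) & (row.position < on_contig["end"])
        ]
        strands = set(hit["strand"])
        inside_strands.append(strands)
        inside_mask[i] = len(hit) > 0
        if len(on_contig):
            dist = np.minimum(
                np.abs(on_contig["start"].to_numpy() - row.position),
                np.abs(on_contig["end"].to_numpy() - 1 - row.position),
            )
            dist[
                (on_contig["start"].to_numpy() <= row.position)
                & (row.position < on_contig["end"].to_numpy())
            ] = 0
            nearest_strand.append(on_contig["strand"].to_numpy()[np.argmin(dist)])
        else:
            nearest_strand.append(None)

    ambiguous = np.array([len(s) > 1 for s in inside_strands])
    n_excluded = int((inside_mask & ambiguous).sum())
    usable = inside_mask & ~ambiguous
    n_in = int(usable.sum())
    if n_in == 0:
        return ConcordanceResult(0, 0, n_excluded, None, None, None, None, None, None)

    pyr = muts["pyrimidine_strand"].to_numpy()
    concordant = np.zeros(len(muts), dtype=bool)
    for i in range(len(muts)):
        if usable[i]:
            concordant[i] = pyr[i] == displaced(next(iter(inside_strands[i])))
    n_conc = int(concordant[usable].sum())
    frac = n_conc / n_in
    lo, hi = proportion_confint(n_conc, n_in, alpha=0.05, method="beta")

    # contingency vs non-overlapping mutations, matched to nearest R-loop strand
    outside = ~inside_mask & np.array([s is not None for s in nearest_strand])
    out_match = np.array(
        [
            pyr[i] == displaced(nearest_strand[i])
            for i in range(len(muts))
            if outside[i]
        ],
        dtype=bool,
    )
    table = np.array(
        [
            [n_conc, n_in - n_conc],
            [int(out_match.sum()), int(len(out_match) - out_match.sum())],
        ]
    )
    chi2 = p = None
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, p = chi_square_2x2(table)
    return ConcordanceResult(
        n_in, n_conc, n_excluded, frac, float(lo), float(hi), table, chi2, p
    )


# ---------------------------------------------------------------------------
# random sites & enrichment
# ---------------------------------------------------------------------------


def random_site_sample(
    contig_lengths: dict[str, int],
    n: int,
    seed: int = 0,
    exclusion: PeakSet | None = None,
) -> pd.DataFrame:
    """Draw n positions uniformly over the genome minus an exclusion set.

    Sampling is by inverse CDF over the cumulative allowed-segment lengths,
    so it is exact and deterministic for a given seed.  Columns: ``contig``,
    ``position`` (0-based).
    """
    segments: list[tuple[str, int, int]] = []
    if exclusion is not None and len(exclusion):
        merged = merge_intervals(exclusion, gap=0, per_strand=False)
        excl = {c: g for c, g in merged.df.groupby("contig", sort=False)}
    else:
        excl = {}
    for contig, length in contig_lengths.items():
        cursor = 0
        if contig in excl:
            for s, e in excl[contig][["start", "end"]].to_numpy():
                s, e = max(0, int(s)), min(length, int(e))
                if s > cursor:
                    segments.append((contig, cursor, s))
                cursor = max(cursor, e)
        if cursor < length:
            segments.append((contig, cursor, length))
    if not segments:
        raise ValueError("exclusion set covers the entire genome")
    seg_len = np.array([e - s for _, s, e in segments], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, draws, side="right") - 1
    offsets = draws - cum[idx]
    return pd.DataFrame(
        {
            "contig": [segments[i][0] for i in idx],
            "position": [segments[i][1] + int(o) for i, o in zip(idx, offsets)],
        }
    )


@dataclass
class AnnotationCatalogue:
    """Ordered consequence categories, each an interval set with a priority rank.

    Lower priority rank wins when a site overlaps several categories; sites
    overlapping none fall through to ``fallback`` (intergenic).
    """

    categories: list[tuple[str, PeakSet]]  # in priority order, highest first
    fallback: str = "intergenic"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("category names (priorities) must be unique")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.categories] + [self.fallback]

    def assign(self, sites: pd.DataFrame) -> pd.Series:
        """Highest-priority overlapping category per site (contig, position)."""
        labels = pd.Series(self.fallback, index=sites.index, dtype=object)
        unassigned = np.ones(len(sites), dtype=bool)
        site_peaks = points_to_peakset(
            sites["contig"].tolist(), sites["position"].to_numpy(), flank=0
        )
        for name, peaks in self.categories:
            if not unassigned.any():
                break
            hit = overlaps_any(site_peaks, peaks)
            take = hit & unassigned
            labels.iloc[np.flatnonzero(take)] = name
            unassigned &= ~hit
        return labels


def consequence_enrichment(
    variants: pd.DataFrame,
    catalogue: AnnotationCatalogue,
    random_sites: pd.DataFrame,
) -> pd.DataFrame:
    """Per-category enrichment of variant sites vs random sites with chi-square tests.

    Each site gets its highest-priority overlapping category; per category a
    2x2 table (variant/random x in-category/not) gives the closed-form
    chi-square statistic and two-sided p, with BH adjustment across
    categories (raw p also reported).
    """
    v_labels = catalogue.assign(variants)
    r_labels = catalogue.assign(random_sites)
    nv, nr = len(variants), len(random_sites)
    rows = []
    for name in catalogue.names:
        a = int((v_labels == name).sum())
        c = int((r_labels == name).sum())
        table = np.array([[a, nv - a], [c, nr - c]])
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            chi2, p = chi_square_2x2(table)
        else:
            chi2, p = np.nan, np.nan
        v_frac = a / nv if nv else np.nan
        r_frac = c / nr if nr else np.nan
        enr = v_frac / r_frac if r_frac else np.nan
        rows.append((name, a, c, v_frac, r_frac, enr, chi2, p))
    out = pd.DataFrame(
        rows,
        columns=[
            "category",
            "n_variant",
            "n_random",
            "variant_fraction",
            "random_fraction",
            "enrichment",
            "chi2",
            "p_value",
        ],
    )
    ok = out["p_value"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    return out


def state_enrichment(
    targets: PeakSet,
    segmentation: PeakSet,
    genome_bases: int,
    flank: int = 0,
    contig_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Fold enrichment of target bases in each chromatin state.

    ``enrichment(state) = (target bases in state / total target bases)
    / (state bases / genome bases)``.  Point targets are expanded by
    +-flank before counting (``flank=0`` uses the intervals as given, the
    full-length-peak mode).  States with zero genomic bases are reported
    missing.  The segmentation's ``name`` column holds the state label.
    """
    if flank > 0:
        mids = targets.midpoints()
        targets = points_to_peakset(
            mids["contig"].tolist(),
            mids["midpoint"].to_numpy(),
            flank=flank,
            contig_lengths=contig_lengths,
        )
    t_total = total_bases(targets)
    rows = []
    for state, grp in segmentation.df.groupby("name", sort=True):
        state_set = PeakSet(grp.reset_index(drop=True))
        state_bases = total_bases(state_set)
        in_state = int(overlap_bases(targets, state_set).sum())
        if state_bases == 0 or t_total == 0:
            rows.append((state, in_state, state_bases, np.nan))
            continue
        enr = (in_state / t_total) / (state_bases / genome_bases)
        rows.append((state, in_state, state_bases, enr))
    return pd.DataFrame(
        rows, columns=["state", "target_bases_in_state", "state_bases", "enrichment"]
    )


# ---------------------------------------------------------------------------
# replication timing
# ---------------------------------------------------------------------------


def replication_quartile_rates(
    mutations: pd.DataFrame, timing: SignalTrack, n_quantiles: int = 4
) -> pd.DataFrame:
    """Relative mutation rate per replication-timing quartile.

    Covered genome bins are split into quartiles of the timing value
    (Q1 = latest replicating = lowest value ... Q4 = earliest), ties broken
    by a stable sort on (value, contig, bin index).  The rate is mutations
    per covered Mb, normalised so the latest quartile equals 1.  Mutations
    on uncovered bins are excluded and their count reported in the
    ``n_excluded`` attribute of the returned frame.
    """
    bins = []
    for contig, vals in timing.values.items():
        for j, v in enumerate(vals):
            if not np.isnan(v):
                bins.append((v, contig, j))
    if not bins:
        raise ValueError("timing track has no covered bins")
    order = sorted(range(len(bins)), key=lambda i: bins[i])
    quartile_of: dict[tuple[str, int], int] = {}
    per_q = len(bins) / n_quantiles
    for rank, i in enumerate(order):
        q = min(int(rank / per_q), n_quantiles - 1)
        _, contig, j = bins[i]
        quartile_of[(contig, j)] = q

    counts = np.zeros(n_quantiles, dtype=np.int64)
    n_excluded = 0
    for row in mutations.itertuples(index=False):
        key = (row.contig, row.position // timing.bin_width)
        if key in quartile_of:
            counts[quartile_of[key]] += 1
        else:
            n_excluded += 1

    mb = np.zeros(n_quantiles)
    for (contig, j), q in quartile_of.items():
        start = j * timing.bin_width
        end = min(start + timing.bin_width, timing.contig_lengths[contig])
        mb[q] += (end - start) / 1e6
    rate = counts / mb
    rel = rate / rate[0] if rate[0] > 0 else np.full(n_quantiles, np.nan)
    out = pd.DataFrame(
        {
            "quartile": [f"Q{i + 1}" for i in range(n_quantiles)],
            "n_mutations": counts,
            "covered_mb": mb,
            "rate_per_mb": rate,
            "relative_rate": rel,
        }
    )
    out.attrs["n_excluded"] = n_excluded
    return out


# ---------------------------------------------------------------------------
# region -> gene (GREAT-style basal plus extension)
# ---------------------------------------------------------------------------


def region_to_gene(
    regions: PeakSet,
    tss: pd.DataFrame,
    basal_upstream: int = 5000,
    basal_downstream: int = 1000,
    extension: int = 1_000_000,
    contig_lengths: dict[str, int] | None = None,
) -> dict[str, list[str]]:
    """Associate regions with genes by basal-plus-extension regulatory domains.

    ``tss`` needs columns ``gene``, ``contig``, ``position`` (0-based TSS)
    and ``strand``.  Each gene's basal domain is -basal_upstream/+
    basal_downstream around its TSS (strand-aware); the domain is then
    extended in both directions up to the nearest neighbouring basal
    domain edge, capped at ``extension`` bp from the TSS.  A region is
    associated with every gene whose domain it intersects.
    """
    domains = []
    for contig, grp in tss.groupby("contig", sort=False):
        length = None if contig_lengths is None else contig_lengths[contig]
        basal = []
        for row in grp.itertuples(index=False):
            if row.strand == "-":
                bs = row.position - basal_downstream + 1
                be = row.position + basal_upstream + 1
            else:
                bs = row.position - basal_upstream
                be = row.position + basal_downstream
            bs = max(0, bs)
            if length is not None:
                be = min(be, length)
            basal.append((row.gene, row.position, bs, be))
        for gene, pos, bs, be in basal:
            # extend to the nearest neighbouring basal edge, cap at `extension`
            # from the TSS, and never shrink below the own basal domain
            left_edges = [b[3] for b in basal if b[0] != gene and b[3] <= pos]
            right_edges = [b[2] for b in basal if b[0] != gene and b[2] >= pos]
            ds = min(bs, max(max(left_edges, default=0), pos - extension, 0))
            cap = length if length is not None else pos + extension
            de = max(be, min(min(right_edges, default=cap), pos + extension, cap))
            domains.append((contig, gene, ds, de))

    out: dict[str, list[str]] = {}
    for row in regions.df.itertuples(index=False):
        genes = [
            g
            for contig, g, ds, de in domains
            if contig == row.contig and row.start < de and ds < row.end
        ]
        out[str(row.name)] = sorted(set(genes))
    return out


# ---------------------------------------------------------------------------
# chi-square 2x2
# ---------------------------------------------------------------------------


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table via the closed form.

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p from the chi-square
    distribution with one degree of freedom.  Zero margins raise (use an
    exact test instead).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin in 2x2 table; use Fisher's exact test")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2, 0.0)
    stat = n * num**2 / np.prod(margins)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p
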