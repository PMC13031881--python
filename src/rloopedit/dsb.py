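"""DSB taxonomy: oestrogen-induced vs A3B-modified breaks and their dependence.

Double-strand-break peaks are classified on two contrasts — induction by
oestradiol (E2) and response to A3B knockdown — and cross-tabulated with
their overlap with A3B binding sites and (overlap-or-proximal) R-loops.
The per-class knockdown dependence is the mean log2 ratio of normalised
DSB signal between A3B-knockdown and non-targeting conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffpeaks import classify_induced, estimate_size_factors, test_differential
from .integration import chi_square_2x2, classify_proximity
from .intervals import PeakSet, overlaps_any

FEATURE_CLASSES = ["A3B_and_Rloop", "A3B_only", "Rloop_only", "neither"]


@dataclass
class DsbClassTable:
    table: pd.DataFrame  # per-DSB flags and class label
    fractions: pd.DataFrame  # per classification axis, fraction per feature class
    chi2: float | None
    p_value: float | None


def _feature_flags(
    dsb_peaks: PeakSet, a3b_peaks: PeakSet, rloops: PeakSet, d: int, rloop_mode: str
) -> pd.DataFrame:
    over_a3b = overlaps_any(dsb_peaks, a3b_peaks)
    if rloop_mode == "overlap":
        near_rloop = overlaps_any(dsb_peaks, rloops)
    elif rloop_mode == "overlap_or_proximal":
        labels, _ = classify_proximity(dsb_peaks, rloops, d=d)
        near_rloop = labels.isin(["overlapping", "proximal"]).to_numpy()
    else:
        raise ValueError("rloop_mode must be 'overlap' or 'overlap_or_proximal'")
    klass = np.select(
        [over_a3b & near_rloop, over_a3b, near_rloop],
        ["A3B_and_Rloop", "A3B_only", "Rloop_only"],
        default="neither",
    )
    return pd.DataFrame(
        {
            "overlaps_A3B": over_a3b,
            "near_Rloop": near_rloop,
            "feature_class": pd.Categorical(klass, categories=FEATURE_CLASSES),
        },
        index=dsb_peaks.df["name"].tolist(),
    )


def classify_dsbs(
    e2_results: pd.DataFrame,
    knockdown_results: pd.DataFrame,
    dsb_peaks: PeakSet,
    a3b_peaks: PeakSet,
    rloops: PeakSet,
    d: int = 1500,
    fdr: float = 0.05,
    fc: float = 1.5,
    rloop_mode: str = "overlap_or_proximal",
) -> DsbClassTable:
    """Classify consensus DSB peaks and cross them with A3B/R-loop features.

    ``e2_results`` and ``knockdown_results`` are differential tables over
    the same DSB feature set (index = peak name).  E2-induced means induced
    (upregulated) on the E2 contrast; A3B-modified means significantly
    changed in either direction on the knockdown contrast.  The chi-square
    tests association between being A3B-modified and sitting at an
    A3B-and-R-loop feature.
    """
    if not e2_results.index.equals(knockdown_results.index):
        raise ValueError("the two differential results cover different feature sets")
    names = list(dsb_peaks.df["name"])
    if set(names) != set(e2_results.index):
        raise ValueError("differential results do not match the DSB peak set")

    e2_flags = classify_induced(e2_results, fdr=fdr, fc=fc)
    kd_flags = classify_induced(knockdown_results, fdr=fdr, fc=fc)
    feat = _feature_flags(dsb_peaks, a3b_peaks, rloops, d, rloop_mode)

    table = feat.copy()
    table["E2_induced"] = (
        e2_flags.loc[table.index, "induced"] & (e2_flags.loc[table.index, "log2FC"] > 0)
    ).to_numpy()
    table["A3B_modified"] = kd_flags.loc[table.index, "induced"].to_numpy()
    table["A3B_direction"] = kd_flags.loc[table.index, "direction"].to_numpy()

    frac_rows = []
    for axis in ["E2_induced", "A3B_modified"]:
        members = table[table[axis]]
        counts = members["feature_class"].value_counts().reindex(FEATURE_CLASSES, fill_value=0)
        total = counts.sum()
        for fc_name in FEATURE_CLASSES:
            frac_rows.append(
                (axis, fc_name, int(counts[fc_name]), counts[fc_name] / total if total else np.nan)
            )
    fractions = pd.DataFrame(frac_rows, columns=["axis", "feature_class", "n", "fraction"])

    both = (table["feature_class"] == "A3B_and_Rloop").to_numpy()
    modified = table["A3B_modified"].to_numpy()
    ct = np.array(
        [
            [int((modified & both).sum()), int((modified & ~both).sum())],
            [int((~modified & both).sum()), int((~modified & ~both).sum())],
        ]
    )
    chi2 = p = None
    if (ct.sum(axis=0) > 0).all() and (ct.sum(axis=1) > 0).all():
        chi2, p = chi_square_2x2(ct)
    return DsbClassTable(table, fractions, chi2, p)


def dependence_ratio_by_class(
    counts: pd.DataFrame,
    genotype: pd.Series,
    class_table: pd.DataFrame,
    knockdown_level: str = "siA3B",
    control_level: str = "NT",
    size_factors: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-class mean log2(knockdown / control) of normalised DSB signal.

    ``class_table`` is the per-DSB table from :func:`classify_dsbs`
    (``feature_class`` column, index = feature names matching ``counts``).
    Features whose control mean is zero are excluded and reported.  Returns
    the per-class summary and a dict with the class-contrast test (Welch's
    t, A3B-and-R-loop class vs all others) plus the per-feature genotype
    Wald test table.
    """
    if size_factors is None:
        # condition-aware refinement: class-conditional knockdown response
        # otherwise drags the factors and biases every log2 ratio
        size_factors = estimate_size_factors(counts, genotype)
    norm = counts.to_numpy(dtype=float) / size_factors[counts.columns].to_numpy()
    kd_cols = np.flatnonzero((genotype[counts.columns] == knockdown_level).to_numpy())
    nt_cols = np.flatnonzero((genotype[counts.columns] == control_level).to_numpy())
    if kd_cols.size == 0 or nt_cols.size == 0:
        raise ValueError("both genotype levels must be present")
    kd_mean = norm[:, kd_cols].mean(axis=1)
    nt_mean = norm[:, nt_cols].mean(axis=1)
    usable = nt_mean > 0
    n_excluded = int((~usable).sum())
    ratio = np.full(len(counts), np.nan)
    ratio[usable] = np.log2(kd_mean[usable] / nt_mean[usable])

    per_feature = pd.DataFrame(
        {
            "log2_ratio": ratio,
            "feature_class": class_table.loc[counts.index, "feature_class"].to_numpy(),
            "excluded": ~usable,
        },
        index=counts.index,
    )
    rows = []
    for fc_name in FEATURE_CLASSES:
        vals = per_feature.loc[
            (per_feature["feature_class"] == fc_name) & usable, "log2_ratio"
        ].to_numpy()
        rows.append(
            (
                fc_name,
                len(vals),
                float(np.mean(vals)) if len(vals) else np.nan,
                float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            )
        )
    summary = pd.DataFrame(rows, columns=["feature_class", "n", "mean_log2_ratio", "sd"])

    in_class = (per_feature["feature_class"] == "A3B_and_Rloop") & usable
    rest = (per_feature["feature_class"] != "A3B_and_Rloop") & usable
    test: dict = {"n_excluded": n_excluded}
    if in_class.sum() >= 2 and rest.sum() >= 2:
        t, p = stats.ttest_ind(
            per_feature.loc[in_class, "log2_ratio"],
            per_feature.loc[rest, "log2_ratio"],
            equal_var=False,
        )
        test["welch_t"] = float(t)
        test["welch_p"] = float(p)
    wald = test_differential(counts, genotype, size_factors=size_factors)
    test["per_feature_wald"] = wald
    return summary, test
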