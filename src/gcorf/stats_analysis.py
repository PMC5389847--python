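"""Statistics over age-stratified protein properties.

Four analyses:

* pairwise two-sided rank-sum (Mann-Whitney) tests between age groups,
  with direction taken from the rank-biserial sign;
* per-species significant-trend counting (how many species show a property
  significantly higher in orphans vs. in ancient proteins, at raw
  ``alpha = 0.01`` with no multiple-testing correction — a deliberate
  faithful-reproduction choice, not a statistical endorsement);
* ordinary least-squares regression of a property on per-protein GC within
  an age group;
* GC-binned running averages of a property (and of each amino acid's
  frequency, with the codon-model expectation alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .codon_model import expected_aa_curve
from .genetic_code import AMINO_ACIDS

logger = logging.getLogger(__name__)

#: Largest combined sample size for which the exact rank-sum null
#: distribution is enumerated; above this the normal approximation with
#: midrank tie correction is used.
EXACT_RANKSUM_MAX_N = 40


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of sample A
    p_two_sided: float
    direction: str  # higher_in_A | higher_in_B | none


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float


@dataclass(frozen=True)
class RunningCurve:
    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray
    property_name: str = ""
    age_group: str = ""


def rank_sum(sample_a, sample_b) -> RankSumResult:
    """Two-sided Mann-Whitney rank-sum test.

    The exact null distribution is enumerated for small samples without
    ties; larger (or tied) samples use the normal approximation with
    midranks and tie correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = (
        "exact" if (a.size + b.size <= EXACT_RANKSUM_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    mid = a.size * b.size / 2.0
    if u_a > mid:
        direction = "higher_in_A"
    elif u_a < mid:
        direction = "higher_in_B"
    else:
        direction = "none"
    return RankSumResult(
        statistic=u_a, p_two_sided=float(res.pvalue), direction=direction
    )


def species_trend_table(
    profiles: pd.DataFrame,
    properties: list[str],
    alpha: float = 0.01,
    group_a: str = "orphan",
    group_b: str = "ancient",
) -> pd.DataFrame:
    """Count, per property, the species where it is significantly higher in
    one age group than the other.

    ``profiles`` needs ``species`` and ``age_group`` columns plus one column
    per property.  For each species with both groups present, an
    orphan-vs-ancient rank-sum test is run; species are counted by direction
    among those with ``p < alpha``.  Species lacking either group are
    skipped (logged).

    Returns a DataFrame indexed by property with columns
    ``n_higher_in_orphans``, ``n_higher_in_ancient`` and ``n_species_tested``.
    """
    rows = {}
    for prop in properties:
        n_a = n_b = n_tested = 0
        for sp, sub in profiles.groupby("species"):
            x = sub.loc[sub["age_group"] == group_a, prop].dropna().to_numpy()
            y = sub.loc[sub["age_group"] == group_b, prop].dropna().to_numpy()
            if x.size == 0 or y.size == 0:
                logger.debug("species %s lacks %s or %s; skipped", sp, group_a, group_b)
                continue
            n_tested += 1
            res = rank_sum(x, y)
            if res.p_two_sided < alpha:
                if res.direction == "higher_in_A":
                    n_a += 1
                elif res.direction == "higher_in_B":
                    n_b += 1
        rows[prop] = {
            f"n_higher_in_{group_a}s": n_a,
            f"n_higher_in_{group_b}s": n_b,
            "n_species_tested": n_tested,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("property")


def property_gc_regression(gc, values) -> RegressionResult:
    """OLS of a property on per-protein GC (slope, intercept, Pearson r, p)."""
    x = np.asarray(gc, dtype=float)
    y = np.asarray(values, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3 or len(np.unique(x)) < 2:
        raise ValueError("need >=3 points with non-constant GC")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
    )


def running_average(
    x,
    y,
    bin_width: float = 0.01,
    min_count: int = 20,
    property_name: str = "",
    age_group: str = "",
) -> RunningCurve:
    """Binned mean of ``y`` against ``x`` (GC), suppressing sparse bins.

    Bins are consecutive intervals of width ``bin_width`` aligned to
    multiples of the width; bins with fewer than ``min_count`` points are
    dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size == 0:
        return RunningCurve(
            np.empty(0), np.empty(0), np.empty(0, dtype=int),
            property_name, age_group,
        )
    idx = np.floor(x / bin_width).astype(int)
    centers, means, counts = [], [], []
    for i in np.unique(idx):
        sel = idx == i
        n = int(sel.sum())
        if n < min_count:
            continue
        centers.append((i + 0.5) * bin_width)
        means.append(float(y[sel].mean()))
        counts.append(n)
    return RunningCurve(
        np.array(centers), np.array(means), np.array(counts, dtype=int),
        property_name, age_group,
    )


def curve_frame(curve: RunningCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "property": curve.property_name,
            "age_group": curve.age_group,
            "gc_bin_center": curve.bin_centers,
            "mean": curve.bin_means,
            "count": curve.bin_counts,
        }
    )


def observed_vs_expected_aa(
    profiles: pd.DataFrame,
    bin_width: float = 0.01,
    min_count: int = 20,
) -> pd.DataFrame:
    """Observed amino-acid frequency vs GC per age group, with the
    codon-model expectation.

    ``profiles`` needs ``cds_gc``, ``age_group`` and the 20 ``freq_*``
    columns.  Returns a long DataFrame with columns ``amino_acid``,
    ``age_group`` (the pseudo-group ``"expected"`` holds the analytic
    curve), ``gc_bin_center``, ``mean`` and ``count``.
    """
    frames = []
    for aa in AMINO_ACIDS:
        for grp, sub in profiles.groupby("age_group", dropna=True):
            curve = running_average(
                sub["cds_gc"], sub[f"freq_{aa}"],
                bin_width=bin_width, min_count=min_count,
                property_name=f"freq_{aa}", age_group=str(grp),
            )
            f = curve_frame(curve)
            f.insert(0, "amino_acid", aa)
            frames.append(f)
    gc = profiles["cds_gc"].dropna()
    if len(gc):
        lo = np.floor(gc.min() / bin_width)
        hi = np.floor(gc.max() / bin_width)
        centers = (np.arange(lo, hi + 1) + 0.5) * bin_width
        centers = centers[(centers > 0) & (centers < 1)]
        expected = expected_aa_curve(centers)
        for j, aa in enumerate(AMINO_ACIDS):
            frames.append(
                pd.DataFrame(
                    {
                        "amino_acid": aa,
                        "property": f"freq_{aa}",
                        "age_group": "expected",
                        "gc_bin_center": centers,
                        "mean": expected[:, j],
                        "count": 0,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
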