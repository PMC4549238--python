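"""Group-level statistics against the transcriptome-wide background.

The workhorse is a two-sided Wilcoxon rank-sum test of a focal gene group
against *all other tested genes* (not all genes): exact by enumeration for
tiny tie-free samples, otherwise a normal approximation with tie-corrected
variance and 0.5 continuity correction.  On top of it sit the category/family
sweep, per-module ECDF comparisons, the top-N list-overlap statistic with
hypergeometric upper-tail p-values, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu, norm, rankdata

from .errors import ConfigError, DataValidationError
from .formats import CategoryMap

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # combined size up to which the tie-free test is enumerated


@dataclass
class WilcoxonResult:
    statistic: float   # rank-sum W of the first group
    z: float           # normal-approximation z (NaN on the exact path)
    p_value: float     # two-sided
    method: str        # "exact" | "approx"


def _rank_sum_normal(w, n_x, n_y, tie_term):
    """Two-sided normal approximation with tie correction and 0.5 continuity."""
    n = n_x + n_y
    mean = n_x * (n + 1) / 2.0
    var = n_x * n_y * (n + 1) / 12.0 - n_x * n_y * tie_term / (12.0 * n * (n - 1))
    if var <= 0:
        return 0.0, 1.0
    z = max(abs(w - mean) - 0.5, 0.0) / math.sqrt(var)
    z = math.copysign(z, w - mean) if w != mean else 0.0
    return z, 2.0 * norm.sf(abs(z))


def _tie_term(pooled_sorted_or_ranks=None, counts=None):
    """Sum over tie groups of t^3 - t."""
    if counts is None:
        _, counts = np.unique(pooled_sorted_or_ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def wilcoxon_rank_sum(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample has at most 12 observations
    and no ties; otherwise the tie-corrected continuity-corrected normal
    approximation.  Symmetric in its arguments: swapping groups leaves the
    p-value unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    ranks = rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if pooled.size <= EXACT_MAX_N and not has_ties:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return WilcoxonResult(w, float("nan"), float(res.pvalue), "exact")
    z, p = _rank_sum_normal(w, x.size, y.size, _tie_term(pooled))
    return WilcoxonResult(w, z, min(p, 1.0), "approx")


def rank_sum_sweep(values: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Vectorized normal-approximation rank-sum p-values for many groups.

    ``membership`` is a (n_groups, n_values) boolean matrix; every group is
    tested against its complement within the *same* pooled sample, so ranks
    and the tie correction are computed once.  Identical to the approximate
    path of :func:`wilcoxon_rank_sum` (same formula, shared implementation
    of the normal step).
    """
    values = np.asarray(values, dtype=float)
    ranks = rankdata(values)
    tie = _tie_term(values)
    out = np.empty(membership.shape[0])
    for i, mask in enumerate(membership):
        n_x = int(mask.sum())
        n_y = values.size - n_x
        if n_x == 0 or n_y == 0:
            out[i] = np.nan
            continue
        w = float(ranks[mask].sum())
        _, out[i] = _rank_sum_normal(w, n_x, n_y, tie)
    return out


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs pass through unchanged and do not count toward the number of tests.
    Monotone and bounded by 1.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise DataValidationError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adjusted, 1.0)
    out[ok] = np.maximum(res, pv)  # guard the p*m/i round-trip at i = m
    return out


# ---------------------------------------------------------------------------
# category sweep
# ---------------------------------------------------------------------------

def category_sweep(values: pd.Series, categories: CategoryMap,
                   min_size: int = 5) -> pd.DataFrame:
    """Rank-sum test of every category's members against all other tested genes.

    ``values`` are per-gene statistics (e.g. interaction log2FC) over the
    analysis universe.  Categories with fewer than ``min_size`` tested
    members are skipped (logged).  Returns one row per tested category with
    the member count, median value, raw p and BH-adjusted p, sorted by p.
    """
    values = values.dropna()
    universe = set(values.index)
    rows = []
    for cat in categories.categories:
        members = [g for g in set(categories.members(cat)) if g in universe]
        if len(members) < min_size:
            logger.info("category %s skipped: %d tested members < min_size %d",
                        cat, len(members), min_size)
            continue
        member_mask = values.index.isin(members)
        res = wilcoxon_rank_sum(values[member_mask], values[~member_mask])
        rows.append({
            "category": cat,
            "name": categories.name_of(cat),
            "n": len(members),
            "median_log2FC": float(values[member_mask].median()),
            "p_value": res.p_value,
        })
    df = pd.DataFrame(rows, columns=["category", "name", "n", "median_log2FC",
                                     "p_value"])
    if len(df):
        df["BH_p_value"] = benjamini_hochberg(df["p_value"].to_numpy())
        df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        df["BH_p_value"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# co-expression-module comparison
# ---------------------------------------------------------------------------

def _ecdf(values: np.ndarray):
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, x.size + 1) / x.size
    return x, y


def module_cdf_compare(values: pd.Series, module_assignments: pd.Series
                       ) -> tuple[pd.DataFrame, dict]:
    """Per-module rank-sum comparison of member values against all other genes.

    Every gene belongs to at most one module.  Modules are ranked by the
    absolute difference between the module median and the median of the
    complement.  Also returns the pair of ECDF step functions per module for
    plotting: ``{module: {"module": (x, y), "background": (x, y)}}``.
    """
    values = values.dropna()
    modules = module_assignments.reindex(values.index).dropna()
    rows, ecdfs = [], {}
    for mod in sorted(modules.unique(), key=str):
        members = modules.index[modules == mod]
        inside = values.loc[values.index.isin(members)]
        outside = values.loc[~values.index.isin(members)]
        if len(outside) == 0:
            raise DataValidationError(
                f"module {mod!r} contains every tested gene; empty complement")
        if len(inside) == 0:
            continue
        res = wilcoxon_rank_sum(inside, outside)
        rows.append({
            "module": mod,
            "n": len(inside),
            "median_difference": float(inside.median() - outside.median()),
            "p_value": res.p_value,
        })
        ecdfs[mod] = {"module": _ecdf(inside.to_numpy()),
                      "background": _ecdf(outside.to_numpy())}
    df = pd.DataFrame(rows)
    df["BH_p_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    df = df.reindex(
        df["median_difference"].abs().sort_values(ascending=False,
                                                  kind="mergesort").index)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True), ecdfs


# ---------------------------------------------------------------------------
# top-N list overlap
# ---------------------------------------------------------------------------

def list_overlap(query, references, universe_size: int) -> pd.DataFrame:
    """Overlap of a top-N gene list with reference top-N lists.

    Per reference list: overlap count ``k`` and hypergeometric upper-tail
    probability P[X >= k] of drawing ``k`` or more shared genes when the
    reference is a random draw of its size from the universe.  Ranked by
    overlap count (descending), ties broken by p-value.
    """
    query = list(query)
    if len(set(query)) != len(query):
        raise DataValidationError("duplicate ids within the query list")
    if len(query) > universe_size:
        raise ConfigError("query larger than the universe")
    qset = set(query)
    if isinstance(references, dict):
        items = references.items()
    else:
        items = ((f"list_{i}", ref) for i, ref in enumerate(references))
    rows = []
    for name, ref in items:
        ref = list(ref)
        if len(set(ref)) != len(ref):
            raise DataValidationError(f"duplicate ids within reference {name!r}")
        if len(ref) > universe_size:
            raise ConfigError(f"reference {name!r} larger than the universe")
        k = len(qset & set(ref))
        p = float(hypergeom.sf(k - 1, universe_size, len(query), len(ref)))
        rows.append({"reference": name, "overlap": k, "p_value": p})
    df = pd.DataFrame(rows)
    df = df.sort_values(["overlap", "p_value"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def top_fraction(overlaps: pd.DataFrame, q: float) -> pd.DataFrame:
    """The ceil(q * m) best-ranked reference lists (e.g. q=0.03: the top 3%)."""
    if not 0 < q <= 1:
        raise ConfigError("q must lie in (0, 1]")
    k = math.ceil(q * len(overlaps))
    return overlaps.head(k)
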