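"""Count filtering, TMM normalization, CPM/FPKM and sample-clustering diagnostics.

TMM (trimmed mean of M-values) is implemented in full: reference selection by
the 75th-percentile count fraction, double trimming of gene-wise M (30%) and
A (5%) values, inverse delta-method precision weights, and rescaling of the
factors to geometric mean one.  Spike-in rows are excluded from the M/A
computation (their fraction allocation is deliberately unrepresentative of
the transcriptome) but are normalized by the resulting factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .errors import ConfigError, DataValidationError
from .formats import FractionCountMatrix


@dataclass
class NormalizationState:
    """Per-sample library sizes and TMM factors (geometric mean 1)."""

    library_sizes: pd.Series
    factors: pd.Series

    @property
    def effective_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors

    @classmethod
    def unit(cls, matrix: FractionCountMatrix) -> "NormalizationState":
        """Library-size-only normalization (all factors 1)."""
        lib = matrix.counts.sum(axis=0).astype(float)
        return cls(lib, pd.Series(1.0, index=lib.index))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_low_counts(matrix: FractionCountMatrix, min_count: int = 6
                      ) -> FractionCountMatrix:
    """Drop genes whose minimum count over all samples is below ``min_count``.

    The default retains exactly the genes with at least 6 reads in *every*
    sample (i.e. removes genes with 5 or fewer reads in one or more samples).
    Spike-in rows are exempt and always kept.  Idempotent.
    """
    keep = (matrix.counts.min(axis=1) >= min_count) | matrix.spike_mask
    return matrix.subset_genes(matrix.genes[keep])


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def tmm_factors(matrix: FractionCountMatrix, trim_m: float = 0.30,
                trim_a: float = 0.05) -> NormalizationState:
    """Trimmed-mean-of-M-values normalization factors.

    Reference sample: the one whose 75th-percentile count fraction is closest
    to the mean of those quantiles across samples.  Per sample, gene-wise
    M (log2 ratio vs reference after library-size scaling) and A (mean log2
    abundance) values are computed over genes positive in both libraries;
    the top and bottom ``trim_m`` of M and ``trim_a`` of A are trimmed, and
    the factor is 2 to the precision-weighted mean of the surviving M values,
    with weights from the delta-method binomial variance.  Factors are
    rescaled to geometric mean 1.
    """
    counts = matrix.counts.loc[~matrix.spike_mask].to_numpy(dtype=float)
    if matrix.counts.shape[1] < 2:
        raise ConfigError("TMM needs at least two samples")
    lib = matrix.counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib == 0):
        bad = matrix.counts.columns[lib == 0][0]
        raise DataValidationError(f"sample {bad!r} has zero total counts")
    frac = counts / lib

    q75 = np.quantile(frac, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_factors = np.zeros(counts.shape[1])
    for k in range(counts.shape[1]):
        if k == ref:
            continue
        log_factors[k] = _tmm_pair(counts[:, k], counts[:, ref],
                                   lib[k], lib[ref], trim_m, trim_a)
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    idx = matrix.counts.columns
    return NormalizationState(pd.Series(lib, index=idx),
                              pd.Series(factors, index=idx))


def _tmm_pair(y, y_ref, n, n_ref, trim_m, trim_a):
    """Weighted trimmed mean of M values of one library against the reference."""
    ok = (y > 0) & (y_ref > 0)
    y, y_ref = y[ok], y_ref[ok]
    if y.size == 0:
        raise DataValidationError("no genes positive in both sample and reference")
    p, p_ref = y / n, y_ref / n_ref
    m = np.log2(p / p_ref)
    a = 0.5 * np.log2(p * p_ref)
    if np.max(np.abs(m)) < 1e-10:          # identical relative profiles
        return 0.0
    # double trimming: drop the extreme trim_m of M and trim_a of A
    lo_m, hi_m = np.quantile(m, [trim_m, 1.0 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1.0 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        return 0.0
    # delta-method variance of M: (n-y)/(n*y) summed over the two libraries
    w = 1.0 / ((n - y[keep]) / (n * y[keep]) + (n_ref - y_ref[keep]) / (n_ref * y_ref[keep]))
    return float(np.sum(w * m[keep]) / np.sum(w))


# ---------------------------------------------------------------------------
# CPM / FPKM
# ---------------------------------------------------------------------------

def cpm(matrix: FractionCountMatrix, state: NormalizationState,
        log2: bool = False, prior: float = 0.5) -> pd.DataFrame:
    """Counts per million over TMM-effective library sizes.

    The log2 variant stabilizes zeros by adding a library-size-proportional
    prior count to the numerator and twice it to the denominator, so the
    result is finite for zero counts and invariant to doubling both counts
    and library sizes.
    """
    if not state.effective_sizes.index.equals(matrix.counts.columns):
        raise DataValidationError("normalization state does not match matrix columns")
    eff = state.effective_sizes.to_numpy(dtype=float)
    counts = matrix.counts.to_numpy(dtype=float)
    if not log2:
        vals = counts * 1e6 / eff
    else:
        prior_s = prior * eff / eff.mean()
        vals = np.log2((counts + prior_s) * 1e6 / (eff + 2.0 * prior_s))
    return pd.DataFrame(vals, index=matrix.genes, columns=matrix.counts.columns)


def fpkm(counts, gene_lengths, library_size) -> np.ndarray:
    """Fragments per kilobase of exon per million mapped fragments."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ConfigError("gene lengths must be positive")
    return counts / (lengths / 1e3) / (np.asarray(library_size, dtype=float) / 1e6)


# ---------------------------------------------------------------------------
# sample clustering
# ---------------------------------------------------------------------------

def cluster_samples(ratio_matrix: pd.DataFrame,
                    fpkm_matrix: pd.DataFrame | None = None,
                    min_fpkm: float = 0.5):
    """Hierarchical clustering of samples on per-gene long/short log-ratios.

    Distance between two sample columns is ``1 - Pearson correlation`` over
    the retained genes (those with FPKM >= ``min_fpkm`` in all samples of
    ``fpkm_matrix``, when given); average linkage; deterministic
    lexicographic input order.  Returns ``(linkage, distance_df, leaf_order)``.
    """
    if ratio_matrix.shape[1] < 2:
        raise ConfigError("need at least two sample columns to cluster")
    ratios = ratio_matrix[sorted(ratio_matrix.columns)]
    if fpkm_matrix is not None:
        keep = (fpkm_matrix >= min_fpkm).all(axis=1)
        keep = keep.reindex(ratios.index, fill_value=False)
        ratios = ratios.loc[keep]
    arr = ratios.to_numpy(dtype=float)
    if np.any(arr.std(axis=0) == 0):
        bad = ratios.columns[arr.std(axis=0) == 0][0]
        raise DataValidationError(
            f"sample {bad!r} has a constant ratio vector; correlation undefined")
    corr = np.corrcoef(arr, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    order = [ratios.columns[i] for i in leaves_list(linkage)]
    dist_df = pd.DataFrame(dist, index=ratios.columns, columns=ratios.columns)
    return linkage, dist_df, order


def cut_two_clusters(linkage, labels) -> tuple:
    """Split the dendrogram at the root into its two top-level clusters."""
    from scipy.cluster.hierarchy import fcluster

    assignment = fcluster(linkage, t=2, criterion="maxclust")
    a = {lab for lab, c in zip(labels, assignment) if c == 1}
    b = {lab for lab, c in zip(labels, assignment) if c == 2}
    return a, b
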