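"""Per-gene negative-binomial inference of tail-length and abundance changes.

The tail-length proxy of a transcript is its normalized abundance in the
long fraction relative to the short fraction.  A genotype-dependent change
in tail length therefore appears as a *ratio of ratios*: the interaction
term of a per-gene NB log-linear model

    log mu = log(effective library size) + b0 + b1*long + b2*mut + b3*long*mut

where ``b3`` is the log ratio-of-ratios (negative: shorter tails in the
mutant).  Dispersions are per-gene moment estimates from Pearson residuals
of a Poisson fit, shrunk toward the median with a prior weight of 10
residual degrees of freedom; p-values come from a likelihood-ratio test of
``b3 = 0`` against chi-square(1).  Abundance changes use the same machinery
on the summed short+long counts per starting sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConfigError, DataValidationError
from .formats import FractionCountMatrix
from .grouptest import benjamini_hochberg
from .normalize import NormalizationState, fpkm

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)
_PHI_FLOOR = 1e-8       # NB with phi below this is numerically Poisson
_MAX_ITER = 50
_DEV_TOL = 1e-8


# ---------------------------------------------------------------------------
# batched NB GLM (log link, offset), IRLS
# ---------------------------------------------------------------------------

def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Negative-binomial deviance, rows = genes.  phi -> 0 recovers Poisson."""
    phi = np.maximum(np.asarray(phi, dtype=float)[:, None], _PHI_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + 1.0 / phi) * (np.log1p(phi * y) - np.log1p(phi * mu))
    return 2.0 * np.sum(term1 - term2, axis=1)


def nb_glm_batch(Y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                 phi: np.ndarray):
    """Fit one NB log-linear model per row of ``Y`` by IRLS.

    All genes share the design ``X`` (n x p) and ``offset`` (n,); ``phi``
    is the per-gene dispersion held fixed during the fit.  Returns
    ``(beta (G,p), deviance (G,), converged (G,))``.  Convergence: relative
    deviance change below 1e-8 within 50 iterations.
    """
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ConfigError("design matrix is not full rank")
    phi = np.maximum(np.asarray(phi, dtype=float), _PHI_FLOOR)

    beta = np.zeros((G, p))
    baseline = np.log(np.maximum(Y.mean(axis=1) / np.exp(offset).mean(), 1e-8))
    beta[:, 0] = baseline
    dev = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    eye = np.eye(p) * 1e-9
    for _ in range(_MAX_ITER):
        eta = offset[None, :] + beta @ X.T
        mu = np.clip(np.exp(eta), 1e-10, 1e12)
        W = mu / (1.0 + phi[:, None] * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X, optimize=True) + eye
        XtWz = np.einsum("ni,gn->gi", X, W * z, optimize=True)
        try:
            beta_new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            break
        beta = np.where(converged[:, None], beta, beta_new)
        eta = offset[None, :] + beta @ X.T
        mu = np.clip(np.exp(eta), 1e-10, 1e12)
        dev_new = nb_deviance(Y, mu, phi)
        delta = np.abs(dev_new - dev)
        newly = delta < _DEV_TOL * (np.abs(dev_new) + 0.1)
        dev = np.where(converged, dev, dev_new)
        converged |= newly
        if converged.all():
            break
    return beta, dev, converged


def _moment_dispersions(Y: np.ndarray, design: np.ndarray, offset: np.ndarray,
                        prior_df: float = 10.0) -> np.ndarray:
    n, p = design.shape
    df = n - p
    if df < 1:
        raise ConfigError(
            f"no residual degrees of freedom: {n} samples, {p} coefficients")
    beta, _, _ = nb_glm_batch(Y, design, offset, np.zeros(Y.shape[0]))
    mu = np.clip(np.exp(offset[None, :] + beta @ design.T), 1e-10, 1e12)
    sq = (Y - mu) ** 2
    # solve sum (y-mu)^2 / (mu + phi*mu^2) = chi2 median(df) for phi by
    # bisection (the statistic is monotone decreasing in phi).  Targeting the
    # chi-square *median* rather than its mean (= df) makes the per-gene
    # estimates median-unbiased despite the right skew of the Pearson
    # statistic, which keeps the common (median) dispersion centred.
    target = chi2.ppf(0.5, df)
    lo = np.zeros(Y.shape[0])
    hi = np.full(Y.shape[0], 10.0)
    solvable = np.sum(sq / mu, axis=1) > target
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        x2 = np.sum(sq / (mu + mid[:, None] * mu**2), axis=1)
        high = x2 > target
        lo = np.where(high, mid, lo)
        hi = np.where(high, hi, mid)
    raw = np.where(solvable, 0.5 * (lo + hi), 0.0)
    common = float(np.median(raw))
    return (df * raw + prior_df * common) / (df + prior_df)


def estimate_dispersions(matrix: FractionCountMatrix, state: NormalizationState,
                         design: np.ndarray, prior_df: float = 10.0) -> pd.Series:
    """Per-gene NB dispersions, moment-estimated and shrunk toward the median.

    A Poisson GLM is fitted per gene; the Pearson chi-square of its residuals
    yields a method-of-moments dispersion (floored at 0), which is then
    shrunk toward the across-gene median with a prior weight equivalent to
    ``prior_df`` residual degrees of freedom.
    """
    Y = matrix.counts.to_numpy(dtype=float)
    offset = np.log(state.effective_sizes.to_numpy(dtype=float))
    shrunk = _moment_dispersions(Y, design, offset, prior_df)
    return pd.Series(shrunk, index=matrix.genes, name="dispersion")


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _interaction_design(samples: pd.DataFrame, reference: str | None):
    genotypes = []
    for g in samples["genotype"]:
        if g not in genotypes:
            genotypes.append(g)
    if len(genotypes) != 2:
        raise DataValidationError(
            f"need exactly two genotypes, found {genotypes}")
    if reference is None:
        reference = genotypes[0]
    if reference not in genotypes:
        raise ConfigError(f"reference genotype {reference!r} not present")
    test = [g for g in genotypes if g != reference][0]
    if set(samples["fraction"]) != {"short", "long"}:
        raise DataValidationError("both fractions must be present")
    long_ind = (samples["fraction"] == "long").to_numpy(float)
    mut_ind = (samples["genotype"] == test).to_numpy(float)
    X = np.column_stack([np.ones(len(samples)), long_ind, mut_ind,
                         long_ind * mut_ind])
    return X, reference, test


@dataclass
class TailChangeFit:
    """Full per-gene fit bundle behind the tail-change result table."""

    results: pd.DataFrame
    dispersions: pd.Series
    reference: str
    test: str


def test_tail_change(matrix: FractionCountMatrix, state: NormalizationState,
                     reference: str | None = None) -> pd.DataFrame:
    """Per-gene interaction test of the long/short ratio between genotypes.

    Returns a frame indexed by gene with ``log2FC_ratio`` (= b3/ln2; the
    log2 ratio of the mutant to the reference long/short ratio), the fitted
    per-genotype long/short log2-ratios, ``logCPM``, the LRT ``p_value``
    and ``BH_p_value``.  Genes whose fit fails to converge get NA p-values
    and are excluded from the BH denominator.
    """
    X, ref, test = _interaction_design(matrix.samples, reference)
    Y = matrix.counts.to_numpy(dtype=float)
    eff = state.effective_sizes.to_numpy(dtype=float)
    offset = np.log(eff)
    disp = estimate_dispersions(matrix, state, X)
    phi = disp.to_numpy()

    beta_full, dev_full, conv_full = nb_glm_batch(Y, X, offset, phi)
    beta_red, dev_red, conv_red = nb_glm_batch(Y, X[:, :3], offset, phi)
    lrt = np.maximum(dev_red - dev_full, 0.0)
    p = chi2.sf(lrt, 1)
    ok = conv_full & conv_red
    if not ok.all():
        logger.warning("%d genes did not converge; reported as NA", (~ok).sum())
    p = np.where(ok, p, np.nan)

    mean_cpm = (Y / eff[None, :] * 1e6).mean(axis=1)
    res = pd.DataFrame(
        {
            "log2FC_ratio": beta_full[:, 3] / LN2,
            f"ls_log2_{ref}": beta_full[:, 1] / LN2,
            f"ls_log2_{test}": (beta_full[:, 1] + beta_full[:, 3]) / LN2,
            "logCPM": np.log2(np.maximum(mean_cpm, 1e-8)),
            "p_value": p,
            "BH_p_value": benjamini_hochberg(p),
            "dispersion": phi,
        },
        index=matrix.genes,
    )
    return res


def test_abundance_change(matrix: FractionCountMatrix, state: NormalizationState,
                          reference: str | None = None) -> pd.DataFrame:
    """Genotype effect on combined (short+long) abundance per starting sample.

    Fraction pairs are summed per (genotype, replicate) with the summed
    effective library sizes as offset; the genotype coefficient is tested by
    LRT against chi-square(1).
    """
    samples = matrix.samples
    genotypes = matrix.genotypes
    if len(genotypes) != 2:
        raise DataValidationError(f"need exactly two genotypes, found {genotypes}")
    ref = reference if reference is not None else genotypes[0]
    if ref not in genotypes:
        raise ConfigError(f"reference genotype {ref!r} not present")
    test = [g for g in genotypes if g != ref][0]

    pairs = []
    for (gt, rep), sub in samples.groupby(["genotype", "replicate"], sort=False):
        pairs.append((gt, rep, list(sub.index)))
    Y = np.column_stack([
        matrix.counts[cols].sum(axis=1).to_numpy(dtype=float)
        for _, _, cols in pairs
    ])
    eff = state.effective_sizes
    offset = np.log(np.array([eff[cols].sum() for _, _, cols in pairs]))
    mut_ind = np.array([1.0 if gt == test else 0.0 for gt, _, _ in pairs])
    X = np.column_stack([np.ones(len(pairs)), mut_ind])

    phi = _moment_dispersions(Y, X, offset)
    beta_full, dev_full, conv_full = nb_glm_batch(Y, X, offset, phi)
    beta_red, dev_red, conv_red = nb_glm_batch(Y, X[:, :1], offset, phi)
    lrt = np.maximum(dev_red - dev_full, 0.0)
    ok = conv_full & conv_red
    p = np.where(ok, chi2.sf(lrt, 1), np.nan)
    return pd.DataFrame(
        {
            "log2FC": beta_full[:, 1] / LN2,
            "logCPM": np.log2(np.maximum(
                (Y / np.exp(offset)[None, :] * 1e6).mean(axis=1), 1e-8)),
            "p_value": p,
            "BH_p_value": benjamini_hochberg(p),
            "dispersion": phi,
        },
        index=matrix.genes,
    )


# ---------------------------------------------------------------------------
# plug-in tail proxy and per-pair ratio matrix
# ---------------------------------------------------------------------------

def tail_proxy(matrix: FractionCountMatrix, state: NormalizationState,
               genotype: str, prior: float = 0.5) -> pd.Series:
    """Plug-in per-gene log2(long/short) for one genotype.

    CPMs (prior-adjusted to stay finite on zeros) are summed across the
    genotype's replicates within each fraction before taking the log ratio.
    """
    if genotype not in matrix.genotypes:
        raise ConfigError(f"genotype {genotype!r} not present")
    eff = state.effective_sizes
    adj = (matrix.counts + prior).mul(1e6).div(eff, axis=1)
    long_cols = matrix.columns_for(genotype, "long")
    short_cols = matrix.columns_for(genotype, "short")
    return pd.Series(
        np.log2(adj[long_cols].sum(axis=1) / adj[short_cols].sum(axis=1)),
        index=matrix.genes, name=f"ls_log2_{genotype}")


def ratio_matrix(matrix: FractionCountMatrix, state: NormalizationState,
                 prior: float = 0.5) -> pd.DataFrame:
    """Per-gene log2(long/short) per (genotype, replicate) pair, for clustering."""
    eff = state.effective_sizes
    adj = (matrix.counts + prior).mul(1e6).div(eff, axis=1)
    cols = {}
    for (gt, rep), sub in matrix.samples.groupby(["genotype", "replicate"],
                                                 sort=False):
        long_col = sub.index[sub["fraction"] == "long"][0]
        short_col = sub.index[sub["fraction"] == "short"][0]
        cols[f"{gt}_r{rep}"] = np.log2(adj[long_col] / adj[short_col])
    return pd.DataFrame(cols, index=matrix.genes)


# ---------------------------------------------------------------------------
# spike-in abundance proxy
# ---------------------------------------------------------------------------

def spike_in_abundance_proxy(fpkm_value, rna_concentration,
                             mapped_nonrrna_fraction):
    """Absolute-abundance proxy: fpkm x RNA concentration x non-rRNA mapping rate."""
    f = np.asarray(fpkm_value, dtype=float)
    c = np.asarray(rna_concentration, dtype=float)
    m = np.asarray(mapped_nonrrna_fraction, dtype=float)
    if np.any(f < 0) or np.any(c <= 0) or np.any(m <= 0):
        raise ConfigError("fpkm must be >= 0; concentration and mapping fraction > 0")
    out = f * c * m
    return out if out.ndim else float(out)


def spike_proxy_table(matrix: FractionCountMatrix,
                      gene_lengths: pd.Series) -> pd.DataFrame:
    """Per-spike, per-sample abundance proxies plus short/long ratios.

    Requires ``rna_concentration`` and ``mapped_nonrrna_fraction`` in the
    sample metadata; raises naming the offending sample when missing.
    Returns one row per (spike, genotype, replicate) with the proxy in each
    fraction and their short/long ratio.
    """
    for col in ("rna_concentration", "mapped_nonrrna_fraction"):
        if col not in matrix.samples:
            raise DataValidationError(f"sample metadata lacks {col!r}")
        missing = matrix.samples.index[matrix.samples[col].isna()]
        if len(missing):
            raise DataValidationError(
                f"sample {missing[0]!r} is missing {col!r}")
    spikes = sorted(matrix.spike_genes)
    if not spikes:
        raise DataValidationError("matrix contains no spike-in rows")
    lib = matrix.library_sizes()
    rows = []
    for (gt, rep), sub in matrix.samples.groupby(["genotype", "replicate"],
                                                 sort=False):
        frac_cols = {fr: sub.index[sub["fraction"] == fr][0]
                     for fr in ("short", "long")}
        for spike in spikes:
            proxies = {}
            for fr, col in frac_cols.items():
                f = fpkm(matrix.counts.at[spike, col], gene_lengths[spike],
                         lib[col])
                proxies[fr] = spike_in_abundance_proxy(
                    f, matrix.samples.at[col, "rna_concentration"],
                    matrix.samples.at[col, "mapped_nonrrna_fraction"])
            rows.append({
                "spike": spike, "genotype": gt, "replicate": rep,
                "proxy_short": proxies["short"], "proxy_long": proxies["long"],
                "short_long_ratio": proxies["short"] / proxies["long"]
                if proxies["long"] > 0 else np.inf,
            })
    return pd.DataFrame(rows)
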