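"""3'-UTR sequence-feature association.

Terminal-window hexamer sweeps (all 4096 6-mers), targeted tests of the
canonical polyadenylation signal AATAAA and its single-substitution
variants, base-composition profiles around the cleavage site, and Pearson
correlations of tail statistics with transcript features.  Motif presence
is boolean (at least one occurrence inside the terminal window); groups are
compared with the same rank-sum machinery used everywhere else.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import ConfigError, DataValidationError
from .formats import UTRAnnotation
from .grouptest import benjamini_hochberg, rank_sum_sweep

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
BASES = "ACGT"
CANONICAL_SIGNAL = "AATAAA"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# window extraction / composition profiles
# ---------------------------------------------------------------------------

def extract_terminal_window(annotation: UTRAnnotation, genome: dict,
                            window: int = 100) -> dict:
    """Strand-aware terminal sequence ending at the most distal cleavage site.

    Plus strand: the ``window`` bases immediately 5' of the distal site;
    minus strand: the reverse complement of the bases 3' of the site on the
    forward strand.  UTRs shorter than the window return their full length.
    """
    out = {}
    for gene, rec in annotation.records.items():
        chrom = rec["chrom"]
        if chrom not in genome:
            raise DataValidationError(f"gene {gene!r}: contig {chrom!r} not in genome")
        contig = genome[chrom]
        site = annotation.distal_site(gene)
        if not 0 <= site <= len(contig):
            raise DataValidationError(
                f"gene {gene!r}: cleavage site {site} outside contig "
                f"{chrom!r} (length {len(contig)})")
        w_eff = min(window, annotation.utr_length(gene))
        if rec["strand"] == "+":
            out[gene] = contig[site - w_eff: site]
        else:
            out[gene] = reverse_complement(contig[site: site + w_eff])
    return out


def base_composition_profile(annotation: UTRAnnotation, genome: dict,
                             flank: int = 200, genes=None) -> pd.DataFrame:
    """Per-position nucleotide frequencies around the distal cleavage site.

    Positions run from ``-flank`` to ``flank - 1`` relative to the cleavage
    site (position 0 = first base past the site in transcript orientation),
    strand-aware.  Positions beyond a contig edge are treated as missing and
    excluded from that position's denominator; at each position the four
    frequencies sum to one.
    """
    genes = list(annotation.records if genes is None else genes)
    if not genes:
        raise DataValidationError("empty gene set")
    positions = np.arange(-flank, flank)
    counts = pd.DataFrame(0, index=positions, columns=list(BASES))
    for gene in genes:
        rec = annotation.records[gene]
        contig = genome[rec["chrom"]]
        site = annotation.distal_site(gene)
        if rec["strand"] == "+":
            start = site - flank
            seg = contig[max(start, 0): min(site + flank, len(contig))]
            pad_left = max(0, -start)
            seq = "N" * pad_left + seg + "N" * (2 * flank - pad_left - len(seg))
        else:
            start = site - flank
            seg = contig[max(start, 0): min(site + flank, len(contig))]
            pad_left = max(0, -start)
            padded = "N" * pad_left + seg + "N" * (2 * flank - pad_left - len(seg))
            seq = reverse_complement(padded)
        for pos, base in zip(positions, seq):
            if base in BASES:
                counts.at[pos, base] += 1
    totals = counts.sum(axis=1)
    freq = counts.div(totals.replace(0, np.nan), axis=0)
    freq.index.name = "position"
    return freq


# ---------------------------------------------------------------------------
# hexamer sweeps
# ---------------------------------------------------------------------------

def all_hexamers() -> list:
    return ["".join(p) for p in itertools.product(BASES, repeat=6)]


def single_substitution_variants(motif: str = CANONICAL_SIGNAL) -> list:
    """The motif itself plus every single-base substitution of it."""
    variants = [motif]
    for i, ref in enumerate(motif):
        for b in BASES:
            if b != ref:
                variants.append(motif[:i] + b + motif[i + 1:])
    return variants


def _presence_matrix(windows: dict, motifs, genes):
    """Boolean (motif x gene) presence matrix via a sliding k-mer scan."""
    index = {m: i for i, m in enumerate(motifs)}
    lengths = sorted({len(m) for m in motifs})
    mat = np.zeros((len(motifs), len(genes)), dtype=bool)
    for j, g in enumerate(genes):
        seq = windows[g]
        for k in lengths:
            for s in range(len(seq) - k + 1):
                i = index.get(seq[s: s + k])
                if i is not None:
                    mat[i, j] = True
    return mat


def _motif_frame(motifs, presence, values):
    """Shared test/effect computation for full and targeted sweeps."""
    n_total = values.size
    n_with = presence.sum(axis=1)
    testable = (n_with > 0) & (n_with < n_total)
    skipped = [m for m, t in zip(motifs, testable) if not t]
    if skipped:
        logger.info("%d motifs skipped (absent from all or present in all windows)",
                    len(skipped))
    p = np.full(len(motifs), np.nan)
    p[testable] = rank_sum_sweep(values, presence[testable])
    linear = 2.0 ** values
    eff_diff = np.full(len(motifs), np.nan)
    eff_ratio = np.full(len(motifs), np.nan)
    for i in np.flatnonzero(testable):
        inside = presence[i]
        eff_diff[i] = values[inside].mean() - values[~inside].mean()
        ratio = linear[inside].mean() / linear[~inside].mean()
        eff_ratio[i] = math.log2(ratio) if ratio > 0 else np.nan
    df = pd.DataFrame({
        "motif": motifs,
        "n_with": n_with,
        "n_without": n_total - n_with,
        "effect_mean_diff": eff_diff,
        "enrichment_log2_ratio": eff_ratio,
        "p_value": p,
    })
    df = df[testable].reset_index(drop=True)
    df["BH_p_value"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def hexamer_sweep(windows: dict, tail_changes: pd.Series) -> pd.DataFrame:
    """Test all 4096 hexamers for association with the tail-length change.

    For each motif, genes whose terminal window contains it are compared to
    genes lacking it by a rank-sum test on the per-gene log2FC; two effect
    sizes are reported — the difference of group means (primary) and the
    log2 ratio of group means of the linearized fold-changes (secondary).
    Motifs present in none or in all windows are skipped.  BH correction is
    across the tested motifs.
    """
    values = tail_changes.dropna()
    genes = [g for g in values.index if g in windows]
    values = values.loc[genes].to_numpy(dtype=float)
    motifs = all_hexamers()
    presence = _presence_matrix(windows, motifs, genes)
    return _motif_frame(motifs, presence, values)


def variant_signal_test(windows: dict, tail_changes: pd.Series,
                        variants=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Targeted version of the sweep for polyadenylation-signal variants.

    Default variants: AATAAA plus its 18 single-substitution variants.
    Additionally returns a positional occurrence profile: per variant, the
    number of occurrences starting at each offset relative to the cleavage
    site (the window's 3' end; offset -6 is a motif ending exactly at the
    site).
    """
    if variants is None:
        variants = single_substitution_variants()
    variants = [v.upper() for v in variants]
    for v in variants:
        if len(v) != 6 or set(v) - set(BASES):
            raise ConfigError(f"variant {v!r} is not an ACGT 6-mer")
    values = tail_changes.dropna()
    genes = [g for g in values.index if g in windows]
    arr = values.loc[genes].to_numpy(dtype=float)
    presence = _presence_matrix(windows, variants, genes)
    results = _motif_frame(variants, presence, arr)

    max_w = max((len(windows[g]) for g in genes), default=0)
    offsets = np.arange(-max_w, -5)  # motif start offsets relative to the site
    prof = pd.DataFrame(0, index=offsets, columns=variants)
    for g in genes:
        seq = windows[g]
        L = len(seq)
        for v in variants:
            start = 0
            while True:
                i = seq.find(v, start)
                if i < 0:
                    break
                prof.at[i - L, v] += 1  # window ends at the cleavage site
                start = i + 1
    prof.index.name = "offset"
    return results, prof


# ---------------------------------------------------------------------------
# feature correlations
# ---------------------------------------------------------------------------

def feature_correlations(metric: pd.Series, features: pd.DataFrame,
                         columns=None) -> pd.DataFrame:
    """Pearson correlation of a per-gene metric with each feature column.

    Pairs with a missing value are dropped per feature; ``t`` and the
    two-sided p use ``df = n - 2``.  Constant features yield NA with a
    warning.  Requires at least 3 complete pairs.
    """
    cols = list(features.columns if columns is None else columns)
    rows = []
    for col in cols:
        joined = pd.concat([metric, features[col]], axis=1, join="inner").dropna()
        n = len(joined)
        if n < 3:
            raise DataValidationError(
                f"feature {col!r}: only {n} complete pairs (need >= 3)")
        x = joined.iloc[:, 0].to_numpy(dtype=float)
        y = joined.iloc[:, 1].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("feature %r is constant; correlation undefined", col)
            rows.append({"feature": col, "n": n, "r": np.nan, "t": np.nan,
                         "p_value": np.nan})
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = max(min(r, 1.0), -1.0)
        if abs(r) == 1.0:
            t_stat, p = math.inf if r > 0 else -math.inf, 0.0
        else:
            t_stat = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * t_dist.sf(abs(t_stat), n - 2)
        rows.append({"feature": col, "n": n, "r": r, "t": t_stat, "p_value": p})
    return pd.DataFrame(rows)
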