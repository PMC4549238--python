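"""Synthetic fractionation experiments with known ground truth.

The generator emulates a two-genotype poly(A)-fractionation design: total RNA
from each starting sample is split into a *short*- and a *long*-tail fraction
around a ~50-nt cutoff, and both fractions are sequenced.  Per gene, a
steady-state tail-length distribution (gamma, truncated at 200 nt) determines
the probability that a transcript molecule is captured in the long fraction
via a logistic capture curve; expected counts are split accordingly and
negative-binomial noise is added.  Three spike-in RNAs with fixed tails of
30, 75 and 134 A are appended with equal expected totals in every sample.

Everything downstream (normalization, interaction tests, group statistics,
motif sweeps, ePAT arithmetic) can therefore be exercised against a recorded
truth table without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataValidationError
from .formats import (CategoryMap, FractionCountMatrix, UTRAnnotation,
                      write_category_map, write_counts, write_fasta,
                      write_feature_table, write_utr_bed)
from .validate import EPATTrace

TAIL_GAMMA_SHAPE = 4.0  # CV = 0.5; fixed shape of the per-gene tail distribution


# ---------------------------------------------------------------------------
# capture model
# ---------------------------------------------------------------------------

def capture_probability(tail_length, cutoff: float = 50.0, steepness: float = 0.15):
    """Probability that a molecule with the given tail ends up in the long fraction.

    Logistic in tail length: ``1 / (1 + exp(-steepness * (tail - cutoff)))``;
    strictly increasing in ``tail_length`` for positive steepness.
    """
    tail = np.asarray(tail_length, dtype=float)
    if np.any(tail < 0):
        raise ConfigError("tail_length must be non-negative")
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-steepness * (tail - cutoff)))
    return p if p.ndim else float(p)


def mean_capture_probability(mean_tail, cutoff=50.0, steepness=0.15,
                             shape=TAIL_GAMMA_SHAPE, truncation=200.0,
                             n_points=201):
    """Capture probability averaged over a gene's tail distribution.

    The tail distribution is gamma with the given mean and shape, truncated at
    ``truncation`` nt; the average is a trapezoid quadrature on an
    ``n_points`` grid over [0, truncation].
    """
    from scipy.stats import gamma as gamma_dist

    mean_tail = np.atleast_1d(np.asarray(mean_tail, dtype=float))
    t = np.linspace(0.0, truncation, n_points)
    cap = capture_probability(t, cutoff, steepness)
    scale = mean_tail / shape  # (G,)
    pdf = gamma_dist.pdf(t[None, :], a=shape, scale=scale[:, None])
    norm = np.trapezoid(pdf, t, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.trapezoid(pdf * cap[None, :], t, axis=1) / norm
    # distributions concentrated below the grid resolution: use the point value
    tiny = ~np.isfinite(p)
    if tiny.any():
        p[tiny] = capture_probability(mean_tail[tiny], cutoff, steepness)
    return p if p.size > 1 else float(p[0])


def _tail_mean_for_capture(target_p, cutoff, steepness, truncation):
    """Invert mean_capture_probability in the tail mean (monotone bisection)."""
    lo, hi = 1e-3, truncation
    f = lambda m: mean_capture_probability(m, cutoff, steepness,
                                           truncation=truncation) - target_p
    if f(lo) > 0 or f(hi) < 0:
        raise ConfigError(
            f"target capture probability {target_p:.4g} not reachable with "
            f"tails in (0, {truncation}]"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# configuration / experiment containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study-design constants of the simulated fractionation experiment.

    Defaults mirror the emulated design: two genotypes with four biological
    replicates each (16 libraries), a ~50-nt capture cutoff, spike-ins of
    30/75/134 A, per-gene mean tails spanning 30-150 nt with distributions
    truncated at 200 nt, and NB count noise with dispersion 0.1.
    """

    n_genes: int = 5000
    n_replicates: int = 4
    genotypes: tuple = ("wt", "mut")
    cutoff_nt: float = 50.0
    capture_steepness: float = 0.15    # 1/nt; ~95% capture at 70 nt
    tail_mean_range: tuple = (30.0, 150.0)
    tail_truncation_nt: float = 200.0
    dispersion: float = 0.1            # NB dispersion phi (0 -> Poisson)
    mean_expression: tuple = (5.3, 1.0)  # lognormal (mu, sigma) of expected totals
    effect_fraction: float = 0.1
    effect_log2: float = -1.0          # planted interaction log2FC on the l/s odds
    abundance_log2: float = 0.0        # planted total-abundance log2FC of effect genes
    spike_tails: tuple = (30.0, 75.0, 134.0)
    spike_expected_total: float = 2000.0
    size_factor_range: tuple = (0.7, 1.4)  # per-sample log-uniform library scaling
    seed: int = 0

    def __post_init__(self):
        if self.cutoff_nt <= 0:
            raise ConfigError("cutoff_nt must be positive")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ConfigError("effect_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if any(t <= 0 for t in self.spike_tails):
            raise ConfigError("spike_tails must be strictly positive")
        if len(self.genotypes) != 2:
            raise ConfigError("exactly two genotypes are supported")


@dataclass
class SimulatedExperiment:
    """Counts plus everything needed to close the loop on parameter recovery."""

    counts: FractionCountMatrix
    truth: pd.DataFrame           # indexed by gene
    annotation: UTRAnnotation
    sequences: dict               # gene -> 3'-UTR sequence (stop -> distal site)
    genome: dict                  # chrom -> sequence consistent with annotation
    categories: CategoryMap
    half_lives: pd.Series
    gene_lengths: pd.Series       # transcript length in bp (for FPKM)
    config: SimConfig


def _nb_draw(rng, mean, phi):
    """Negative-binomial draw with mean ``mean`` and dispersion ``phi``."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _gene_rng(seed: int, stream: int, counter: int = 0) -> np.random.Generator:
    # per-gene counter-derived substreams, keyed (seed, stream, gene index):
    # results for gene i never depend on how many other genes exist
    return np.random.default_rng([seed, stream, counter])


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate a complete fractionation experiment from a :class:`SimConfig`.

    Per gene: a wild-type mean tail is drawn, the mean capture probability is
    computed by quadrature over the gamma tail distribution, the mutant
    capture odds of effect genes are shifted by ``2**effect_log2`` (realised
    as a multiplicative shrinkage of the mutant mean tail found by
    bisection), and fraction counts are NB-sampled around expected totals.
    Reproducible bit-for-bit from ``config.seed``.
    """
    if config.n_replicates < 2:
        raise ConfigError("n_replicates must be >= 2 (inference needs replication)")
    cfg = config
    rng_global = _gene_rng(cfg.seed, 9)  # sample-level stream

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    g_wt, g_mut = cfg.genotypes

    # -- sample layout ------------------------------------------------------
    samples = []
    for gt in cfg.genotypes:
        for rep in range(1, cfg.n_replicates + 1):
            for fr in ("short", "long"):
                samples.append((f"{gt}_r{rep}_{fr}", gt, rep, fr))
    sample_ids = [s[0] for s in samples]
    n_samples = len(samples)
    log_lo, log_hi = np.log(cfg.size_factor_range[0]), np.log(cfg.size_factor_range[1])
    size_factors = np.exp(rng_global.uniform(log_lo, log_hi, size=n_samples))
    rna_conc = rng_global.uniform(20.0, 40.0, size=n_samples)
    mapped_frac = rng_global.uniform(0.5, 0.8, size=n_samples)

    # -- per-gene truth -----------------------------------------------------
    n_effect = int(round(cfg.effect_fraction * cfg.n_genes))
    effect_idx = rng_global.choice(cfg.n_genes, size=n_effect, replace=False)
    is_effect = np.zeros(cfg.n_genes, dtype=bool)
    is_effect[effect_idx] = True

    wt_tail = np.empty(cfg.n_genes)
    expr = np.empty(cfg.n_genes)
    for i in range(cfg.n_genes):
        rng = _gene_rng(cfg.seed, 0, i)
        wt_tail[i] = rng.uniform(*cfg.tail_mean_range)
        expr[i] = rng.lognormal(*cfg.mean_expression)

    p_wt = np.asarray(mean_capture_probability(
        wt_tail, cfg.cutoff_nt, cfg.capture_steepness,
        truncation=cfg.tail_truncation_nt))
    p_mut = p_wt.copy()
    mut_tail = wt_tail.copy()
    if n_effect and cfg.effect_log2 != 0.0:
        odds = p_wt[is_effect] / (1.0 - p_wt[is_effect])
        odds_mut = odds * 2.0 ** cfg.effect_log2
        p_target = odds_mut / (1.0 + odds_mut)
        for j, i in enumerate(np.flatnonzero(is_effect)):
            mut_tail[i] = _tail_mean_for_capture(
                p_target[j], cfg.cutoff_nt, cfg.capture_steepness,
                cfg.tail_truncation_nt)
        p_mut[is_effect] = p_target
    true_log2fc = np.where(
        is_effect,
        np.log2((p_mut / (1 - p_mut)) / (p_wt / (1 - p_wt))),
        0.0,
    )

    # -- counts -------------------------------------------------------------
    counts = np.zeros((cfg.n_genes + len(cfg.spike_tails), n_samples), dtype=np.int64)
    p_by_genotype = {g_wt: p_wt, g_mut: p_mut}
    for i in range(cfg.n_genes):
        rng = _gene_rng(cfg.seed, 1, i)
        for s, (sid, gt, rep, fr) in enumerate(samples):
            p = p_by_genotype[gt][i]
            share = p if fr == "long" else 1.0 - p
            total = expr[i]
            if is_effect[i] and gt == g_mut:
                total *= 2.0 ** cfg.abundance_log2
            counts[i, s] = _nb_draw(rng, total * share * size_factors[s],
                                    cfg.dispersion)

    spike_ids = [f"spike_{int(t)}A" for t in cfg.spike_tails]
    p_spike = capture_probability(np.asarray(cfg.spike_tails), cfg.cutoff_nt,
                                  cfg.capture_steepness)
    for k, sid_gene in enumerate(spike_ids):
        rng = _gene_rng(cfg.seed, 2, k)
        for s, (sid, gt, rep, fr) in enumerate(samples):
            share = p_spike[k] if fr == "long" else 1.0 - p_spike[k]
            # spike-ins: identical expected totals in every sample
            counts[cfg.n_genes + k, s] = _nb_draw(
                rng, cfg.spike_expected_total * share, cfg.dispersion)

    all_genes = genes + spike_ids
    counts_df = pd.DataFrame(counts, index=pd.Index(all_genes, name="gene"),
                             columns=sample_ids)
    meta = pd.DataFrame(
        {
            "genotype": [s[1] for s in samples],
            "replicate": [s[2] for s in samples],
            "fraction": [s[3] for s in samples],
            "library_size": counts_df.sum(axis=0).to_numpy(),
            "rna_concentration": rna_conc,
            "mapped_nonrrna_fraction": mapped_frac,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    matrix = FractionCountMatrix(counts_df, meta, frozenset(spike_ids))

    truth = pd.DataFrame(
        {
            "wt_tail_mean": np.concatenate([wt_tail, cfg.spike_tails]),
            "mut_tail_mean": np.concatenate([mut_tail, cfg.spike_tails]),
            "p_long_wt": np.concatenate([p_wt, p_spike]),
            "p_long_mut": np.concatenate([p_mut, p_spike]),
            "true_log2fc": np.concatenate([true_log2fc, np.zeros(len(spike_ids))]),
            "true_abundance_log2fc": np.concatenate(
                [np.where(is_effect, cfg.abundance_log2, 0.0),
                 np.zeros(len(spike_ids))]),
            "is_effect": np.concatenate([is_effect, np.zeros(len(spike_ids), bool)]),
            "is_spike": np.concatenate(
                [np.zeros(cfg.n_genes, bool), np.ones(len(spike_ids), bool)]),
            "mean_expression": np.concatenate(
                [expr, np.full(len(spike_ids), cfg.spike_expected_total)]),
        },
        index=pd.Index(all_genes, name="gene"),
    )

    # -- sequences, annotation, genome --------------------------------------
    sequences, annotation, genome, gene_lengths = _build_sequences(cfg, genes, spike_ids)

    categories = _build_categories(cfg, genes, is_effect)
    half_lives = generate_half_lives(truth, target_r=-0.21, seed=cfg.seed)

    return SimulatedExperiment(matrix, truth, annotation, sequences, genome,
                               categories, half_lives, gene_lengths, cfg)


def _build_sequences(cfg, genes, spike_ids):
    """Random 3'-UTR sequences placed on a single toy chromosome.

    Even-indexed genes sit on the plus strand, odd-indexed on the minus
    strand; the genomic segment of a minus-strand gene holds the reverse
    complement of its UTR so that strand-aware extraction recovers the
    stored sequence.
    """
    comp = str.maketrans("ACGT", "TGCA")
    slot = 400
    sequences, records = {}, {}
    chrom = "chr1"
    genome_parts = []
    lengths = {}
    pos = 0
    for i, gene in enumerate(genes):
        rng = _gene_rng(cfg.seed, 3, i)
        utr_len = int(rng.integers(80, 251))
        seq = "".join(rng.choice(list("ACGT"), size=utr_len))
        n_sites = int(rng.integers(1, 4))
        inner = sorted(
            int(round(utr_len * u)) for u in rng.uniform(0.3, 0.9, size=n_sites - 1)
        )
        strand = "+" if i % 2 == 0 else "-"
        pad = slot - utr_len
        left = pad // 2
        start = pos + left              # genomic start of the UTR segment
        if strand == "+":
            stop = start
            sites = [start + d for d in inner] + [start + utr_len]
            segment = seq
        else:
            stop = start + utr_len
            sites = [start] + [start + utr_len - d for d in inner]
            segment = seq.translate(comp)[::-1]
        filler_l = "".join(rng.choice(list("ACGT"), size=left))
        filler_r = "".join(rng.choice(list("ACGT"), size=pad - left))
        genome_parts.append(filler_l + segment + filler_r)
        sequences[gene] = seq
        records[gene] = {"chrom": chrom, "strand": strand, "stop": stop,
                         "cleavage_sites": sites}
        lengths[gene] = utr_len + 1000  # toy transcript length for FPKM
        pos += slot
    genome = {chrom: "".join(genome_parts)}
    for sid in spike_ids:
        lengths[sid] = 500
    return sequences, UTRAnnotation(records), genome, pd.Series(lengths, name="length")


def _build_categories(cfg, genes, is_effect, n_categories: int = 40):
    rng = _gene_rng(cfg.seed, 8)
    rows = []
    arr = np.asarray(genes)
    for c in range(n_categories):
        size = int(rng.integers(10, 101))
        members = rng.choice(arr, size=min(size, len(arr)), replace=False)
        for g in members:
            rows.append({"category": f"bin_{c:02d}", "name": f"category {c}", "gene": g})
    effect_genes = arr[is_effect]
    if len(effect_genes):
        fam = rng.choice(effect_genes, size=min(60, len(effect_genes)), replace=False)
        for g in fam:
            rows.append({"category": "FAM_TARGET", "name": "planted target family",
                         "gene": g})
    return CategoryMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# motif planting / half-lives / ePAT fixtures
# ---------------------------------------------------------------------------

def plant_motif(sequences: Mapping[str, str], motif: str, gene_set,
                window: int = 100, seed: int = 0) -> dict:
    """Insert ``motif`` at a seeded random offset within the terminal window.

    Only the listed genes are touched; the motif overwrites ``len(motif)``
    bases inside the last ``window`` nt (or the full sequence if shorter).
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise DataValidationError(f"motif must be over ACGT, got {motif!r}")
    if len(motif) > window:
        raise ConfigError("motif longer than the terminal window")
    missing = [g for g in gene_set if g not in sequences]
    if missing:
        raise DataValidationError(f"genes not in sequence set: {missing[:10]}")
    out = dict(sequences)
    rng = np.random.default_rng([seed, 7])
    for gene in gene_set:
        seq = out[gene]
        w_eff = min(window, len(seq))
        if w_eff < len(motif):
            raise ConfigError(f"sequence of {gene!r} shorter than the motif")
        off = int(rng.integers(0, w_eff - len(motif) + 1))
        start = len(seq) - w_eff + off
        out[gene] = seq[:start] + motif + seq[start + len(motif):]
    return out


def generate_half_lives(truth: pd.DataFrame, target_r: float = -0.21,
                        seed: int = 0, mean_hours: float = 6.0,
                        sd_hours: float = 1.5) -> pd.Series:
    """Half-lives (hours) correlated with the true wild-type mean tail.

    Gaussian construction: z = r * x + sqrt(1 - r^2) * eps with x the
    standardized wild-type tail mean, mapped affinely to positive hours.
    The sample Pearson correlation with the tail means converges to
    ``target_r`` as the gene count grows.
    """
    if not -1.0 < target_r < 1.0:
        raise ConfigError("target_r must lie strictly inside (-1, 1)")
    sub = truth.loc[~truth["is_spike"]]
    x = sub["wt_tail_mean"].to_numpy(dtype=float)
    xs = (x - x.mean()) / x.std()
    rng = np.random.default_rng([seed, 11])
    eps = rng.standard_normal(len(xs))
    z = target_r * xs + math.sqrt(1.0 - target_r**2) * eps
    hl = np.maximum(mean_hours + sd_hours * z, 0.1)
    return pd.Series(hl, index=sub.index, name="half_life")


def generate_epat_traces(mean_tail_by_group: Mapping[str, float],
                         utr_length: float = 300.0,
                         size_grid: Sequence[float] | None = None,
                         seed: int = 0, n_replicates: int = 3,
                         tail_shape: float = TAIL_GAMMA_SHAPE,
                         peak_sd: float = 5.0,
                         noise_sd: float = 0.03) -> list:
    """Synthetic electropherogram traces for the tail-extension PCR assay.

    Per group (genotype): the *control* product is a Gaussian peak at the
    tail-less product size ``utr_length``; the *ePAT* product is that peak
    smeared by the group's tail-length distribution (gamma with the given
    mean, or a point mass at zero).  Multiplicative replicate noise is
    applied; intensities are clipped at zero.
    """
    from scipy.stats import gamma as gamma_dist, norm

    grid = (np.arange(200.0, 601.0, 2.0) if size_grid is None
            else np.asarray(size_grid, dtype=float))
    if np.any(np.diff(grid) <= 0):
        raise ConfigError("size_grid must be strictly increasing")
    rng = np.random.default_rng([seed, 13])
    traces = []
    control_mean = norm.pdf(grid, loc=utr_length, scale=peak_sd)
    for group, mean_tail in mean_tail_by_group.items():
        if mean_tail > 0:
            tails = np.linspace(0.0, 4.0 * mean_tail, 161)
            w = gamma_dist.pdf(tails, a=tail_shape, scale=mean_tail / tail_shape)
            w /= w.sum()
            epat_mean = (norm.pdf(grid[:, None], loc=utr_length + tails[None, :],
                                  scale=peak_sd) * w[None, :]).sum(axis=1)
        else:
            epat_mean = control_mean.copy()
        for rep in range(1, n_replicates + 1):
            for assay, base in (("ePAT", epat_mean), ("control", control_mean)):
                noisy = base * (1.0 + noise_sd * rng.standard_normal(len(grid)))
                traces.append(EPATTrace(
                    sample_id=f"{group}_r{rep}_{assay}", assay=assay,
                    genotype=group, replicate=rep, size_grid=grid.copy(),
                    intensity=np.clip(noisy, 0.0, None)))
    return traces


# ---------------------------------------------------------------------------
# on-disk export of the standard pipeline inputs
# ---------------------------------------------------------------------------

def write_experiment(exp: SimulatedExperiment, outdir) -> dict:
    """Write counts/meta/FASTA/BED/category/feature/truth files; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "meta": outdir / "samples.tsv",
        "regions": outdir / "utr_regions.fa",
        "genome": outdir / "genome.fa",
        "utr_bed": outdir / "utrs.bed",
        "categories": outdir / "categories.tsv",
        "features": outdir / "features.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_counts(exp.counts, paths["counts"], paths["meta"])
    write_fasta(exp.sequences, paths["regions"])
    write_fasta(exp.genome, paths["genome"])
    write_utr_bed(exp.annotation, paths["utr_bed"])
    write_category_map(exp.categories, paths["categories"])
    features = exp.annotation.feature_frame()
    features["half_life"] = exp.half_lives
    features["length"] = exp.gene_lengths
    write_feature_table(features, paths["features"])
    exp.truth.to_csv(paths["truth"], sep="\t", na_rep="NA")
    return paths
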