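"""Readers and writers for every file the pipeline touches.

Conventions, fixed once for the whole package:

* tables are tab-delimited UTF-8 with a header line; ``#`` starts a comment;
  missing numeric fields serialize as ``NA`` and parsers accept ``NA`` or
  an empty field;
* genomic coordinates are **0-based half-open** internally.  GFF3 input
  (1-based, closed) is converted by subtracting one from the start; BED input
  is already 0-based half-open and passes through unchanged;
* a fractionation experiment has exactly one *short* and one *long* column
  per (genotype, replicate) pair.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError

FRACTIONS = ("short", "long")

#: column order of the tail-change result table (per-genotype long/short
#: log2-ratios are appended after these, one column per genotype)
RESULT_COLUMNS = ["gene", "log2FC_ratio", "logCPM", "p_value", "BH_p_value"]


# ---------------------------------------------------------------------------
# fraction count matrix
# ---------------------------------------------------------------------------

@dataclass
class FractionCountMatrix:
    """Integer gene x sample counts plus per-sample metadata.

    ``counts`` is a genes-by-samples integer DataFrame; ``samples`` is indexed
    by sample id with columns ``genotype``, ``replicate``, ``fraction`` and
    optional ``library_size``, ``rna_concentration``,
    ``mapped_nonrrna_fraction``.  ``spike_genes`` flags rows that are
    synthetic spike-in controls rather than transcriptome genes.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    spike_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dups[:5]}")
        if not c.columns.equals(self.samples.index):
            missing = set(c.columns) ^ set(self.samples.index)
            raise DataValidationError(
                f"count columns and sample metadata disagree: {sorted(missing)[:5]}"
            )
        arr = c.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise DataValidationError("counts must be numeric")
            if (arr < 0).any():
                bad = np.argwhere(arr < 0)[0]
                raise DataValidationError(
                    f"negative count at gene {c.index[bad[0]]!r}, "
                    f"sample {c.columns[bad[1]]!r}"
                )
            if not np.issubdtype(arr.dtype, np.integer):
                frac = arr != np.round(arr)
                if frac.any():
                    bad = np.argwhere(frac)[0]
                    raise DataValidationError(
                        f"non-integer count {arr[bad[0], bad[1]]} at gene "
                        f"{c.index[bad[0]]!r}, sample {c.columns[bad[1]]!r}"
                    )
                self.counts = c.astype(np.int64)
        bad_frac = set(self.samples["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise DataValidationError(f"unknown fraction labels: {sorted(bad_frac)}")
        # every (genotype, replicate) needs exactly one short and one long
        grouped = self.samples.groupby(["genotype", "replicate"], sort=False)
        for (gt, rep), sub in grouped:
            fr = sorted(sub["fraction"])
            if fr != sorted(FRACTIONS):
                raise DataValidationError(
                    f"unpaired sample: genotype {gt!r}, replicate {rep!r} "
                    f"has fractions {fr} (need one 'short' and one 'long')"
                )

    # -- convenience accessors --------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def genotypes(self) -> list:
        seen: list = []
        for g in self.samples["genotype"]:
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def spike_mask(self) -> pd.Series:
        return pd.Series(self.genes.isin(self.spike_genes), index=self.genes)

    def library_sizes(self) -> pd.Series:
        """Per-sample library size: metadata value if present, else column sum."""
        if "library_size" in self.samples and self.samples["library_size"].notna().all():
            return self.samples["library_size"].astype(float)
        return self.counts.sum(axis=0).astype(float)

    def columns_for(self, genotype=None, fraction=None) -> list:
        sel = pd.Series(True, index=self.samples.index)
        if genotype is not None:
            sel &= self.samples["genotype"] == genotype
        if fraction is not None:
            sel &= self.samples["fraction"] == fraction
        return list(self.samples.index[sel])

    def subset_genes(self, genes: Iterable) -> "FractionCountMatrix":
        genes = pd.Index(genes)
        return FractionCountMatrix(
            self.counts.loc[genes], self.samples,
            frozenset(g for g in self.spike_genes if g in genes),
        )


def read_counts(counts_path, meta_path, spike_genes: Iterable = ()) -> FractionCountMatrix:
    """Read a counts TSV (genes x samples) and its sample-metadata TSV.

    Fails loudly on duplicate gene ids, non-integer entries and unpaired
    (genotype, replicate) fraction pairs.
    """
    counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0,
                       na_values=["NA", ""])
    required = {"genotype", "replicate", "fraction"}
    if not required <= set(meta.columns):
        raise DataValidationError(
            f"sample metadata missing columns: {sorted(required - set(meta.columns))}"
        )
    missing = set(counts.columns) - set(meta.index)
    if missing:
        raise DataValidationError(f"metadata missing for samples: {sorted(missing)}")
    meta = meta.loc[counts.columns]
    return FractionCountMatrix(counts, meta, frozenset(spike_genes))


def write_counts(matrix: FractionCountMatrix, counts_path, meta_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene")
    matrix.samples.to_csv(meta_path, sep="\t", index_label="sample", na_rep="NA")


# ---------------------------------------------------------------------------
# 3'-UTR annotation
# ---------------------------------------------------------------------------

@dataclass
class UTRAnnotation:
    """Per-gene 3'-UTR geometry.

    ``records`` maps gene id -> dict with keys ``chrom``, ``strand``
    ('+'/'-'), ``stop`` (stop-codon boundary, 0-based) and
    ``cleavage_sites`` (sorted list of annotated 3'-end coordinates,
    0-based).  On the plus strand cleavage sites lie at or beyond the stop
    coordinate; mirrored on the minus strand.
    """

    records: dict

    def __post_init__(self) -> None:
        for gene, rec in self.records.items():
            if rec["strand"] not in "+-":
                raise DataValidationError(
                    f"gene {gene!r}: strand must be '+' or '-', got {rec['strand']!r}"
                )
            sites = sorted(set(rec["cleavage_sites"]))
            if not sites:
                raise DataValidationError(f"gene {gene!r}: no cleavage sites")
            if rec["strand"] == "+" and sites[0] < rec["stop"]:
                raise DataValidationError(
                    f"gene {gene!r}: cleavage site {sites[0]} upstream of stop "
                    f"{rec['stop']} on + strand"
                )
            if rec["strand"] == "-" and sites[-1] > rec["stop"]:
                raise DataValidationError(
                    f"gene {gene!r}: cleavage site {sites[-1]} downstream of stop "
                    f"{rec['stop']} on - strand"
                )
            rec["cleavage_sites"] = sites

    @property
    def genes(self) -> list:
        return list(self.records)

    def distal_site(self, gene) -> int:
        """Most distal cleavage site (largest stop-to-site distance)."""
        rec = self.records[gene]
        sites = rec["cleavage_sites"]
        return sites[-1] if rec["strand"] == "+" else sites[0]

    def n_utrs(self, gene) -> int:
        return len(self.records[gene]["cleavage_sites"])

    def utr_length(self, gene) -> int:
        """Maximum stop-to-cleavage-site distance in bp."""
        rec = self.records[gene]
        return abs(self.distal_site(gene) - rec["stop"])

    def feature_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "utr_length": self.utr_length(g), "n_utrs": self.n_utrs(g)}
            for g in self.records
        ]
        return pd.DataFrame(rows).set_index("gene")


def _collapse_sites(sites: Sequence[int], collapse_nt: int) -> list:
    """Collapse cleavage sites closer than ``collapse_nt`` to one site."""
    sites = sorted(set(sites))
    if collapse_nt <= 0 or len(sites) < 2:
        return sites
    kept = [sites[0]]
    for s in sites[1:]:
        if s - kept[-1] > collapse_nt:
            kept.append(s)
    return kept


def read_utr_annotation(paths, dialect: str = "bed", collapse_nt: int = 0) -> UTRAnnotation:
    """Read one or more 3'-UTR annotation files (BED6 or GFF3).

    Every interval is interpreted as a 3' UTR running from the stop-codon
    boundary to a cleavage site: on the plus strand (start=stop, end=site),
    mirrored on the minus strand.  Multiple files are merged per gene by the
    union of cleavage sites; the stop codon of the *first* file mentioning a
    gene is authoritative.  Distinct sites closer than ``collapse_nt`` are
    collapsed (default 0: count sites as-is).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if dialect not in ("bed", "gff3"):
        raise DataValidationError(f"unknown annotation dialect {dialect!r}")
    records: dict = {}
    for path in paths:
        for chrom, start, end, gene, strand in _iter_utr_intervals(path, dialect):
            if strand not in "+-":
                raise DataValidationError(
                    f"{path}: invalid strand {strand!r} for gene {gene!r}"
                )
            stop, site = (start, end) if strand == "+" else (end, start)
            rec = records.setdefault(
                gene, {"chrom": chrom, "strand": strand, "stop": stop,
                       "cleavage_sites": []}
            )
            if rec["strand"] != strand or rec["chrom"] != chrom:
                raise DataValidationError(
                    f"gene {gene!r}: conflicting chrom/strand across annotations"
                )
            rec["cleavage_sites"].append(site)
    for rec in records.values():
        rec["cleavage_sites"] = _collapse_sites(rec["cleavage_sites"], collapse_nt)
    return UTRAnnotation(records)


def _iter_utr_intervals(path, dialect):
    if dialect == "bed":
        bed = pd.read_csv(path, sep="\t", comment="#", header=None,
                          names=["chrom", "start", "end", "name", "score", "strand"],
                          dtype={"chrom": str, "name": str, "strand": str})
        for row in bed.itertuples(index=False):
            yield row.chrom, int(row.start), int(row.end), row.name, row.strand
    else:  # gff3: 1-based closed -> subtract 1 from start
        gff = pd.read_csv(path, sep="\t", comment="#", header=None,
                          names=["seqid", "source", "type", "start", "end",
                                 "score", "strand", "phase", "attributes"],
                          dtype=str)
        gff = gff[gff["type"] == "three_prime_UTR"]
        for row in gff.itertuples(index=False):
            yield (row.seqid, int(row.start) - 1, int(row.end),
                   _gff_gene_id(row.attributes), row.strand)


def _gff_gene_id(attributes: str) -> str:
    attrs = dict(
        kv.split("=", 1) for kv in attributes.strip().split(";") if "=" in kv
    )
    for key in ("Parent", "ID", "gene_id"):
        if key in attrs:
            return attrs[key]
    raise DataValidationError(f"GFF3 attributes lack Parent/ID: {attributes!r}")


def write_utr_bed(annotation: UTRAnnotation, path) -> None:
    """Write one BED6 line per cleavage site (stop->site interval)."""
    with open(path, "w") as fh:
        for gene, rec in annotation.records.items():
            for site in rec["cleavage_sites"]:
                start, end = ((rec["stop"], site) if rec["strand"] == "+"
                              else (site, rec["stop"]))
                fh.write(f"{rec['chrom']}\t{start}\t{end}\t{gene}\t.\t{rec['strand']}\n")


# ---------------------------------------------------------------------------
# category map / gene feature table
# ---------------------------------------------------------------------------

@dataclass
class CategoryMap:
    """Many-to-many gene grouping (MapMan-style bins, gene families, modules)."""

    table: pd.DataFrame  # columns: category, name, gene

    def __post_init__(self) -> None:
        need = {"category", "name", "gene"}
        if not need <= set(self.table.columns):
            raise DataValidationError(
                f"category table missing columns {sorted(need - set(self.table.columns))}"
            )

    @property
    def categories(self) -> list:
        return list(self.table["category"].unique())

    def members(self, category) -> list:
        return list(self.table.loc[self.table["category"] == category, "gene"])

    def name_of(self, category) -> str:
        sub = self.table.loc[self.table["category"] == category, "name"]
        return str(sub.iloc[0]) if len(sub) else str(category)

    def restricted_to(self, genes: Iterable) -> "CategoryMap":
        genes = set(genes)
        return CategoryMap(self.table[self.table["gene"].isin(genes)].reset_index(drop=True))


def read_category_map(path) -> CategoryMap:
    return CategoryMap(pd.read_csv(path, sep="\t", comment="#", dtype=str))


def write_category_map(cm: CategoryMap, path) -> None:
    cm.table.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Per-gene feature table (half_life hours, utr_length bp, n_utrs, ...)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA", ""])
    if "half_life" in df.columns:
        bad = df["half_life"].dropna() <= 0
        if bad.any():
            raise DataValidationError(
                f"non-positive half-life for genes {list(df.index[df['half_life'] <= 0])[:5]}"
            )
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


# ---------------------------------------------------------------------------
# FASTA (minimal, text-only; sequences are plain ACGT strings)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    seqs: dict = {}
    name = None
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path) -> None:
    """Write a tail-change (or abundance-change) result table.

    Fixed column order: gene, log2FC_ratio, logCPM, p_value, BH_p_value,
    then any per-genotype long/short log2-ratio columns.  NaN serializes as
    ``NA``; values round-trip at 10 significant digits.
    """
    df = results.reset_index() if results.index.name == "gene" else results.copy()
    extra = [c for c in df.columns if c not in RESULT_COLUMNS]
    cols = [c for c in RESULT_COLUMNS if c in df.columns] + extra
    df[cols].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA", ""])
    return df.set_index("gene")
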