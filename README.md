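# tailfrac

Transcriptome-wide poly(A)-tail-length analysis by mRNA fractionation.

## The problem

The poly(A) tail at the 3' end of an mRNA influences its export, stability
and translation. One way to survey tail lengths genome-wide is to split
total RNA into two pools by oligo(dT) capture stringency — a *short*-tail
and a *long*-tail fraction, separated around a ~50-nt cutoff — and sequence
both. For each gene the normalized abundance ratio

&nbsp;&nbsp;&nbsp;&nbsp;*l/s* = (abundance in the long fraction) / (abundance in the short fraction)

is a proxy for its tail-length distribution, and the change of that ratio
between a mutant and the wild type (the **ratio of ratios**,
log2FC = log2[(mut *l/s*) / (wt *l/s*)]) reveals transcripts whose
polyadenylation depends on the perturbed poly(A)-polymerase isoform —
negative values mean shorter tails in the mutant.

`tailfrac` implements the full desk side of such a study for people who want
to analyse fraction count matrices or to study the statistical behaviour of
the design:

* **simdata** — a generator of complete synthetic experiments (2 genotypes x
  4 replicates x 2 fractions, spike-ins of 30/75/134 A, logistic capture
  around a 50-nt cutoff, NB count noise, planted interaction effects, 3'-UTR
  sequences with plantable motifs, half-lives correlated with tail length)
  with a recorded ground truth for parameter-recovery tests.
* **formats** — strict readers/writers (counts/metadata TSV, BED6/GFF3 3'-UTR
  annotation with fixed 0-based half-open internal coordinates, FASTA,
  category maps, result tables).
* **normalize** — the "more than 5 reads in every sample" filter, TMM
  normalization factors, CPM/FPKM, and correlation-distance sample
  clustering.
* **tailtest** — per-gene NB log-linear models
  `log mu = offset + b0 + b1*long + b2*mut + b3*long*mut`, with moment
  dispersion estimation shrunk toward the median, likelihood-ratio tests of
  the interaction `b3` (tail change) and of the genotype effect on summed
  fractions (abundance change), plug-in tail proxies, and spike-in
  abundance proxies (fpkm x RNA concentration x non-rRNA mapping rate).
* **grouptest** — Wilcoxon rank-sum tests of gene groups against all other
  tested genes, category sweeps, co-expression-module ECDF comparisons,
  top-N list-overlap statistics with hypergeometric tails, and
  Benjamini-Hochberg FDR control.
* **seqfeat** — terminal-window hexamer sweeps (all 4096 6-mers), canonical
  polyadenylation-signal variant tests, base-composition profiles around the
  cleavage site, and feature correlations.
* **validate** — ePAT electropherogram normalization/differencing/shift
  scores, `PCReff^-ct` qPCR proxies, and segregation chi-square tests.
* **pipeline / cli** — a YAML-driven orchestrator with checksummed manifests
  and a thin `tailfrac` command-line layer.

## Worked example

```python
import math
from tailfrac import simdata, normalize, tailtest

cfg = simdata.SimConfig(n_genes=2000, seed=2, dispersion=0.02,
                        mean_expression=(math.log(400.0), 0.0))
exp = simdata.simulate_experiment(cfg)

filtered = normalize.filter_low_counts(exp.counts)   # min count >= 6 everywhere
state = normalize.tmm_factors(filtered)
sub = filtered.subset_genes(filtered.genes[~filtered.spike_mask])
sub_state = normalize.NormalizationState(
    state.library_sizes[sub.counts.columns], state.factors[sub.counts.columns])
res = tailtest.test_tail_change(sub, sub_state)
print((res.BH_p_value < 0.05).sum())
```

Running `python examples/02_tail_change_inference.py` (the same analysis
with narration) prints:

```
kept 2003 of 2003 genes; TMM factors span 0.819-1.216
significant tail changes (BH < 0.05): 163
strongest five changes:
        log2FC_ratio  logCPM  p_value  BH_p_value
G00171       -1.4323  9.6394      0.0         0.0
...
of the significant genes, 93.3% carry a planted effect (the rest are false positives)
```

163 of the 200 planted genes reach BH < 0.05; their negative `log2FC_ratio`
values mean the long/short ratio — and hence the poly(A) tail — shrank in
the mutant. The other scripts in `examples/` walk through the simulator and
spike-ins (01), group/module statistics (03), sequence features (04),
validation-assay arithmetic (05) and the checksummed full pipeline (06).

The same steps are available from the shell:

```bash
tailfrac simulate --seed 1 --n-genes 2000 --out sim/
tailfrac infer --counts sim/counts.tsv --meta sim/samples.tsv --out tail.tsv
tailfrac segregate --observed 111,67,0 --ratio 1:2:1
```

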