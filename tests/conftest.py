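"""Shared fixtures: small simulated experiments and hand-built matrices."""

import numpy as np
import pandas as pd
import pytest

from tailfrac import formats, normalize, simdata


def make_matrix(counts: dict, n_replicates: int = 2, genotypes=("wt", "mut"),
                spikes=()) -> formats.FractionCountMatrix:
    """Build a FractionCountMatrix from {gene: list of counts} with the
    standard column order wt_r1_short, wt_r1_long, ..., mut_rN_long."""
    samples = []
    for gt in genotypes:
        for rep in range(1, n_replicates + 1):
            for fr in ("short", "long"):
                samples.append((f"{gt}_r{rep}_{fr}", gt, rep, fr))
    ids = [s[0] for s in samples]
    df = pd.DataFrame(counts, index=ids).T
    meta = pd.DataFrame(
        {"genotype": [s[1] for s in samples],
         "replicate": [s[2] for s in samples],
         "fraction": [s[3] for s in samples]},
        index=pd.Index(ids, name="sample"))
    df.index.name = "gene"
    return formats.FractionCountMatrix(df, meta, frozenset(spikes))


@pytest.fixture(scope="session")
def small_experiment():
    """800-gene default-parameter simulation shared across test modules."""
    return simdata.simulate_experiment(simdata.SimConfig(n_genes=800, seed=5))


@pytest.fixture(scope="session")
def small_analysis(small_experiment):
    """Filtered matrix, normalization state and tail-change results."""
    exp = small_experiment
    filt = normalize.filter_low_counts(exp.counts)
    state = normalize.tmm_factors(filt)
    sub = filt.subset_genes(filt.genes[~filt.spike_mask])
    sub_state = normalize.NormalizationState(
        state.library_sizes[sub.counts.columns],
        state.factors[sub.counts.columns])
    from tailfrac import tailtest
    results = tailtest.test_tail_change(sub, sub_state)
    return {"exp": exp, "filtered": filt, "state": state, "matrix": sub,
            "sub_state": sub_state, "results": results}
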