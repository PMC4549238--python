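"""3'-UTR sequence features: hexamer sweep, signal variants, correlations.

Tests whether any 6-mer in the last 100 bp before the polyadenylation site
separates genes by their tail-length change, profiles base composition
around the cleavage site, and correlates tail statistics with transcript
features such as mRNA half-life.
"""

import math

from tailfrac import normalize, seqfeat, simdata, tailtest

cfg = simdata.SimConfig(n_genes=2000, seed=4, dispersion=0.02,
                        mean_expression=(math.log(400.0), 0.0))
exp = simdata.simulate_experiment(cfg)

filtered = normalize.filter_low_counts(exp.counts)
state = normalize.tmm_factors(filtered)
sub = filtered.subset_genes(filtered.genes[~filtered.spike_mask])
sub_state = normalize.NormalizationState(
    state.library_sizes[sub.counts.columns], state.factors[sub.counts.columns])
res = tailtest.test_tail_change(sub, sub_state)

# plant the canonical polyadenylation signal into the effect genes so the
# sweep has something to find
eff = list(exp.truth.index[exp.truth.is_effect & ~exp.truth.is_spike])
seqs = simdata.plant_motif(exp.sequences, "AATAAA", eff, window=100, seed=4)
windows = {g: s[-100:] for g, s in seqs.items()}

sweep = seqfeat.hexamer_sweep(windows, res["log2FC_ratio"].dropna())
print(f"hexamer sweep over {len(sweep)} testable motifs; top three:")
cols = ["motif", "n_with", "effect_mean_diff", "p_value", "BH_p_value"]
print(sweep.head(3)[cols].round(5).to_string(index=False))
print("-> the planted AATAAA attains the minimum p; its negative effect "
      "size means motif-carrying genes lose more tail in the mutant.\n")

variants, profile = seqfeat.variant_signal_test(windows,
                                                res["log2FC_ratio"].dropna())
print(f"canonical-signal variants tested: {len(variants)}; "
      f"total AATAAA occurrences by position: {int(profile['AATAAA'].sum())}")

comp = seqfeat.base_composition_profile(exp.annotation, exp.genome, flank=50)
print(f"base composition at the cleavage site (position -1): "
      f"{comp.loc[-1].round(3).to_dict()}")

feats = exp.annotation.feature_frame()
feats["half_life"] = exp.half_lives
wt_proxy = tailtest.tail_proxy(sub, sub_state, "wt")
corr = seqfeat.feature_correlations(wt_proxy, feats)
print("\ncorrelation of the wild-type tail proxy with transcript features:")
print(corr.round(4).to_string(index=False))
print("-> half-life is negatively correlated with tail length "
      "(stable mRNAs carry shorter steady-state tails).")
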