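"""Quantify cross-cohort reproducibility of a driver-network.

Two synthetic cohorts share one planted module (independent noise and
samples).  Driver-networks grown from the same seeds in both cohorts are
compared by normalised overlap |A∩B|/|A∪B|, and the overlap's significance
is assessed against two permutation nulls: random seed sets (shared by both
cohorts, real expression) and per-cohort shuffles of the expression probe
labels (true seeds, scrambled gene identities).
"""

import drivernet as dn

net = dn.generate_network(6000, mean_degree=20, rng_seed=3)
cfg = dn.GeneratorConfig(n_genes=6000, mean_degree=20, n_seed_genes=12,
                         seed_degree_range=(10, 13), rng_seed=3)
cohort_a, cohort_b, truth = dn.generate_cohort_pair(net, cfg)
seeds = dn.select_cohort_seeds(cohort_a, "TNBC")  # one cohort's seeds, reused

report = dn.reproducibility_report(cohort_a, cohort_b, net, seeds, "TNBC",
                                   reps_null=99, observed_reps=30, rng_seed=0)

print(f"driver-network sizes: {len(report['network_a'].members)} vs "
      f"{len(report['network_b'].members)} members")
print(f"observed normalised overlap: {report['observed_overlap']:.3f}")
print(f"resampled-DE control overlap: {report['de_control_overlap']:.3f}")
print("\nnull distributions (mean ± sd, add-one empirical p):")
for null in (report["seed_null"], report["expression_null"]):
    s = null.summary()
    print(f"  {s['scheme']:26s} {s['null_mean']:.3f} ± {s['null_sd']:.3f} "
          f"(p = {s['p_value']:.3f})")
# A planted module shared by both cohorts puts the observed overlap far above
# both nulls; the DE-control overlap shows plain differential expression is
# less reproducible than the network-anchored member sets.
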