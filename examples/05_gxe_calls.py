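"""Call gene-by-environment interactions from titration curves.

Per-replicate 4-parameter logistic fits (min, max, Hill, IG-50) of the
SG1 compounding series are compared between glucose and glycerol by
Welch's t-test per parameter with SGoF correction.  Genes whose min is
unchanged but whose IG-50/Hill/max shifts are "titration_only": couplings
invisible to a single maximal-knockdown screen.
"""

import warnings

from titracrispr import (
    GLUCOSE,
    GLYCEROL,
    design_library,
    estimate_growth,
    gxe_from_results,
    planted_gxe_truth,
    simulate_counts,
    synthetic_genes,
)

genes = synthetic_genes(12, length=600, seed=3)
lib = design_library(genes, n_negc=45, seed=3)
ids = [g.gene_id for g in genes]
# plant a 3-mutation IG-50 shift in half the genes, identical min/max/Hill
truth = planted_gxe_truth(ids[:6], ids[6:], seed=3, depth=500_000,
                          replicate_jitter_sd=0.02)

results, floor = {}, "auto"
for i, env in enumerate((GLUCOSE, GLYCEROL)):
    ct, _ = simulate_counts(truth, lib, env, seed=3 + 7919 * (i + 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = estimate_growth(ct, lib, env.doublings_per_hour, floor_raw=floor)
    floor = res.floor_raw  # one shared anchor keeps both scales comparable
    results[env.name] = res

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    calls, fits, medians = gxe_from_results(results, lib)

print("gene        planted     call              significant parameters")
for c in calls:
    planted = "ig50 shift" if c.gene_id in ids[:6] else "null"
    print(f"{c.gene_id:<11} {planted:<11} {c.interaction_class:<17} "
          f"{','.join(sorted(c.significant)) or '-'}")
print("\ntitration_only = interaction detectable only at intermediate")
print("knockdown; SGoF rejects just the excess of small p-values over its")
print("binomial null, so a few true shifts can stay uncalled.")
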