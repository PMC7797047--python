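"""Design a titrating sgRNA library for a handful of genes.

Each gene gets up to three parent guides: SG1/SG2 near the start codon
(PAM within 150 bp, non-overlapping) and SG3 past the 200-bp mark.  SG1
and SG3 are expanded into 14 compounding, 15 single and 5 double
complement-mismatch variants; 45 scrambled spacers serve as non-targeting
controls.
"""

from collections import Counter

from titracrispr import compact_subset, design_library, synthetic_genes

genes = synthetic_genes(4, length=600, seed=7)
lib = design_library(genes, n_negc=45, seed=7)

print(f"designed {len(lib)} guides for {len(genes)} genes")
print("per strategy:", dict(Counter(v.strategy for v in lib.variants)))
for gene_id, variants in lib.by_gene().items():
    roles = sorted({v.role for v in variants})
    print(f"  {gene_id}: {len(variants)} guides, parent roles {roles}")

compact = compact_subset(lib)
n_targeting = sum(v.strategy != "negC" for v in compact.variants)
print(f"compact library: {n_targeting} targeting guides "
      "(16 per complete gene: SG1/SG3 parents + compounding 4-10)")
# The compounding counts (14 per parent) and the 16-guide compact set are
# the fixed series sizes of the design; controls stay in both libraries.
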