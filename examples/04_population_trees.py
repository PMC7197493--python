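"""Gene trees, majority-rule consensus and Robinson-Foulds distances.

Builds per-gene UPGMA trees from gene-level F_ST distances, forms the
majority-rule consensus population tree with node support (the fraction
of gene trees containing each clade), and tabulates RF distances between
gene trees and the consensus.
"""

from pbs4.pipeline import gene_trees_and_rf, genetic_differentiation
from pbs4.simulate import QuartetModel, simulate_genotypes

model = QuartetModel(sample_sizes={p: 40 for p in "WXYZ"})
# variable SNP counts per gene: genes with few SNPs give noisier trees
sim = simulate_genotypes(model, n_genes=400, snps_per_gene=(2, 40), seed=21)
fst = genetic_differentiation(sim)

gene_trees, consensus, rf = gene_trees_and_rf(fst, value_col="fst")
print(f"{len(gene_trees)} gene trees built by UPGMA")
print(f"consensus population tree: {consensus.newick(lengths=False)}")
print("  (internal-node numbers are clade frequencies among gene trees)")

print("\nRF distance to the consensus vs SNPs per gene:")
summary = rf.groupby("rf")["snp_count"].agg(["count", "median"])
print(summary.to_string())
print("\ngenes matching the population tree (RF=0) have the most SNPs; "
      "fully discordant genes (RF=4) have the fewest.")
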