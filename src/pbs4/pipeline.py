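"""In-memory orchestration of the analysis stages.

These helpers chain the library stages on in-memory objects — handy for
simulation studies where writing VCF/TSV intermediates per replicate would
dominate the run time.  The file-based CLI mirrors the same stages.
"""

from __future__ import annotations

import pandas as pd

from pbs4.branch import pbs_table
from pbs4.expression import (
    fpkm,
    log_transform,
    median_ratio_size_factors,
    pst_table,
)
from pbs4.fst import assign_snps_to_genes, gene_pair_fst
from pbs4.simulate import (
    SimulatedExpression,
    SimulatedGenotypes,
    allele_summaries_from_dosages,
)
from pbs4.trees import majority_consensus, rf_distance, upgma


def genetic_differentiation(sim: SimulatedGenotypes) -> pd.DataFrame:
    """Gene-level Hudson F_ST table straight from simulated dosages
    (monomorphic sites dropped, SNPs assigned to genes by interval)."""
    snps = allele_summaries_from_dosages(sim.dosages, positions=sim.positions)
    gene_index = assign_snps_to_genes(snps, sim.annotation)
    pops = sorted(sim.dosages)
    return gene_pair_fst(snps, gene_index, pops)


def genetic_pbs(sim: SimulatedGenotypes, labels) -> pd.DataFrame:
    """Per-gene genetic PBS4 for all four populations."""
    return pbs_table(genetic_differentiation(sim), tuple(labels), "genetic",
                     value_col="fst")


def expression_differentiation(
    se: SimulatedExpression, h2_values=(0.5, 1.0)
) -> pd.DataFrame:
    """Gene-level P_ST table: median-ratio normalization, FPKM,
    log(FPKM+1), then pairwise P_ST."""
    factors = median_ratio_size_factors(se.counts)
    logfpkm = log_transform(fpkm(se.counts, factors, se.gene_lengths))
    return pst_table(logfpkm, se.sample_map, h2_values=h2_values)


def expression_pbs(se: SimulatedExpression, labels, h2: float) -> pd.DataFrame:
    """Per-gene expression PBS4 at a single heritability."""
    table = expression_differentiation(se, h2_values=(h2,))
    return pbs_table(table, tuple(labels), f"expression-h{h2:g}",
                     value_col="pst")


def gene_trees_and_rf(
    z_table: pd.DataFrame, value_col: str = "fst"
):
    """UPGMA gene trees, their majority consensus, and per-gene RF to it.

    Genes missing any pairwise value are excluded.  Returns
    (gene_trees dict, consensus RootedTree, rf DataFrame with snp_count
    when present).
    """
    pops = sorted(set(z_table["pop_a"]) | set(z_table["pop_b"]))
    n_pairs = len(pops) * (len(pops) - 1) // 2
    trees, snp_counts = {}, {}
    for gene, sub in z_table.groupby("gene", sort=True):
        if len(sub) != n_pairs or sub[value_col].isna().any():
            continue
        d = pd.DataFrame(0.0, index=pops, columns=pops)
        for row in sub.itertuples(index=False):
            v = getattr(row, value_col)
            d.loc[row.pop_a, row.pop_b] = d.loc[row.pop_b, row.pop_a] = v
        trees[gene] = upgma(d)
        if "snp_count" in sub.columns:
            snp_counts[gene] = int(sub["snp_count"].min())
    consensus = majority_consensus(list(trees.values()))
    rf = pd.DataFrame(
        {
            "gene": list(trees),
            "rf": [rf_distance(t, consensus) for t in trees.values()],
            "snp_count": [snp_counts.get(g) for g in trees],
        }
    )
    return trees, consensus, rf
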