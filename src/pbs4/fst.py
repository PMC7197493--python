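"""Per-SNP Hudson F_ST and gene-level ratio-of-averages aggregation.

For each biallelic SNP with sample alternate-allele frequencies p1, p2 and
allele sample sizes n1, n2 in two populations,

    numerator   = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

Gene-level F_ST is the "ratio of averages": per-SNP numerators and
denominators are summed separately over the SNPs of a gene before dividing.
Negative gene-level estimates are set to 0; per-SNP components are never
clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpAlleleSummary:
    """Per-SNP, per-population allele summary: the atoms of F_ST.

    ``p`` maps population -> alternate-allele sample frequency in [0, 1];
    ``n`` maps population -> allele sample size (2 x non-missing diploid
    genotypes).
    """

    chrom: str
    pos: int  # 1-based VCF position
    p: Mapping[str, float]
    n: Mapping[str, int]


def hudson_fst_snp(p1: float, n1: int, p2: float, n2: int):
    """Hudson per-SNP F_ST components (numerator, denominator), unclamped.

    Vectorized over array inputs.  Sites where both populations are fixed
    for the same allele have denominator 0 and are non-informative for the
    pair; callers must exclude them from the pair's sums.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("allele sample sizes must be >= 2")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if num.ndim == 0:
        return float(num), float(den)
    return num, den


def gene_fst(num_sum: float, den_sum: float) -> float:
    """Ratio-of-averages gene F_ST, clamped at 0 (negatives have no
    biological interpretation).  Requires a positive denominator sum."""
    if den_sum <= 0:
        raise ValueError("gene has no informative SNPs for this pair")
    return max(0.0, num_sum / den_sum)


def filter_variants(
    vcf_path: str,
    sample_map: Mapping[str, str],
    maf: float = 0.0,
) -> Iterator[SnpAlleleSummary]:
    """Stream allele summaries for biallelic SNPs polymorphic in the union
    of analyzed samples.

    Insertions, deletions, multiallelic records and sites monomorphic
    across all mapped samples are dropped.  ``maf`` > 0 additionally drops
    sites with union minor-allele frequency <= ``maf`` (the conventional
    cutoff is 0.01; default off).

    Raises ``ValueError`` if any sample in ``sample_map`` is absent from
    the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path, gts012=True)
    vcf_samples = list(vcf.samples)
    missing = sorted(set(sample_map) - set(vcf_samples))
    if missing:
        raise ValueError(f"samples in map missing from VCF: {missing}")

    pops = sorted(set(sample_map.values()))
    pop_idx = {
        pop: np.array(
            [i for i, s in enumerate(vcf_samples) if sample_map.get(s) == pop],
            dtype=int,
        )
        for pop in pops
    }
    analyzed = np.concatenate([pop_idx[pop] for pop in pops])

    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue  # indel
        # gts012: 0/1/2 = alt-allele dosage, 3 = missing
        g = rec.gt_types
        ga = g[analyzed]
        called = ga[ga != 3]
        if called.size == 0:
            continue
        alt_total = int(called.sum())
        if alt_total == 0 or alt_total == 2 * called.size:
            continue  # monomorphic across the union
        if maf > 0.0:
            union_p = alt_total / (2 * called.size)
            if min(union_p, 1 - union_p) <= maf:
                continue
        p, n = {}, {}
        for pop in pops:
            gp = g[pop_idx[pop]]
            gp = gp[gp != 3]
            n_alleles = 2 * gp.size
            n[pop] = n_alleles
            p[pop] = float(gp.sum() / n_alleles) if n_alleles else float("nan")
        yield SnpAlleleSummary(chrom=rec.CHROM, pos=rec.POS, p=p, n=n)


def summaries_to_frame(summaries: Iterable[SnpAlleleSummary]) -> pd.DataFrame:
    """Collect a summary stream into a wide table with p_<pop>, n_<pop>
    columns, one row per SNP."""
    rows = []
    for s in summaries:
        row = {"chrom": s.chrom, "pos": s.pos}
        for pop in s.p:
            row[f"p_{pop}"] = s.p[pop]
            row[f"n_{pop}"] = s.n[pop]
        rows.append(row)
    return pd.DataFrame(rows)


def assign_snps_to_genes(
    snps: pd.DataFrame, annotation: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Map gene id -> integer row indices of ``snps`` falling in the gene.

    ``snps`` carries 1-based VCF positions (columns ``chrom``, ``pos``);
    ``annotation`` carries 0-based half-open intervals (columns ``chrom``,
    ``start``, ``end``, ``gene``).  A SNP overlapping k genes is assigned
    to all k; SNPs in no gene are dropped.
    """
    from pbs4.io import vcf_pos_to_zero_based

    bad = annotation[annotation["end"] <= annotation["start"]]
    if len(bad):
        raise ValueError(f"degenerate gene intervals: {bad['gene'].tolist()}")

    trees: dict[str, IntervalTree] = {}
    for row in annotation.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end, row.gene
        )

    hits: dict[str, list[int]] = {}
    for i, (chrom, pos) in enumerate(zip(snps["chrom"], snps["pos"])):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(vcf_pos_to_zero_based(pos)):
            hits.setdefault(iv.data, []).append(i)
    return {g: np.array(ix, dtype=int) for g, ix in sorted(hits.items())}


def gene_pair_fst(
    snps: pd.DataFrame,
    gene_index: Mapping[str, np.ndarray],
    populations: Iterable[str],
) -> pd.DataFrame:
    """Gene-level Hudson F_ST for every population pair.

    Returns a long table (gene, pop_a, pop_b, fst, snp_count).  For each
    pair, SNPs where both populations are fixed for the same allele
    (denominator 0) are excluded from that pair's sums; a gene with no
    informative SNPs for a pair is omitted for that pair.
    """
    pops = sorted(populations)
    out = []
    comp = {}
    for a, b in [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]:
        num, den = hudson_fst_snp(
            snps[f"p_{a}"].to_numpy(),
            snps[f"n_{a}"].to_numpy(),
            snps[f"p_{b}"].to_numpy(),
            snps[f"n_{b}"].to_numpy(),
        )
        comp[(a, b)] = (num, den)
    for gene, idx in gene_index.items():
        for (a, b), (num, den) in comp.items():
            informative = den[idx] > 0
            if not informative.any():
                logger.info("gene %s: no informative SNPs for pair %s-%s", gene, a, b)
                continue
            num_sum = float(num[idx][informative].sum())
            den_sum = float(den[idx][informative].sum())
            out.append(
                {
                    "gene": gene,
                    "pop_a": a,
                    "pop_b": b,
                    "fst": gene_fst(num_sum, den_sum),
                    "snp_count": int(informative.sum()),
                }
            )
    return pd.DataFrame(out, columns=["gene", "pop_a", "pop_b", "fst", "snp_count"])


def _rescale_log_distance(fst: float, b_gene: float, b_reference: float) -> float:
    """Provisional background-selection correction: shrink or stretch the
    gene's -log(1 - F_ST) distance by B_gene / B_reference, then transform
    back.  B < reference (stronger linked selection) deflates F_ST."""
    e = -np.log1p(-min(fst, 1.0 - 1e-12))
    return float(1.0 - np.exp(-e * b_gene / b_reference))


def corrected_gene_fst(
    fst: float,
    b_gene: float,
    b_reference: float,
    correction: Callable[[float, float, float], float] | None = None,
) -> float:
    """Background-selection-corrected gene F_ST.

    ``b_gene`` is the gene's B value (fraction of neutral diversity
    remaining under background selection, in (0, 1]); ``b_reference`` is a
    genome-wide reference, typically the median B over genes.  The
    correction rule is pluggable; the default rescales the log-distance by
    B_gene / B_reference.
    """
    if b_gene <= 0 or b_reference <= 0:
        raise ValueError("B values must be positive")
    if not 0.0 <= fst <= 1.0:
        raise ValueError("fst must lie in [0, 1]")
    fn = correction or _rescale_log_distance
    return fn(fst, b_gene, b_reference)
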