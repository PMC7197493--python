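"""Expression normalization and quantitative-trait differentiation (P_ST).

Raw RNA-seq counts are normalized with median-ratio size factors, converted
to FPKM, filtered, log(FPKM+1)-transformed, and compared between
populations with

    P_ST = sigma2_between / (sigma2_between + 2 h2 sigma2_within)

where h2 is heritability.  At h2 = 1, P_ST equals Q_ST.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (genes x samples counts).

    For each gene with a positive geometric mean across samples, form the
    ratio count/geomean per sample; the sample's factor is the median of
    these ratios over genes.
    """
    c = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_c = np.log(c)
    finite = np.all(np.isfinite(log_c), axis=1)
    if not finite.any():
        raise ValueError(
            "no gene has positive counts in all samples; consider a "
            "pseudo-reference fallback"
        )
    log_geomean = log_c[finite].mean(axis=1)
    factors = np.exp(np.median(log_c[finite] - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def fpkm(
    counts: pd.DataFrame, size_factors: pd.Series, gene_lengths: pd.Series
) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads, on normalized counts.

    FPKM_gj = 1e9 * (count_gj / s_j) / (L_g * N_j) with N_j the total
    normalized count of sample j and L_g the gene length in bp.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene lengths missing for some genes in the count matrix")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    norm = counts.div(size_factors.reindex(counts.columns), axis=1)
    lib = norm.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size after normalization")
    return 1e9 * norm.div(lib, axis=1).div(lengths, axis=0)


def filter_genes(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    min_reads: int = 10,
    low_expression_rule: str = "all",
) -> tuple[pd.Index, dict[str, int]]:
    """Keep genes passing the expression filters; report removal counts.

    Removes genes that (i) are lowly expressed — under the default
    ``"all"`` rule, fewer than ``min_reads`` reads in *every* sample; the
    stricter ``"any"`` rule removes genes with fewer than ``min_reads`` in
    any sample — (ii) lie on a sex chromosome, or (iii) are not protein
    coding.  ``annotation`` needs columns ``gene``, ``chrom``, ``biotype``.
    """
    ann = annotation.set_index("gene")
    missing = counts.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"genes missing from annotation: {sorted(missing)}")
    ann = ann.reindex(counts.index)

    if low_expression_rule == "all":
        low = (counts < min_reads).all(axis=1)
    elif low_expression_rule == "any":
        low = (counts < min_reads).any(axis=1)
    else:
        raise ValueError("low_expression_rule must be 'all' or 'any'")
    sex = ann["chrom"].isin(SEX_CHROMOSOMES)
    noncoding = ann["biotype"] != "protein_coding"

    removed = {
        "low_expression": int(low.sum()),
        "sex_chromosome": int((sex & ~low).sum()),
        "non_protein_coding": int((noncoding & ~low & ~sex).sum()),
    }
    kept = counts.index[~(low | sex | noncoding)]
    logger.info("filter_genes: kept %d of %d genes (%s)", len(kept), len(counts), removed)
    return kept, removed


def log_transform(fpkm_matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise natural log(FPKM + 1)."""
    if (fpkm_matrix < 0).any().any():
        raise ValueError("FPKM values must be non-negative")
    return np.log1p(fpkm_matrix)


@dataclass(frozen=True)
class PstValue:
    gene: str
    pop_a: str
    pop_b: str
    h2: float
    sigma2_between: float
    sigma2_within: float
    pst: float  # NaN when undefined (zero total variance)

    @property
    def defined(self) -> bool:
        return not np.isnan(self.pst)


def _variance_components(x: np.ndarray, y: np.ndarray, method: str):
    """One-way two-group variance components.

    ``"anova"`` (default): method-of-moments from mean squares,
    sigma2_b = max(0, (MSB - MSW)/n0) with n0 the balanced-size
    coefficient; ``"means"``: sample variance of the two group means.
    """
    n1, n2 = x.size, y.size
    n = n1 + n2
    m1, m2, gm = x.mean(), y.mean(), np.concatenate([x, y]).mean()
    ssw = ((x - m1) ** 2).sum() + ((y - m2) ** 2).sum()
    msw = ssw / (n - 2)
    if method == "anova":
        msb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2  # df = 1
        n0 = (n - (n1**2 + n2**2) / n) / 1.0
        s2b = max(0.0, (msb - msw) / n0)
    elif method == "means":
        s2b = float(np.var([m1, m2], ddof=1))
    else:
        raise ValueError("method must be 'anova' or 'means'")
    return s2b, float(msw)


def pst(
    values_a: Iterable[float],
    values_b: Iterable[float],
    h2: float,
    gene: str = "",
    pop_a: str = "A",
    pop_b: str = "B",
    method: str = "anova",
) -> PstValue:
    """P_ST between two populations for one gene's expression values.

    Requires at least two samples per population and h2 in (0, 1].  When
    both variance components are zero the statistic is undefined; the
    returned value is flagged (NaN) so the gene can be omitted from
    rankings rather than silently scored.
    """
    x = np.asarray(list(values_a), dtype=float)
    y = np.asarray(list(values_b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 samples per population")
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    s2b, s2w = _variance_components(x, y, method)
    denom = s2b + 2.0 * h2 * s2w
    value = s2b / denom if denom > 0 else float("nan")
    return PstValue(gene, pop_a, pop_b, h2, s2b, s2w, value)


def pst_table(
    expression: pd.DataFrame,
    sample_map: Mapping[str, str],
    h2_values: Iterable[float] = (0.5, 1.0),
    method: str = "anova",
) -> pd.DataFrame:
    """Pairwise P_ST for every gene, population pair and h2.

    ``expression`` is genes x samples (normally log-FPKM).  Undefined
    genes (zero total variance for a pair) are flagged with NaN and logged;
    downstream rankings drop them.
    """
    pops = sorted(set(sample_map.values()))
    cols = {
        pop: [s for s in expression.columns if sample_map.get(s) == pop]
        for pop in pops
    }
    values = {pop: expression[cols[pop]].to_numpy(dtype=float) for pop in pops}

    rows = []
    h2_values = list(h2_values)
    for ia, a in enumerate(pops):
        for b in pops[ia + 1 :]:
            xa, xb = values[a], values[b]
            n1, n2 = xa.shape[1], xb.shape[1]
            m1, m2 = xa.mean(axis=1), xb.mean(axis=1)
            gm = (n1 * m1 + n2 * m2) / (n1 + n2)
            msw = (
                ((xa - m1[:, None]) ** 2).sum(axis=1)
                + ((xb - m2[:, None]) ** 2).sum(axis=1)
            ) / (n1 + n2 - 2)
            if method == "anova":
                msb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2
                n0 = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
                s2b = np.maximum(0.0, (msb - msw) / n0)
            elif method == "means":
                s2b = np.var(np.stack([m1, m2]), axis=0, ddof=1)
            else:
                raise ValueError("method must be 'anova' or 'means'")
            for h2 in h2_values:
                denom = s2b + 2.0 * h2 * msw
                with np.errstate(invalid="ignore"):
                    vals = np.where(denom > 0, s2b / np.where(denom > 0, denom, 1.0), np.nan)
                for g, s2b_g, s2w_g, v in zip(expression.index, s2b, msw, vals):
                    rows.append(
                        {
                            "gene": g,
                            "pop_a": a,
                            "pop_b": b,
                            "h2": h2,
                            "sigma2_between": s2b_g,
                            "sigma2_within": s2w_g,
                            "pst": v,
                        }
                    )
    df = pd.DataFrame(rows)
    n_undef = int(df["pst"].isna().sum())
    if n_undef:
        logger.info("pst_table: %d gene/pair/h2 entries undefined (zero variance)", n_undef)
    return df
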