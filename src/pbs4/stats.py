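"""Permutation tests, correlations and group comparisons.

The workhorse is a two-sample permutation test with the difference of group
medians as the statistic: labels are shuffled, the statistic recomputed,
and the two-sided p value is the proportion of permutations whose absolute
difference is at least the observed absolute difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    observed: float  # difference of group medians, median(x) - median(y)
    n_permutations: int
    p_value: float
    seed: int | None = None


def permutation_test_two_sample(
    x: Iterable[float],
    y: Iterable[float],
    n_perm: int = 1000,
    seed: int | None = None,
    plus_one: bool = False,
) -> PermutationResult:
    """Two-sided permutation test on the difference of medians.

    ``plus_one`` switches the p value from the plain proportion count/n_perm
    to the (count+1)/(n_perm+1) convention that never returns exactly 0.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(np.median(x) - np.median(y))
    pool = np.concatenate([x, y])
    n, nx = pool.size, x.size
    # vectorized label shuffles: each row of `order` is one permutation
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    shuffled = pool[order]
    perm_stat = np.median(shuffled[:, :nx], axis=1) - np.median(
        shuffled[:, nx:], axis=1
    )
    count = int(np.sum(np.abs(perm_stat) >= abs(observed)))
    p = (count + 1) / (n_perm + 1) if plus_one else count / n_perm
    return PermutationResult(observed, n_perm, float(p), seed)


def correlate_fst_pst(table: pd.DataFrame, fst_col: str = "fst", pst_col: str = "pst"):
    """Pearson r and Spearman rho between gene-level F_ST and P_ST for one
    population pair, with t-test p values.

    The t statistic is t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom (same for rho on ranks).  Returns a dict; a zero-variance
    vector makes the correlation undefined (``defined: False``).
    """
    sub = table[[fst_col, pst_col]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError("need >= 3 genes with both values")
    f = sub[fst_col].to_numpy(dtype=float)
    p = sub[pst_col].to_numpy(dtype=float)
    if np.ptp(f) == 0 or np.ptp(p) == 0:
        logger.warning("correlate_fst_pst: zero variance; correlation undefined")
        return {"n": n, "defined": False}

    def t_test(r):
        r = min(max(r, -1.0), 1.0)
        if abs(r) == 1.0:
            return np.inf, 0.0
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        return t, 2.0 * sps.t.sf(abs(t), df=n - 2)

    r = float(np.corrcoef(f, p)[0, 1])
    rho = float(np.corrcoef(sps.rankdata(f), sps.rankdata(p))[0, 1])
    t_r, p_r = t_test(r)
    t_rho, p_rho = t_test(rho)
    return {
        "n": n,
        "defined": True,
        "pearson_r": r,
        "pearson_t": t_r,
        "pearson_p": p_r,
        "spearman_rho": rho,
        "spearman_t": t_rho,
        "spearman_p": p_rho,
    }


def cnv_group_comparison(
    pbs: pd.DataFrame,
    cnv_genes: set[str],
    kind: str,
    n_perm: int = 1000,
    seed: int | None = None,
    mode: str = "max",
) -> PermutationResult:
    """Compare per-gene summary PBS4 between CNV and non-CNV genes.

    ``mode="max"`` (default) summarizes each gene by its maximum PBS4
    across the four populations — one value per gene; ``mode="per-population"``
    pools all per-population values instead.  The comparison is a
    two-sample permutation test on the difference of group medians, run on
    the rows of ``pbs`` matching ``kind``.
    """
    sub = pbs[pbs["kind"] == kind]
    if sub.empty:
        raise ValueError(f"no PBS rows of kind {kind!r}")
    if mode == "max":
        per_gene = sub.groupby("gene")["value"].max()
    elif mode == "per-population":
        per_gene = sub.set_index("gene")["value"]
    else:
        raise ValueError("mode must be 'max' or 'per-population'")
    genes = set(per_gene.index)
    cnv_in = genes & set(cnv_genes)
    if not cnv_in:
        raise ValueError("CNV gene set shares no genes with the PBS table")
    if cnv_in == genes:
        raise ValueError("all scored genes labeled CNV; complement group empty")
    is_cnv = per_gene.index.isin(cnv_in)
    return permutation_test_two_sample(
        per_gene[is_cnv], per_gene[~is_cnv], n_perm=n_perm, seed=seed
    )


def rf_snp_association(
    rf_values: Mapping[str, int],
    snp_counts: Mapping[str, int],
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Compare SNP-count distributions across Robinson–Foulds groups.

    Genes are grouped by their gene-tree-vs-population-tree RF value (0, 2
    or 4); each pair of groups is compared with the two-sample permutation
    test.  Returns a table with group medians, sizes and p values; pairs
    where a group is empty are skipped with a log notice.
    """
    rf = pd.Series(rf_values)
    snps = pd.Series(snp_counts).reindex(rf.index)
    if not set(rf.unique()) <= {0, 2, 4}:
        raise ValueError("RF values for four-taxon trees must be 0, 2 or 4")
    groups = {int(v): snps[rf == v].dropna().to_numpy() for v in sorted(rf.unique())}
    levels = sorted(groups)
    rows = []
    if len(levels) < 2:
        logger.info("rf_snp_association: fewer than two RF groups; nothing to compare")
    rng = np.random.default_rng(seed)
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            if groups[a].size == 0 or groups[b].size == 0:
                logger.info("rf_snp_association: empty group, skipping RF%d vs RF%d", a, b)
                continue
            sub_seed = int(rng.integers(2**31 - 1))
            res = permutation_test_two_sample(
                groups[a], groups[b], n_perm=n_perm, seed=sub_seed
            )
            rows.append(
                {
                    "rf_a": a,
                    "rf_b": b,
                    "n_a": groups[a].size,
                    "n_b": groups[b].size,
                    "median_a": float(np.median(groups[a])),
                    "median_b": float(np.median(groups[b])),
                    "observed_diff": res.observed,
                    "p_value": res.p_value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "rf_a", "rf_b", "n_a", "n_b",
            "median_a", "median_b", "observed_diff", "p_value",
        ],
    )


def export_ranked_genes(pbs: pd.DataFrame, population: str, kind: str) -> list[str]:
    """Gene ids ranked by descending PBS4 for one population and statistic
    kind; ties broken lexicographically.  The list is ready to write one id
    per line for ranked-list GO enrichment tools."""
    sub = pbs[(pbs["population"] == population) & (pbs["kind"] == kind)]
    if sub.empty:
        raise ValueError(f"no rows for population {population!r}, kind {kind!r}")
    sub = sub.dropna(subset=["value"])
    ranked = sub.sort_values(
        ["value", "gene"], ascending=[False, True], kind="mergesort"
    )
    return ranked["gene"].tolist()


def benjamini_hochberg(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p values (available but not applied by
    default; group-comparison p values are reported raw)."""
    p = np.asarray(list(p_values), dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out
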