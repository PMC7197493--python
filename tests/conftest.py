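import numpy as np
import pytest
from hypothesis import settings

from pbs4.simulate import QuartetModel

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from pbs4.trees import RootedTree


@pytest.fixture
def small_model():
    return QuartetModel(sample_sizes={p: 10 for p in "WXYZ"})


@pytest.fixture
def balanced_quartet():
    return RootedTree.from_newick("((A,B),(C,D));")


@pytest.fixture
def caterpillar_quartet():
    return RootedTree.from_newick("(((A,B),C),D);")


@pytest.fixture
def conflicting_quartet():
    return RootedTree.from_newick("((A,C),(B,D));")


def brute_force_gene_fst(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Independent oracle: gene-level ratio-of-averages Hudson F_ST
    recomputed from raw diploid dosages with explicit per-SNP loops."""
    num_sum = den_sum = 0.0
    for k in range(dosage_a.shape[0]):
        n1 = 2 * dosage_a.shape[1]
        n2 = 2 * dosage_b.shape[1]
        p1 = dosage_a[k].sum() / n1
        p2 = dosage_b[k].sum() / n2
        den = p1 * (1 - p2) + p2 * (1 - p1)
        if den == 0:
            continue
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        num_sum += num
        den_sum += den
    return max(0.0, num_sum / den_sum)


def exact_median_diff_p(x, y):
    """Independent oracle: exact permutation p value for the two-sided
    difference-of-medians test by full enumeration of label assignments."""
    from itertools import combinations

    pool = np.concatenate([x, y])
    nx = len(x)
    observed = abs(np.median(x) - np.median(y))
    idx = set(range(len(pool)))
    count = total = 0
    for comb in combinations(range(len(pool)), nx):
        rest = sorted(idx - set(comb))
        stat = abs(np.median(pool[list(comb)]) - np.median(pool[rest]))
        count += stat >= observed - 1e-12
        total += 1
    return count / total
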