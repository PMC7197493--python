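"""Branch-length statistics (PBS) on three- and four-population trees.

Pairwise differentiation values Z_ST (either F_ST or P_ST) are turned into
distances E = -log(1 - Z_ST) and branch lengths are solved for on a fixed
quartet topology ((W,X),(Y,Z)).  The four-population statistic assigns the
focal population's external branch

    PBS4_W = 1/4 * (2*E_WX + E_WY + E_WZ - E_XY - E_XZ)

where X is the focal population's cherry partner and Y, Z sit on the other
side of the internal edge.  On additive distances this recovers every
external branch exactly; negative estimates are clamped to zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Largest Z admitted into the -log transform; Z = 1 (fixed differences at
#: every site of a gene) would give an infinite distance.
Z_MAX = 1.0 - 1e-12


def log_distance(z):
    """Distance E = -log(1 - z) for differentiation z in [0, 1].

    Accepts scalars or arrays.  z = 1 is clamped just below 1 with a
    warning so that fixed differences yield a large, finite distance.
    """
    arr = np.asarray(z, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("differentiation value is NaN")
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError("differentiation must lie in [0, 1]")
    if np.any(arr >= 1.0):
        logger.warning("Z_ST == 1 encountered; clamping below 1 for -log transform")
        arr = np.minimum(arr, Z_MAX)
    out = -np.log1p(-arr)
    return out if out.ndim else float(out)


def pbs3(e_wx: float, e_wy: float, e_xy: float) -> float:
    """Three-population branch length for the focal population W.

    PBS_W = 1/2 (E_WX + E_WY - E_XY), clamped at zero.
    """
    for e in (e_wx, e_wy, e_xy):
        if e < 0 or not np.isfinite(e):
            raise ValueError("distances must be finite and >= 0")
    return max(0.0, 0.5 * (e_wx + e_wy - e_xy))


@dataclass(frozen=True)
class QuartetDistanceMatrix:
    """Six pairwise distances among four labeled populations.

    ``labels`` are ordered so that the first two form one cherry and the
    last two the other, i.e. the rooted shape ((labels[0], labels[1]),
    (labels[2], labels[3])).  ``matrix`` is the symmetric 4x4 distance
    matrix in label order.
    """

    labels: tuple[str, str, str, str]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        if len(self.labels) != 4 or len(set(self.labels)) != 4:
            raise ValueError("need four distinct population labels")
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("matrix diagonal must be zero")
        if np.any(~np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and >= 0")
        object.__setattr__(self, "matrix", m)

    def distance(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    @classmethod
    def from_pairs(cls, labels, pair_distances) -> "QuartetDistanceMatrix":
        """Build from a mapping {frozenset({a, b}): distance}."""
        labels = tuple(labels)
        m = np.zeros((4, 4))
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            key = frozenset({a, b})
            if key not in pair_distances:
                raise KeyError(f"missing distance for pair {a},{b}")
            m[i, j] = m[j, i] = pair_distances[key]
        return cls(labels=labels, matrix=m)


def _quartet_roles(labels: tuple[str, ...], focal: str):
    """Return (partner, cross1, cross2) for a focal leaf on ((0,1),(2,3))."""
    if focal not in labels:
        raise ValueError(f"focal population {focal!r} not among labels {labels}")
    idx = labels.index(focal)
    if idx < 2:
        partner = labels[1 - idx]
        cross = (labels[2], labels[3])
    else:
        partner = labels[5 - idx]
        cross = (labels[0], labels[1])
    return partner, cross


def pbs4_branch(dm: QuartetDistanceMatrix, focal: str, clamp: bool = True) -> float:
    """Four-population branch length for ``focal``.

    The focal population's cherry partner carries the doubled term; the two
    cross-cherry populations enter positively with the focal population and
    negatively with the partner.  ``clamp=False`` returns the raw estimate
    (used to verify the cherry-sum identity).
    """
    partner, (c1, c2) = _quartet_roles(dm.labels, focal)
    e = dm.distance
    raw = 0.25 * (
        2.0 * e(focal, partner)
        + e(focal, c1)
        + e(focal, c2)
        - e(partner, c1)
        - e(partner, c2)
    )
    return max(0.0, raw) if clamp else raw


def pbs_table(
    z_table: pd.DataFrame,
    labels: tuple[str, str, str, str],
    kind: str,
    value_col: str = "value",
) -> pd.DataFrame:
    """Per-gene PBS4 values for all four populations.

    Parameters
    ----------
    z_table
        Long-format table with columns ``gene``, ``pop_a``, ``pop_b`` and a
        differentiation column (``value_col``) holding gene-level Z_ST in
        [0, 1] (already clamped at 0).
    labels
        Population labels in cherry order ((labels[0],labels[1]),
        (labels[2],labels[3])); fixed by configuration, never inferred.
    kind
        Statistic tag recorded in the output, e.g. ``"genetic"``,
        ``"expression-h0.5"``, ``"expression-h1"``.

    Genes missing any of the six pairwise values are omitted and logged.
    """
    required = {frozenset(p) for p in itertools.combinations(labels, 2)}
    df = z_table.copy()
    df["_pair"] = [frozenset((a, b)) for a, b in zip(df["pop_a"], df["pop_b"])]
    if not set(df["_pair"]).issubset(required):
        extra = set(df["_pair"]) - required
        raise ValueError(f"table contains pairs outside the quartet: {extra}")

    rows = []
    n_dropped = 0
    for gene, sub in df.groupby("gene", sort=True):
        pairs = dict(zip(sub["_pair"], sub[value_col]))
        if set(pairs) != required or any(pd.isna(v) for v in pairs.values()):
            n_dropped += 1
            continue
        dm = QuartetDistanceMatrix.from_pairs(
            labels, {k: log_distance(v) for k, v in pairs.items()}
        )
        for pop in labels:
            rows.append(
                {
                    "gene": gene,
                    "population": pop,
                    "kind": kind,
                    "value": pbs4_branch(dm, pop),
                }
            )
    if n_dropped:
        logger.info("pbs_table: omitted %d genes lacking all six pairs", n_dropped)
    return pd.DataFrame(rows, columns=["gene", "population", "kind", "value"])
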