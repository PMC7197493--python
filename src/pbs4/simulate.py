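"""Synthetic data with the statistical structure the analysis assumes.

Genotypes follow a hierarchical Balding–Nichols model on a rooted quartet
((W,X),(Y,Z)): an ancestral allele frequency is drawn per SNP, then drifts
independently down each branch as Beta(p(1-F)/F, (1-p)(1-F)/F) with
branch-specific drift F, and diploid genotypes are Binomial(2, p_pop).
Expression counts are negative binomial with sample-specific size factors
and optional population-specific fold changes.  An additive-quartet
distance oracle supports exact branch-length recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from pbs4.branch import QuartetDistanceMatrix

DEFAULT_LABELS = ("W", "X", "Y", "Z")


@dataclass(frozen=True)
class QuartetModel:
    """Demographic model for four populations on the rooted shape
    ((labels[0], labels[1]), (labels[2], labels[3])).

    ``branch_F`` holds the Balding–Nichols drift per branch: one entry per
    population (external branches) plus ``"internal"`` for the branch
    separating the first cherry from the root.  ``sample_sizes`` are
    diploid individuals per population.
    """

    labels: tuple[str, str, str, str] = DEFAULT_LABELS
    branch_F: Mapping[str, float] = field(
        default_factory=lambda: {
            "W": 0.05, "X": 0.05, "Y": 0.05, "Z": 0.05, "internal": 0.05
        }
    )
    sample_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"W": 50, "X": 50, "Y": 50, "Z": 50}
    )

    def __post_init__(self):
        if len(self.labels) != 4 or len(set(self.labels)) != 4:
            raise ValueError("need four distinct population labels")
        expected = set(self.labels) | {"internal"}
        if set(self.branch_F) != expected:
            raise ValueError(f"branch_F must have keys {sorted(expected)}")
        for k, f in self.branch_F.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"branch_F[{k!r}]={f} must lie strictly in (0, 1)")
        for pop in self.labels:
            if self.sample_sizes.get(pop, 0) < 2:
                raise ValueError(f"sample_sizes[{pop!r}] must be >= 2")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators for oracle tests."""

    branch_F: dict[str, float]
    shifted_genes: set[str] = field(default_factory=set)
    cnv_genes: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        return json.dumps(
            {
                "branch_F": self.branch_F,
                "shifted_genes": sorted(self.shifted_genes),
                "cnv_genes": sorted(self.cnv_genes),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            branch_F=d["branch_F"],
            shifted_genes=set(d["shifted_genes"]),
            cnv_genes=set(d["cnv_genes"]),
        )


def _drift(p: np.ndarray, F, rng: np.random.Generator) -> np.ndarray:
    """One Balding–Nichols step: Beta(p(1-F)/F, (1-p)(1-F)/F) per site.
    ``F`` may be a scalar or per-site array."""
    F = np.broadcast_to(np.asarray(F, dtype=float), p.shape)
    scale = (1.0 - F) / F
    out = rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))
    return np.clip(out, 0.0, 1.0)


def simulate_site_frequencies(
    model: QuartetModel,
    n_snps: int,
    rng: np.random.Generator,
    anc_range: tuple[float, float] = (0.05, 0.95),
    extra_F: Mapping[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Per-population allele frequencies for ``n_snps`` sites.

    ``extra_F`` optionally adds per-site drift on named external branches
    (an additional Balding–Nichols step with the given per-site F where
    F > 0) — used to plant population-specific differentiation at chosen
    genes.
    """
    w, x, y, z = model.labels
    p_anc = rng.uniform(*anc_range, size=n_snps)
    p_wx = _drift(p_anc, model.branch_F["internal"], rng)
    freqs = {
        w: _drift(p_wx, model.branch_F[w], rng),
        x: _drift(p_wx, model.branch_F[x], rng),
        y: _drift(p_anc, model.branch_F[y], rng),
        z: _drift(p_anc, model.branch_F[z], rng),
    }
    if extra_F:
        for pop, fs in extra_F.items():
            fs = np.asarray(fs, dtype=float)
            mask = fs > 0
            if mask.any():
                freqs[pop] = freqs[pop].copy()
                freqs[pop][mask] = _drift(freqs[pop][mask], fs[mask], rng)
    return freqs


def genotype_dosages(
    freqs: Mapping[str, np.ndarray],
    sample_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Diploid alternate-allele dosages, Binomial(2, p_pop) per individual;
    arrays of shape (n_snps, n_individuals)."""
    return {
        pop: rng.binomial(2, p[:, None], size=(p.size, sample_sizes[pop]))
        for pop, p in freqs.items()
    }


def allele_summaries_from_dosages(
    dosages: Mapping[str, np.ndarray],
    chrom: str = "chr1",
    positions: np.ndarray | None = None,
    drop_monomorphic: bool = True,
) -> pd.DataFrame:
    """Wide per-SNP allele-summary table (p_<pop>, n_<pop> columns) straight
    from dosage arrays, optionally dropping sites monomorphic across the
    union of samples — the same filter the VCF path applies."""
    pops = sorted(dosages)
    n_snps = next(iter(dosages.values())).shape[0]
    if positions is None:
        positions = np.arange(1, n_snps + 1)
    df = pd.DataFrame({"chrom": chrom, "pos": positions})
    total_alt = np.zeros(n_snps, dtype=int)
    total_alleles = 0
    for pop in pops:
        d = dosages[pop]
        df[f"p_{pop}"] = d.sum(axis=1) / (2 * d.shape[1])
        df[f"n_{pop}"] = 2 * d.shape[1]
        total_alt += d.sum(axis=1)
        total_alleles += 2 * d.shape[1]
    if drop_monomorphic:
        keep = (total_alt > 0) & (total_alt < total_alleles)
        df = df[keep].reset_index(drop=True)
    return df


@dataclass
class SimulatedGenotypes:
    vcf_path: Path | None
    annotation: pd.DataFrame
    annotation_path: Path | None
    truth: SyntheticTruth
    truth_path: Path | None
    cnv_path: Path | None
    b_values: pd.Series
    b_path: Path | None
    dosages: dict[str, np.ndarray]
    positions: np.ndarray
    gene_of_snp: np.ndarray


def _snp_counts(snps_per_gene, n_genes: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve the per-gene SNP count spec: a fixed int, a (low, high)
    inclusive range drawn uniformly, or an explicit array."""
    if isinstance(snps_per_gene, int):
        counts = np.full(n_genes, snps_per_gene)
    elif isinstance(snps_per_gene, tuple) and len(snps_per_gene) == 2:
        counts = rng.integers(snps_per_gene[0], snps_per_gene[1] + 1, size=n_genes)
    else:
        counts = np.asarray(snps_per_gene, dtype=int)
        if counts.shape != (n_genes,):
            raise ValueError("snps_per_gene array must have one entry per gene")
    if np.any(counts < 1):
        raise ValueError("every gene needs at least one SNP")
    return counts


def simulate_genotypes(
    model: QuartetModel,
    n_genes: int,
    snps_per_gene=20,
    seed: int = 0,
    out_dir: str | Path | None = None,
    anc_range: tuple[float, float] = (0.05, 0.95),
    shift_pop: str | None = None,
    shift_F: float = 0.2,
    cnv_fraction: float = 0.1,
    cnv_shifted_fraction: float = 0.5,
    b_range: tuple[float, float] = (0.5, 1.0),
    chrom: str = "chr1",
) -> SimulatedGenotypes:
    """Simulate a genic SNP data set under the quartet model.

    Genes occupy contiguous non-overlapping blocks on one chromosome, with
    ``snps_per_gene`` biallelic sites each (an int, an inclusive
    ``(low, high)`` range drawn uniformly per gene, or a per-gene array).  A ``cnv_fraction`` of genes is
    labeled CNV-bearing; of those, ``cnv_shifted_fraction`` receive extra
    drift ``shift_F`` on the ``shift_pop`` branch (planted population-
    specific differentiation; requires ``shift_pop``).  Per-gene median B
    values are drawn Uniform over ``b_range``.

    Sites that come out monomorphic across all samples are still written to
    the VCF — downstream filters are expected to remove them.  With
    ``out_dir`` set, writes VCF v4.2, a BED-like annotation TSV, a CNV
    gene-id list, a B-value TSV and a truth JSON; otherwise everything
    stays in memory.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    counts = _snp_counts(snps_per_gene, n_genes, rng)
    n_snps = int(counts.sum())
    gene_ids = np.array([f"gene{i:05d}" for i in range(n_genes)])
    gene_of_snp = np.repeat(np.arange(n_genes), counts)

    # gene intervals: 0-based half-open, laid end to end with spacing
    span = np.maximum(rng.integers(2000, 8001, size=n_genes), 2 * counts)
    starts = np.zeros(n_genes, dtype=int)
    pos0 = 0
    for i in range(n_genes):
        starts[i] = pos0
        pos0 += span[i] + 1000
    ends = starts + span
    exonic = np.maximum((span * rng.uniform(0.2, 0.8, size=n_genes)).astype(int), 100)
    annotation = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "gene": gene_ids,
            "strand": rng.choice(["+", "-"], size=n_genes),
            "biotype": "protein_coding",
            "exonic_length": exonic,
        }
    )

    # SNP positions: sorted unique offsets within each gene (1-based VCF)
    positions = np.empty(n_snps, dtype=int)
    offset = 0
    for i in range(n_genes):
        lo, hi = starts[i], ends[i]
        offs = np.sort(
            rng.choice(np.arange(lo, hi), size=counts[i], replace=False)
        )
        positions[offset : offset + counts[i]] = offs + 1
        offset += counts[i]

    # CNV labels and planted shifts
    n_cnv = int(round(cnv_fraction * n_genes))
    cnv_idx = rng.choice(n_genes, size=n_cnv, replace=False)
    n_shift = int(round(cnv_shifted_fraction * n_cnv)) if shift_pop else 0
    shift_idx = rng.choice(cnv_idx, size=n_shift, replace=False) if n_shift else np.array([], dtype=int)

    extra = None
    if shift_pop is not None and n_shift:
        if shift_pop not in model.labels:
            raise ValueError(f"shift_pop {shift_pop!r} not in model labels")
        per_site = np.zeros(n_snps)
        per_site[np.isin(gene_of_snp, shift_idx)] = shift_F
        extra = {shift_pop: per_site}

    freqs = simulate_site_frequencies(model, n_snps, rng, anc_range, extra_F=extra)
    dosages = genotype_dosages(freqs, model.sample_sizes, rng)
    b_values = pd.Series(
        rng.uniform(*b_range, size=n_genes), index=gene_ids, name="b_value"
    )
    truth = SyntheticTruth(
        branch_F={k: float(v) for k, v in model.branch_F.items()},
        shifted_genes={str(g) for g in gene_ids[shift_idx]},
        cnv_genes={str(g) for g in gene_ids[cnv_idx]},
    )

    paths = dict.fromkeys(("vcf", "annotation", "truth", "cnv", "b"))
    if out_dir is not None:
        from pbs4 import io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["vcf"] = out / "genotypes.vcf"
        io.write_vcf(
            paths["vcf"], chrom, positions, dosages, model.labels,
            contig_length=int(ends[-1] + 1000),
        )
        paths["annotation"] = out / "genes.tsv"
        annotation.to_csv(paths["annotation"], sep="\t", index=False)
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(truth.to_json())
        paths["cnv"] = out / "cnv_genes.txt"
        paths["cnv"].write_text("".join(f"{g}\n" for g in sorted(truth.cnv_genes)))
        paths["b"] = out / "b_values.tsv"
        b_values.rename_axis("gene").to_csv(paths["b"], sep="\t")

    return SimulatedGenotypes(
        vcf_path=paths["vcf"],
        annotation=annotation,
        annotation_path=paths["annotation"],
        truth=truth,
        truth_path=paths["truth"],
        cnv_path=paths["cnv"],
        b_values=b_values,
        b_path=paths["b"],
        dosages=dosages,
        positions=positions,
        gene_of_snp=gene_of_snp,
    )


@dataclass
class SimulatedExpression:
    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_map: dict[str, str]
    annotation: pd.DataFrame
    truth: SyntheticTruth


def simulate_expression(
    model: QuartetModel,
    n_genes: int,
    shift_spec: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    dispersion: float = 0.2,
    size_factor_log_sd: float = 0.25,
    length_range: tuple[int, int] = (500, 5000),
    mean_log_rate: float = np.log(0.05),
    sd_log_rate: float = 1.0,
    out_dir: str | Path | None = None,
) -> SimulatedExpression:
    """Simulate an RNA-seq count matrix for the four populations.

    Counts for gene g in sample j are NegativeBinomial with mean
    s_j * L_g * mu_g * shift(g, pop(j)) and dispersion ``dispersion``
    (variance mu + dispersion*mu^2).  Size factors s_j are log-normal with
    log-sd ``size_factor_log_sd``; gene lengths are uniform over
    ``length_range`` bp; per-bp base rates mu_g are log-normal.

    ``shift_spec`` maps gene id -> {population: fold change} for planted
    population-specific expression shifts; shifted gene/population names
    must exist.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    lengths = pd.Series(
        rng.integers(length_range[0], length_range[1] + 1, size=n_genes),
        index=gene_ids,
        name="length",
        dtype=float,
    )
    mu = np.exp(rng.normal(mean_log_rate, sd_log_rate, size=n_genes))

    samples, sample_map = [], {}
    for pop in model.labels:
        for i in range(model.sample_sizes[pop]):
            name = f"{pop}_{i:03d}"
            samples.append(name)
            sample_map[name] = pop

    fold = pd.DataFrame(1.0, index=gene_ids, columns=list(model.labels))
    if shift_spec:
        for g, shifts in shift_spec.items():
            if g not in fold.index:
                raise ValueError(f"shift gene {g!r} not generated")
            for pop, f in shifts.items():
                if pop not in fold.columns:
                    raise ValueError(f"shift population {pop!r} not in model")
                fold.loc[g, pop] = f

    s = np.exp(rng.normal(0.0, size_factor_log_sd, size=len(samples)))
    base = lengths.to_numpy() * mu  # per-gene expected count at s=1
    mean = (
        base[:, None]
        * s[None, :]
        * fold[[sample_map[j] for j in samples]].to_numpy()
    )
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    counts = pd.DataFrame(counts, index=gene_ids, columns=samples)

    annotation = pd.DataFrame(
        {"gene": gene_ids, "chrom": "chr1", "biotype": "protein_coding"}
    )
    truth = SyntheticTruth(
        branch_F={k: float(v) for k, v in model.branch_F.items()},
        shifted_genes=set(shift_spec) if shift_spec else set(),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        counts.rename_axis("gene").to_csv(out / "counts.tsv", sep="\t")
        lengths.rename_axis("gene").to_csv(out / "gene_lengths.tsv", sep="\t")
        pd.Series(sample_map, name="population").rename_axis("sample").to_csv(
            out / "sample_map.tsv", sep="\t"
        )
        annotation.to_csv(out / "expr_genes.tsv", sep="\t", index=False)
        (out / "expr_truth.json").write_text(truth.to_json())
    return SimulatedExpression(counts, lengths, sample_map, annotation, truth)


def additive_quartet_distances(
    external,
    internal: float,
    labels: tuple[str, str, str, str] = DEFAULT_LABELS,
) -> QuartetDistanceMatrix:
    """Exact path-length distances on the unrooted quartet ((W,X),(Y,Z)).

    ``external`` gives the four external branch lengths in label order and
    ``internal`` the middle edge: d(W,X) = w + x, d(W,Y) = w + m + y, and
    so on.  The oracle for exact branch-length recovery by PBS4.
    """
    w, x, y, z = (float(v) for v in external)
    m = float(internal)
    if min(w, x, y, z, m) < 0:
        raise ValueError("branch lengths must be >= 0")
    pairs = {
        frozenset({labels[0], labels[1]}): w + x,
        frozenset({labels[0], labels[2]}): w + m + y,
        frozenset({labels[0], labels[3]}): w + m + z,
        frozenset({labels[1], labels[2]}): x + m + y,
        frozenset({labels[1], labels[3]}): x + m + z,
        frozenset({labels[2], labels[3]}): y + z,
    }
    return QuartetDistanceMatrix.from_pairs(labels, pairs)
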