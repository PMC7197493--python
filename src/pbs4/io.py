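"""File formats: VCF writing, TSV tables, gene lists.

Coordinate conventions are centralized here: VCF positions are 1-based;
annotation intervals are 0-based half-open (BED-like).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def vcf_pos_to_zero_based(pos: int) -> int:
    """Convert a 1-based VCF position to a 0-based coordinate."""
    return pos - 1


def write_vcf(
    path: str | Path,
    chrom: str,
    positions: np.ndarray,
    dosages: Mapping[str, np.ndarray],
    pop_order: Iterable[str],
    contig_length: int | None = None,
    ref: str = "A",
    alt: str = "G",
) -> Path:
    """Write diploid dosages as a sorted VCF v4.2 with GT only.

    Samples are named ``<pop>_<index>`` in population order.  All sites are
    written as they are, including any that happen to be monomorphic."""
    path = Path(path)
    pops = list(pop_order)
    samples = [
        f"{pop}_{i:03d}" for pop in pops for i in range(dosages[pop].shape[1])
    ]
    order = np.argsort(positions, kind="mergesort")
    mat = np.concatenate([dosages[pop] for pop in pops], axis=1)[order]
    positions = np.asarray(positions)[order]

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_length:
            fh.write(f"##contig=<ID={chrom},length={contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for k, pos in enumerate(positions):
            gts = "\t".join(_GT[g] for g in mat[k])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
    return path


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> population TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "population"]:
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=["sample", "population"])
    return dict(zip(df["sample"], df["population"]))


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene annotation TSV (chrom, start, end, gene,
    strand, biotype, exonic_length); start/end 0-based half-open."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gene"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples raw count TSV, gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_lengths(path: str | Path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0].astype(float)


def read_gene_set(path: str | Path) -> set[str]:
    """Plain gene-id list, one per line."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def read_b_values(path: str | Path) -> pd.Series:
    """Per-gene median B values (TSV gene -> B)."""
    s = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0].astype(float)
    if (s <= 0).any() or (s > 1).any():
        raise ValueError("B values must lie in (0, 1]")
    return s


def write_ranked_genes(path: str | Path, genes: Iterable[str]) -> Path:
    """One gene id per line, ready for ranked-list GO enrichment tools."""
    path = Path(path)
    path.write_text("".join(f"{g}\n" for g in genes))
    return path


def write_trees(path: str | Path, trees, lengths: bool = True) -> Path:
    """One Newick tree per line."""
    path = Path(path)
    path.write_text("".join(t.newick(lengths=lengths) + "\n" for t in trees))
    return path


def read_trees(path: str | Path):
    from pbs4.trees import RootedTree

    return [
        RootedTree.from_newick(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
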