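"""Rank genes by the number of SNPs with differing genotypes in two strains.

This is the divergence screen applied to array-resequencing genotype tables:
for a chosen pair of strains, count per gene the SNPs at which both strains
have an unambiguous call (``A/C/G/T``) and the calls differ. ``N`` genotypes
never count as differences — the conservative rule, since an ambiguous call
gives no evidence of divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

VALID_CALLS = frozenset("ACGT")
VALID_SYMBOLS = frozenset("ACGTN")


@dataclass(frozen=True)
class GeneInterval:
    """Gene span in BED convention: 0-based, half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    pseudogene_flag: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")

    def contains(self, chrom: str, pos_1based: int) -> bool:
        return self.chrom == chrom and self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class GeneDifferenceCount:
    gene_id: str
    n_snps_in_gene: int
    n_differing: int
    pseudogene_flag: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_differing <= self.n_snps_in_gene:
            raise ValueError("n_differing must be between 0 and n_snps_in_gene")


class StrainGenotypeTable:
    """Per-SNP genotype calls for a named set of strains.

    Backed by a DataFrame with columns ``chrom``, ``pos`` (1-based) and one
    column per strain carrying symbols in ``{A, C, G, T, N}``. Any other
    ambiguity code is rejected at construction.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "pos"}
        if not required <= set(df.columns):
            raise ValueError("genotype table needs 'chrom' and 'pos' columns")
        self.df = df.reset_index(drop=True)
        self.strains = [c for c in df.columns if c not in required]
        if not self.strains:
            raise ValueError("genotype table has no strain columns")
        if self.df.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) records in genotype table")
        for strain in self.strains:
            symbols = set(self.df[strain].astype(str).str.upper())
            bad = symbols - VALID_SYMBOLS
            if bad:
                raise ValueError(
                    f"strain {strain!r} carries disallowed symbols {sorted(bad)}; "
                    "only A/C/G/T/N genotype calls are accepted"
                )
            self.df[strain] = self.df[strain].astype(str).str.upper()

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StrainGenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Read genes from BED: chrom, start, end, name[, pseudogene(0/1)]."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
        pseudo = len(fields) > 4 and fields[4] not in ("0", ".", "")
        genes.append(GeneInterval(name, chrom, start, end, pseudogene_flag=pseudo))
    return genes


def write_gene_intervals(genes: list[GeneInterval], path: str | Path) -> None:
    lines = [
        f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{int(g.pseudogene_flag)}\n"
        for g in genes
    ]
    Path(path).write_text("".join(lines))


def count_differences_per_gene(
    table: StrainGenotypeTable,
    strain_a: str,
    strain_b: str,
    genes: list[GeneInterval],
) -> list[GeneDifferenceCount]:
    """Count, per gene, SNPs where the two focal strains differ unambiguously.

    A SNP at 1-based position ``pos`` belongs to a gene iff ``pos - 1`` falls
    in the gene's half-open ``[start, end)`` on the same chromosome. A SNP
    overlapping two genes is counted in both (with a logged warning). Every
    input gene yields one output row, zero counts included.
    """
    for strain in (strain_a, strain_b):
        if strain not in table.strains:
            raise KeyError(f"strain {strain!r} not in genotype table ({table.strains})")

    import numpy as np

    chroms = table.df["chrom"].to_numpy(dtype=object)
    pos0 = table.df["pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
    calls_a = table.df[strain_a].to_numpy(dtype="<U1")
    calls_b = table.df[strain_b].to_numpy(dtype="<U1")
    unambiguous_diff = (
        (calls_a != calls_b) & (calls_a != "N") & (calls_b != "N")
    )

    counts = []
    assigned = np.zeros(len(table.df), dtype=np.int64)
    for gene in genes:
        in_gene = (chroms == gene.chrom) & (pos0 >= gene.start) & (pos0 < gene.end)
        assigned += in_gene
        counts.append(
            GeneDifferenceCount(
                gene.gene_id,
                int(in_gene.sum()),
                int((in_gene & unambiguous_diff).sum()),
                gene.pseudogene_flag,
            )
        )
    n_multi = int((assigned > 1).sum())
    if n_multi:
        logger.warning("%d SNPs overlap more than one gene; counted in each", n_multi)
    return counts


def rank_candidates(
    counts: list[GeneDifferenceCount],
    exclude_pseudogenes: bool = False,
    top_k: int | None = None,
) -> list[GeneDifferenceCount]:
    """Order genes by descending difference count; ties break lexicographically.

    With ``exclude_pseudogenes`` set, flagged genes are dropped before
    ranking. ``top_k`` truncates the ranking and must be positive.
    """
    if not counts:
        raise ValueError("empty counts")
    if top_k is not None and top_k <= 0:
        raise ValueError("top_k must be positive")
    pool = [c for c in counts if not (exclude_pseudogenes and c.pseudogene_flag)]
    ranked = sorted(pool, key=lambda c: (-c.n_differing, c.gene_id))
    return ranked[:top_k] if top_k is not None else ranked


def write_screen_report(counts: list[GeneDifferenceCount], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in counts],
            "n_snps_in_gene": [c.n_snps_in_gene for c in counts],
            "n_differing": [c.n_differing for c in counts],
            "pseudogene": [int(c.pseudogene_flag) for c in counts],
        }
    )
    df.to_csv(path, sep="\t", index=False)
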