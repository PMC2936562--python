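"""Inter-gene linkage disequilibrium over concatenated haplotypes.

Inbred strains are phased haploid haplotypes, so r-squared between two
variable sites is computed directly from the 2x2 haplotype table — no EM
phasing step. Per-gene alignments are reduced to their biallelic variable
sites, concatenated in genomic gene order with gene-of-origin bookkeeping,
and all pairwise r-squared values are reported along with per-gene-pair
summaries (max and mean). Two genes whose sites are each fixed between the
same two strain groups show r-squared of exactly 1 across genes — the
association signature — while a gene carrying only within-group
polymorphism shows no such coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import BASES, MISSING, MultiStrainAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HaplotypeMatrix:
    """Strains x variable-sites matrix with per-column gene annotation.

    ``data`` holds one row per strain and one column per retained biallelic
    site; entries are nucleotides or ``N`` for missing. ``genes`` and
    ``positions`` give each column's gene of origin and 1-based position
    within that gene's alignment. ``n_multiallelic_excluded`` counts columns
    dropped for carrying more than two alleles.
    """

    strains: tuple[str, ...]
    data: np.ndarray  # dtype '<U1'
    genes: tuple[str, ...]
    positions: tuple[int, ...]
    n_multiallelic_excluded: int = 0

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.strains), len(self.genes)):
            raise ValueError("haplotype matrix shape mismatch")
        if len(self.genes) != len(self.positions):
            raise ValueError("gene/position annotation length mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.genes)

    def to_tsv(self, path: str | Path) -> None:
        """Reduced-matrix TSV: gene and position header rows, then one row
        of site alleles per strain."""
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(self.genes) + "\n")
            fh.write("position\t" + "\t".join(str(p) for p in self.positions) + "\n")
            for i, strain in enumerate(self.strains):
                fh.write(strain + "\t" + "\t".join(self.data[i]) + "\n")


def _candidate_columns(aln: MultiStrainAlignment) -> list[tuple[int, set[str]]]:
    """1-based columns variable among non-missing entries, with allele sets."""
    seqs = list(aln.sequences.values())
    out = []
    for i in range(aln.length):
        alleles = {s[i] for s in seqs if s[i] not in MISSING}
        if len(alleles) >= 2:
            out.append((i + 1, alleles))
    return out


def concatenate(
    alignments: list[MultiStrainAlignment],
    gene_ids: list[str] | None = None,
) -> HaplotypeMatrix:
    """Reduce each gene to its variable sites and join them in gene order.

    All alignments must cover an identical strain set; row order follows the
    first alignment. Columns with more than two alleles are excluded (their
    count is logged and recorded on the matrix).
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(len(alignments))]
    if len(gene_ids) != len(alignments):
        raise ValueError("one gene id per alignment required")
    strains = alignments[0].strains
    for gid, aln in zip(gene_ids, alignments):
        if set(aln.strains) != set(strains):
            missing = set(strains) ^ set(aln.strains)
            raise ValueError(f"strain set mismatch at {gid}: {sorted(missing)}")

    columns: list[list[str]] = []
    genes: list[str] = []
    positions: list[int] = []
    n_excluded = 0
    for gid, aln in zip(gene_ids, alignments):
        for site, alleles in _candidate_columns(aln):
            if len(alleles) > 2:
                n_excluded += 1
                continue
            col = aln.column(site)
            columns.append(["N" if col[s] in MISSING else col[s] for s in strains])
            genes.append(gid)
            positions.append(site)
    if n_excluded:
        logger.info("excluded %d multi-allelic columns", n_excluded)
    data = (
        np.array(columns, dtype="<U1").T
        if columns
        else np.empty((len(strains), 0), dtype="<U1")
    )
    return HaplotypeMatrix(
        strains=tuple(strains),
        data=data,
        genes=tuple(genes),
        positions=tuple(positions),
        n_multiallelic_excluded=n_excluded,
    )


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise r-squared over sites, with allele-count bookkeeping.

    ``r2[i, j]`` is NaN when a pair is undefined (a site monomorphic after
    pairwise-complete filtering) — deliberately distinct from 0, which means
    measured independence. ``n_pairs`` holds the haplotype count used per
    pair.
    """

    hap: HaplotypeMatrix
    r2: np.ndarray
    n_pairs: np.ndarray

    def gene_pair_summary(self) -> pd.DataFrame:
        """Max and mean r-squared for every ordered gene pair (upper triangle)."""
        genes = sorted(set(self.hap.genes), key=self.hap.genes.index)
        rows = []
        garr = np.array(self.hap.genes)
        for ga, gb in combinations_with_replacement(genes, 2):
            ia = np.where(garr == ga)[0]
            ib = np.where(garr == gb)[0]
            block = self.r2[np.ix_(ia, ib)]
            if ga == gb:
                iu = np.triu_indices(len(ia), k=1)
                vals = block[iu] if len(ia) > 1 else np.array([])
            else:
                vals = block.ravel()
            vals = vals[~np.isnan(vals)] if vals.size else vals
            rows.append(
                {
                    "gene_a": ga,
                    "gene_b": gb,
                    "n_pairs": int(vals.size),
                    "max_r2": float(np.max(vals)) if vals.size else np.nan,
                    "mean_r2": float(np.mean(vals)) if vals.size else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        labels = [f"{g}:{p}" for g, p in zip(self.hap.genes, self.hap.positions)]
        pd.DataFrame(self.r2, index=labels, columns=labels).to_csv(path, sep="\t")


def r2_pair(col_i: np.ndarray, col_j: np.ndarray) -> tuple[float, int]:
    """r-squared between two site columns over pairwise-complete rows.

    Returns (r2, n_used); r2 is NaN if either site is monomorphic after
    dropping rows missing at either site.
    """
    keep = (col_i != "N") & (col_j != "N")
    a, b = col_i[keep], col_j[keep]
    n = int(keep.sum())
    ua, ub = np.unique(a), np.unique(b)
    if len(ua) < 2 or len(ub) < 2:
        return float("nan"), n
    # major allele = most frequent; ties by alphabetical order (np.unique sorts)
    counts_a = [(a == x).sum() for x in ua]
    counts_b = [(b == x).sum() for x in ub]
    major_a = ua[int(np.argmax(counts_a))]
    major_b = ub[int(np.argmax(counts_b))]
    p_i = (a == major_a).mean()
    p_j = (b == major_b).mean()
    p_ij = ((a == major_a) & (b == major_b)).mean()
    denom = p_i * (1 - p_i) * p_j * (1 - p_j)
    return float((p_ij - p_i * p_j) ** 2 / denom), n


def r2_matrix(hap: HaplotypeMatrix) -> LDMatrix:
    """All pairwise r-squared values for a haplotype matrix."""
    if len(hap.strains) < 2:
        raise ValueError("need at least 2 haplotypes")
    k = hap.n_sites
    r2 = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            val, n = r2_pair(hap.data[:, i], hap.data[:, j])
            r2[i, j] = r2[j, i] = val
            n_pairs[i, j] = n_pairs[j, i] = n
    return LDMatrix(hap=hap, r2=r2, n_pairs=n_pairs)


def fisher_exact_pvalues(hap: HaplotypeMatrix) -> np.ndarray:
    """Optional per-pair Fisher exact test on the 2x2 haplotype table.

    Off the main path: association in this design is read from r-squared;
    with five haplotypes per group the exact test has little power.
    """
    from scipy.stats import fisher_exact

    k = hap.n_sites
    pvals = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            col_i, col_j = hap.data[:, i], hap.data[:, j]
            keep = (col_i != "N") & (col_j != "N")
            a, b = col_i[keep], col_j[keep]
            ua, ub = np.unique(a), np.unique(b)
            if len(ua) < 2 or len(ub) < 2:
                continue
            table = [
                [int(((a == ua[0]) & (b == ub[0])).sum()),
                 int(((a == ua[0]) & (b == ub[1])).sum())],
                [int(((a == ua[1]) & (b == ub[0])).sum()),
                 int(((a == ua[1]) & (b == ub[1])).sum())],
            ]
            pvals[i, j] = pvals[j, i] = fisher_exact(table)[1]
    return pvals


def plot_heatmap(ld: LDMatrix, path: str | Path) -> None:
    """Site-by-site r-squared heat map with gene boundaries marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(ld.r2, vmin=0, vmax=1, cmap="Reds", interpolation="nearest")
    genes = list(ld.hap.genes)
    bounds = [i for i in range(1, len(genes)) if genes[i] != genes[i - 1]]
    for b in bounds:
        ax.axhline(b - 0.5, color="grey", lw=0.5)
        ax.axvline(b - 0.5, color="grey", lw=0.5)
    ax.set_title("pairwise $r^2$ over concatenated variable sites")
    fig.colorbar(im, ax=ax, label="$r^2$")
    fig.savefig(path, dpi=150)
    plt.close(fig)
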