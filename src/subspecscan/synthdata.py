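"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's substrates:

* :func:`make_two_group_alignment` — two groups of haploid strains with a
  requested number of fixed inter-group differences and private
  polymorphisms injected at disjoint positions (optionally steering how many
  fixed differences are nonsynonymous);
* :func:`evolve_on_tree` — sequences evolved site-independently on a
  phylogeny under HKY, with an infinite-sites mode in which every mutation
  hits a fresh site so recurrent change is impossible by construction;
* :func:`make_genotype_table` — an array-resequencing style genotype table
  with missing (``N``) calls and a recorded per-gene ground truth.

Every generator is a pure function of its spec (same seed, byte-identical
output), and each records the ground truth it injected so downstream
operations can be tested against construction rather than re-derivation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignment import BASES, GroupPartition, MultiStrainAlignment
from .phylo import transition_probabilities
from .screen import GeneInterval, StrainGenotypeTable
from .varsites import STOP_CODONS, _translate

_BASE_ARR = np.array(list(BASES))


# ---------------------------------------------------------------------------
# two-group alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimAlignmentSpec:
    """Recipe for a two-group alignment with injected variants.

    ``n_fixed`` columns differ between the groups with each group internally
    monomorphic; ``n_poly_a``/``n_poly_b`` columns vary privately within one
    group (minor-allele count ``minor_count``, singletons by default). When
    ``n_fixed_nonsyn`` is given, that many fixed differences are placed so
    the group-B allele changes the encoded amino acid and the remainder so
    it does not, one injected fixed site per codon.
    """

    n_per_group: int
    length: int
    n_fixed: int
    n_poly_a: int = 0
    n_poly_b: int = 0
    frame_offset: int = 0
    seed: int = 0
    n_fixed_nonsyn: int | None = None
    minor_count: int = 1
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if min(self.n_fixed, self.n_poly_a, self.n_poly_b) < 0:
            raise ValueError("variant counts must be nonnegative")
        if self.n_fixed + self.n_poly_a + self.n_poly_b > self.length:
            raise ValueError("more injected sites than alignment columns")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if (self.n_poly_a or self.n_poly_b) and not (
            self.n_per_group >= 2 and 1 <= self.minor_count <= self.n_per_group - 1
        ):
            raise ValueError(
                "polymorphisms need n_per_group >= 2 and 1 <= minor_count < n_per_group"
            )
        if self.n_fixed_nonsyn is not None and not 0 <= self.n_fixed_nonsyn <= self.n_fixed:
            raise ValueError("n_fixed_nonsyn must be between 0 and n_fixed")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")


@dataclass(frozen=True)
class AlignmentTruth:
    """Ground truth injected by the generator, keyed by 1-based column."""

    fixed_sites: dict[int, str]  # site -> 'synonymous'/'nonsynonymous'/'unassessed'
    poly_a_sites: tuple[int, ...]
    poly_b_sites: tuple[int, ...]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "fixed_sites": {str(k): v for k, v in self.fixed_sites.items()},
                    "poly_a_sites": list(self.poly_a_sites),
                    "poly_b_sites": list(self.poly_b_sites),
                },
                indent=2,
            )
        )


@dataclass(frozen=True)
class SimulatedAlignment:
    alignment: MultiStrainAlignment
    partition: GroupPartition
    truth: AlignmentTruth


def _codon_candidates(codon: str, want_nonsyn: bool) -> list[tuple[int, str]]:
    """(offset, alt base) pairs whose single substitution has the wanted
    coding effect; substitutions creating or destroying a stop are skipped
    so injected sequences stay plausible coding material."""
    if codon in STOP_CODONS:
        return []
    out = []
    ref_aa = _translate(codon)
    for off in range(3):
        for alt in BASES:
            if alt == codon[off]:
                continue
            mutated = codon[:off] + alt + codon[off + 1:]
            if mutated in STOP_CODONS:
                continue
            if (_translate(mutated) != ref_aa) == want_nonsyn:
                out.append((off, alt))
    return out


def make_two_group_alignment(spec: SimAlignmentSpec) -> SimulatedAlignment:
    """Build the alignment described by ``spec`` plus its ground truth.

    Group A keeps the ancestral base everywhere; fixed differences give all
    of group B an alternate base; private polymorphisms give ``minor_count``
    strains of one group an alternate base. All injected positions are
    disjoint, so a brute-force column scan recovers the spec's counts.
    """
    rng = np.random.default_rng(spec.seed)
    ancestral = rng.choice(4, size=spec.length, p=spec.base_freqs)
    names_a = [f"dom{i + 1}" for i in range(spec.n_per_group)]
    names_b = [f"mus{i + 1}" for i in range(spec.n_per_group)]
    seqs = {name: ancestral.copy() for name in names_a + names_b}

    fixed_sites: dict[int, str] = {}
    used_positions: set[int] = set()

    def draw_alt(pos: int) -> int:
        choices = [b for b in range(4) if b != ancestral[pos]]
        return int(rng.choice(choices))

    if spec.n_fixed_nonsyn is None:
        total = spec.n_fixed + spec.n_poly_a + spec.n_poly_b
        positions = rng.choice(spec.length, size=total, replace=False)
        fixed_pos = positions[: spec.n_fixed]
        poly_pos_a = positions[spec.n_fixed: spec.n_fixed + spec.n_poly_a]
        poly_pos_b = positions[spec.n_fixed + spec.n_poly_a:]
        for pos in fixed_pos:
            alt = draw_alt(pos)
            for name in names_b:
                seqs[name][pos] = alt
            fixed_sites[int(pos) + 1] = "unassessed"
            used_positions.add(int(pos))
    else:
        codon_starts = [
            s for s in range(spec.frame_offset, spec.length - 2, 3)
        ]
        if spec.n_fixed > len(codon_starts):
            raise ValueError("not enough complete codons for the requested fixed sites")
        targets = ["nonsynonymous"] * spec.n_fixed_nonsyn + ["synonymous"] * (
            spec.n_fixed - spec.n_fixed_nonsyn
        )
        order = rng.permutation(len(codon_starts))
        cursor = 0
        for want in targets:
            placed = False
            while cursor < len(order):
                start = codon_starts[order[cursor]]
                cursor += 1
                codon = "".join(_BASE_ARR[ancestral[start:start + 3]])
                cands = _codon_candidates(codon, want_nonsyn=(want == "nonsynonymous"))
                if not cands:
                    continue
                off, alt = cands[rng.integers(len(cands))]
                pos = start + off
                for name in names_b:
                    seqs[name][pos] = _BASE_INDEX_ARR[alt]
                fixed_sites[pos + 1] = want
                used_positions.update(range(start, start + 3))
                placed = True
                break
            if not placed:
                raise ValueError("could not place all requested coding fixed sites")
        n_poly = spec.n_poly_a + spec.n_poly_b
        if n_poly:
            free = np.array(
                [p for p in range(spec.length) if p not in used_positions], dtype=int
            )
            if len(free) < n_poly:
                raise ValueError("not enough free columns for the requested polymorphisms")
            chosen = rng.choice(free, size=n_poly, replace=False)
        else:
            chosen = np.array([], dtype=int)
        poly_pos_a = chosen[: spec.n_poly_a]
        poly_pos_b = chosen[spec.n_poly_a:]

    for pos_list, names in ((poly_pos_a, names_a), (poly_pos_b, names_b)):
        for pos in pos_list:
            alt = draw_alt(pos)
            carriers = rng.choice(len(names), size=spec.minor_count, replace=False)
            for k in carriers:
                seqs[names[k]][pos] = alt
            used_positions.add(int(pos))

    alignment = MultiStrainAlignment(
        {name: "".join(_BASE_ARR[arr]) for name, arr in seqs.items()}
    )
    partition = GroupPartition(
        {**{n: "A" for n in names_a}, **{n: "B" for n in names_b}}
    )
    truth = AlignmentTruth(
        fixed_sites=fixed_sites,
        poly_a_sites=tuple(sorted(int(p) + 1 for p in poly_pos_a)),
        poly_b_sites=tuple(sorted(int(p) + 1 for p in poly_pos_b)),
    )
    return SimulatedAlignment(alignment, partition, truth)


_BASE_INDEX_ARR = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# sequence evolution on a tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeSimSpec:
    """Recipe for evolving an alignment on a phylogeny under HKY.

    ``tree`` is a Newick string or dendropy Tree with branch lengths in
    expected substitutions per site. In ``infinite_sites`` mode mutation
    events are Poisson on each branch and every event strikes a previously
    untouched column, so no identical change can recur on two branches.
    """

    tree: str | dendropy.Tree
    length: int
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 2.0
    seed: int = 0
    infinite_sites: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("zero-length alignment request")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    def as_tree(self) -> dendropy.Tree:
        if isinstance(self.tree, dendropy.Tree):
            tree = self.tree.clone(depth=1)
        else:
            tree = dendropy.Tree.get(data=self.tree, schema="newick")
        n_leaves = sum(1 for _ in tree.leaf_node_iter())
        if n_leaves < 2:
            raise ValueError("tree needs at least 2 leaves")
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                node.edge.length = 0.0
            if node.edge.length < 0:
                raise ValueError("negative branch length in simulation tree")
        return tree


def evolve_on_tree(spec: TreeSimSpec) -> MultiStrainAlignment:
    """One sequence per leaf, sites evolving independently along the tree."""
    tree = spec.as_tree()
    rng = np.random.default_rng(spec.seed)
    freqs = np.asarray(spec.base_freqs)
    root_seq = rng.choice(4, size=spec.length, p=freqs)

    states: dict = {tree.seed_node: root_seq}
    if spec.infinite_sites:
        fresh = list(rng.permutation(spec.length))
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            seq = states[node.parent_node].copy()
            n_mut = rng.poisson(node.edge.length * spec.length)
            if n_mut > len(fresh):
                raise ValueError(
                    "infinite-sites site pool exhausted; increase alignment length"
                )
            for _ in range(n_mut):
                pos = fresh.pop()
                alt = [b for b in range(4) if b != seq[pos]]
                seq[pos] = rng.choice(alt)
            states[node] = seq
    else:
        cache: dict[float, np.ndarray] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            t = float(node.edge.length)
            if t not in cache:
                cache[t] = transition_probabilities(freqs, spec.kappa, t)
            P = cache[t]
            parent = states[node.parent_node]
            seq = parent.copy()
            for a in range(4):
                idx = np.where(parent == a)[0]
                if idx.size:
                    seq[idx] = rng.choice(4, size=idx.size, p=P[a])
            states[node] = seq

    out = {}
    for leaf in tree.leaf_node_iter():
        out[leaf.taxon.label] = "".join(_BASE_ARR[states[leaf]])
    return MultiStrainAlignment(out)


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimTableSpec:
    """Recipe for an array-resequencing style strain-genotype table."""

    n_genes: int
    snp_rate: float = 5.0
    n_rate: float = 0.1
    diff_rate: float = 0.3
    seed: int = 0
    gene_length: int = 1000
    gene_gap: int = 500
    pseudo_rate: float = 0.0
    strains: tuple[str, ...] = ("focalA", "focalB", "bg1", "bg2")

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name, p in (("n_rate", self.n_rate), ("diff_rate", self.diff_rate),
                        ("pseudo_rate", self.pseudo_rate)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.snp_rate < 0:
            raise ValueError("snp_rate must be nonnegative")
        if len(self.strains) < 2:
            raise ValueError("need at least the two focal strains")


@dataclass(frozen=True)
class SimulatedTable:
    table: StrainGenotypeTable
    genes: list[GeneInterval]
    truth: dict[str, int]  # gene_id -> true differing-SNP count after masking

    def truth_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.truth, indent=2))


def make_genotype_table(spec: SimTableSpec) -> SimulatedTable:
    """Genotype table, gene intervals, and recorded per-gene truth.

    The two focal strains are ``spec.strains[0]`` and ``spec.strains[1]``.
    Each gene draws a Poisson number of SNPs; a SNP gives the focal pair
    differing bases with probability ``diff_rate``; every genotype is then
    independently masked to ``N`` with probability ``n_rate``. The recorded
    truth counts, per gene, the SNPs left with two unambiguous differing
    focal calls — exactly what an honest screen should report.
    """
    rng = np.random.default_rng(spec.seed)
    focal_a, focal_b = spec.strains[0], spec.strains[1]
    genes: list[GeneInterval] = []
    rows: list[dict] = []
    truth: dict[str, int] = {}
    for g in range(spec.n_genes):
        start = g * (spec.gene_length + spec.gene_gap)
        gene = GeneInterval(
            gene_id=f"gene{g:04d}",
            chrom="chr1",
            start=start,
            end=start + spec.gene_length,
            pseudogene_flag=bool(rng.random() < spec.pseudo_rate),
        )
        genes.append(gene)
        n_snps = min(int(rng.poisson(spec.snp_rate)), spec.gene_length)
        offsets = rng.choice(spec.gene_length, size=n_snps, replace=False)
        n_true = 0
        for off in sorted(int(o) for o in offsets):
            ref = int(rng.integers(4))
            if rng.random() < spec.diff_rate:
                alt = int(rng.choice([b for b in range(4) if b != ref]))
            else:
                alt = ref
            calls = {focal_a: BASES[ref], focal_b: BASES[alt]}
            for other in spec.strains[2:]:
                calls[other] = BASES[int(rng.choice([ref, alt]))]
            masked = {
                s: ("N" if rng.random() < spec.n_rate else c) for s, c in calls.items()
            }
            if masked[focal_a] != "N" and masked[focal_b] != "N" and ref != alt:
                n_true += 1
            rows.append({"chrom": "chr1", "pos": start + off + 1, **masked})
        truth[gene.gene_id] = n_true
    columns = ["chrom", "pos", *spec.strains]
    df = pd.DataFrame(rows, columns=columns)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
        df["pos"] = df["pos"].astype(int)
    return SimulatedTable(StrainGenotypeTable(df), genes, truth)


# ---------------------------------------------------------------------------
# study-condition presets
# ---------------------------------------------------------------------------

def vmn1r67_like_spec(seed: int = 0) -> SimAlignmentSpec:
    """Divergence-dominated receptor gene: 915 bp coding, five strains per
    subspecies, 24 fixed inter-group differences of which 15 are
    nonsynonymous and 9 synonymous, plus two group-A private polymorphisms."""
    return SimAlignmentSpec(
        n_per_group=5, length=915, n_fixed=24, n_poly_a=2, n_poly_b=0,
        frame_offset=0, seed=seed, n_fixed_nonsyn=15,
    )


def vmn1r71_like_spec(seed: int = 0) -> SimAlignmentSpec:
    """Polymorphism-dominated neighbour gene: 921 bp, no fixed differences,
    35 private polymorphisms (split 18 group A / 17 group B; the source data
    report only the total)."""
    return SimAlignmentSpec(
        n_per_group=5, length=921, n_fixed=0, n_poly_a=18, n_poly_b=17,
        frame_offset=0, seed=seed,
    )


def abpa27_like_spec(seed: int = 0) -> SimAlignmentSpec:
    """Stand-in for the pheromone gene with subspecies-fixed alleles and no
    within-group polymorphism (synthetic: the real sequences are not part of
    this package): 1185 bp with 8 fixed differences."""
    return SimAlignmentSpec(
        n_per_group=5, length=1185, n_fixed=8, n_poly_a=0, n_poly_b=0,
        frame_offset=0, seed=seed,
    )


MURID_SPECIES_TREE = (
    "(rat,(pahari,(caroli,((spicilegus,macedonicus),"
    "(spretus,(domesticus,musculus,castaneus))))));"
)
"""Canonical murid species topology; the three M. musculus subspecies form
an unresolved polytomy. Branch lengths deliberately absent — this is the
guide topology, not an estimate."""

MURID_DISCORDANT_GENE_TREE = (
    "(rat:0.30,(pahari:0.12,(caroli:0.09,((musculus:0.01,castaneus:0.012):0.05,"
    "(spicilegus:0.03,(macedonicus:0.025,(spretus:0.02,domesticus:0.018):0.012)"
    ":0.01):0.02):0.01):0.03):0.05);"
)
"""A gene history discordant with the species tree: the domesticus allele
clusters inside the outgroup species rather than with its sister
subspecies — the pattern an introgressed or anciently sorted locus shows.
Branch lengths are in substitutions/site at murid-like divergence."""


def discordant_locus(
    seed: int = 0,
    length: int = 918,
    kappa: float = 2.0,
    infinite_sites: bool = True,
) -> MultiStrainAlignment:
    """Evolve a locus on the discordant gene tree, for guide-tree contrasts.

    Defaults to the infinite-sites mode: at shallow murid divergence real
    loci rarely take repeat hits at one column, so recurrent identical
    changes inferred under a guide tree reflect discordant history, not
    mutational saturation. Set ``infinite_sites=False`` for finite-sites
    evolution with genuine multiple hits.
    """
    return evolve_on_tree(
        TreeSimSpec(
            tree=MURID_DISCORDANT_GENE_TREE, length=length, kappa=kappa,
            seed=seed, infinite_sites=infinite_sites,
        )
    )
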