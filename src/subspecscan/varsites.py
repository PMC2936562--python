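"""Classify variable alignment columns and compute diversity statistics.

A column in a two-group alignment is a *fixed difference* when each group is
internally monomorphic but the two groups carry different nucleotides; it is
a *polymorphism* when at least one group varies internally. Fixed coding
differences are further scored synonymous or nonsynonymous against the
group-A consensus codon. Diversity is summarised per group by nucleotide
diversity (pi) and Watterson's theta, both per site, after complete deletion
of columns containing missing data (``N``) or gaps — the convention DnaSP
applies by default, which keeps the segregating-site count S unambiguous.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from itertools import combinations

from Bio.Data.CodonTable import standard_dna_table

from .alignment import BASES, MISSING, GroupPartition, MultiStrainAlignment

logger = logging.getLogger(__name__)

CODON_TABLE = standard_dna_table.forward_table
STOP_CODONS = set(standard_dna_table.stop_codons)


def _translate(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stop."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


class SiteCategory(str, Enum):
    FIXED_DIFFERENCE = "fixed_difference"
    POLYMORPHIC_A = "polymorphic_A"
    POLYMORPHIC_B = "polymorphic_B"
    POLYMORPHIC_BOTH = "polymorphic_both"


class CodingEffect(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class SiteClassification:
    """Category of one variable column (1-based ``site``)."""

    site: int
    category: SiteCategory
    alleles_by_group: dict[str, frozenset[str]]
    coding_effect: CodingEffect = CodingEffect.NOT_ASSESSED


@dataclass(frozen=True)
class DiversityStats:
    """Per-site diversity summary for one group of sequences.

    ``theta_w = S / (a_n * L_eff)`` with ``a_n`` the harmonic number
    ``sum(1/i for i in 1..n-1)``; ``pi`` averages pairwise differences over
    all sequence pairs and included sites.
    """

    n: int
    L_eff: int
    S: int
    pi: float
    theta_w: float
    a_n: float


def included_columns(aln: MultiStrainAlignment) -> list[int]:
    """1-based columns free of N and gaps in every sequence (complete deletion)."""
    seqs = list(aln.sequences.values())
    return [
        i + 1
        for i in range(aln.length)
        if not any(s[i] in MISSING for s in seqs)
    ]


def variable_sites(aln: MultiStrainAlignment) -> list[int]:
    """1-based columns with >= 2 distinct nucleotides, after complete deletion.

    Columns containing any ``N`` or gap are excluded from all site statistics,
    so a column that varies only among its non-missing entries is not reported.
    """
    seqs = list(aln.sequences.values())
    out = []
    for i in included_columns(aln):
        col = {s[i - 1] for s in seqs}
        if len(col) >= 2:
            out.append(i)
    return out


def classify_sites(
    aln: MultiStrainAlignment,
    partition: GroupPartition,
    frame_offset: int | None = None,
    joint_codon: bool = False,
) -> list[SiteClassification]:
    """Partition the variable columns into fixed differences and polymorphisms.

    When ``frame_offset`` is given, fixed differences are additionally scored
    synonymous/nonsynonymous (see :func:`coding_effect`).
    """
    partition.validate_against(aln)
    label_a, label_b = partition.labels
    group_a = partition.members(label_a)
    group_b = partition.members(label_b)
    for label, members in ((label_a, group_a), (label_b, group_b)):
        if len(members) == 1:
            logger.warning(
                "group %s has a single strain; within-group polymorphism cannot be observed",
                label,
            )

    out = []
    for site in variable_sites(aln):
        col = aln.column(site)
        alleles_a = frozenset(col[s] for s in group_a)
        alleles_b = frozenset(col[s] for s in group_b)
        if len(alleles_a) == 1 and len(alleles_b) == 1:
            # both groups monomorphic; the site is variable, so alleles differ
            category = SiteCategory.FIXED_DIFFERENCE
        elif len(alleles_a) > 1 and len(alleles_b) > 1:
            category = SiteCategory.POLYMORPHIC_BOTH
        elif len(alleles_a) > 1:
            category = SiteCategory.POLYMORPHIC_A
        else:
            category = SiteCategory.POLYMORPHIC_B
        effect = CodingEffect.NOT_ASSESSED
        if frame_offset is not None and category is SiteCategory.FIXED_DIFFERENCE:
            effect = coding_effect(aln, partition, site, frame_offset, joint_codon=joint_codon)
        out.append(
            SiteClassification(
                site=site,
                category=category,
                alleles_by_group={label_a: alleles_a, label_b: alleles_b},
                coding_effect=effect,
            )
        )
    return out


def _consensus_base(aln: MultiStrainAlignment, strains: list[str], site: int) -> str:
    """Majority base among non-missing entries; ties broken alphabetically."""
    col = aln.column(site)
    counts = Counter(col[s] for s in strains if col[s] not in MISSING)
    if not counts:
        return "N"
    top = max(counts.values())
    return min(b for b, c in counts.items() if c == top)


def coding_effect(
    aln: MultiStrainAlignment,
    partition: GroupPartition,
    site: int,
    frame_offset: int,
    joint_codon: bool = False,
) -> CodingEffect:
    """Score a fixed difference as synonymous or nonsynonymous.

    The reference codon is the group-A consensus codon containing ``site``.
    In the default per-site mode the alternate codon substitutes group B's
    allele at ``site`` only, holding the other two positions at the group-A
    consensus; in ``joint_codon`` mode the full group-B consensus codon is
    compared instead. Codons truncated at the alignment edge, or containing
    missing consensus bases, are not assessed.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    pos0 = site - 1
    if pos0 < frame_offset:
        return CodingEffect.NOT_ASSESSED
    codon_index = (pos0 - frame_offset) // 3
    start = frame_offset + 3 * codon_index
    if start + 3 > aln.length:
        return CodingEffect.NOT_ASSESSED

    label_a, label_b = partition.labels
    group_a = partition.members(label_a)
    group_b = partition.members(label_b)
    codon_a = "".join(
        _consensus_base(aln, group_a, start + k + 1) for k in range(3)
    )
    if any(c in MISSING for c in codon_a):
        return CodingEffect.NOT_ASSESSED
    if joint_codon:
        codon_b = "".join(
            _consensus_base(aln, group_b, start + k + 1) for k in range(3)
        )
    else:
        allele_b = _consensus_base(aln, group_b, site)
        within = pos0 - start
        codon_b = codon_a[:within] + allele_b + codon_a[within + 1:]
    if any(c in MISSING for c in codon_b):
        return CodingEffect.NOT_ASSESSED
    if _translate(codon_a) == _translate(codon_b):
        return CodingEffect.SYNONYMOUS
    return CodingEffect.NONSYNONYMOUS


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson denominator."""
    return sum(1.0 / i for i in range(1, n))


def diversity(aln: MultiStrainAlignment) -> DiversityStats:
    """Nucleotide diversity pi and Watterson's theta for one group of sequences.

    Both statistics are per site over the columns retained by complete
    deletion. ``pi`` is the average pairwise difference count divided by
    the effective length; for a monomorphic sample both estimators are 0.
    """
    if aln.n < 2:
        raise ValueError("diversity needs at least 2 sequences")
    cols = included_columns(aln)
    L_eff = len(cols)
    if L_eff == 0:
        raise ValueError("no columns remain after complete deletion")
    seqs = list(aln.sequences.values())
    n = len(seqs)

    S = 0
    for i in cols:
        if len({s[i - 1] for s in seqs}) >= 2:
            S += 1

    total_diffs = 0
    for s1, s2 in combinations(seqs, 2):
        total_diffs += sum(1 for i in cols if s1[i - 1] != s2[i - 1])
    pi = (2.0 / (n * (n - 1))) * total_diffs / L_eff

    a_n = harmonic_number(n)
    theta_w = S / (a_n * L_eff)
    return DiversityStats(n=n, L_eff=L_eff, S=S, pi=pi, theta_w=theta_w, a_n=a_n)


def count_categories(classifications: list[SiteClassification]) -> dict[str, int]:
    """Tally of site categories and coding effects, for reports."""
    tally = Counter(c.category.value for c in classifications)
    effects = Counter(
        c.coding_effect.value
        for c in classifications
        if c.category is SiteCategory.FIXED_DIFFERENCE
    )
    return {
        "variable_sites": len(classifications),
        "fixed_difference": tally.get("fixed_difference", 0),
        "polymorphic_A": tally.get("polymorphic_A", 0),
        "polymorphic_B": tally.get("polymorphic_B", 0),
        "polymorphic_both": tally.get("polymorphic_both", 0),
        "fixed_synonymous": effects.get("synonymous", 0),
        "fixed_nonsynonymous": effects.get("nonsynonymous", 0),
    }
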