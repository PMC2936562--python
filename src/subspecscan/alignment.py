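"""Core containers: multi-strain alignments and two-group partitions.

Wild-derived inbred mouse strains are homozygous, so each strain is carried
as a single haploid sequence. Alignments are equal-length DNA strings over
``{A, C, G, T, N, -}``; a :class:`GroupPartition` labels every strain with
one of two subspecies groups (canonically ``A`` and ``B``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN-")
BASES = ("A", "C", "G", "T")
MISSING = frozenset("N-")


@dataclass(frozen=True)
class MultiStrainAlignment:
    """Equal-length haploid sequences keyed by strain name.

    Parameters
    ----------
    sequences
        Mapping of strain name to DNA string. Sequences are uppercased on
        construction and must share one length and use only ``ACGTN-``.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        normalized = {name: seq.upper() for name, seq in self.sequences.items()}
        lengths = {len(s) for s in normalized.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        for name, seq in normalized.items():
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains symbols outside ACGTN-: {sorted(bad)}"
                )
        object.__setattr__(self, "sequences", normalized)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def strains(self) -> list[str]:
        return list(self.sequences)

    @property
    def n(self) -> int:
        return len(self.sequences)

    def column(self, site: int) -> dict[str, str]:
        """Return the alignment column at 1-based position ``site``."""
        if not 1 <= site <= self.length:
            raise IndexError(f"site {site} outside alignment of length {self.length}")
        return {name: seq[site - 1] for name, seq in self.sequences.items()}

    def subset(self, strains: Iterable[str]) -> "MultiStrainAlignment":
        strains = list(strains)
        missing = [s for s in strains if s not in self.sequences]
        if missing:
            raise KeyError(f"strains not in alignment: {missing}")
        return MultiStrainAlignment({s: self.sequences[s] for s in strains})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MultiStrainAlignment":
        records = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            name = rec.id.split("|")[0]
            records[name] = str(rec.seq)
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path, partition: "GroupPartition | None" = None) -> None:
        recs = []
        for name, seq in self.sequences.items():
            rid = name
            if partition is not None:
                rid = f"{name}|group{partition.assignment[name]}"
            recs.append(SeqRecord(Seq(seq), id=rid, description=""))
        SeqIO.write(recs, str(path), "fasta")


@dataclass(frozen=True)
class GroupPartition:
    """Assignment of strains to exactly two groups, canonically ``A``/``B``."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if len(labels) != 2:
            raise ValueError(f"a partition needs exactly 2 nonempty groups, got {sorted(labels)}")

    @property
    def labels(self) -> tuple[str, str]:
        return tuple(sorted(set(self.assignment.values())))  # type: ignore[return-value]

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == label]

    def swapped(self) -> "GroupPartition":
        """Relabel the two groups (A becomes B and vice versa)."""
        a, b = self.labels
        flip = {a: b, b: a}
        return GroupPartition({s: flip[g] for s, g in self.assignment.items()})

    def validate_against(self, aln: MultiStrainAlignment) -> None:
        unassigned = set(aln.strains) - set(self.assignment)
        if unassigned:
            raise ValueError(f"strains without a group: {sorted(unassigned)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupPartition":
        """Read a two-column TSV of (strain, group), no header."""
        assignment: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            strain, group = line.split("\t")[:2]
            assignment[strain] = group
        return cls(assignment)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{s}\t{g}\n" for s, g in self.assignment.items())
        )
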