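"""Genetic code tables for mitochondrial codon-usage analysis.

The invertebrate mitochondrial code (NCBI translation table 5) differs from
the standard code in three reassignments: AGA/AGG encode serine (making
serine an 8-fold family), AUA encodes methionine, and UGA encodes
tryptophan.  Only UAA and UAG terminate translation, leaving 62 sense
codons distributed over twelve 2-fold, six 4-fold, one 6-fold (leucine)
and one 8-fold (serine) degeneracy families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data import CodonTable

RNA_BASES = "ACGU"


@dataclass(frozen=True)
class GeneticCode:
    """A codon-to-amino-acid map with its synonymous-family structure.

    Codons are held in the RNA alphabet (e.g. ``UUA``); DNA input is
    transcribed on the way in by the counting routines.
    """

    table_id: str
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]
    family_of: Mapping[str, tuple[str, ...]] = field(init=False)

    def __post_init__(self) -> None:
        fams: dict[str, list[str]] = {}
        for codon in sorted(self.codon_to_aa):
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        object.__setattr__(
            self, "family_of", {aa: tuple(c) for aa, c in fams.items()}
        )

    @classmethod
    def from_ncbi_id(cls, ncbi_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_rna_by_id[ncbi_id]
        return cls(
            table_id=table.names[0] if table.names else str(ncbi_id),
            codon_to_aa=dict(table.forward_table),
            stop_codons=frozenset(table.stop_codons),
        )

    @classmethod
    def invertebrate_mito(cls) -> "GeneticCode":
        """NCBI translation table 5, the code used for insect mitogenomes."""
        return cls.from_ncbi_id(5)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    def degeneracy(self, codon: str) -> int:
        return len(self.family_of[self.codon_to_aa[codon]])

    @property
    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Map family size k -> amino acids whose family has k codons."""
        classes: dict[int, list[str]] = {}
        for aa, codons in self.family_of.items():
            classes.setdefault(len(codons), []).append(aa)
        return {k: tuple(sorted(v)) for k, v in classes.items()}

    def translate_codon(self, codon: str) -> str:
        """Amino acid for an RNA codon; ``*`` for stops."""
        if codon in self.stop_codons:
            return "*"
        return self.codon_to_aa[codon]


def as_rna(seq: str) -> str:
    """Uppercase and transcribe a nucleotide string to the RNA alphabet."""
    return seq.upper().replace("T", "U")


def as_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")
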