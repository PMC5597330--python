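"""Genetic-code definitions: codons, synonymous families, translation.

A :class:`GeneticCode` maps each of the 64 DNA codons to an amino-acid
symbol (stop rendered ``*``) and groups them into synonymous families.
Families drive everything downstream: relative codon adaptiveness is
defined within a family, and recoding only ever swaps codons inside one.

Codes are built from NCBI translation tables via Biopython, so any
``table_id`` Biopython knows is accepted; the default is the standard
code (table 1), under which amino-acid assignments are identical for
the bacterial, archaeal and eukaryotic hosts this package targets.
Alternative start codons are deliberately ignored: tables count codons,
not translational starts, so e.g. GTG is always valine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

STOP_SYMBOL = "*"
BASES = "ACGT"

#: All 64 DNA codons in alphabetical order.
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
)


class SequenceError(ValueError):
    """Raised for sequences that violate coding-sequence preconditions."""


def normalize_dna(seq: str) -> str:
    """Upper-case a nucleotide string and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus the induced synonymous families.

    Parameters
    ----------
    table_id:
        NCBI translation-table identifier (1 = standard code).
    codon_to_aa:
        Mapping of each of the 64 codons to a one-letter amino-acid
        symbol, with stop codons mapped to ``"*"``.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            missing = sorted(set(ALL_CODONS) - set(self.codon_to_aa))
            raise ValueError(f"genetic code must map all 64 codons; missing {missing}")
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:  # alphabetical within each family
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        object.__setattr__(
            self, "families", {aa: tuple(cods) for aa, cods in fams.items()}
        )

    @classmethod
    @lru_cache(maxsize=None)
    def from_table_id(cls, table_id: int = 1) -> "GeneticCode":
        """Build a code from an NCBI translation table (default: standard)."""
        ncbi = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = {c: ncbi.forward_table.get(c, STOP_SYMBOL) for c in ALL_CODONS}
        return cls(table_id=table_id, codon_to_aa=mapping)

    def amino_acid(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def synonymous_codons(self, codon: str) -> tuple[str, ...]:
        """Synonymous family of ``codon`` (always contains ``codon``)."""
        codon = normalize_dna(codon)
        if codon not in self.codon_to_aa:
            raise SequenceError(f"invalid codon {codon!r}")
        return self.families[self.codon_to_aa[codon]]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP_SYMBOL

    def translate(self, dna: str) -> str:
        """Translate an in-frame DNA string; stops render as ``*``.

        Raises
        ------
        SequenceError
            If the length is not a multiple of 3 or a codon contains a
            non-ACGT character (the message names the offending codon
            position, 1-based).
        """
        dna = normalize_dna(dna)
        if len(dna) % 3 != 0:
            raise SequenceError(
                f"sequence length {len(dna)} is not a multiple of 3"
            )
        out = []
        for i in range(0, len(dna), 3):
            codon = dna[i : i + 3]
            aa = self.codon_to_aa.get(codon)
            if aa is None:
                raise SequenceError(
                    f"non-ACGT character in codon {i // 3 + 1} ({codon!r})"
                )
            out.append(aa)
        return "".join(out)


STANDARD_CODE = GeneticCode.from_table_id(1)


def codons_of(dna: str) -> list[str]:
    """Split an in-frame DNA string into its codons (no validation)."""
    return [dna[i : i + 3] for i in range(0, len(dna) - len(dna) % 3, 3)]
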