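"""The standard genetic code as an explicit, validated object.

The whole package works on the standard (translation table 1) code: 61 sense
codons, 3 stop codons (TAA, TAG, TGA), ATG as the initiator.  Alternative
codes and selenocysteine are deliberately unsupported.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from types import MappingProxyType
from typing import Mapping

from Bio.Data import CodonTable

BASES = "ACGT"

#: The 20 standard amino acids, alphabetical by one-letter code.  Every
#: 20-vector in the package is ordered this way.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

ALL_CODONS: tuple[str, ...] = tuple("".join(c) for c in product(BASES, repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """A codon-to-amino-acid translation table.

    Parameters
    ----------
    codon_to_aa
        Mapping of all 64 trinucleotides to one-letter amino acids, with
        ``"*"`` for stops.
    start_codon
        The initiator codon (ATG for the standard code).
    """

    codon_to_aa: Mapping[str, str]
    start_codon: str = "ATG"

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("codon table must cover all 64 trinucleotides")
        sense = [c for c, a in self.codon_to_aa.items() if a != "*"]
        stops = [c for c, a in self.codon_to_aa.items() if a == "*"]
        if len(sense) != 61 or len(stops) != 3:
            raise ValueError(
                f"expected 61 sense / 3 stop codons, got {len(sense)}/{len(stops)}"
            )
        aas = {self.codon_to_aa[c] for c in sense}
        if aas != set(AMINO_ACIDS):
            raise ValueError("every standard amino acid needs at least one codon")
        object.__setattr__(
            self, "codon_to_aa", MappingProxyType(dict(self.codon_to_aa))
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] != "*")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c in ALL_CODONS if self.codon_to_aa[c] == "*")

    def codons_for(self, aa: str) -> tuple[str, ...]:
        """All codons encoding ``aa`` (one-letter code)."""
        if aa not in AMINO_ACIDS:
            raise KeyError(f"unknown amino acid {aa!r}")
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == aa)

    def translate_codon(self, codon: str) -> str:
        """One-letter amino acid for ``codon``; ``"*"`` for a stop."""
        try:
            return self.codon_to_aa[codon]
        except KeyError:
            raise ValueError(f"invalid codon {codon!r}") from None


@lru_cache(maxsize=1)
def standard_code() -> GeneticCode:
    """The standard genetic code, built from Biopython's table 1."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return GeneticCode(codon_to_aa=mapping)
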