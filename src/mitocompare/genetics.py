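"""Genetic-code helpers for the invertebrate mitochondrial code.

All coding-sequence arithmetic in this package runs under NCBI translation
table 5 (invertebrate mitochondrial: TGA=Trp, ATA=Met, AGA/AGG=Ser), the code
used by insect mitochondria. The table itself comes from Biopython; this module
only derives the lookups the rest of the package needs (codon -> amino acid,
synonymous families, family sizes).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable
from Bio.Seq import Seq

INVERTEBRATE_MITO_TABLE_ID = 5

BASES = "TCAG"

_table = CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE_ID]

#: all 64 codons in TCAG enumeration order
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(BASES, repeat=3)
)

#: stop codons under table 5 (TAA, TAG)
STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

#: codon -> one-letter amino acid for sense codons
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)

#: sense (non-stop) codons, TCAG order
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: amino acid -> tuple of synonymous codons (the codon family)
AA_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_FAMILIES.setdefault(CODON_TO_AA[_codon], ())
AA_FAMILIES = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa) for aa in AA_FAMILIES
}

#: amino acid -> family size k (number of synonymous codons)
FAMILY_SIZES: dict[str, int] = {aa: len(cods) for aa, cods in AA_FAMILIES.items()}

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}

VALID_BASES = frozenset("ACGTN")


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, ``*`` for a stop."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


@lru_cache(maxsize=None)
def is_synonymous(codon_a: str, codon_b: str) -> bool:
    """True when two sense codons encode the same amino acid."""
    return CODON_TO_AA[codon_a] == CODON_TO_AA[codon_b]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
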