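"""Standard genetic code tables shared by all modules.

Only the standard (NCBI table 1) code is supported: 61 sense codons, 3 stop
codons, 20 amino acids.  Synonymous families follow Wright's convention for
the effective number of codons: Leu/Ser/Arg are single six-fold families
(not split 2+4), Ile is the lone three-fold family, and Met/Trp are the two
single-codon amino acids.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))  # TAA, TAG, TGA
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

#: amino acid -> tuple of its synonymous codons (alphabetical)
FAMILIES: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AMINO_ACIDS
}

#: amino acid -> family size (degeneracy)
DEGENERACY: dict[str, int] = {aa: len(codons) for aa, codons in FAMILIES.items()}

#: degeneracy class -> amino acids in that class (Wright's grouping)
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(aa for aa in AMINO_ACIDS if DEGENERACY[aa] == k) for k in (1, 2, 3, 4, 6)
}

SINGLE_CODON_AAS: tuple[str, ...] = DEGENERACY_CLASSES[1]  # M, W

START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_gc(base: str) -> bool:
    return base in "GC"
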