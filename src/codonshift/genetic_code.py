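"""Standard genetic-code constants shared across the package.

Everything downstream assumes one fixed codon ordering: the 61 sense codons
in alphabetical order (AAA ... TTT, stops excluded).  The tables are derived
from Biopython's standard codon table rather than typed by hand.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))  # TAA TAG TGA

#: the canonical 61-codon ordering used for every profile / CEC vector
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

ALL_CODONS: tuple[str, ...] = tuple(sorted(list(CODON_TO_AA) + list(STOP_CODONS)))

#: sense codons whose wobble (third) base is G or C / A or T
GC3_CODONS: tuple[str, ...] = tuple(c for c in SENSE_CODONS if c[2] in "GC")
AU3_CODONS: tuple[str, ...] = tuple(c for c in SENSE_CODONS if c[2] in "AT")

#: amino acid -> tuple of synonymous codons (alphabetical)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _aa = CODON_TO_AA[_codon]
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: degeneracy of each family
FAMILY_SIZES: dict[str, int] = {aa: len(cs) for aa, cs in SYNONYMOUS_FAMILIES.items()}

#: the 59 sense codons from degenerate families (Met and Trp excluded); the
#: per-amino-acid fraction of a single-codon family is identically 1, so those
#: two codons carry no correlation signal.
DEGENERATE_SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if FAMILY_SIZES[CODON_TO_AA[c]] > 1
)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(SYNONYMOUS_FAMILIES))

del _codon, _aa
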