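"""Codon-level sequence utilities shared across the pipeline."""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

CODONS = sorted(STANDARD_TABLE.forward_table) + sorted(STANDARD_TABLE.stop_codons)
STOP_CODONS = frozenset(STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)  # 61 codons

CODON_TO_AA = dict(STANDARD_TABLE.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(STANDARD_TABLE.forward_table.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def translate(dna: str) -> str:
    """Translate a DNA string codon-by-codon; trailing partial codon dropped.

    Internal stops appear as '*'; ambiguous codons (with N) as 'X'.
    """
    n = len(dna) - len(dna) % 3
    out = []
    for i in range(0, n, 3):
        codon = dna[i : i + 3]
        out.append(CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform synonymous codon choice."""
    codons = []
    for aa in protein:
        options = AA_TO_CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def is_transition(a: str, b: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine substitution."""
    purines = {"A", "G"}
    return (a in purines) == (b in purines)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))
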