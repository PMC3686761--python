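"""Standard genetic code tables for the 61-sense-codon state space.

Codon substitution models operate on the 61 sense codons of the standard
genetic code (the three stop codons TAA, TAG and TGA are excluded). This
module fixes the state ordering used throughout the package and precomputes
the structural quantities a Goldman-Yang style rate matrix needs: which
codon pairs differ at a single position, whether that change is a
transition or a transversion, and whether it is synonymous.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA, TAG, TGA

#: The 61 sense codons in lexicographic (A<C<G<T) order; this ordering is the
#: state index used by every rate matrix, partial likelihood and simulator.
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)

#: Amino acid encoded by each sense codon, aligned with SENSE_CODONS.
CODON_AA: tuple[str, ...] = tuple(
    standard_dna_table.forward_table[c] for c in SENSE_CODONS
)

_PURINES = {"A", "G"}

# IUPAC nucleotide ambiguity codes -> compatible unambiguous bases.
IUPAC_NUCLEOTIDES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"), "-": frozenset("ACGT"),
}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition (A<->G, C<->T)."""
    return a != b and (a in _PURINES) == (b in _PURINES)


def _single_difference_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays over codon pairs differing at exactly one position.

    Returns (pairs, transition_flag, synonymous_flag) where pairs is an
    (n, 2) array of state indices.
    """
    pairs, ts, syn = [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            pairs.append((i, j))
            ts.append(is_transition(*diffs[0]))
            syn.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.array(pairs, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


SINGLE_DIFF_PAIRS, SINGLE_DIFF_TRANSITION, SINGLE_DIFF_SYNONYMOUS = (
    _single_difference_tables()
)


def codon_state_vector(codon: str) -> np.ndarray:
    """Partial-likelihood leaf vector (length 61) for one observed codon.

    An unambiguous sense codon yields a one-hot vector. Gap characters and
    IUPAC ambiguity codes yield 1 at every compatible sense codon (missing
    data summed over states). A codon string that is compatible with no
    sense codon (e.g. an unambiguous stop) raises ValueError.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    vec = np.zeros(N_CODONS)
    idx = CODON_INDEX.get(codon)
    if idx is not None:
        vec[idx] = 1.0
        return vec
    try:
        sets = [IUPAC_NUCLEOTIDES[ch] for ch in codon]
    except KeyError as exc:
        raise ValueError(f"unknown nucleotide code in codon {codon!r}") from exc
    for c1 in sets[0]:
        for c2 in sets[1]:
            for c3 in sets[2]:
                j = CODON_INDEX.get(c1 + c2 + c3)
                if j is not None:
                    vec[j] = 1.0
    if not vec.any():
        raise ValueError(f"codon {codon!r} is compatible with no sense codon")
    return vec


def translate_codon(codon: str) -> str:
    """Amino acid for an unambiguous sense codon; '*' for a stop codon."""
    codon = codon.upper().replace("U", "T")
    if codon in STOP_CODONS:
        return "*"
    try:
        return standard_dna_table.forward_table[codon]
    except KeyError as exc:
        raise ValueError(f"cannot translate codon {codon!r}") from exc
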