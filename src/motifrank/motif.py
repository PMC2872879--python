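"""IUPAC consensus motif algebra.

Motifs are plain strings over the 11-symbol degenerate nucleotide alphabet
{A, C, G, T, W, S, R, Y, K, M, N} where W={A,T}, S={C,G}, R={A,G}, Y={C,T},
K={G,T}, M={A,C} and N matches any base.  A motif is considered present in a
sequence if an exact position-wise match occurs on either strand of a DNA
sequence, or on the forward strand only in RNA mode (e.g. when scanning
3' UTRs for miRNA target sites).

Matching semantics for ambiguous sequence bases: a sequence ``N`` (masked or
undetermined genomic base) is matched only by the motif symbol ``N``.  This
prevents masked stretches from spuriously joining the positive set of a
specific motif.  Input ``U`` is normalized to ``T``; lowercase (soft-masked)
bases are uppercased by default or optionally converted to ``N``.
"""

from __future__ import annotations

import itertools
from typing import Iterator, List, Set

IUPAC_SETS = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "W": "AT",
    "S": "CG",
    "R": "AG",
    "Y": "CT",
    "K": "GT",
    "M": "AC",
    "N": "ACGT",
}

DEGENERACY = {sym: len(bases) for sym, bases in IUPAC_SETS.items()}

#: IUPAC-aware complement (W and S are self-complementary).
_COMPLEMENT = str.maketrans("ACGTWSRYKMN", "TGCAWSYRMKN")

#: Motif lengths handled by the search space.
MIN_LENGTH = 5
MAX_LENGTH = 20

_SEQ_ALPHABET = frozenset("ACGTN")


def validate(motif: str, *, min_length: int = MIN_LENGTH, max_length: int = MAX_LENGTH) -> str:
    """Validate an IUPAC motif string; returns it unchanged.

    Raises ``ValueError`` naming the offending symbol and (1-based) position,
    or complaining about the length being outside ``[min_length, max_length]``.
    """
    for i, sym in enumerate(motif):
        if sym not in IUPAC_SETS:
            raise ValueError(
                f"unknown IUPAC symbol {sym!r} at position {i + 1} of motif {motif!r}"
            )
    if not min_length <= len(motif) <= max_length:
        raise ValueError(
            f"motif length {len(motif)} outside [{min_length}, {max_length}]: {motif!r}"
        )
    return motif


def reverse_complement(motif: str) -> str:
    """IUPAC-aware reverse complement (an involution)."""
    validate(motif, min_length=1, max_length=10**9)
    return motif.translate(_COMPLEMENT)[::-1]


def expand(motif: str) -> Set[str]:
    """All exact (non-degenerate) instantiations of the motif.

    Cardinality is the product of per-symbol degeneracies.
    """
    validate(motif, min_length=1, max_length=10**9)
    return {"".join(word) for word in itertools.product(*(IUPAC_SETS[s] for s in motif))}


def expansion_size(motif: str) -> int:
    """Number of exact instantiations, without materializing them."""
    n = 1
    for sym in motif:
        n *= DEGENERACY[sym]
    return n


def canonical_form(motif: str) -> str:
    """Lexicographically smaller of a motif and its reverse complement.

    Used to pool a motif with its reverse complement in double-stranded
    (DNA / transcription factor) mode; all 4^5 words collapse to 512
    canonical 5-mers.
    """
    rc = reverse_complement(motif)
    return motif if motif <= rc else rc


def normalize_sequence(seq: str, *, lowercase_to_n: bool = False) -> str:
    """Normalize a nucleotide sequence to the {A,C,G,T,N} alphabet.

    ``U`` becomes ``T``.  Soft-masked lowercase bases are uppercased, or
    converted to ``N`` when ``lowercase_to_n`` is set.  Any other ambiguity
    character collapses to ``N``.
    """
    if lowercase_to_n:
        seq = "".join("N" if c.islower() else c for c in seq)
    seq = seq.upper().replace("U", "T")
    if not _SEQ_ALPHABET.issuperset(seq):
        seq = "".join(c if c in _SEQ_ALPHABET else "N" for c in seq)
    return seq


def _window_match(motif: str, seq: str, start: int) -> bool:
    for j, sym in enumerate(motif):
        c = seq[start + j]
        if c == "N":
            if sym != "N":
                return False
        elif c not in IUPAC_SETS[sym]:
            return False
    return True


def _scan(motif: str, seq: str) -> Iterator[int]:
    w = len(motif)
    for i in range(len(seq) - w + 1):
        if _window_match(motif, seq, i):
            yield i


def matches(motif: str, seq: str, mode: str = "dna") -> bool:
    """True iff the motif occurs in the sequence.

    In ``dna`` mode the reverse complement of the motif is also tested
    against the forward text, which is equivalent to searching the reverse
    strand.  ``rna`` mode is forward-strand only.  An empty sequence simply
    yields ``False``.
    """
    _check_mode(mode)
    validate(motif, min_length=1, max_length=10**9)
    seq = normalize_sequence(seq)
    for _ in _scan(motif, seq):
        return True
    if mode == "dna":
        for _ in _scan(reverse_complement(motif), seq):
            return True
    return False


def find_occurrences(motif: str, seq: str, mode: str = "dna") -> List[tuple]:
    """All match windows as ``(offset, strand)`` pairs, 0-based.

    Reverse-strand hits (``dna`` mode only) are reported at the offset of the
    window on the forward text with strand ``-``.  A window matching both the
    motif and its reverse complement is reported once per strand.
    """
    _check_mode(mode)
    validate(motif, min_length=1, max_length=10**9)
    seq = normalize_sequence(seq)
    occ = [(i, "+") for i in _scan(motif, seq)]
    if mode == "dna":
        occ.extend((i, "-") for i in _scan(reverse_complement(motif), seq))
    occ.sort()
    return occ


def _check_mode(mode: str) -> None:
    if mode not in ("dna", "rna"):
        raise ValueError(f"mode must be 'dna' or 'rna', got {mode!r}")
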