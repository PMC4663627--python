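"""RNA sequence algebra and duplex geometry.

Everything downstream of the read loaders works on plain Python strings over
the RNA alphabet {A, C, G, U}, read 5'->3'.  A *duplex* here is the structure
p19 recognises: two equal-length strands paired antiparallel in a single
gapless register that leaves a fixed number of unpaired nucleotides at each
3' terminus (the Dicer-product geometry, 2 nt by default).  G:U wobble pairs
count as paired; every other non-Watson-Crick combination is a mismatch.
Positions are 1-based throughout, matching the convention used when miRNA
mismatch positions are reported (e.g. "positions 9-11").
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

RNA_ALPHABET = frozenset("ACGU")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: bases that form a stable (WC or wobble) pair with the key base
PAIRING_PARTNERS = {
    "A": frozenset("U"),
    "U": frozenset("AG"),
    "G": frozenset("CU"),
    "C": frozenset("G"),
}


class AlphabetError(ValueError):
    """A sequence contains a symbol outside {A, C, G, U}."""


class DuplexRegisterError(ValueError):
    """No gapless antiparallel register with the requested overhangs exists.

    Raised for unequal strand lengths or strands too short to leave the
    overhangs -- structurally impossible cases, distinct from a valid duplex
    that merely has many mismatches.
    """


class PairClass(str, Enum):
    """Classification of one opposed base pair in a duplex register."""

    WATSON_CRICK = "watson_crick"
    WOBBLE = "wobble"
    MISMATCH = "mismatch"


def validate_rna(seq: str) -> str:
    """Return ``seq`` unchanged if it is a valid non-empty RNA string.

    Raises :class:`AlphabetError` otherwise.  Transliteration (T->U,
    upper-casing) is an ingest concern and happens in :mod:`srnaduplex.sra_io`;
    by the time sequences reach this module they must be clean.
    """
    if not seq:
        raise AlphabetError("empty sequence")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise AlphabetError(f"invalid RNA symbol(s) {sorted(bad)} in {seq!r}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, returned 5'->3'."""
    validate_rna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def pair_class(base_a: str, base_b: str) -> PairClass:
    """Classify an opposed base pair; symmetric in its arguments."""
    if base_a not in RNA_ALPHABET or base_b not in RNA_ALPHABET:
        raise AlphabetError(f"invalid base pair ({base_a!r}, {base_b!r})")
    pair = base_a + base_b
    if pair in ("AU", "UA", "GC", "CG"):
        return PairClass.WATSON_CRICK
    if pair in ("GU", "UG"):
        return PairClass.WOBBLE
    return PairClass.MISMATCH


@dataclass(frozen=True)
class Duplex:
    """An antiparallel gapless pairing of two equal-length strands.

    Strand-a position ``i`` (1-based) pairs strand-b position
    ``L - overhang + 1 - i`` for ``i`` in ``1..L-overhang``; the last
    ``overhang`` nucleotides of each strand are its unpaired 3' overhang.
    ``pair_classes[i-1]`` classifies the pair at strand-a position ``i``.
    """

    strand_a: str
    strand_b: str
    overhang: int
    pair_classes: tuple[PairClass, ...]
    mismatch_positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.strand_a)

    @property
    def paired_length(self) -> int:
        return self.length - self.overhang

    @property
    def mismatch_count(self) -> int:
        return len(self.mismatch_positions)


def assemble_duplex(strand_a: str, strand_b: str, overhang: int = 2) -> Duplex:
    """Build the unique duplex register with ``overhang`` nt at each 3' end.

    Both strands are read 5'->3'.  Overhang bases are never scored; wobble
    pairs count as paired.  Raises :class:`DuplexRegisterError` when the
    strands differ in length or are too short (``L <= 2*overhang``) for the
    register to exist -- cases structurally distinct from a low-quality but
    valid duplex.
    """
    validate_rna(strand_a)
    validate_rna(strand_b)
    if overhang < 0:
        raise ValueError("overhang must be >= 0")
    L = len(strand_a)
    if len(strand_b) != L:
        raise DuplexRegisterError(
            f"strand lengths differ ({L} vs {len(strand_b)}): no gapless "
            "register with equal 3' overhangs exists"
        )
    if L <= 2 * overhang:
        raise DuplexRegisterError(
            f"length {L} <= 2*overhang ({2 * overhang}): no paired region"
        )
    classes = []
    mismatches = []
    for i in range(1, L - overhang + 1):
        j = L - overhang + 1 - i  # partner position on strand b
        cls = pair_class(strand_a[i - 1], strand_b[j - 1])
        classes.append(cls)
        if cls is PairClass.MISMATCH:
            mismatches.append(i)
    return Duplex(
        strand_a=strand_a,
        strand_b=strand_b,
        overhang=overhang,
        pair_classes=tuple(classes),
        mismatch_positions=tuple(mismatches),
    )


def try_assemble_duplex(strand_a: str, strand_b: str, overhang: int = 2) -> Duplex | None:
    """Like :func:`assemble_duplex` but returns None when no register exists."""
    try:
        return assemble_duplex(strand_a, strand_b, overhang)
    except DuplexRegisterError:
        return None
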