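"""Reference cleaning and pre-miRNA hairpin support.

Candidate miRNA/miRNA* pairs gain biological plausibility when both reads
derive from one transcribed locus and sit on opposite arms of a hairpin
stem, the way Dicer products do.  This module provides the two reference
steps around the duplex scan: exact-match read cleaning against genome
contigs, and a structural test that locates both reads of a call in a
common contig, folds the spanned region, and asks whether the reads pair
with each other in the predicted structure.

Folding is base-pair maximisation (Nussinov-style, wobble-aware) with a
deterministic traceback; a thermodynamic fold computed externally can be
substituted as a dot-bracket string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .duplex_scan import DuplexCall
from .seq_core import PAIRING_PARTNERS, reverse_complement, validate_rna
from .sra_io import CountTable, _clean_sequence


@dataclass(frozen=True)
class Contig:
    """A reference contig, stored transliterated to the RNA alphabet."""

    name: str
    seq: str


def load_contigs(path: str | Path) -> list[Contig]:
    """Load reference contigs from FASTA (DNA or RNA alphabet)."""
    contigs = []
    names = set()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(record.seq))
        if seq is None:
            raise ValueError(f"contig {record.id!r} contains ambiguity codes")
        if record.id in names:
            raise ValueError(f"duplicate contig name {record.id!r}")
        names.add(record.id)
        contigs.append(Contig(record.id, seq))
    return contigs


def write_contigs(contigs: list[Contig], path: str | Path) -> None:
    """Write contigs as DNA-alphabet FASTA (U -> T), the genomic convention."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.name}\n{c.seq.replace('U', 'T')}\n")


def filter_by_reference(table: CountTable, contigs: list[Contig]) -> CountTable:
    """Keep reads occurring exactly (either orientation) in some contig.

    This is the error-cleaning step: a sequencing error makes a read absent
    from the genome, so exact substring matching against the contigs removes
    it.  Counts of retained species are unchanged.
    """
    if not contigs:
        raise ValueError("reference contig set is empty")
    keep = set()
    for read in table:
        rc = reverse_complement(read.seq)
        for contig in contigs:
            if read.seq in contig.seq or rc in contig.seq:
                keep.add(read.seq)
                break
    return table.subset(keep)


def locate_read(seq: str, contig: Contig) -> list[tuple[int, str]]:
    """All exact occurrences of ``seq`` in a contig as (1-based start, strand).

    Plus-strand hits match the read itself; minus-strand hits match its
    reverse complement.  Overlapping occurrences are all reported, ascending.
    """
    validate_rna(seq)
    hits = []
    for strand, probe in (("+", seq), ("-", reverse_complement(seq))):
        start = contig.seq.find(probe)
        while start != -1:
            hits.append((start + 1, strand))
            start = contig.seq.find(probe, start + 1)
    hits.sort()
    return hits


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested secondary structure in dot-bracket form with its pair table."""

    dotbracket: str
    pair_table: dict[int, int]  # 1-based position -> partner (absent if unpaired)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_table) // 2

    @classmethod
    def from_dotbracket(cls, db: str) -> "SecondaryStructure":
        stack = []
        table: dict[int, int] = {}
        for pos, ch in enumerate(db, start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise ValueError("unbalanced dot-bracket string")
                i = stack.pop()
                table[i] = pos
                table[pos] = i
            elif ch != ".":
                raise ValueError(f"invalid dot-bracket symbol {ch!r}")
        if stack:
            raise ValueError("unbalanced dot-bracket string")
        return cls(db, table)


def _can_pair(a: str, b: str) -> bool:
    return b in PAIRING_PARTNERS[a]


def nussinov_fold(seq: str, min_loop: int = 3) -> SecondaryStructure:
    """Maximum base-pairing nested structure (WC + wobble), deterministic.

    Dynamic programme over intervals with a traceback that, on ties, pairs
    the 5'-most base with its 5'-most compatible partner.  ``min_loop`` is
    the minimum number of unpaired bases enclosed by any pair.
    """
    validate_rna(seq)
    n = len(seq)
    # N[i][j] = max pairs in seq[i..j], 0-based inclusive
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(seq[i], seq[k]):
                    inner = N[i + 1][k - 1] if k - 1 > i else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + inner + right
                    if cand > best:
                        best = cand
            N[i][j] = best
    db = ["."] * n
    table: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = N[i][j]
        # prefer pairing the 5'-most base; among partners take the 5'-most
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(seq[i], seq[k]):
                inner = N[i + 1][k - 1] if k - 1 > i else 0
                right = N[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + right == target:
                    db[i], db[k] = "(", ")"
                    table[i + 1] = k + 1
                    table[k + 1] = i + 1
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return SecondaryStructure("".join(db), table)


@dataclass(frozen=True)
class HairpinSupport:
    """Audit record of the hairpin-stem test for one duplex call."""

    supported: bool
    contig: str | None = None
    strand: str | None = None
    interval_a: tuple[int, int] | None = None  # 1-based closed, contig coords
    interval_b: tuple[int, int] | None = None
    structure: SecondaryStructure | None = None
    paired_fraction_a: float = 0.0
    paired_fraction_b: float = 0.0
    cross_pair_fraction_a: float = 0.0
    cross_pair_fraction_b: float = 0.0
    reason: str = ""


def _arm_fractions(
    structure: SecondaryStructure,
    own: tuple[int, int],
    other: tuple[int, int],
) -> tuple[float, float]:
    """(fraction of own bases paired, fraction of those pairing into other).

    Intervals are 1-based closed in the folded region's coordinates.
    """
    lo, hi = own
    olo, ohi = other
    n = hi - lo + 1
    paired = cross = 0
    for pos in range(lo, hi + 1):
        partner = structure.pair_table.get(pos)
        if partner is not None:
            paired += 1
            if olo <= partner <= ohi:
                cross += 1
    if paired == 0:
        return 0.0, 0.0
    return paired / n, cross / paired


def hairpin_support(
    call: DuplexCall,
    contigs: list[Contig],
    window: int = 300,
    min_paired_fraction: float = 0.6,
    min_cross_fraction: float = 0.5,
    structures: dict[str, SecondaryStructure] | None = None,
    flank: int = 10,
) -> HairpinSupport:
    """Test whether a duplex call maps to opposite arms of one hairpin stem.

    The call is supported when some contig carries both reads on the same
    strand within ``window`` nt, and in the folded region spanning both reads
    (plus ``flank`` nt on each side) each read has at least
    ``min_paired_fraction`` of its bases paired, with at least
    ``min_cross_fraction`` of those partners inside the other read's
    interval.  ``structures`` optionally supplies externally computed
    dot-bracket folds keyed by contig name (full-contig coordinates, plus
    strand); contigs named there must exist in the reference.
    """
    if structures:
        known = {c.name for c in contigs}
        missing = set(structures) - known
        if missing:
            raise KeyError(f"external structures name unknown contig(s): {sorted(missing)}")
    best: HairpinSupport | None = None
    for contig in contigs:
        hits_a = locate_read(call.read_a.seq, contig)
        hits_b = locate_read(call.read_b.seq, contig)
        for start_a, strand_a in hits_a:
            for start_b, strand_b in hits_b:
                if strand_a != strand_b:
                    continue
                end_a = start_a + len(call.read_a.seq) - 1
                end_b = start_b + len(call.read_b.seq) - 1
                gap = max(start_a, start_b) - min(end_a, end_b)
                if gap > window:
                    continue
                result = _evaluate_placement(
                    call, contig, strand_a,
                    (start_a, end_a), (start_b, end_b),
                    min_paired_fraction, min_cross_fraction,
                    structures, flank,
                )
                if result.supported:
                    return result
                if best is None:
                    best = result
    if best is not None:
        return best
    return HairpinSupport(supported=False, reason="reads not co-located in any contig")


def _evaluate_placement(
    call: DuplexCall,
    contig: Contig,
    strand: str,
    iv_a: tuple[int, int],
    iv_b: tuple[int, int],
    min_paired_fraction: float,
    min_cross_fraction: float,
    structures: dict[str, SecondaryStructure] | None,
    flank: int,
) -> HairpinSupport:
    if structures and contig.name in structures:
        structure = structures[contig.name]
        if len(structure.dotbracket) != len(contig.seq):
            raise ValueError(
                f"external structure for {contig.name!r} has wrong length"
            )
        # full-contig coordinates; external structures describe the + strand
        local_a, local_b, folded = iv_a, iv_b, structure
    else:
        lo = max(1, min(iv_a[0], iv_b[0]) - flank)
        hi = min(len(contig.seq), max(iv_a[1], iv_b[1]) + flank)
        region = contig.seq[lo - 1 : hi]
        if strand == "-":
            region = reverse_complement(region)
            # position p (contig) -> hi - p + 1 in the reversed region
            local_a = (hi - iv_a[1] + 1, hi - iv_a[0] + 1)
            local_b = (hi - iv_b[1] + 1, hi - iv_b[0] + 1)
        else:
            local_a = (iv_a[0] - lo + 1, iv_a[1] - lo + 1)
            local_b = (iv_b[0] - lo + 1, iv_b[1] - lo + 1)
        folded = nussinov_fold(region)
    frac_a, cross_a = _arm_fractions(folded, local_a, local_b)
    frac_b, cross_b = _arm_fractions(folded, local_b, local_a)
    ok = (
        frac_a >= min_paired_fraction
        and frac_b >= min_paired_fraction
        and cross_a >= min_cross_fraction
        and cross_b >= min_cross_fraction
    )
    return HairpinSupport(
        supported=ok,
        contig=contig.name,
        strand=strand,
        interval_a=iv_a,
        interval_b=iv_b,
        structure=folded,
        paired_fraction_a=frac_a,
        paired_fraction_b=frac_b,
        cross_pair_fraction_a=cross_a,
        cross_pair_fraction_b=cross_b,
        reason="" if ok else "stem criteria not met",
    )


def load_structures(path: str | Path) -> dict[str, SecondaryStructure]:
    """Load external folds: blocks of ``>name`` / sequence / dot-bracket lines."""
    structures: dict[str, SecondaryStructure] = {}
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>name' at line {i + 1}")
        name = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated block for {name!r}")
        seq, db = lines[i + 1], lines[i + 2]
        if len(seq) != len(db):
            raise ValueError(f"{path}: sequence/structure length mismatch for {name!r}")
        structures[name] = SecondaryStructure.from_dotbracket(db)
        i += 3
    return structures
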