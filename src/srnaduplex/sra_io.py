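"""Reading and collapsing small-RNA libraries.

Sequencing reads arrive as FASTA or FASTQ (optionally gzipped), in DNA or RNA
alphabet.  Loading upper-cases, transliterates T->U, drops reads outside the
length window or containing ambiguity codes, and collapses identical
sequences into a count table -- the "read count (weight)" representation in
which one row is one distinct sRNA species.  Collapsed FASTA headers of the
form ``name_xN`` are honoured as pre-summed counts.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .seq_core import RNA_ALPHABET, validate_rna

DEFAULT_LENGTH_RANGE = (18, 30)


@dataclass(frozen=True)
class CollapsedRead:
    """One distinct sRNA species with its read count (weight)."""

    seq: str
    count: int

    def __post_init__(self):
        validate_rna(self.seq)
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass
class LoadStats:
    """Bookkeeping from one load: accepted read units and what was dropped."""

    accepted_records: int = 0
    dropped_length: int = 0
    dropped_alphabet: int = 0


class CountTable:
    """Collapsed read table: distinct sequence -> read count.

    ``total_reads`` is the sum of counts; ``total_species`` the number of
    distinct sequences.  Iteration yields :class:`CollapsedRead` in canonical
    order (descending count, then lexicographic sequence) so that serialised
    outputs are byte-reproducible.
    """

    def __init__(self, counts: dict[str, int] | None = None):
        self._counts: dict[str, int] = {}
        if counts:
            for seq, n in counts.items():
                self.add(seq, n)
        self.stats: LoadStats | None = None

    def add(self, seq: str, count: int = 1) -> None:
        validate_rna(seq)
        if count < 1:
            raise ValueError("count must be >= 1")
        self._counts[seq] = self._counts.get(seq, 0) + count

    def count(self, seq: str) -> int:
        return self._counts.get(seq, 0)

    def __contains__(self, seq: str) -> bool:
        return seq in self._counts

    def __len__(self) -> int:
        return len(self._counts)

    def __iter__(self) -> Iterator[CollapsedRead]:
        for seq, n in sorted(self._counts.items(), key=lambda kv: (-kv[1], kv[0])):
            yield CollapsedRead(seq, n)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self._counts == other._counts

    @property
    def total_reads(self) -> int:
        return sum(self._counts.values())

    @property
    def total_species(self) -> int:
        return len(self._counts)

    def counts(self) -> dict[str, int]:
        """A copy of the underlying sequence -> count mapping."""
        return dict(self._counts)

    def subset(self, keep: Iterable[str]) -> "CountTable":
        keep = set(keep)
        return CountTable({s: n for s, n in self._counts.items() if s in keep})


def _clean_sequence(raw: str) -> str | None:
    """Upper-case and transliterate to RNA; None if ambiguity codes remain."""
    seq = raw.upper().replace("T", "U")
    if set(seq) <= RNA_ALPHABET and seq:
        return seq
    return None


def _header_count(record_id: str) -> int:
    """Collapsed-FASTA count suffix ``name_xN``; 1 when absent."""
    stem, sep, tail = record_id.rpartition("_x")
    if sep and stem and tail.isdigit():
        return int(tail)
    return 1


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _infer_format(path: str | Path) -> str:
    name = Path(path).name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def load_reads(
    path: str | Path,
    fmt: str | None = None,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> CountTable:
    """Load and collapse an sRNA library from FASTA/FASTQ.

    Reads outside ``length_range`` (inclusive bounds, in nt) or containing
    symbols other than A/C/G/U/T are dropped and tallied in ``table.stats``.
    FASTQ qualities are ignored.  An empty file yields an empty table.
    """
    fmt = fmt or _infer_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    lo, hi = length_range
    table = CountTable()
    stats = LoadStats()
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, fmt):
            n = _header_count(record.id) if fmt == "fasta" else 1
            seq = _clean_sequence(str(record.seq))
            if seq is None:
                stats.dropped_alphabet += n
                continue
            if not (lo <= len(seq) <= hi):
                stats.dropped_length += n
                continue
            stats.accepted_records += n
            table.add(seq, n)
    table.stats = stats
    return table


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a TSV count table (``sequence\\tcount``) in canonical order."""
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for read in table:
            fh.write(f"{read.seq}\t{read.count}\n")


def read_count_table(path: str | Path) -> CountTable:
    """Load a TSV written by :func:`write_count_table`."""
    table = CountTable()
    with open(path) as fh:
        header = fh.readline()
        if header and header.rstrip("\n").split("\t")[:2] != ["sequence", "count"]:
            raise ValueError(f"{path}: not a count-table TSV (bad header)")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                seq, count = line.split("\t")
                table.add(seq, int(count))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
    table.stats = LoadStats(accepted_records=table.total_reads)
    return table


def write_collapsed_fasta(table: CountTable, path: str | Path, prefix: str = "sp") -> None:
    """Write the table as collapsed FASTA with ``>prefixN_xCOUNT`` headers."""
    with open(path, "w") as fh:
        for i, read in enumerate(table, start=1):
            fh.write(f">{prefix}{i}_x{read.count}\n{read.seq}\n")
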