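"""Duplex-pair discovery in a collapsed read table.

A pair of sRNA species is called a duplex when it satisfies four criteria:
(1) both read counts strictly exceed a threshold (default 30);
(2) the two strands form a gapless antiparallel register with 2-nt 3'
    overhangs on both termini;
(3) the register contains at most 3 mismatched pairings;
(4) G:U wobble pairs count as paired, not mismatched.

Two search strategies produce identical output.  ``brute`` tests every
unordered pair of equal-length species and is the reference oracle.
``seeded`` exploits the fact that every stable pair (Watson-Crick or wobble)
joins a purine to a pyrimidine: collapsing each strand to its R/Y pattern,
a partner with at most m mismatches must agree with the expected partner
pattern everywhere except at mismatch positions, so by pigeonhole at least
one of m+1 contiguous blocks of the expected pattern matches exactly and
candidates can be harvested from hash lookups, then verified exactly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .seq_core import Duplex, PURINES, try_assemble_duplex
from .sra_io import CollapsedRead, CountTable


@dataclass(frozen=True)
class ScanParams:
    """Tunables of the four-criterion duplex scan."""

    min_count_exclusive: int = 30
    overhang: int = 2
    max_mismatches: int = 3
    allow_self_pairs: bool = True
    strategy: str = "seeded"

    def __post_init__(self):
        if self.min_count_exclusive < 0 or self.max_mismatches < 0 or self.overhang < 0:
            raise ValueError("scan parameters must be non-negative")
        if self.strategy not in ("brute", "seeded"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass(frozen=True)
class DuplexCall:
    """An accepted duplex pair, canonically ordered (seq_a <= seq_b)."""

    read_a: CollapsedRead
    read_b: CollapsedRead
    duplex: Duplex

    @property
    def mismatches(self) -> int:
        return self.duplex.mismatch_count

    @property
    def self_pair(self) -> bool:
        return self.read_a.seq == self.read_b.seq

    @property
    def key(self) -> tuple[str, str]:
        return (self.read_a.seq, self.read_b.seq)


def filter_by_count(table: CountTable, min_count_exclusive: int) -> CountTable:
    """Keep species with count strictly greater than the threshold."""
    return CountTable(
        {s: n for s, n in table.counts().items() if n > min_count_exclusive}
    )


def _ry(seq: str) -> str:
    return "".join("R" if b in PURINES else "Y" for b in seq)


_FLIP = str.maketrans("RY", "YR")


def _blocks(length: int, k: int) -> list[tuple[int, int]]:
    """Split [0, length) into k near-equal contiguous half-open blocks."""
    k = min(k, length)
    bounds = [round(i * length / k) for i in range(k + 1)]
    return [(bounds[i], bounds[i + 1]) for i in range(k) if bounds[i] < bounds[i + 1]]


def _make_call(a: CollapsedRead, b: CollapsedRead, duplex_ab: Duplex, overhang: int) -> DuplexCall:
    if a.seq <= b.seq:
        return DuplexCall(a, b, duplex_ab)
    # reassemble in canonical orientation; mismatch count is symmetric
    return DuplexCall(b, a, try_assemble_duplex(b.seq, a.seq, overhang))


def _scan_brute(reads: list[CollapsedRead], params: ScanParams) -> list[DuplexCall]:
    calls = []
    for i, a in enumerate(reads):
        start = i if params.allow_self_pairs else i + 1
        for b in reads[start:]:
            dup = try_assemble_duplex(a.seq, b.seq, params.overhang)
            if dup is not None and dup.mismatch_count <= params.max_mismatches:
                calls.append(_make_call(a, b, dup, params.overhang))
    return calls


def _scan_seeded(reads: list[CollapsedRead], params: ScanParams) -> list[DuplexCall]:
    by_len: dict[int, list[CollapsedRead]] = defaultdict(list)
    for r in reads:
        by_len[len(r.seq)].append(r)

    calls: dict[tuple[str, str], DuplexCall] = {}
    for L, group in by_len.items():
        P = L - params.overhang  # paired-region length
        if P <= params.overhang:
            continue
        blocks = _blocks(P, params.max_mismatches + 1)
        # index each read by the R/Y pattern of its own paired region
        index: dict[tuple[int, str], list[int]] = defaultdict(list)
        own = [_ry(r.seq[:P]) for r in group]
        for ri, pat in enumerate(own):
            for bi, (s, e) in enumerate(blocks):
                index[(bi, pat[s:e])].append(ri)
        for ri, r in enumerate(group):
            # a valid partner's own pattern equals the reversed, R/Y-flipped
            # pattern of this read's paired region, except at mismatches
            expected = own[ri].translate(_FLIP)[::-1]
            seen: set[int] = set()
            for bi, (s, e) in enumerate(blocks):
                for ci in index.get((bi, expected[s:e]), ()):
                    if ci in seen or ci < ri:
                        continue  # unordered pairs: visit each once
                    seen.add(ci)
                    c = group[ci]
                    if ci == ri and not params.allow_self_pairs:
                        continue
                    dup = try_assemble_duplex(r.seq, c.seq, params.overhang)
                    if dup is not None and dup.mismatch_count <= params.max_mismatches:
                        call = _make_call(r, c, dup, params.overhang)
                        calls[call.key] = call
    return list(calls.values())


def find_duplex_pairs(table: CountTable, params: ScanParams | None = None) -> list[DuplexCall]:
    """All unordered duplex pairs passing the four criteria, in canonical order.

    The count filter is applied internally (idempotent on a pre-filtered
    table).  One species may participate in several calls; a near-palindromic
    species may pair with itself when ``allow_self_pairs`` is set.
    """
    params = params or ScanParams()
    filtered = filter_by_count(table, params.min_count_exclusive)
    reads = sorted(filtered, key=lambda r: r.seq)
    if params.strategy == "brute":
        calls = _scan_brute(reads, params)
    else:
        calls = _scan_seeded(reads, params)
    # canonical, deduplicated output ordering
    uniq = {c.key: c for c in calls}
    return [uniq[k] for k in sorted(uniq)]


def write_calls(calls: list[DuplexCall], path) -> None:
    """Write a call list as the scan's TSV dialect."""
    cols = "seq_a\tcount_a\tseq_b\tcount_b\tmismatches\tmismatch_positions\tself_pair\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for c in calls:
            pos = ",".join(map(str, c.duplex.mismatch_positions))
            fh.write(
                f"{c.read_a.seq}\t{c.read_a.count}\t{c.read_b.seq}\t"
                f"{c.read_b.count}\t{c.mismatches}\t{pos}\t{int(c.self_pair)}\n"
            )
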