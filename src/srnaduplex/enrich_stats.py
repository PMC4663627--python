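"""Library-level descriptive statistics and input-vs-eluted comparison.

Read-count spectra are binned by powers of two (a species with count c falls
in bin k iff 2^k <= c <= 2^(k+1)-1) and normalised by the number of distinct
species, so "fraction of species sequenced once" and "fraction with count
>= 16" drop straight out of the spectrum.  Relative abundance expresses
species counts (or qPCR amounts) as percent of a chosen reference species.
The comparison report summarises how a capture step shifts the spectrum and
the duplex fraction (duplex calls per distinct species).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .duplex_scan import DuplexCall
from .sra_io import CountTable


@dataclass(frozen=True)
class CountSpectrum:
    """Power-of-two read-count spectrum of a collapsed library."""

    bins: tuple[tuple[int, int, float], ...]  # (low, high, species fraction)
    total_species: int
    fraction_singletons: float
    fraction_ge16: float

    def fraction_ge(self, cutoff: int) -> float:
        """Fraction of species with count >= cutoff (cutoff a power of 2)."""
        return sum(f for lo, hi, f in self.bins if lo >= cutoff)


def bin_counts_pow2(table: CountTable) -> CountSpectrum:
    """Bin species counts by powers of two, normalised by distinct species."""
    if table.total_species == 0:
        return CountSpectrum((), 0, float("nan"), float("nan"))
    tallies: dict[int, int] = {}
    singletons = ge16 = 0
    for read in table:
        k = read.count.bit_length() - 1  # 2^k <= count <= 2^(k+1)-1
        tallies[k] = tallies.get(k, 0) + 1
        if read.count == 1:
            singletons += 1
        if read.count >= 16:
            ge16 += 1
    n = table.total_species
    bins = tuple(
        (2**k, 2 ** (k + 1) - 1, tallies[k] / n) for k in sorted(tallies)
    )
    return CountSpectrum(bins, n, singletons / n, ge16 / n)


@dataclass(frozen=True)
class AbundanceReport:
    """Quantities as percent of a reference species (reference = 100%)."""

    reference_name: str
    percent: dict[str, float]


def relative_abundance(values: dict[str, float], reference: str) -> AbundanceReport:
    """Express each quantity as 100 * value / value(reference)."""
    if reference not in values:
        raise KeyError(f"reference {reference!r} not present")
    ref = values[reference]
    if not ref > 0:
        raise ValueError("reference quantity must be positive")
    return AbundanceReport(
        reference,
        {name: 100.0 * v / ref for name, v in values.items()},
    )


@dataclass(frozen=True)
class LibraryComparison:
    """Input-vs-eluted summary: spectra, call counts and duplex fractions."""

    spectrum_input: CountSpectrum
    spectrum_eluted: CountSpectrum
    n_calls_input: int
    n_calls_eluted: int
    distinct_in_calls_input: int
    distinct_in_calls_eluted: int
    duplex_fraction_input: float  # calls / total species
    duplex_fraction_eluted: float
    enrichment_ratio: float  # eluted fraction / input fraction; inf/nan flagged

    @property
    def ratio_defined(self) -> bool:
        return math.isfinite(self.enrichment_ratio)


def _duplex_fraction(n_calls: int, n_species: int) -> float:
    return n_calls / n_species if n_species else float("nan")


def compare_libraries(
    input_table: CountTable,
    eluted_table: CountTable,
    calls_input: list[DuplexCall],
    calls_eluted: list[DuplexCall],
) -> LibraryComparison:
    """Summarise the effect of the capture step on duplex content.

    The enrichment ratio is (eluted duplex fraction) / (input duplex
    fraction); it is flagged infinite when the input fraction is zero but the
    eluted one is not, and NaN when either library is empty or both fractions
    are zero.
    """
    fi = _duplex_fraction(len(calls_input), input_table.total_species)
    fe = _duplex_fraction(len(calls_eluted), eluted_table.total_species)
    if math.isnan(fi) or math.isnan(fe):
        ratio = float("nan")
    elif fi == 0:
        ratio = float("inf") if fe > 0 else float("nan")
    else:
        ratio = fe / fi

    def distinct(calls: list[DuplexCall]) -> int:
        seqs = set()
        for c in calls:
            seqs.add(c.read_a.seq)
            seqs.add(c.read_b.seq)
        return len(seqs)

    return LibraryComparison(
        spectrum_input=bin_counts_pow2(input_table),
        spectrum_eluted=bin_counts_pow2(eluted_table),
        n_calls_input=len(calls_input),
        n_calls_eluted=len(calls_eluted),
        distinct_in_calls_input=distinct(calls_input),
        distinct_in_calls_eluted=distinct(calls_eluted),
        duplex_fraction_input=fi,
        duplex_fraction_eluted=fe,
        enrichment_ratio=ratio,
    )
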