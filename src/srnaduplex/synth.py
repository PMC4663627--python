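"""Synthetic sRNA libraries with planted miRNA/miRNA* duplexes and p19 capture.

The generator inverts the discovery problem: it writes pre-miRNA hairpins
(5' arm + loop + 3' arm, the arms complementary up to a chosen number of
mismatches) into random-background contigs, samples a collapsed input
library around them, and then simulates the protein-capture step that
enriches duplexes.

The input library emulates a real collapsed sRNA sequencing run: a heavy
singleton background (~80% of distinct species seen once), planted guide
strands at counts above the scan threshold, and star strands surviving at
only a few percent of their guides (strand-asymmetric degradation in vivo).
Capture acts at the duplex level -- the protein binds the paired duplex, so
guide and star copies are retained together up to the pairing minimum of
their counts -- with Langmuir occupancy C / (C + K_d(class)) at an effective
protein concentration, where the K_d ladder by duplex class comes from the
measured affinities of synthesized duplex variants (perfect duplex 16 nM,
central mismatches 55 nM, terminal mismatches 227 and 1138 nM).  Everything
else (unpaired leftovers, single strands, background) is retained only with
a small nonspecific probability.

All randomness flows from numpy generators seeded from ``SimParams.seed``;
identical parameters give byte-identical libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .hairpin_map import Contig
from .seq_core import (
    PAIRING_PARTNERS,
    RNA_ALPHABET,
    reverse_complement,
    try_assemble_duplex,
)
from .sra_io import CountTable

_BASES = "ACGU"


@dataclass(frozen=True)
class CaptureParams:
    """Langmuir-occupancy capture model of the protein sequestration step."""

    p19_concentration_nM: float = 100.0
    #: dissociation constant (nM) by duplex class = planted mismatch count
    kd_by_class: dict[int, float] = field(
        default_factory=lambda: {0: 16.0, 1: 55.0, 2: 227.0, 3: 1138.0}
    )
    nonspecific_capture_prob: float = 0.01


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one simulated input/eluted library pair."""

    seed: int
    n_hairpins: int = 5
    arm_length: int = 21
    overhang: int = 2
    mismatch_spectrum: dict[int, float] = field(
        default_factory=lambda: {0: 0.5, 1: 0.3, 2: 0.2}
    )
    loop_length: tuple[int, int] = (8, 15)
    contig_length: int = 400
    n_background: int = 1000
    background_singleton_fraction: float = 0.8
    star_survival: float = 0.05
    planted_count_range: tuple[int, int] = (31, 500)
    capture: CaptureParams = field(default_factory=CaptureParams)

    def __post_init__(self):
        if self.arm_length <= 4:
            raise ValueError("arm_length must exceed 4")
        for p in (self.background_singleton_fraction, self.star_survival):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(p < 0 for p in self.mismatch_spectrum.values()):
            raise ValueError("mismatch spectrum weights must be non-negative")

    @classmethod
    def scan_benchmark(cls, seed: int, **overrides) -> "SimParams":
        """Conditions for duplex-recall benchmarking: both strands abundant.

        Mirrors a perfusion of synthesized duplex where guide and star are
        present in comparable amounts, so every planted pair is eligible
        under the count criterion and recall of the scan itself is measured,
        not the upstream degradation.
        """
        overrides.setdefault("star_survival", 1.0)
        return cls(seed=seed, **overrides)


@dataclass
class TruthRecord:
    """Ground truth for one planted hairpin, filled in as stages run."""

    hairpin_id: str
    contig: str
    mirna: str
    star: str
    mismatch_count: int
    mirna_start: int  # 1-based closed, + strand
    mirna_end: int
    star_start: int
    star_end: int
    input_count_mirna: int = 0
    input_count_star: int = 0
    eluted_count_mirna: int = 0
    eluted_count_star: int = 0


@dataclass(frozen=True)
class SimResult:
    contigs: tuple[Contig, ...]
    truths: tuple[TruthRecord, ...]
    input_table: CountTable
    eluted_table: CountTable


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    # independent streams per stage so each stage is reproducible in isolation
    return np.random.default_rng([seed, stage])


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _sample_mismatch_count(rng: np.random.Generator, spectrum: dict[int, float]) -> int:
    ks = sorted(spectrum)
    w = np.array([spectrum[k] for k in ks], dtype=float)
    return int(rng.choice(ks, p=w / w.sum()))


def generate_premirna_set(params: SimParams) -> tuple[list[Contig], list[TruthRecord]]:
    """Plant ``n_hairpins`` pre-miRNA hairpins into random contigs.

    Each hairpin is 5'arm + loop + star read, where the star's first
    ``arm_length - overhang`` nt are the reverse complement of the arm's
    first ``arm_length - overhang`` nt with the drawn number of mismatch
    substitutions injected, followed by ``overhang`` random 3' nt.  By
    construction arm and star assemble into a duplex with the recorded
    mismatch count and 2-nt 3' overhangs, and both occur on the + strand of
    their contig.  Deterministic given the seed.
    """
    rng = _stage_rng(params.seed, 0)
    L, o = params.arm_length, params.overhang
    P = L - o
    contigs: list[Contig] = []
    truths: list[TruthRecord] = []
    for h in range(params.n_hairpins):
        arm = _random_rna(rng, L)
        m = _sample_mismatch_count(rng, params.mismatch_spectrum)
        star_core = list(reverse_complement(arm[:P]))
        positions = sorted(rng.choice(np.arange(1, P + 1), size=m, replace=False))
        for i in positions:  # strand-a position i pairs star position P+1-i
            j = P + 1 - int(i)
            options = sorted(RNA_ALPHABET - PAIRING_PARTNERS[arm[i - 1]])
            star_core[j - 1] = str(rng.choice(options))
        star = "".join(star_core) + _random_rna(rng, o)
        loop = _random_rna(rng, int(rng.integers(params.loop_length[0], params.loop_length[1] + 1)))
        hairpin = arm + loop + star
        if params.contig_length < len(hairpin) + 20:
            raise ValueError("contig_length too small for a hairpin plus margins")
        background = _random_rna(rng, params.contig_length)
        at = int(rng.integers(10, params.contig_length - len(hairpin) - 10 + 1))
        contig_seq = background[:at] + hairpin + background[at + len(hairpin):]
        name = f"contig{h + 1}"
        contigs.append(Contig(name, contig_seq))
        mirna_start = at + 1
        star_start = at + L + len(loop) + 1
        truths.append(
            TruthRecord(
                hairpin_id=f"hp{h + 1}",
                contig=name,
                mirna=arm,
                star=star,
                mismatch_count=m,
                mirna_start=mirna_start,
                mirna_end=mirna_start + L - 1,
                star_start=star_start,
                star_end=star_start + L - 1,
            )
        )
    return contigs, truths


def _background_count(rng: np.random.Generator, singleton_fraction: float) -> int:
    if rng.random() < singleton_fraction:
        return 1
    # heavy-tailed non-singleton counts: a few species are very abundant,
    # as in real collapsed libraries
    return int(min(rng.zipf(1.6), 4999)) + 1


def generate_library(
    contigs: list[Contig],
    truths: list[TruthRecord],
    params: SimParams,
    max_mismatches: int = 3,
) -> CountTable:
    """Sample the collapsed *input* library around the planted hairpins.

    Guide (miRNA) counts are uniform over ``planted_count_range``; star
    counts are binomial thinnings at ``star_survival``.  Background species
    are random sRNA-length sequences rejection-sampled so none forms a valid
    duplex (<= ``max_mismatches`` at the planted overhang) with any planted
    read, with counts tuned so ``background_singleton_fraction`` of species
    are singletons.  Deterministic given the seed.
    """
    rng = _stage_rng(params.seed, 1)
    table = CountTable()
    planted: list[str] = []
    for t in truths:
        lo, hi = params.planted_count_range
        t.input_count_mirna = int(rng.integers(lo, hi + 1))
        t.input_count_star = int(rng.binomial(t.input_count_mirna, params.star_survival))
        table.add(t.mirna, t.input_count_mirna)
        planted.append(t.mirna)
        if t.input_count_star >= 1:
            table.add(t.star, t.input_count_star)
            planted.append(t.star)
    lengths = np.array([21, 22, 23, 24])
    length_probs = np.array([0.4, 0.25, 0.25, 0.10])
    accepted = 0
    while accepted < params.n_background:
        length = int(rng.choice(lengths, p=length_probs))
        seq = _random_rna(rng, length)
        if seq in table:
            continue
        clash = False
        for p in planted:
            if len(p) == length:
                dup = try_assemble_duplex(seq, p, params.overhang)
                if dup is not None and dup.mismatch_count <= max_mismatches:
                    clash = True
                    break
        if clash:
            continue
        table.add(seq, _background_count(rng, params.background_singleton_fraction))
        accepted += 1
    return table


def simulate_sequestration(
    library: CountTable,
    truths: list[TruthRecord],
    params: SimParams,
) -> CountTable:
    """Apply the duplex-capture step and return the *eluted* library.

    For each planted pair, ``min(guide, star)`` copies are paired duplexes;
    each duplex is captured with Langmuir occupancy C / (C + K_d(class)).
    Captured duplexes contribute one guide and one star copy each, so at
    zero nonspecific retention the eluted strands are exactly balanced.
    Unpaired leftovers and background copies survive only with the
    nonspecific probability; uncaptured duplexes are washed out.
    """
    rng = _stage_rng(params.seed, 2)
    cap = params.capture
    ns = cap.nonspecific_capture_prob
    eluted = CountTable()
    planted_seqs = set()
    for t in truths:
        if t.mismatch_count not in cap.kd_by_class:
            raise KeyError(
                f"no K_d configured for duplex class {t.mismatch_count} "
                f"(have {sorted(cap.kd_by_class)})"
            )
        kd = cap.kd_by_class[t.mismatch_count]
        p_capture = cap.p19_concentration_nM / (cap.p19_concentration_nM + kd)
        m = library.count(t.mirna)
        s = library.count(t.star)
        planted_seqs.update((t.mirna, t.star))
        paired = min(m, s)
        captured = int(rng.binomial(paired, p_capture)) if paired else 0
        extra_m = int(rng.binomial(m - paired, ns)) if m > paired else 0
        extra_s = int(rng.binomial(s - paired, ns)) if s > paired else 0
        t.eluted_count_mirna = captured + extra_m
        t.eluted_count_star = captured + extra_s
        if t.eluted_count_mirna >= 1:
            eluted.add(t.mirna, t.eluted_count_mirna)
        if t.eluted_count_star >= 1:
            eluted.add(t.star, t.eluted_count_star)
    for read in library:
        if read.seq in planted_seqs:
            continue
        kept = int(rng.binomial(read.count, ns)) if ns > 0 else 0
        if kept >= 1:
            eluted.add(read.seq, kept)
    return eluted


def simulate_experiment(params: SimParams) -> SimResult:
    """Run the three generator stages end to end."""
    contigs, truths = generate_premirna_set(params)
    input_table = generate_library(contigs, truths, params)
    eluted_table = simulate_sequestration(input_table, truths, params)
    return SimResult(tuple(contigs), tuple(truths), input_table, eluted_table)


def write_truth_tsv(truths: list[TruthRecord], path: str | Path) -> None:
    cols = [
        "hairpin_id", "contig", "mirna", "star", "mismatch_count",
        "mirna_start", "mirna_end", "star_start", "star_end",
        "input_count_mirna", "input_count_star",
        "eluted_count_mirna", "eluted_count_star",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truths:
            fh.write("\t".join(str(getattr(t, c)) for c in cols) + "\n")


def write_params_yaml(params: SimParams, path: str | Path) -> None:
    """Echo the full parameter set to a YAML sidecar for reproducibility."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)
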