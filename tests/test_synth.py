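"""The hairpin/library generator and the duplex-capture simulator."""

import numpy as np
import pytest

from srnaduplex.duplex_scan import ScanParams, find_duplex_pairs
from srnaduplex.hairpin_map import hairpin_support
from srnaduplex.seq_core import try_assemble_duplex
from srnaduplex.synth import (
    CaptureParams,
    SimParams,
    generate_library,
    generate_premirna_set,
    simulate_experiment,
    simulate_sequestration,
)


def truth_pairs(truths):
    return {tuple(sorted((t.mirna, t.star))) for t in truths}


class TestGeneratePremirnaSet:
    def test_truths_assemble_with_recorded_mismatches(self):
        params = SimParams(seed=11, n_hairpins=6, mismatch_spectrum={0: 1, 1: 1, 2: 1, 3: 1})
        contigs, truths = generate_premirna_set(params)
        assert len(truths) == 6
        for t in truths:
            dup = try_assemble_duplex(t.mirna, t.star, 2)
            assert dup is not None
            assert dup.mismatch_count == t.mismatch_count

    def test_reads_planted_at_recorded_coordinates(self):
        contigs, truths = generate_premirna_set(SimParams(seed=3, n_hairpins=3))
        by_name = {c.name: c for c in contigs}
        for t in truths:
            c = by_name[t.contig]
            assert c.seq[t.mirna_start - 1 : t.mirna_end] == t.mirna
            assert c.seq[t.star_start - 1 : t.star_end] == t.star

    def test_planted_hairpins_have_structural_support(self):
        params = SimParams.scan_benchmark(
            seed=5, n_hairpins=3, mismatch_spectrum={0: 1.0}, n_background=0
        )
        result = simulate_experiment(params)
        calls = find_duplex_pairs(result.input_table, ScanParams())
        assert len(calls) == 3
        for call in calls:
            assert hairpin_support(call, list(result.contigs)).supported

    def test_deterministic_given_seed(self):
        a = generate_premirna_set(SimParams(seed=42))
        b = generate_premirna_set(SimParams(seed=42))
        assert a == b
        c = generate_premirna_set(SimParams(seed=43))
        assert [x.seq for x in a[0]] != [x.seq for x in c[0]]

    def test_tiny_arm_rejected(self):
        with pytest.raises(ValueError):
            SimParams(seed=1, arm_length=4)


class TestGenerateLibrary:
    def test_singleton_fraction_near_target(self):
        result = simulate_experiment(SimParams(seed=3))
        singles = sum(1 for r in result.input_table if r.count == 1)
        frac = singles / result.input_table.total_species
        assert abs(frac - 0.8) < 0.05

    def test_background_never_pairs_with_planted_reads(self):
        result = simulate_experiment(SimParams(seed=9, n_background=200))
        planted = {t.mirna for t in result.truths} | {t.star for t in result.truths}
        for read in result.input_table:
            if read.seq in planted:
                continue
            for p in planted:
                if len(p) == len(read.seq):
                    dup = try_assemble_duplex(read.seq, p, 2)
                    assert dup is None or dup.mismatch_count > 3

    def test_star_survival_zero_removes_star_strands(self):
        params = SimParams(seed=2, star_survival=0.0, n_background=50)
        result = simulate_experiment(params)
        for t in result.truths:
            assert t.input_count_star == 0
            assert t.star not in result.input_table
        assert find_duplex_pairs(result.input_table, ScanParams()) == []

    def test_full_star_survival_makes_all_pairs_callable(self):
        params = SimParams.scan_benchmark(seed=4, mismatch_spectrum={0: 1.0})
        result = simulate_experiment(params)
        calls = find_duplex_pairs(result.input_table, ScanParams())
        assert truth_pairs(result.truths) <= {c.key for c in calls}

    def test_mismatch_class_three_called_only_at_three(self):
        params = SimParams.scan_benchmark(seed=6, mismatch_spectrum={3: 1.0})
        result = simulate_experiment(params)
        at3 = {c.key for c in find_duplex_pairs(result.input_table, ScanParams(max_mismatches=3))}
        at2 = {c.key for c in find_duplex_pairs(result.input_table, ScanParams(max_mismatches=2))}
        assert truth_pairs(result.truths) <= at3
        assert truth_pairs(result.truths).isdisjoint(at2)


class TestSimulateSequestration:
    def test_half_occupancy_at_kd_equal_concentration(self):
        """When the protein concentration equals K_d, half the duplexes bind."""
        params = SimParams.scan_benchmark(
            seed=10, n_hairpins=20, n_background=0,
            mismatch_spectrum={0: 1.0},
            capture=CaptureParams(p19_concentration_nM=100.0,
                                  kd_by_class={0: 100.0},
                                  nonspecific_capture_prob=0.0),
        )
        result = simulate_experiment(params)
        paired = sum(min(t.input_count_mirna, t.input_count_star) for t in result.truths)
        captured = sum(t.eluted_count_mirna for t in result.truths)
        frac = captured / paired
        assert abs(frac - 0.5) < 0.05

    def test_capture_ordering_follows_kd_ladder(self):
        """Lower-K_d duplex classes are captured at higher rates."""
        rates = []
        for mm, kd in [(0, 16.0), (1, 55.0), (2, 227.0), (3, 1138.0)]:
            params = SimParams.scan_benchmark(
                seed=20, n_hairpins=10, n_background=0,
                mismatch_spectrum={mm: 1.0},
                capture=CaptureParams(p19_concentration_nM=100.0,
                                      nonspecific_capture_prob=0.0),
            )
            result = simulate_experiment(params)
            paired = sum(min(t.input_count_mirna, t.input_count_star) for t in result.truths)
            captured = sum(t.eluted_count_mirna for t in result.truths)
            rates.append(captured / paired)
        assert rates == sorted(rates, reverse=True)

    def test_strand_balance_exact_without_nonspecific_capture(self):
        params = SimParams(seed=7, capture=CaptureParams(nonspecific_capture_prob=0.0))
        result = simulate_experiment(params)
        for t in result.truths:
            assert t.eluted_count_mirna == t.eluted_count_star

    def test_unknown_duplex_class_rejected(self):
        params = SimParams(seed=1, mismatch_spectrum={2: 1.0},
                           capture=CaptureParams(kd_by_class={0: 16.0}))
        contigs, truths = generate_premirna_set(params)
        library = generate_library(contigs, truths, params)
        with pytest.raises(KeyError):
            simulate_sequestration(library, truths, params)

    def test_whole_experiment_deterministic(self):
        a = simulate_experiment(SimParams(seed=12, n_background=100))
        b = simulate_experiment(SimParams(seed=12, n_background=100))
        assert a.input_table == b.input_table
        assert a.eluted_table == b.eluted_table
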