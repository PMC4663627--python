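"""Reference filtering, read location, folding and the hairpin-stem test."""

import numpy as np
import pytest

from srnaduplex.duplex_scan import DuplexCall
from srnaduplex.hairpin_map import (
    Contig,
    SecondaryStructure,
    filter_by_reference,
    hairpin_support,
    load_contigs,
    locate_read,
    nussinov_fold,
    write_contigs,
)
from srnaduplex.seq_core import assemble_duplex, reverse_complement
from srnaduplex.sra_io import CollapsedRead, CountTable

# independent fold oracle: plain recursive exhaustive search over nested
# structures, no interval memoisation
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def oracle_max_pairs(seq, i=0, j=None, min_loop=3):
    if j is None:
        j = len(seq) - 1
    if j - i <= min_loop:
        return 0
    best = oracle_max_pairs(seq, i + 1, j, min_loop)
    for k in range(i + min_loop + 1, j + 1):
        if (seq[i], seq[k]) in _PAIRS:
            best = max(
                best,
                1
                + oracle_max_pairs(seq, i + 1, k - 1, min_loop)
                + oracle_max_pairs(seq, k + 1, j, min_loop),
            )
    return best


def make_call(a: str, b: str) -> DuplexCall:
    if a > b:
        a, b = b, a
    return DuplexCall(CollapsedRead(a, 40), CollapsedRead(b, 40), assemble_duplex(a, b))


def hairpin_contig(arm: str, loop: str = "AAAAAAAA", tail: str = "AA"):
    """A minimal pre-miRNA: arm + loop + (rc of arm's first 19 nt) + tail."""
    star = reverse_complement(arm[:19]) + tail
    return Contig("hp", arm + loop + star), arm, star


class TestReferenceFilter:
    def test_exact_and_reverse_complement_matches_kept(self):
        contig = Contig("c1", "G" * 10 + "CGUACGCGGAAUACUUCGAUU" + "G" * 10)
        inside = "CGUACGCGGAAUACUUCGAUU"
        table = CountTable({
            inside: 5,
            reverse_complement(inside): 3,
            # one substitution relative to the contig
            "CGUACGCGGAAAACUUCGAUU": 7,
        })
        kept = filter_by_reference(table, [contig])
        assert set(kept.counts()) == {inside, reverse_complement(inside)}
        assert kept.count(inside) == 5  # counts unchanged

    def test_never_increases_species_or_reads(self):
        contig = Contig("c1", "ACGU" * 30)
        table = CountTable({"ACGUACGUACGUACGUACGUA": 2, "GGGGGGGGGGGGGGGGGGGGG": 9})
        kept = filter_by_reference(table, [contig])
        assert kept.total_species <= table.total_species
        assert kept.total_reads <= table.total_reads

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            filter_by_reference(CountTable(), [])


class TestLocateRead:
    def test_planted_position_found(self):
        contig = Contig("c", "A" * 10 + "CGUACGCGGAAUACUUCGAUU" + "A" * 5)
        assert locate_read("CGUACGCGGAAUACUUCGAUU", contig) == [(11, "+")]

    def test_absent_read_gives_empty_list(self):
        assert locate_read("G" * 21, Contig("c", "A" * 50)) == []

    def test_both_occurrences_reported_ascending(self):
        probe = "CGUACGCGGAAUACUUCGAUU"
        contig = Contig("c", probe + "AAAA" + probe)
        assert locate_read(probe, contig) == [(1, "+"), (26, "+")]

    def test_minus_strand_hit(self):
        probe = "CGUACGCGGAAUACUUCGAUU"
        contig = Contig("c", "UU" + reverse_complement(probe) + "GG")
        assert locate_read(probe, contig) == [(3, "-")]


class TestNussinovFold:
    def test_simple_hairpin(self):
        s = nussinov_fold("GGGAAAACCC")
        assert s.dotbracket == "(((....)))"
        assert s.n_pairs == 3

    def test_unpairable_sequence(self):
        s = nussinov_fold("AAAAAA")
        assert s.dotbracket == "......"
        assert s.n_pairs == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_pair_count_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(6, 13))))
        assert nussinov_fold(seq).n_pairs == oracle_max_pairs(seq)

    def test_structure_is_well_formed(self):
        rng = np.random.default_rng(99)
        seq = "".join(rng.choice(list("ACGU"), size=40))
        s = nussinov_fold(seq)
        # pair table symmetric, min-loop respected, matches the dot-bracket
        for i, j in s.pair_table.items():
            assert s.pair_table[j] == i
            assert abs(i - j) > 3
        assert SecondaryStructure.from_dotbracket(s.dotbracket).pair_table == s.pair_table

    def test_deterministic(self):
        seq = "GCGCGCAAAAGCGCGCUUUUGCGC"
        assert nussinov_fold(seq).dotbracket == nussinov_fold(seq).dotbracket


class TestHairpinSupport:
    def test_perfect_hairpin_supported(self):
        arm = "GCGGCCGCGGCCGGCGCCGGC"  # G/C arm: loop A's cannot pair
        contig, arm, star = hairpin_contig(arm)
        support = hairpin_support(make_call(arm, star), [contig])
        assert support.supported
        assert support.contig == "hp"
        assert support.paired_fraction_a >= 0.6
        assert support.cross_pair_fraction_a >= 0.9
        assert support.cross_pair_fraction_b >= 0.9

    def test_reads_in_different_contigs_unsupported(self):
        arm = "GCGGCCGCGGCCGGCGCCGGC"
        star = reverse_complement(arm[:19]) + "AA"
        c1 = Contig("c1", "A" * 10 + arm + "A" * 10)
        c2 = Contig("c2", "A" * 10 + star + "A" * 10)
        support = hairpin_support(make_call(arm, star), [c1, c2])
        assert not support.supported

    def test_read_over_loop_only_unsupported(self):
        arm = "GCGGCCGCGGCCGGCGCCGGC"
        contig, arm, star = hairpin_contig(arm, loop="AAAAAAAAAAAAAAAAAAAAA")
        loop_read = contig.seq[21:42]  # the all-A loop region
        support = hairpin_support(make_call(arm, loop_read), [contig])
        assert not support.supported

    def test_non_complementary_neighbour_unsupported(self):
        # a co-located read that is not the arm's complement: the arm's
        # paired bases do not point into the neighbour's interval
        arm = "GCGGCCGCGGCCGGCGCCGGC"
        rng = np.random.default_rng(1)
        decoy = "".join(rng.permutation(list("AAAAAAAAAAUUUUUUUUUUU")))
        contig = Contig("c", arm + "AAAAAAAA" + decoy)
        support = hairpin_support(make_call(arm, decoy), [contig])
        assert not support.supported

    def test_minus_strand_placement_supported(self):
        arm = "GCGGCCGCGGCCGGCGCCGGC"
        contig, arm, star = hairpin_contig(arm)
        flipped = Contig("hp", reverse_complement(contig.seq))
        support = hairpin_support(make_call(arm, star), [flipped])
        assert support.supported
        assert support.strand == "-"

    def test_window_limits_colocation(self):
        arm = "GCGGCCGCGGCCGGCGCCGGC"
        star = reverse_complement(arm[:19]) + "AA"
        contig = Contig("c", arm + "A" * 150 + star)
        assert not hairpin_support(make_call(arm, star), [contig], window=100).supported
        assert hairpin_support(make_call(arm, star), [contig], window=300).supported

    def test_external_structure_used_and_validated(self):
        arm = "GCGGCCGCGGCCGGCGCCGGC"
        contig, arm, star = hairpin_contig(arm)
        n = len(contig.seq)
        db = nussinov_fold(contig.seq).dotbracket
        ext = {"hp": SecondaryStructure.from_dotbracket(db)}
        support = hairpin_support(make_call(arm, star), [contig], structures=ext)
        assert support.supported
        with pytest.raises(KeyError):
            hairpin_support(make_call(arm, star), [contig],
                            structures={"nope": SecondaryStructure.from_dotbracket("." * n)})


class TestContigIO:
    def test_fasta_roundtrip_rna_to_dna(self, tmp_path):
        contigs = [Contig("c1", "ACGUACGUAC"), Contig("c2", "GGGGUUUU")]
        p = tmp_path / "ref.fasta"
        write_contigs(contigs, p)
        assert "T" in p.read_text() and "U" not in p.read_text().splitlines()[1]
        assert load_contigs(p) == contigs

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "ref.fasta"
        p.write_text(">a\nACGT\n>a\nGGGG\n")
        with pytest.raises(ValueError):
            load_contigs(p)
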