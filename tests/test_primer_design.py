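"""Selection, overlap merging, and degenerate variant folding."""

import pytest

from kmerprimer import (
    PipelineConfig,
    combine_variants,
    count_kmers,
    design_primers,
    merge_overlapping,
    select_high_frequency,
)
from kmerprimer.iupac import expand
from kmerprimer.kmer_engine import KmerStat, KmerTable
from kmerprimer.primer_design import DegeneratePrimer, overlap_length

from conftest import make_db


def table_of(counts: dict[str, tuple[int, int]], n_sequences: int) -> KmerTable:
    """Build a KmerTable directly from kmer -> (occurrences, seq_hits)."""
    ks = {len(k) for k in counts}
    t = KmerTable(k=ks.pop() if len(ks) == 1 else max(len(k) for k in counts),
                  n_sequences=n_sequences)
    for kmer, (occ, hits) in counts.items():
        t.stats[kmer] = KmerStat(kmer, occ, hits, hits / n_sequences)
    return t


class TestSelectHighFrequency:
    def test_top_by_occurrence(self):
        t = table_of({"AAAA": (10, 5), "CCCC": (5, 3)}, 10)
        assert [s.kmer for s in select_high_frequency(t, top_n=1)] == ["AAAA"]

    def test_lexicographic_tie_break(self):
        t = table_of({"CCCC": (5, 3), "AAAA": (5, 3)}, 10)
        assert [s.kmer for s in select_high_frequency(t, top_n=1)] == ["AAAA"]

    def test_min_fraction_floor_can_empty_the_selection(self):
        t = table_of({"AAAA": (10, 1), "CCCC": (5, 1)}, 100)  # fractions 0.01
        assert select_high_frequency(t, top_n=5, min_fraction=0.2) == []

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            select_high_frequency(KmerTable(k=4, n_sequences=1))


class TestOverlapLength:
    def test_suffix_prefix_both_orders(self):
        assert overlap_length("AAACGT", "ACGTTT") == 4
        assert overlap_length("ACGTTT", "AAACGT") == 4

    def test_containment_counts_as_shorter_length(self):
        assert overlap_length("ACGTACGT", "GTAC") == 4

    def test_disjoint_strings(self):
        assert overlap_length("AAAA", "CCCC") == 0


class TestMergeOverlapping:
    def test_highest_frequency_survives(self):
        # two same-locus 19-mers sharing a 15-base overlap
        a = "CGCGGTTGCTCGTGTGTGG"
        b = a[4:] + "ACTG"  # shifted by four bases
        assert overlap_length(a, b) == 15
        t = table_of({a: (1218, 900), b: (1137, 850)}, 3397)
        out = merge_overlapping(list(t), x=10)
        assert [s.kmer for s in out] == [a]

    def test_equal_count_equal_length_breaks_lexicographically(self):
        a, b = "ACGTACGTACGT", "CGTACGTACGTA"
        assert overlap_length(a, b) == 11
        t = table_of({a: (7, 5), b: (7, 5)}, 10)
        out = merge_overlapping(list(t), x=10)
        assert [s.kmer for s in out] == [a]

    def test_disjoint_kmers_all_survive(self):
        t = table_of({"AAAAAAAAAAAA": (5, 5), "CCCCCCCCCCCC": (4, 4)}, 10)
        out = merge_overlapping(list(t), x=6)
        assert [s.kmer for s in out] == ["AAAAAAAAAAAA", "CCCCCCCCCCCC"]

    def test_no_surviving_pair_overlaps_above_threshold(self):
        kmers = {
            "ACGTACGTACGT": (9, 9),
            "CGTACGTACGTA": (8, 8),
            "TTTTGGGGCCCC": (7, 7),
            "GGGGCCCCAAAA": (6, 6),
        }
        out = merge_overlapping(list(table_of(kmers, 10)), x=7)
        for i, a in enumerate(out):
            for b in out[i + 1 :]:
                assert overlap_length(a.kmer, b.kmer) <= 7

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            merge_overlapping([], x=0)


class TestCombineVariants:
    def test_iupac_union_at_differing_positions(self):
        db = make_db(["ACGT"] * 80 + ["ACGA"] * 12 + ["ACGC"] * 8)
        t = count_kmers(db, 4)
        p = combine_variants("ACGT", t, variant_min_fraction=0.01)
        assert p.iupac_seq == "ACGH"  # {T} u {A} u {C}
        assert sorted(p.absorbed_variants) == ["ACGA", "ACGC"]

    def test_no_eligible_variants_gives_identity(self):
        t = count_kmers(make_db(["ACGT"] * 5), 4)
        p = combine_variants("ACGT", t)
        assert p.iupac_seq == "ACGT"
        assert p.degeneracy == 1

    def test_fraction_floor_excludes_rare_variants(self):
        db = make_db(["ACGT"] * 99 + ["TCGT"])
        t = count_kmers(db, 4)
        p = combine_variants("ACGT", t, variant_min_fraction=0.05)
        assert p.iupac_seq == "ACGT"

    def test_absorption_stops_at_degeneracy_cap(self):
        # three variants at distinct positions, absorbed best-first
        db = make_db(["ACGT"] * 60 + ["TCGT"] * 20 + ["AGGT"] * 15 + ["ACTT"] * 5)
        t = count_kmers(db, 4)
        p = combine_variants("ACGT", t, variant_min_fraction=0.01, max_degeneracy=4)
        assert p.iupac_seq == "WSGT"  # third absorption would reach 8 > 4
        assert p.degeneracy == 4

    def test_seed_always_among_expansions_and_sets_never_shrink(self):
        db = make_db(["ACGT"] * 50 + ["ACGA"] * 30 + ["CCGT"] * 20)
        t = count_kmers(db, 4)
        p = combine_variants("ACGT", t)
        assert p.seed_kmer in expand(p.iupac_seq)
        for v in p.absorbed_variants:
            assert v in expand(p.iupac_seq)
        assert p.degeneracy == len(expand(p.iupac_seq))

    def test_absent_seed_is_an_error(self):
        t = count_kmers(make_db(["ACGT"]), 4)
        with pytest.raises(KeyError):
            combine_variants("TTTT", t)


class TestDegeneratePrimer:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            DegeneratePrimer("ACGT", "ACG")

    def test_reverse_complement_roundtrip(self):
        p = DegeneratePrimer("AYGT", "ACGT", absorbed_variants=["ATGT"])
        rc = p.reverse_complement()
        assert rc.iupac_seq == "ACRT"
        assert rc.reverse_complement().iupac_seq == p.iupac_seq


class TestDesignPrimers:
    def test_identical_sequences_give_nondegenerate_full_coverage(self):
        db = make_db(["ACGTACGTACGTACGTACGTACGTACG"] * 10)
        primers = design_primers(
            db, PipelineConfig(primer_len_min=18, primer_len_max=20)
        )
        assert primers
        for p in primers:
            assert p.degeneracy == 1
            assert p.coverage == 1.0

    def test_coverage_floor_excludes_rare_motif(self):
        motif = "TTCTACGACTGGTACGCCGA"
        rare = make_db(
            [motif + "ACGT" * 10 if i < 2 else "ACGT" * 15 for i in range(20)]
        )
        primers = design_primers(
            rare,
            PipelineConfig(primer_len_min=20, primer_len_max=20, min_coverage=0.2),
        )
        assert all(motif not in p.iupac_seq for p in primers)

    def test_empty_db_is_an_error(self):
        with pytest.raises(ValueError):
            design_primers([], PipelineConfig())

    def test_primers_sorted_by_coverage_and_named_sequentially(self):
        db = make_db(["ACGTACGTACGTACGTACGTACGTACG"] * 10)
        primers = design_primers(
            db, PipelineConfig(primer_len_min=18, primer_len_max=19),
            name_prefix="gene",
        )
        covs = [p.coverage for p in primers]
        assert covs == sorted(covs, reverse=True)
        assert [p.name for p in primers] == [
            f"gene_kmer{i}" for i in range(1, len(primers) + 1)
        ]
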