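"""IUPAC matcher, coverage, pairing arithmetic, and specificity."""

import pytest

from kmerprimer import (
    SequenceRecord,
    evaluate_pair,
    match_sites,
    pair_and_report,
    primer_coverage,
    specificity,
)
from kmerprimer.iupac import reverse_complement

from _oracles import match_starts_brute
from conftest import make_db, random_dna, random_iupac


def rec(seq: str, id: str = "s1") -> SequenceRecord:
    return SequenceRecord(id=id, description="", seq=seq)


class TestMatchSites:
    def test_degenerate_forward_sites(self):
        sites = match_sites("AYG", rec("ATGACG"))
        fwd = [(s.start, s.end) for s in sites if s.strand == "forward"]
        assert fwd == [(0, 3), (3, 6)]

    def test_palindrome_matches_both_strands(self):
        sites = match_sites("ACGT", rec("ACGT"))
        assert {s.strand for s in sites} == {"forward", "reverse"}
        assert all((s.start, s.end) == (0, 4) for s in sites)

    def test_no_match_with_zero_budget(self):
        assert match_sites("AAAA", rec("CCCC")) == []

    def test_primer_longer_than_sequence(self):
        assert match_sites("ACGTACGT", rec("ACG")) == []

    def test_template_n_matches_only_primer_n(self):
        assert match_sites("ACG", rec("ANG")) == []
        sites = match_sites("ANG", rec("ANG"))
        assert [s.strand for s in sites] == ["forward"]

    def test_mismatch_budget_admits_near_sites(self):
        assert match_sites("AAAA", rec("AATA")) == []
        sites = match_sites("AAAA", rec("AATA"), max_mismatches=1)
        assert [(s.start, s.mismatches) for s in sites if s.strand == "forward"] == [
            (0, 1)
        ]

    def test_site_width_equals_primer_length(self, rng):
        seq = random_dna(rng, 200)
        for s in match_sites("ACGTAY", rec(seq), max_mismatches=1):
            assert s.end - s.start == 6
            assert 0 <= s.start < s.end <= len(seq)


class TestMatcherAgainstBruteForce:
    def test_forward_sites_equal_expansion_scan(self, rng):
        for _ in range(30):
            primer = random_iupac(rng, int(rng.integers(4, 10)), 64)
            seq = random_dna(rng, 150)
            mm = int(rng.integers(0, 2))
            got = [
                s.start
                for s in match_sites(primer, rec(seq), mm)
                if s.strand == "forward"
            ]
            assert got == match_starts_brute(primer, seq, mm)

    def test_reverse_sites_equal_expansion_scan_of_revcomp(self, rng):
        for _ in range(15):
            primer = random_iupac(rng, 8, 16)
            seq = random_dna(rng, 120)
            got = [
                s.start
                for s in match_sites(primer, rec(seq))
                if s.strand == "reverse"
            ]
            assert got == match_starts_brute(reverse_complement(primer), seq, 0)

    def test_revcomp_involution_mirrors_sites(self, rng):
        primer = random_iupac(rng, 7, 16)
        seq = random_dna(rng, 100)
        mirrored = rec(reverse_complement(seq), id="s1")
        direct = {
            (s.start, s.strand) for s in match_sites(primer, rec(seq))
        }
        flipped = set()
        for s in match_sites(reverse_complement(primer), mirrored):
            start = len(seq) - s.end
            strand = "forward" if s.strand == "reverse" else "reverse"
            flipped.add((start, strand))
        assert direct == flipped


class TestPrimerCoverage:
    def test_planted_motif_fraction(self, rng):
        motif = "TTCTACGACTGGTACGCCGA"
        seqs = [
            (random_dna(rng, 30) + motif + random_dna(rng, 30))
            if i < 8
            else random_dna(rng, 80)
            for i in range(10)
        ]
        assert primer_coverage(motif, make_db(seqs)) == 0.8

    def test_absent_primer_gives_zero(self, rng):
        db = make_db([random_dna(rng, 50) for _ in range(5)])
        assert primer_coverage("TTTTTTTTTTTTTTTTTTTT", db) == 0.0

    def test_degenerate_primer_covers_at_least_its_seed(self, rng):
        seed = "ACGTACGTACGT"
        degenerate = "ACGTAYGTACRT"
        db = make_db([random_dna(rng, 100) for _ in range(20)]
                     + [random_dna(rng, 40) + seed + random_dna(rng, 40)])
        assert primer_coverage(degenerate, db) >= primer_coverage(seed, db)

    def test_mismatch_budget_never_decreases_coverage(self, rng):
        primer = "ACGTACGTAC"
        db = make_db([random_dna(rng, 60) for _ in range(30)])
        covs = [primer_coverage(primer, db, mm) for mm in (0, 1, 2)]
        assert covs == sorted(covs)


class TestPairEvaluation:
    def _paired_db(self, rng, n=10, spacing=401, fwd=None, rev=None):
        fwd = fwd or "TTCTACGACTGGTACGCCGA"
        rev = rev or "ACGTTGCAACGTAGGTCGTA"
        down = reverse_complement(rev)
        seqs = []
        for _ in range(n):
            s = random_dna(rng, 600)
            s = s[:50] + fwd + s[70:]
            pstart = 50 + spacing
            s = s[:pstart] + down + s[pstart + 20 :]
            seqs.append(s)
        return make_db(seqs), fwd, rev

    def test_fixed_spacing_gives_single_mode(self, rng):
        db, fwd, rev = self._paired_db(rng)
        rep = evaluate_pair(fwd, rev, db, 200, 500)
        assert rep.pair_coverage == 1.0
        assert rep.product_length_mode == 421
        assert set(rep.product_lengths) == {421}

    def test_bounds_excluding_planted_spacing_zero_coverage(self, rng):
        db, fwd, rev = self._paired_db(rng)
        rep = evaluate_pair(fwd, rev, db, 200, 400)
        assert rep.pair_coverage == 0.0
        assert rep.product_length_mode is None

    def test_pair_coverage_bounded_by_single_coverages(self, rng):
        db, fwd, rev = self._paired_db(rng, n=6)
        db += make_db([random_dna(rng, 300) for _ in range(4)])
        for i, r in enumerate(db):
            r.id = f"s{i + 1}"
        rep = evaluate_pair(fwd, rev, db, 200, 500)
        assert rep.pair_coverage <= min(
            primer_coverage(fwd, db), primer_coverage(rev, db)
        )

    def test_amplicon_lengths_at_least_both_primers(self, rng):
        db, fwd, rev = self._paired_db(rng, n=4, spacing=230)
        rep = evaluate_pair(fwd, rev, db, 200, 500)
        for L in rep.product_lengths:
            assert L >= len(fwd) and L >= len(rev)
            assert 200 <= L <= 500

    def test_pair_and_report_sorts_by_coverage(self, rng):
        from kmerprimer import DegeneratePrimer

        db, fwd, rev = self._paired_db(rng)
        p1 = DegeneratePrimer(fwd, fwd, name="f")
        p2 = DegeneratePrimer(rev, rev, name="r")
        reports = pair_and_report([p1, p2], db, 200, 500)
        assert len(reports) == 2  # ordered pairs
        covs = [r.pair_coverage for r in reports]
        assert covs == sorted(covs, reverse=True)
        assert reports[0].pair_coverage == 1.0

    def test_fewer_than_two_primers_rejected(self):
        with pytest.raises(ValueError):
            pair_and_report([], make_db(["ACGT"]), 1, 10)


class TestSpecificity:
    def test_zero_when_offtarget_lacks_expansions(self, rng):
        db = make_db([random_dna(rng, 60) for _ in range(10)])
        assert specificity("TTTTTTTTTTTTTTTTTTTT", db) == 0.0

    def test_planted_in_one_of_two_hundred(self, rng):
        motif = "TTCTACGACTGGTACGCCGA"
        seqs = [random_dna(rng, 60) for _ in range(199)]
        seqs.append(random_dna(rng, 20) + motif + random_dna(rng, 20))
        assert specificity(motif, make_db(seqs)) == pytest.approx(0.005)

    def test_same_database_equals_coverage(self, rng):
        motif = "ACGTACGTACGTACGTACGT"
        db = make_db(
            [random_dna(rng, 30) + motif + random_dna(rng, 30) for _ in range(4)]
            + [random_dna(rng, 80) for _ in range(6)]
        )
        assert specificity(motif, db) == primer_coverage(motif, db)
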