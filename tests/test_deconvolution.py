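"""Read deconvolution: anchor extraction, translation, cyclisation,
ranking, family collapse."""

import itertools

import numpy as np
import pytest

from cyclodisplay import (
    LibraryDesign,
    assign_cyclization,
    collapse_families,
    deconvolute_reads,
    extract_random_region,
    reverse_translate,
    tally_and_rank,
    translate,
)
from cyclodisplay.deconvolution import EmptyPoolError, PeptideRecord, rank_counts
from cyclodisplay.library_design import build_library_read
from conftest import PADI4_3_CORE, PADI4_3_SYNTH


def make_read(core, design=None):
    return build_library_read(reverse_translate(core), design)


class TestExtract:
    def test_recovers_constructed_insert(self, design):
        insert = reverse_translate(PADI4_3_CORE)
        assert extract_random_region(make_read(PADI4_3_CORE), design, 0) == insert

    def test_no_anchor_returns_none(self, design):
        assert extract_random_region("A" * 150, design) is None

    def test_off_frame_insert_rejected(self, design):
        insert = reverse_translate(PADI4_3_CORE) + "A"  # 31 bases
        read = design.five_prime_const + insert + design.three_prime_const
        assert extract_random_region(read, design) is None

    def test_length_outside_design_rejected(self, design):
        read = make_read("RDHHY")  # n=5 not in the 6-12 design
        assert extract_random_region(read, design) is None

    def test_anchor_mismatch_tolerance(self, design):
        read = make_read(PADI4_3_CORE)
        mutated = "C" + read[1:]  # first template base altered
        assert mutated != read
        assert extract_random_region(mutated, design, max_mismatch=0) is None
        assert extract_random_region(mutated, design, max_mismatch=1) \
            == reverse_translate(PADI4_3_CORE)

    def test_malformed_characters_raise(self, design):
        with pytest.raises(ValueError):
            extract_random_region("ACGU" * 30, design)


class TestTranslate:
    def test_lead_inhibitor_linear_sequence(self, design, table_d):
        rec = translate(reverse_translate(PADI4_3_CORE), table_d)
        assert rec.linear_str == "Y" + PADI4_3_CORE + "CGSGSGS"
        assert rec.n == 10 and not rec.flags

    def test_empty_insert_gives_initiator_plus_linker(self, table_d):
        rec = translate("", table_d)
        assert rec.linear_str == "YCGSGSGS"

    def test_internal_stop_truncates(self, table_d):
        insert = reverse_translate("RD") + "TAG" + reverse_translate("HH")
        rec = translate(insert, table_d)
        assert "truncated_by_stop" in rec.flags
        assert rec.linear_str == "YRD"

    def test_internal_met_flagged_ambiguous(self, table_d, table_scan):
        insert = reverse_translate("RMD")
        rec = translate(insert, table_d)
        assert "contains_unassigned" in rec.flags and rec.linear_str[2] == "M"
        # scanning code replaces Met with N-Me-Ala instead
        rec2 = translate(insert, table_scan)
        assert "contains_unassigned" not in rec2.flags
        assert rec2.linear_str == "YRaDCGSGSGS"


class TestCyclization:
    def test_constant_cys_rule(self, table_d):
        rec = assign_cyclization(translate(reverse_translate(PADI4_3_CORE), table_d))
        assert rec.bridge == (0, 11)
        assert rec.key == PADI4_3_SYNTH and len(rec.synthesis_form) == 13

    def test_internal_cys_rule(self, table_d):
        # activator-style peptide: Cys at position 4 closes the macrocycle
        rec = assign_cyclization(translate(reverse_translate("ESCRYRQVLQL"), table_d))
        assert rec.bridge == (0, 3)
        assert rec.key == "YESCRYRQVLQL" and len(rec.synthesis_form) == 12

    def test_no_cysteine_flagged(self):
        rec = PeptideRecord(linear=tuple("YRDA"), n=3)
        rec = assign_cyclization(rec)
        assert rec.bridge is None and "no_cysteine" in rec.flags
        assert not rec.valid_for_ranking

    def test_synthesis_length_is_n_plus_3_without_internal_cys(self, table_d):
        rng = np.random.default_rng(11)
        alphabet = [a for a in "ADEFGHIKLNPQRSTVWY"]  # no Cys, no Met
        for n in range(6, 13):
            core = "".join(rng.choice(alphabet, n))
            rec = assign_cyclization(translate(reverse_translate(core), table_d))
            assert len(rec.synthesis_form) == n + 3


class TestRanking:
    def _records(self, keys):
        recs = []
        for k in keys:
            r = PeptideRecord(linear=tuple(k), n=len(k) - 1)
            r = assign_cyclization(r)
            recs.append(r)
        return recs

    def test_tie_broken_lexicographically(self):
        keys = ["YAAC"] * 5 + ["YDDC"] * 3 + ["YDAC"] * 3
        _, ranked = tally_and_rank(self._records(keys))
        assert list(ranked["peptide"]) == ["YAAC", "YDAC", "YDDC"]

    def test_single_peptide_frequency_one(self):
        rc, ranked = tally_and_rank(self._records(["YAC"] * 100))
        assert ranked.loc[0, "frequency"] == 1.0 and rc.total == 100

    def test_ranking_stable_under_permutation(self):
        keys = ["YAAC"] * 4 + ["YEAC"] * 4 + ["YDDC"] * 2
        rng = np.random.default_rng(3)
        orders = [list(keys)]
        for _ in range(3):
            perm = list(keys)
            rng.shuffle(perm)
            orders.append(perm)
        tables = [tally_and_rank(self._records(o))[1] for o in orders]
        for t in tables[1:]:
            assert t.equals(tables[0])

    def test_empty_pool_raises(self):
        with pytest.raises(EmptyPoolError):
            tally_and_rank([])


class TestEndToEnd:
    def test_count_conservation_and_qc_reconciliation(self, design, table_d):
        reads = (
            [make_read(PADI4_3_CORE)] * 5
            + [make_read("ESCRYRQVLQL")] * 3
            + ["A" * 120] * 2            # no anchor
        )
        counts, qc = deconvolute_reads(reads, design, table_d)
        assert counts.total == 8
        skipped = sum(v for k, v in qc.items() if k not in ("valid", "input_reads"))
        assert qc["valid"] + skipped == qc["input_reads"] == 10

    def test_reverse_complement_rescue(self, design, table_d):
        from cyclodisplay.deconvolution import reverse_complement
        read = make_read(PADI4_3_CORE)
        rc_read = reverse_complement(read)
        counts, qc = deconvolute_reads([rc_read], design, table_d)
        assert counts.total == 0
        counts, qc = deconvolute_reads([rc_read], design, table_d,
                                       rescue_reverse_complement=True)
        assert counts.counts == {PADI4_3_SYNTH: 1}

    def test_fixture_round_trip_recovers_source_peptides(self, design, table_d):
        """Deconvolution of reverse-translated fixtures recovers each source
        peptide's synthesis form exactly."""
        rng = np.random.default_rng(5)
        alphabet = list("ADEFGHIKLNPQRSTVWY")
        cores = {"".join(rng.choice(alphabet, rng.integers(6, 13)))
                 for _ in range(300)}
        reads = [make_read(c) for c in cores]
        counts, qc = deconvolute_reads(reads, design, table_d)
        assert qc["valid"] == len(reads)
        assert set(counts.counts) == {"Y" + c + "CG" for c in cores}


class TestCollapseFamilies:
    def _ranked(self, counts):
        from collections import Counter
        from cyclodisplay.deconvolution import RoundCounts
        return rank_counts(RoundCounts("r", Counter(counts)))

    def test_distance_zero_is_identity(self):
        ranked = self._ranked({"YRDHH": 5, "YRDHY": 3})
        out = collapse_families(ranked, 0)
        assert out.equals(ranked)

    def test_single_substitution_merges(self):
        out = collapse_families(self._ranked({"YRDHH": 5, "YRDHY": 3}), 1)
        assert len(out) == 1
        assert out.loc[0, "peptide"] == "YRDHH" and out.loc[0, "count"] == 8

    def test_single_linkage_chains_clusters(self):
        # pairwise distances: (A,B)=1, (B,C)=1, (A,C)=2; threshold 1 chains all
        counts = {"YAAAA": 5, "YAAAB": 3, "YAABB": 2}
        import itertools as it
        def lev(a, b):
            # brute-force oracle: full DP edit distance
            m = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
            for i in range(len(a) + 1):
                m[i][0] = i
            for j in range(len(b) + 1):
                m[0][j] = j
            for i in range(1, len(a) + 1):
                for j in range(1, len(b) + 1):
                    m[i][j] = min(m[i - 1][j] + 1, m[i][j - 1] + 1,
                                  m[i - 1][j - 1] + (a[i - 1] != b[j - 1]))
            return m[-1][-1]
        d = {p: lev(*p) for p in it.combinations(counts, 2)}
        assert sorted(d.values()) == [1, 1, 2]
        out = collapse_families(self._ranked(counts), 1)
        assert len(out) == 1 and out.loc[0, "count"] == 10
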