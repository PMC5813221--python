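"""The three search modalities: full scan, 80-mer window scan, 8-mer words."""

import numpy as np
import pytest

from allerscreen import (
    ProteinRecord,
    build_word_index,
    calibrate_evalues,
    calibrate_window_scan,
    enumerate_windows,
    full_length_identity,
    full_scan,
    window_scan,
    word_scan,
)
from allerscreen.synthetic import (
    SyntheticSpec,
    gen_decoy_db,
    legh_fixture,
    plant_homolog,
)

from conftest import as_entry
from oracles import best_ungapped_window_identity, naive_shared_kmers

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def planted_db(query, k, seed=21, n_decoys=5, mask_flanks=True):
    """A database of one planted homolog (k mismatches over 80) + decoys."""
    subject = plant_homolog(query, start=30, length=80, mismatches=k,
                            seed=seed, mask_flanks=mask_flanks)
    spec = SyntheticSpec(n_decoys=n_decoys, length_range=(90, 140),
                         seed=seed + 1)
    decoys, _ = gen_decoy_db(spec, queries=[query])
    return [as_entry(subject, name="Syn t 1")] + decoys


class TestEnumerateWindows:
    @pytest.mark.parametrize("length,expected", [(145, 66), (80, 1), (50, 1),
                                                 (81, 2)])
    def test_window_count(self, length, expected):
        seq = "A" * length
        assert len(enumerate_windows(seq)) == expected

    def test_short_query_yields_single_full_length_window(self):
        windows = enumerate_windows("MGAFTEKQEA" * 5)  # 50 residues
        assert windows == [(1, "MGAFTEKQEA" * 5)]

    def test_windows_tile_the_query_with_step_one(self, leghb):
        windows = enumerate_windows(leghb)
        starts = [s for s, _ in windows]
        assert starts == list(range(1, 67))
        assert all(len(w) == 80 for _, w in windows)
        assert windows[0][1] == leghb.sequence[:80]


class TestFullScan:
    def test_identical_entry_is_a_strong_full_length_hit(self, leghb,
                                                         decoy_db, scheme):
        db = [as_entry(ProteinRecord(id="TWIN", sequence=leghb.sequence))] \
            + decoy_db
        cal = calibrate_evalues(leghb, db, scheme, n_shuffles=150, seed=2)
        summary = full_scan(leghb, db, scheme, cal)
        assert summary.n_e1 >= 1
        top = summary.hits[0]
        assert top.subject_id == "TWIN"
        assert top.percent_identity == 100.0
        assert summary.n_id50 == 1

    def test_sub50_homolog_is_hit_but_below_aalberse_line(self, scheme):
        """A clear full-length homolog below 50 % identity is reported as a
        hit yet never counted under the > 50 % cross-reactivity rule.  The
        plant mutates 112/200 positions (44 % positional identity) so that
        the few extra coincidental identities a gapped realignment can
        recover cannot lift it over the line."""
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list(AA20), 200))
        query = ProteinRecord(id="q", sequence=seq)
        from allerscreen.synthetic import mutate_segment
        hom = ProteinRecord(id="HOM44", sequence=mutate_segment(seq, 112, rng))
        spec = SyntheticSpec(n_decoys=6, length_range=(150, 220), seed=18)
        decoys, _ = gen_decoy_db(spec, queries=[query])
        db = [as_entry(hom)] + decoys
        cal = calibrate_evalues(query, db, scheme, n_shuffles=150, seed=3)
        summary = full_scan(query, db, scheme, cal)
        top = summary.hits[0]
        assert top.subject_id == "HOM44"
        assert top.evalue < 1.0
        assert full_length_identity(top) < 50.0
        assert summary.n_id50 == 0

    def test_counts_nest(self, leghb, decoy_db, scheme):
        cal = calibrate_evalues(leghb, decoy_db, scheme, n_shuffles=150,
                                seed=4)
        summary = full_scan(leghb, decoy_db, scheme, cal)
        assert summary.n_e1 <= summary.n_e10 <= len(decoy_db)
        assert summary.n_id50 == 0

    def test_empty_database_rejected(self, leghb, decoy_db, scheme):
        cal = calibrate_evalues(leghb, decoy_db, scheme, n_shuffles=150,
                                seed=4)
        with pytest.raises(ValueError):
            full_scan(leghb, [], scheme, cal)


class TestWindowScan:
    def test_verbatim_planted_80mer_scores_100(self, leghb, scheme):
        db = planted_db(leghb, k=0)
        cal = calibrate_window_scan(leghb, db, scheme, n_shuffles=120, seed=5)
        summary = window_scan(leghb, db, scheme, cal)
        stats = summary.per_allergen["PLANTED"]
        assert stats.best_identity == 100.0
        assert stats.pass_count >= 1
        assert summary.best_subject_id == "PLANTED"

    @pytest.mark.parametrize("k,expected_identity,passes", [
        (52, 35.0, False),   # 28/80 == 35 % exactly: strict threshold, no pass
        (51, 36.25, True),   # 29/80 is the smallest passing fraction
    ])
    def test_strict_35_percent_threshold_boundary(self, leghb, scheme, k,
                                                  expected_identity, passes):
        db = planted_db(leghb, k=k)
        cal = calibrate_window_scan(leghb, db, scheme, n_shuffles=120, seed=6)
        summary = window_scan(leghb, db, scheme, cal)
        stats = summary.per_allergen["PLANTED"]
        assert stats.best_identity == expected_identity
        assert (stats.pass_count >= 1) == passes

    @pytest.mark.parametrize("k", [0, 2, 18, 40, 52])
    def test_planted_identity_recovered_exactly(self, leghb, scheme, k):
        db = planted_db(leghb, k=k, seed=100 + k)
        cal = calibrate_window_scan(leghb, db, scheme, n_shuffles=120, seed=7)
        summary = window_scan(leghb, db, scheme, cal)
        assert summary.per_allergen["PLANTED"].best_identity == \
               pytest.approx(100.0 * (80 - k) / 80, abs=1e-12)

    def test_pass_counts_match_ungapped_slide_oracle(self, leghb, scheme):
        """Per-entry passing-window counts agree with a brute-force oracle
        that slides each window over the subject ungapped.  For the planted
        entry the best identity itself must also agree exactly."""
        db = planted_db(leghb, k=18, n_decoys=4)
        cal = calibrate_window_scan(leghb, db, scheme, n_shuffles=120, seed=8)
        summary = window_scan(leghb, db, scheme, cal)
        for entry in db:
            oracle_count = sum(
                best_ungapped_window_identity(w, entry.record.sequence) > 35.0
                for _, w in enumerate_windows(leghb)
            )
            assert summary.per_allergen[entry.record.id].pass_count == \
                   oracle_count, entry.record.id
        oracle_best = max(
            best_ungapped_window_identity(w, db[0].record.sequence)
            for _, w in enumerate_windows(leghb)
        )
        assert summary.per_allergen["PLANTED"].best_identity == \
               pytest.approx(oracle_best, abs=1e-9)

    def test_adding_an_entry_never_reduces_window_hits(self, leghb, scheme):
        db = planted_db(leghb, k=10)
        cal = calibrate_window_scan(leghb, db, scheme, n_shuffles=120, seed=9)
        small = window_scan(leghb, db[:-1], scheme, cal)
        large = window_scan(leghb, db, scheme, cal)
        for eid, stats in small.per_allergen.items():
            assert large.per_allergen[eid].pass_count >= stats.pass_count


class TestWordScan:
    def test_single_length8_entry_indexes_one_word(self):
        entry = as_entry(ProteinRecord(id="w", sequence="MGAFTEKQ"))
        index = build_word_index([entry])
        assert list(index.words) == ["MGAFTEKQ"]

    def test_homopolymer_has_one_word_with_two_offsets(self):
        entry = as_entry(ProteinRecord(id="polyA", sequence="AAAAAAAAA"))
        index = build_word_index([entry])
        assert index.words == {"AAAAAAAA": [("polyA", 0), ("polyA", 1)]}

    def test_clean_decoys_share_no_8mer_with_leghemoglobin(self, leghb,
                                                           decoy_db):
        index = build_word_index(decoy_db)
        summary = word_scan(leghb, index)
        assert summary.total_hits == 0
        assert all(c == 0 for c in summary.per_allergen.values())

    def test_query_containing_entry_prefix_is_counted(self, decoy_db):
        prefix = decoy_db[0].record.sequence[:8]
        query = ProteinRecord(id="q", sequence=prefix + "MGAFTEKQEALVSSS")
        summary = word_scan(query, build_word_index(decoy_db))
        assert summary.per_allergen[decoy_db[0].record.id] >= 1

    def test_counts_match_naive_substring_oracle(self, scheme):
        rng = np.random.default_rng(31)
        for rep in range(25):
            query = ProteinRecord(
                id="q", sequence="".join(rng.choice(list("ACDE"), 60)))
            entries = [
                as_entry(ProteinRecord(
                    id=f"s{i}",
                    sequence="".join(rng.choice(list("ACDE"), 80))))
                for i in range(5)
            ]
            summary = word_scan(query, build_word_index(entries))
            for e in entries:
                assert summary.per_allergen[e.record.id] == \
                       naive_shared_kmers(query.sequence, e.record.sequence)

    def test_word_positions_are_reported(self):
        entry = as_entry(ProteinRecord(id="s", sequence="WWWMGAFTEKQWWW"))
        query = ProteinRecord(id="q", sequence="MGAFTEKQEALVSSS")
        summary = word_scan(query, build_word_index([entry]))
        (match,) = summary.matches["s"]
        assert match.word == "MGAFTEKQ"
        assert match.query_offsets == [0]
        assert match.subject_offsets == [3]

    def test_short_query_warns_and_returns_zero_counts(self, decoy_db, caplog):
        query = ProteinRecord(id="tiny", sequence="MGAF")
        with caplog.at_level("WARNING"):
            summary = word_scan(query, build_word_index(decoy_db))
        assert summary.total_hits == 0
        assert "shorter than the word size" in caplog.text

    def test_adding_an_entry_never_reduces_word_counts(self, leghb, decoy_db):
        planted = as_entry(plant_homolog(leghb, start=10, length=80,
                                         mismatches=0, seed=77))
        small = word_scan(leghb, build_word_index(decoy_db))
        large = word_scan(leghb, build_word_index(decoy_db + [planted]))
        for eid, count in small.per_allergen.items():
            assert large.per_allergen[eid] >= count
        assert large.per_allergen["PLANTED"] >= 1
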