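import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_fragment, random_seq
from offscreen.fragmentation import dice
from offscreen.homology_search import (TranscriptDb, run_statistics, scan,
                                       search_db)
from offscreen.io_formats import NucleotideSequence, reverse_complement
from offscreen.offtarget_filter import FilterConfig
from oracles import naive_run_statistics, naive_scan


def plant(transcript: str, site: str, offset0: int) -> str:
    return transcript[:offset0] + site + transcript[offset0 + len(site):]


class TestRunStatistics:
    @pytest.mark.parametrize("positions,k,m,expected", [
        ([], 21, 2, (21, 21)),          # perfect match
        ([10], 21, 2, (11, 21)),        # single mid mismatch
        ([2, 8, 15], 21, 2, (6, 19)),   # frozen from the exhaustive oracle
        ([1], 21, 2, (20, 21)),
        ([1, 2, 3], 21, 2, (18, 20)),   # window 2..21 absorbs mismatches 2,3
        ([11], 21, 0, (10, 10)),        # m=0 collapses onto the perfect run
    ])
    def test_known_values(self, positions, k, m, expected):
        assert run_statistics(positions, k, m) == expected
        assert naive_run_statistics(positions, k, m) == expected

    def test_position_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            run_statistics([0], 21, 2)
        with pytest.raises(ValueError, match="out of range"):
            run_statistics([22], 21, 2)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(8, 25), st.data())
    def test_matches_exhaustive_enumeration(self, k, data):
        positions = data.draw(st.lists(st.integers(1, k), unique=True,
                                       max_size=k))
        m = data.draw(st.integers(0, 4))
        assert run_statistics(positions, k, m) == \
            naive_run_statistics(positions, k, m)


class TestScan:
    def test_exact_planting_forward(self, rng):
        frag = make_fragment(random_seq(rng, 21))
        transcript = plant(random_seq(rng, 400), frag.residues, 100)
        hits = scan(frag, NucleotideSequence("t", transcript),
                    min_identities=16)
        exact = [h for h in hits if h.t_start == 101
                 and h.target_strand == "forward"]
        assert len(exact) == 1
        h = exact[0]
        assert (h.identities, h.mismatch_positions,
                h.longest_perfect_run, h.best_near_perfect) == (21, (), 21, 21)
        assert h.t_end == 121

    def test_single_substitution_statistics(self, rng):
        frag = make_fragment(random_seq(rng, 21))
        site = list(frag.residues)
        site[9] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[9]]
        transcript = plant(random_seq(rng, 400), "".join(site), 100)
        hits = scan(frag, NucleotideSequence("t", transcript),
                    min_identities=16)
        h = next(h for h in hits if h.t_start == 101
                 and h.target_strand == "forward")
        assert h.identities == 20
        assert h.mismatch_positions == (10,)
        assert h.longest_perfect_run == 11  # stretch 11-21
        assert h.best_near_perfect == 21

    def test_reverse_strand_guide_coordinates(self, rng):
        """A substitution at guide position 5 of a reverse-planted site is
        reported at guide position 5, not at its transcript-strand offset."""
        frag = make_fragment(random_seq(rng, 21))
        site = list(frag.residues)
        site[4] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[4]]
        planted = reverse_complement("".join(site))
        transcript = plant(random_seq(rng, 300), planted, 50)
        hits = scan(frag, NucleotideSequence("t", transcript),
                    min_identities=18)
        h = next(h for h in hits if h.t_start == 51
                 and h.target_strand == "reverse")
        assert h.identities == 20
        assert h.mismatch_positions == (5,)

    def test_n_counts_as_mismatch_on_either_side(self):
        frag = make_fragment("A" * 21)
        hits = scan(frag, NucleotideSequence("t", "A" * 10 + "N" + "A" * 10),
                    min_identities=15)
        fwd = [h for h in hits if h.target_strand == "forward"]
        assert fwd[0].identities == 20
        assert fwd[0].mismatch_positions == (11,)
        frag_n = make_fragment("A" * 10 + "N" + "A" * 10)
        hits = scan(frag_n, NucleotideSequence("t", "A" * 21),
                    min_identities=15)
        assert [h for h in hits if h.target_strand == "forward"][0].identities == 20

    def test_short_transcript_warns_and_returns_empty(self, caplog):
        frag = make_fragment("A" * 21)
        with caplog.at_level(logging.WARNING):
            hits = scan(frag, NucleotideSequence("t", "ACGT"))
        assert hits == []
        assert "shorter than fragment length" in caplog.text

    def test_hit_ordering(self, rng):
        frag = make_fragment("A" * 21)
        hits = scan(frag, NucleotideSequence("t", "A" * 60),
                    min_identities=15)
        fwd = [h for h in hits if h.target_strand == "forward"]
        assert all(h.identities == 21 for h in fwd)
        # equal identities: ascending t_start
        assert [h.t_start for h in fwd] == sorted(h.t_start for h in fwd)
        assert hits[0].identities == max(h.identities for h in hits)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(21, 400),
           st.integers(12, 21))
    def test_oracle_equivalence(self, seed, tlen, min_identities):
        """scan() equals the naive per-position comparator exactly."""
        rng = np.random.default_rng(seed)
        frag = make_fragment(random_seq(rng, 21))
        transcript = random_seq(rng, tlen)
        hits = scan(frag, NucleotideSequence("t", transcript),
                    min_identities=min_identities)
        got = sorted((h.t_start, h.target_strand, h.identities,
                      h.mismatch_positions) for h in hits)
        assert got == sorted(naive_scan(frag.residues, transcript,
                                        min_identities))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_strand_symmetry(self, seed):
        """Reverse-complementing the transcript flips strand labels and
        mirrors positions but preserves every hit's identities."""
        rng = np.random.default_rng(seed)
        frag = make_fragment(random_seq(rng, 21))
        transcript = random_seq(rng, 150)
        fwd = scan(frag, NucleotideSequence("t", transcript),
                   min_identities=13)
        rev = scan(frag, NucleotideSequence("t",
                                            reverse_complement(transcript)),
                   min_identities=13)
        L = len(transcript)

        def mirror(h):
            return (L - h.t_end + 1,
                    "reverse" if h.target_strand == "forward" else "forward",
                    h.identities, h.mismatch_positions)

        assert sorted(mirror(h) for h in fwd) == \
            sorted((h.t_start, h.target_strand, h.identities,
                    h.mismatch_positions) for h in rev)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_threshold_monotonicity(self, seed):
        """Lowering min_identities never removes a hit."""
        rng = np.random.default_rng(seed)
        frag = make_fragment(random_seq(rng, 21))
        t = NucleotideSequence("t", random_seq(rng, 200))
        strict = {(h.t_start, h.target_strand) for h in
                  scan(frag, t, min_identities=15)}
        loose = {(h.t_start, h.target_strand) for h in
                 scan(frag, t, min_identities=12)}
        assert strict <= loose


class TestSearchDb:
    def test_single_exact_transcript(self, rng):
        frag = make_fragment(random_seq(rng, 21))
        db = TranscriptDb(records=(
            NucleotideSequence("t1", frag.residues),), db_name="tiny")
        hits = search_db([frag], db, FilterConfig())
        fwd = [h for h in hits if h.target_strand == "forward"]
        assert len(fwd) == 1
        assert fwd[0].identities == 21

    def test_duplicate_fragments_deduplicated(self, rng):
        residues = random_seq(rng, 21)
        f1 = make_fragment(residues, index=0)
        f2 = make_fragment(residues, start=5, index=1)  # same 21-mer
        db = TranscriptDb(records=(NucleotideSequence("t1", residues),))
        hits = search_db([f1, f2], db, FilterConfig())
        keys = [(h.fragment.residues, h.transcript_id, h.t_start,
                 h.target_strand) for h in hits]
        assert len(keys) == len(set(keys))
        fwd = [h for h in hits if h.target_strand == "forward"]
        assert len(fwd) == 1

    def test_global_ordering(self, rng, construct_398):
        frags = dice(construct_398)[:40]
        transcript = plant(random_seq(rng, 500), frags[0].residues, 200)
        db = TranscriptDb(records=(
            NucleotideSequence("tB", transcript),
            NucleotideSequence("tA", plant(random_seq(rng, 300),
                                           frags[3].residues, 50)),
        ))
        hits = search_db(frags, db, FilterConfig())
        keys = [(h.transcript_id, h.t_start, h.fragment.fragment_index)
                for h in hits]
        assert keys == sorted(keys)

    def test_empty_database_errors(self, construct_398):
        with pytest.raises(ValueError, match="empty"):
            search_db(dice(construct_398), TranscriptDb(records=()),
                      FilterConfig())

    def test_no_fragments_errors(self):
        db = TranscriptDb(records=(NucleotideSequence("t", "A" * 30),))
        with pytest.raises(ValueError, match="no fragments"):
            search_db([], db, FilterConfig())

    def test_short_transcript_skipped_with_warning(self, rng, caplog):
        frag = make_fragment(random_seq(rng, 21))
        db = TranscriptDb(records=(
            NucleotideSequence("short", "ACGT"),
            NucleotideSequence("long", plant(random_seq(rng, 100),
                                             frag.residues, 40))))
        with caplog.at_level(logging.WARNING):
            hits = search_db([frag], db, FilterConfig())
        assert "short" in caplog.text
        assert any(h.transcript_id == "long" for h in hits)

    def test_duplicate_transcript_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            TranscriptDb(records=(NucleotideSequence("t", "A" * 30),
                                  NucleotideSequence("t", "C" * 30)))
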