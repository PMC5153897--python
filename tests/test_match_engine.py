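"""Window index construction and longest-prefix queries vs the oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nimap as nm
from conftest import random_seq


class TestBuildIndex:
    def test_hand_enumerated_windows_aaaa(self):
        idx = nm.build_index([nm.Genome("b", "AAAA")], nm.IndexConfig(2))
        assert dict(idx.windows) == {"AA": 3, "TT": 3}

    def test_hand_enumerated_windows_with_self_rc_record(self):
        idx = nm.build_index([nm.Genome("b", "ACGTACGT")], nm.IndexConfig(4))
        assert dict(idx.windows) == {"ACGT": 4, "CGTA": 2, "GTAC": 2, "TACG": 2}

    def test_two_identical_records_double_multiplicities(self):
        one = nm.build_index([nm.Genome("b", "ACGTACGT")], nm.IndexConfig(4))
        two = nm.build_index(
            [nm.Genome("b1", "ACGTACGT"), nm.Genome("b2", "ACGTACGT")],
            nm.IndexConfig(4),
        )
        assert dict(two.windows) == {w: 2 * c for w, c in one.windows.items()}

    def test_multiplicity_conservation_closed_form(self):
        rng = np.random.default_rng(3)
        recs = [nm.Genome(f"r{i}", random_seq(rng, int(n)))
                for i, n in enumerate(rng.integers(20, 200, size=4))]
        W = 15
        idx = nm.build_index(recs, nm.IndexConfig(W))
        expected = sum(2 * max(0, len(g) - W + 1) for g in recs)
        assert sum(idx.windows.values()) == expected
        assert idx.total_window_multiplicity == expected

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            nm.build_index([], nm.IndexConfig(10))

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError, match="window"):
            nm.IndexConfig(1)


class TestLongestExtensions:
    def test_exact_worked_examples(self, tiny_index):
        assert nm.longest_exact_extension(tiny_index, "ACGTAAA") == 5
        assert nm.longest_exact_extension(tiny_index, "GACGT") == 1

    def test_query_equal_to_window_returns_full_length(self):
        idx = nm.build_index([nm.Genome("b", "ACGTACGTTT")], nm.IndexConfig(4))
        assert nm.longest_exact_extension(idx, "GTAC") == 4

    def test_onemm_worked_example(self, tiny_index):
        # ACGTAA vs ACGTAC is one substitution; length 7 would need two
        assert nm.longest_onemm_extension(tiny_index, "ACGTAAA") == 6

    def test_single_mismatch_consumes_budget(self):
        idx = nm.build_index([nm.Genome("b", "A" * 40)], nm.IndexConfig(10))
        assert nm.longest_onemm_extension(idx, "CC") == 1

    def test_background_n_never_matches_but_may_consume_budget(self):
        idx = nm.build_index([nm.Genome("b", "ACNTACGG")], nm.IndexConfig(8))
        # exact search must step around the N: prefix ACG occurs at
        # offset 4, not through the N at offset 2
        assert nm.longest_exact_extension(idx, "ACGTACG") == 3
        # with one mismatch the N is consumable: ACGTACG ~ ACNTACG
        assert nm.longest_onemm_extension(idx, "ACGTACG") == 7

    def test_query_n_never_matches_background_n(self):
        idx = nm.build_index([nm.Genome("b", "ACNTACGG")], nm.IndexConfig(8))
        assert nm.longest_exact_extension(idx, "ACNT") == 2
        assert nm.longest_onemm_extension(idx, "ACNT") == 4

    def test_empty_query_rejected(self, tiny_index):
        for fn in (nm.longest_exact_extension, nm.longest_onemm_extension):
            with pytest.raises(ValueError, match="empty"):
                fn(tiny_index, "")

    def test_unit_edit_model_allows_an_indel(self):
        # deleting the extra G aligns the full query; a single
        # substitution cannot rescue the frame shift
        bg = [nm.Genome("b", "CCCCACGTCCCC")]
        sub = nm.build_index(bg, nm.IndexConfig(12, "substitution"))
        ed = nm.build_index(bg, nm.IndexConfig(12, "unit_edit"))
        assert nm.longest_onemm_extension(sub, "ACGGTC") == 4
        assert nm.longest_onemm_extension(ed, "ACGGTC") == 6


class TestCountSimilar:
    def test_hand_counts(self):
        idx = nm.build_index([nm.Genome("b", "AAAA")], nm.IndexConfig(4))
        assert nm.count_similar_occurrences(idx, "AA", 0) == 3
        assert nm.count_similar_occurrences(idx, "AT", 1) == 6

    def test_absent_with_zero_budget(self):
        idx = nm.build_index([nm.Genome("b", "AAAA")], nm.IndexConfig(4))
        assert nm.count_similar_occurrences(idx, "CG", 0) == 0


class TestOracle:
    def test_verbatim_query_returns_full_length(self):
        bg = [nm.Genome("b", "TTGATTACATT")]
        assert nm.oracle_longest_extension(bg, "GATTACA", 0) == 7

    def test_budget_one_at_least_budget_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            bg = [nm.Genome("b", random_seq(rng, 300))]
            q = random_seq(rng, int(rng.integers(1, 40)))
            assert nm.oracle_longest_extension(bg, q, 1) >= \
                nm.oracle_longest_extension(bg, q, 0)

    @pytest.mark.parametrize("model", ["substitution", "unit_edit"])
    def test_index_agrees_with_oracle_randomized(self, model):
        rng = np.random.default_rng(99)
        for trial in range(60):
            with_n = model == "substitution" and trial % 3 == 0
            bg_seq = random_seq(rng, int(rng.integers(60, 1200)), with_n)
            bg = [nm.Genome("b", bg_seq)]
            if trial % 2 == 0:
                i = int(rng.integers(0, len(bg_seq)))
                q = (bg_seq[i : i + int(rng.integers(1, 55))]
                     + random_seq(rng, 8)).replace("N", "A")[:60]
            else:
                q = random_seq(rng, int(rng.integers(1, 60)))
            idx = nm.build_index(bg, nm.IndexConfig(450, model))
            assert nm.longest_exact_extension(idx, q) == \
                nm.oracle_longest_extension(bg, q, 0)
            assert nm.longest_onemm_extension(idx, q) == \
                nm.oracle_longest_extension(bg, q, 1, model)


class TestProperties:
    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_strand_symmetry(self, seed):
        """Reverse-complementing every background record leaves all query
        results unchanged."""
        rng = np.random.default_rng(seed)
        bg = [nm.Genome("b", random_seq(rng, int(rng.integers(50, 400))))]
        bg_rc = [g.reverse_complement() for g in bg]
        q = random_seq(rng, int(rng.integers(1, 40)))
        for model in ("substitution", "unit_edit"):
            a = nm.build_index(bg, nm.IndexConfig(450, model))
            b = nm.build_index(bg_rc, nm.IndexConfig(450, model))
            assert nm.longest_exact_extension(a, q) == \
                nm.longest_exact_extension(b, q)
            assert nm.longest_onemm_extension(a, q) == \
                nm.longest_onemm_extension(b, q)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_prefix_and_budget_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        bg = [nm.Genome("b", random_seq(rng, 300))]
        idx = nm.build_index(bg, nm.IndexConfig(450))
        q = random_seq(rng, int(rng.integers(2, 50)))
        p = q[: int(rng.integers(1, len(q)))]
        assert nm.longest_exact_extension(idx, p) <= \
            nm.longest_exact_extension(idx, q)
        assert nm.longest_onemm_extension(idx, p) <= \
            nm.longest_onemm_extension(idx, q)
        assert nm.longest_onemm_extension(idx, q) >= \
            nm.longest_exact_extension(idx, q)

    def test_results_independent_of_record_order(self):
        rng = np.random.default_rng(5)
        recs = [nm.Genome(f"r{i}", random_seq(rng, 150)) for i in range(3)]
        q = random_seq(rng, 30)
        a = nm.build_index(recs, nm.IndexConfig(100))
        b = nm.build_index(recs[::-1], nm.IndexConfig(100))
        assert nm.longest_exact_extension(a, q) == nm.longest_exact_extension(b, q)
        assert dict(a.windows) == dict(b.windows)


class TestSerialization:
    def test_index_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        bg = [nm.Genome("b", random_seq(rng, 200, with_n=True))]
        idx = nm.build_index(bg, nm.IndexConfig(50))
        p = tmp_path / "bg.idx.npz"
        nm.save_index(idx, p)
        back = nm.load_index(p)
        assert back.config == idx.config and back.records == idx.records
        q = random_seq(rng, 25)
        assert nm.longest_onemm_extension(back, q) == \
            nm.longest_onemm_extension(idx, q)
        assert dict(back.windows) == dict(idx.windows)
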