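"""Stoichiometry parsing, pairing enumeration, species linking, M-score."""

import itertools

import pytest

from msaforge import fixtures, multimer
from msaforge.errors import StoichiometryError
from msaforge.fixtures import MockPredictor, make_complex_fixture
from msaforge.msa_io import Msa, SeqRecord
from msaforge.multimer import (
    PairedMsa,
    concat_homomer,
    enumerate_pairings,
    link_heteromer,
    m_score,
    pairing_depth,
    parse_stoichiometry,
    run_multimer,
    select_paired,
)


class TestStoichiometry:
    def test_three_chain_example(self):
        st = parse_stoichiometry("A2B2C1")
        assert st.N == 3
        assert [n for _, n in st.chains] == [2, 2, 1]
        assert not st.is_homomer

    def test_homomer_octamer(self):
        st = parse_stoichiometry("A8")
        assert st.is_homomer and st.chains[0][1] == 8

    @pytest.mark.parametrize("bad", ["2A", "", "A", "A2B", "A0"])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(StoichiometryError):
            parse_stoichiometry(bad)

    def test_round_trips(self):
        for s in ("A2B2C1", "A8", "A1B1", "A3B1"):
            assert parse_stoichiometry(s).format() == s

    def test_duplicate_chain_rejected(self):
        with pytest.raises(StoichiometryError):
            parse_stoichiometry("A2A1")


class TestPairingDepth:
    @pytest.mark.parametrize("N,expected", [(3, 4), (2, 10), (7, 1)])
    def test_reference_values(self, N, expected):
        assert pairing_depth(N) == expected

    @pytest.mark.parametrize("N", range(1, 9))
    def test_matches_brute_force(self, N):
        budget, available = 100, 10
        feasible = [m for m in range(1, budget + 1) if m ** N <= budget]
        expected = min(available, max(feasible)) if feasible else 1
        m = pairing_depth(N, budget, available)
        assert m == max(1, expected)
        assert m ** N <= budget or m == 1

    def test_capped_by_availability(self):
        assert pairing_depth(2, available=3) == 3


class TestEnumeratePairings:
    def test_heterotrimer_yields_64(self):
        st = parse_stoichiometry("A2B2C1")
        chain_set, _ = make_complex_fixture(
            st, {"9606": {"A": 1, "B": 1, "C": 1}}, seed=1, candidates_per_chain=5)
        M = pairing_depth(st.N)
        combos = enumerate_pairings(chain_set, M)
        assert len(combos) == 64
        assert combos == sorted(combos)  # lexicographic

    def test_single_chain_degenerate(self):
        chain_set, _ = make_complex_fixture(
            parse_stoichiometry("A1"), {"9606": {"A": 1}}, seed=2, candidates_per_chain=4)
        assert len(enumerate_pairings(chain_set, 4)) == 4

    def test_m_one_takes_top_only(self):
        chain_set, _ = make_complex_fixture(
            parse_stoichiometry("A1B1"), {"9606": {"A": 1, "B": 1}}, seed=3,
            candidates_per_chain=2)
        assert enumerate_pairings(chain_set, 1) == [(0, 0)]

    def test_m_lowered_to_minimum_available(self):
        chain_set, _ = make_complex_fixture(
            parse_stoichiometry("A1B1"), {"9606": {"A": 1, "B": 1}}, seed=4,
            candidates_per_chain=2)
        assert len(enumerate_pairings(chain_set, 10)) == 4


def _chain_msa(chain, query, homologs):
    """homologs: list of (id, seq, species)."""
    records = [SeqRecord(id=f"{chain}_q", aligned_seq=query)]
    records += [
        SeqRecord(id=i, aligned_seq=s, species_key=sp) for i, s, sp in homologs
    ]
    return Msa(records)


class TestLinkHeteromer:
    def test_minimal_shared_species_links_one_row(self):
        st = parse_stoichiometry("A1B1")
        choice = {
            "A": _chain_msa("A", "ACDE", [("a1", "ACDF", "s1")]),
            "B": _chain_msa("B", "GHIK", [("b1", "GHIL", "s1")]),
        }
        paired = link_heteromer(choice, st)
        assert paired.linked_rows == 1
        assert paired.msa.N == 2  # query + 1 linked
        assert paired.msa.records[1].aligned_seq == "ACDFGHIL"

    def test_disjoint_species_all_padded(self):
        st = parse_stoichiometry("A1B1")
        choice = {
            "A": _chain_msa("A", "ACDE", [("a1", "ACDF", "s1")]),
            "B": _chain_msa("B", "GHIK", [("b1", "GHIL", "s2")]),
        }
        paired = link_heteromer(choice, st)
        assert paired.linked_rows == 0
        assert paired.msa.N == 3
        seqs = {r.aligned_seq for r in paired.msa.homologs}
        assert seqs == {"ACDF----", "----GHIL"}

    def test_rank_matched_depth_with_leftover(self):
        # s1: 2 members in A, 1 in B -> one linked row; A's rank-2 s1 member
        # and A's s2-only member stay unlinked
        st = parse_stoichiometry("A1B1")
        choice = {
            "A": _chain_msa("A", "ACDE", [
                ("a1", "ACDF", "s1"),   # identity 0.75 -> rank 1 in s1
                ("a2", "ACGG", "s1"),   # identity 0.50 -> rank 2 in s1
                ("a3", "AGGG", "s2"),
            ]),
            "B": _chain_msa("B", "GHIK", [("b1", "GHIL", "s1")]),
        }
        paired = link_heteromer(choice, st)
        assert paired.linked_rows == 1
        assert paired.msa.records[1].aligned_seq == "ACDFGHIL"
        unlinked = {r.aligned_seq for r in paired.msa.records[2:]}
        assert unlinked == {"ACGG----", "AGGG----"}

    def test_species_in_two_of_three_chains_pads_the_third(self):
        st = parse_stoichiometry("A1B1C1")
        choice = {
            "A": _chain_msa("A", "ACDE", [("a1", "ACDF", "s1")]),
            "B": _chain_msa("B", "GHIK", [("b1", "GHIL", "s1")]),
            "C": _chain_msa("C", "MNPQ", []),
        }
        paired = link_heteromer(choice, st)
        assert paired.linked_rows == 1
        assert paired.msa.records[1].aligned_seq == "ACDFGHIL----"

    def test_copy_counts_repeat_chain_blocks(self):
        st = parse_stoichiometry("A2B1")
        choice = {
            "A": _chain_msa("A", "ACDE", [("a1", "ACDF", "s1")]),
            "B": _chain_msa("B", "GHIK", [("b1", "GHIL", "s1")]),
        }
        paired = link_heteromer(choice, st)
        assert paired.msa.L == 2 * 4 + 4
        assert paired.msa.records[1].aligned_seq == "ACDFACDFGHIL"
        assert paired.chain_spans == [
            {"chain": "A", "copy": 0, "start": 0, "stop": 4},
            {"chain": "A", "copy": 1, "start": 4, "stop": 8},
            {"chain": "B", "copy": 0, "start": 8, "stop": 12},
        ]

    def test_unannotated_rows_are_never_linked(self):
        st = parse_stoichiometry("A1B1")
        choice = {
            "A": _chain_msa("A", "ACDE", [("a1", "ACDF", None)]),
            "B": _chain_msa("B", "GHIK", [("b1", "GHIL", None)]),
        }
        paired = link_heteromer(choice, st)
        assert paired.linked_rows == 0
        assert paired.msa.N == 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_row_conservation_and_constant_length(self, seed):
        st = parse_stoichiometry("A2B1C1")
        overlap = {
            "9606": {"A": 2, "B": 1, "C": 1},
            "10090": {"A": 1, "B": 2},
            "559292": {"C": 1},
        }
        chain_set, expected = make_complex_fixture(
            st, overlap, seed=seed, n_unannotated=1)
        choice = {cid: chain_set[cid][0].msa for cid in st.chain_ids}
        paired = link_heteromer(choice, st)
        assert paired.linked_rows == expected
        n_homologs = sum(choice[cid].N - 1 for cid in st.chain_ids)
        # every homolog appears exactly once: linked rows merge one per chain
        n_merged = sum(
            len(r.id.split("|")) for r in paired.msa.homologs if "|" in r.id)
        n_single = sum(1 for r in paired.msa.homologs if "|" not in r.id)
        assert n_merged + n_single == n_homologs
        total_L = sum(choice[cid].L * st.copies[cid] for cid in st.chain_ids)
        assert all(r.n_match_columns == total_L for r in paired.msa.records)

    def test_link_depth_one_caps_shared_species(self):
        st = parse_stoichiometry("A1B1")
        choice = {
            "A": _chain_msa("A", "ACDE", [("a1", "ACDF", "s1"), ("a2", "ACGG", "s1")]),
            "B": _chain_msa("B", "GHIK", [("b1", "GHIL", "s1"), ("b2", "GHLL", "s1")]),
        }
        full = link_heteromer(choice, st)
        capped = link_heteromer(choice, st, link_depth=1)
        assert full.linked_rows == 2
        assert capped.linked_rows == 1


class TestConcatHomomer:
    def test_dimensions(self):
        msa = fixtures.diverse_msa(5, 50, seed=10)
        paired = concat_homomer(msa, 3)
        assert paired.msa.L == 150
        assert paired.msa.N == 5
        assert paired.msa.query.id == msa.query.id

    def test_block_slices_reproduce_the_monomer(self):
        msa = fixtures.diverse_msa(4, 12, seed=11)
        paired = concat_homomer(msa, 2)
        for span in paired.chain_spans:
            for rec, orig in zip(paired.msa.records, msa.records):
                assert rec.match_columns[span["start"]:span["stop"]] == orig.match_columns

    def test_needs_at_least_two_copies(self):
        with pytest.raises(ValueError):
            concat_homomer(fixtures.diverse_msa(3, 10, seed=12), 1)


def _dummy_paired(neff_value):
    msa = Msa([SeqRecord(id="q", aligned_seq="ACDE")])
    return PairedMsa(msa=msa, component_choice=(0,), linked_rows=0, neff=neff_value)


class TestMScore:
    def test_unit_confidences_reduce_to_neff(self):
        st = parse_stoichiometry("A2B1")
        paired = _dummy_paired(3.7)
        assert m_score(paired, {"A": 1.0, "B": 1.0}, st) == pytest.approx(3.7)

    def test_copy_weighted_hand_value(self):
        st = parse_stoichiometry("A2B1")
        paired = _dummy_paired(2.0)
        assert m_score(paired, {"A": 0.8, "B": 0.5}, st) == pytest.approx(1.4)

    def test_zero_confidences_give_zero(self):
        st = parse_stoichiometry("A1B1")
        assert m_score(_dummy_paired(9.0), {"A": 0.0, "B": 0.0}, st) == 0.0

    def test_monotone_in_each_confidence_and_linear_in_neff(self):
        st = parse_stoichiometry("A2B1")
        lo = m_score(_dummy_paired(2.0), {"A": 0.4, "B": 0.5}, st)
        hi = m_score(_dummy_paired(2.0), {"A": 0.6, "B": 0.5}, st)
        assert hi > lo
        assert m_score(_dummy_paired(4.0), {"A": 0.4, "B": 0.5}, st) == pytest.approx(2 * lo)

    def test_out_of_range_confidence_rejected(self):
        st = parse_stoichiometry("A1")
        with pytest.raises(ValueError):
            m_score(_dummy_paired(1.0), {"A": 1.2}, st)


class TestSelectPaired:
    def _paired_list(self, n, seed=0):
        out = []
        for i in range(n):
            p = _dummy_paired(float(n - i))
            p.component_choice = (i,)
            p.m_score = float(n - i)
            out.append(p)
        return out

    def test_heteromer_keeps_top_25_of_64(self):
        st = parse_stoichiometry("A2B2C1")
        kept = select_paired(self._paired_list(64), st)
        assert len(kept) == 25
        assert [p.m_score for p in kept] == sorted(
            (p.m_score for p in kept), reverse=True)

    def test_homomer_passthrough(self):
        st = parse_stoichiometry("A3")
        assert len(select_paired(self._paired_list(10), st)) == 10

    def test_fewer_than_k_all_kept(self):
        st = parse_stoichiometry("A1B1")
        assert len(select_paired(self._paired_list(20), st)) == 20

    def test_input_order_does_not_change_selection(self):
        st = parse_stoichiometry("A1B1")
        items = self._paired_list(40)
        kept_fwd = select_paired(items, st)
        kept_rev = select_paired(list(reversed(items)), st)
        assert {p.component_choice for p in kept_fwd} == \
            {p.component_choice for p in kept_rev}


class TestRunMultimer:
    def test_heteromer_generates_625_models(self):
        st = parse_stoichiometry("A1B1")
        overlap = {"9606": {"A": 2, "B": 2}, "10090": {"A": 1, "B": 1}}
        chain_set, _ = make_complex_fixture(st, overlap, seed=20, candidates_per_chain=10)
        result = run_multimer(chain_set, st, MockPredictor())
        assert result.n_generated == 625
        assert len(result.models) == 5
        assert len(result.paired_msas) == 25

    def test_homomer_generates_250_models(self):
        st = parse_stoichiometry("A3")
        chain_set, _ = make_complex_fixture(st, {"9606": {"A": 2}}, seed=21,
                                            candidates_per_chain=10)
        result = run_multimer(chain_set, st, MockPredictor())
        assert result.n_generated == 250
        assert len(result.models) == 5

    def test_final_k_larger_than_generated_returns_all(self):
        st = parse_stoichiometry("A2")
        chain_set, _ = make_complex_fixture(st, {"9606": {"A": 1}}, seed=22,
                                            candidates_per_chain=1)
        result = run_multimer(chain_set, st, MockPredictor(), models_per_msa=3,
                              final_k=100)
        assert result.n_generated == 3
        assert len(result.models) == 3

    def test_models_sorted_by_predicted_tm(self):
        st = parse_stoichiometry("A1B1")
        chain_set, _ = make_complex_fixture(st, {"9606": {"A": 1, "B": 1}}, seed=23,
                                            candidates_per_chain=3)
        result = run_multimer(chain_set, st, MockPredictor())
        tms = [m.predicted_tm for m in result.models]
        assert tms == sorted(tms, reverse=True)

    def test_predictor_failure_skips_msa_with_diagnostic(self):
        class FlakyPredictor(MockPredictor):
            def predict(self, paired, count):
                if paired.component_choice == (0, 0):
                    raise RuntimeError("boom")
                return super().predict(paired, count)

        st = parse_stoichiometry("A1B1")
        chain_set, _ = make_complex_fixture(st, {"9606": {"A": 1, "B": 1}}, seed=24,
                                            candidates_per_chain=2)
        result = run_multimer(chain_set, st, FlakyPredictor(), models_per_msa=2)
        assert result.diagnostics
        assert result.n_generated == (4 - 1) * 2
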