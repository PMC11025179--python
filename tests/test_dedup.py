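"""Deduplication pipelines: greedy MIS admission, baselines, cross-method agreement."""

import numpy as np
import pytest

from wildtrie import (
    SeqRecord,
    dedup,
    dedup_exact,
    dedup_pairwise,
    dedup_trie,
    exact_collapse,
    seq_equivalent,
    sort_by_ambiguity,
)
from tests.conftest import make_instance


def records_of(seqs):
    return [SeqRecord(f"r{i}", s, input_rank=i) for i, s in enumerate(seqs)]


def assert_valid_mis(result, records):
    """The representative set must be a maximal independent set of the
    equivalence graph: pairwise non-equivalent, and every input equivalent to
    its assigned representative."""
    reps = result.representatives
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            assert not seq_equivalent(reps[i].seq, reps[j].seq)
    seq_of = {r.read_id: r.seq for r in records}
    rep_seq = {r.read_id: r.seq for r in reps}
    for rid, rep in result.assignment.items():
        assert seq_equivalent(seq_of[rid], rep_seq[rep])


class TestExactCollapse:
    def test_groups_identical_strings(self):
        uniques, assign, mult = exact_collapse(records_of(["TAC", "TAC", "TNC"]))
        assert [u.seq for u in uniques] == ["TAC", "TNC"]
        assert mult == {"r0": 2, "r2": 1}
        assert assign == {"r0": "r0", "r1": "r0", "r2": "r2"}

    def test_identical_wildcards_do_collapse(self):
        uniques, _, mult = exact_collapse(records_of(["TNC", "TNC"]))
        assert len(uniques) == 1 and mult == {"r0": 2}

    def test_all_distinct_is_identity(self):
        uniques, assign, _ = exact_collapse(records_of(["AA", "AC", "AG"]))
        assert len(uniques) == 3
        assert all(k == v for k, v in assign.items())


class TestSortByAmbiguity:
    def test_ascending_with_stable_ties(self):
        recs = records_of(["TNC", "TAC", "NNC", "GGG"])
        for r in recs:
            r.n_ambiguous = r.seq.count("N")
        assert [r.read_id for r in sort_by_ambiguity(recs)] == ["r1", "r3", "r0", "r2"]


class TestToyGraph:
    """The path graph TAC - TNC - TGC has two MIS flavours; the ascending-N
    preference picks the wildcard-free tips."""

    @pytest.mark.parametrize("method", ["trie", "pairwise"])
    @pytest.mark.parametrize(
        "order", [("TAC", "TNC", "TGC"), ("TNC", "TAC", "TGC"), ("TGC", "TNC", "TAC")]
    )
    def test_tips_win_in_any_input_order(self, method, order):
        result = dedup(records_of(order), method=method)
        assert {r.seq for r in result.representatives} == {"TAC", "TGC"}

    @pytest.mark.parametrize("method", ["trie", "pairwise"])
    def test_forced_order_yields_center_mis(self, method):
        # admitting the ambiguous read first collapses both tips onto it
        result = dedup(records_of(["TNC", "TAC", "TGC"]), method=method, presorted=True)
        assert [r.seq for r in result.representatives] == ["TNC"]
        assert result.multiplicity == {"r0": 3}

    def test_singleton_ambiguous_read_is_admitted(self):
        result = dedup_trie(records_of(["TNC"]))
        assert [r.seq for r in result.representatives] == ["TNC"]


class TestResultInvariants:
    @pytest.mark.parametrize("method", ["trie", "pairwise", "exact"])
    def test_bookkeeping_totals(self, rng, method):
        records = make_instance(rng, 120, 12, wc_frac=0.1)
        result = dedup(records, method=method)
        assert set(result.assignment) == {r.read_id for r in records}
        assert sum(result.multiplicity.values()) == len(records)
        assert set(result.multiplicity) == {r.read_id for r in result.representatives}
        for rep in result.representatives:
            assert result.assignment[rep.read_id] == rep.read_id

    @pytest.mark.parametrize("method", ["trie", "pairwise"])
    def test_result_is_maximal_independent_set(self, rng, method):
        records = make_instance(rng, 80, 8, wc_frac=0.15)
        assert_valid_mis(dedup(records, method=method), records)

    def test_representative_never_more_ambiguous_than_duplicate(self, rng):
        records = make_instance(rng, 150, 10, wc_frac=0.15)
        result = dedup_trie(records)
        n_of = {r.read_id: r.seq.count("N") for r in records}
        for rid, rep in result.assignment.items():
            assert n_of[rep] <= n_of[rid]

    def test_empty_input(self):
        result = dedup_trie([])
        assert result.representatives == [] and result.assignment == {}

    def test_idempotent_on_own_representatives(self, rng):
        records = make_instance(rng, 100, 10, wc_frac=0.1)
        first = dedup_trie(records)
        again = dedup_trie(first.representatives)
        assert [r.read_id for r in again.representatives] == [
            r.read_id for r in first.representatives
        ]


class TestMethodAgreement:
    def test_trie_equals_pairwise_randomized(self, rng):
        for _ in range(150):
            n = int(rng.integers(2, 200))
            length = int(rng.integers(5, 31))
            frac = float(rng.choice([0.0, 0.05, 0.1, 0.2]))
            records = make_instance(rng, n, length, wc_frac=frac)
            a = dedup_trie(records)
            b = dedup_pairwise(records)
            assert [r.read_id for r in a.representatives] == [
                r.read_id for r in b.representatives
            ]
            assert a.assignment == b.assignment
            assert a.multiplicity == b.multiplicity

    def test_wildcard_free_input_matches_exact(self, rng):
        records = make_instance(rng, 200, 8, wc_frac=0.0)
        t = dedup_trie(records)
        p = dedup_pairwise(records)
        e = dedup_exact(records)
        for other in (p, e):
            assert {r.seq for r in t.representatives} == {
                r.seq for r in other.representatives
            }
            assert t.assignment == other.assignment

    def test_exact_never_smaller_than_trie(self, rng):
        for _ in range(30):
            records = make_instance(rng, 100, 10, wc_frac=0.1)
            assert len(dedup_exact(records)) >= len(dedup_trie(records))


class TestScalingCounters:
    def test_pairwise_work_grows_quadratically_trie_slower(self, rng):
        # hardware-free scaling: equivalence calls vs trie node visits
        from wildtrie import SimConfig, loglog_slope, simulate_reads

        ns = [100, 400, 1600]
        comps, visits = [], []
        for i, n in enumerate(ns):
            cfg = SimConfig(
                n_parents=n, n_reads=n, read_length=60, mask_fraction=0.05, seed=10 + i
            )
            recs, _ = simulate_reads(cfg)
            comps.append(dedup_pairwise(recs).stats.comparisons)
            visits.append(dedup_trie(recs).stats.node_visits)
        assert 1.6 <= loglog_slope(ns, comps) <= 2.4
        assert loglog_slope(ns, visits) < loglog_slope(ns, comps)
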