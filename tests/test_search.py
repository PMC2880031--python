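"""Local-similarity search and the g1/g2 best-HSP selection rule."""

import itertools
import random

import numpy as np
import pytest

from ligmotif.core import Interval, revcomp
from ligmotif.errors import SearchError
from ligmotif.refdb import RefDB, RefDbEntry
from ligmotif.search import (
    HSP,
    SearchParams,
    blastn_available,
    compare_hsps,
    filter_hsps,
    local_search,
)


def _random_seq(rng, n):
    return "".join("acgt"[i] for i in rng.integers(0, 4, n))


def _db_with(label, seq, id="ref1"):
    db = RefDB()
    db.add(label, RefDbEntry(id, seq))
    return db


def _mk(label="V-EXON", start=0, end=100, score=50.0, evalue=1e-10,
        identity=100.0, strand="+", subject="s"):
    return HSP(
        query_interval=Interval(start, end), strand=strand, label=label,
        subject_id=subject, score=score, evalue=evalue, identity=identity,
        length=end - start,
    )


PARAMS = SearchParams(backend="internal")


class TestLocalSearch:
    def test_exact_planted_copy_found_with_full_coverage(self):
        rng = np.random.default_rng(0)
        ref = _random_seq(rng, 120)
        query = _random_seq(rng, 500) + ref + _random_seq(rng, 500)
        hits = local_search(query, _db_with("L-PART1", ref), PARAMS)
        best = max(hits, key=lambda h: h.score)
        assert best.label == "L-PART1"
        assert best.strand == "+"
        assert best.identity == 100.0
        planted = Interval(500, 620)
        got = best.query_interval.intersect(planted)
        assert got is not None and len(got) >= 0.9 * len(planted)
        assert best.subject_interval == Interval(0, best.length)

    def test_reverse_complement_mirrors_coordinates(self):
        rng = np.random.default_rng(1)
        ref = _random_seq(rng, 80)
        query = _random_seq(rng, 300) + ref + _random_seq(rng, 200)
        fwd = max(local_search(query, _db_with("J-REGION", ref), PARAMS),
                  key=lambda h: h.score)
        rev = max(local_search(revcomp(query), _db_with("J-REGION", ref), PARAMS),
                  key=lambda h: h.score)
        assert rev.strand == "-"
        assert rev.score == fwd.score
        assert rev.query_interval == fwd.query_interval.mirror(len(query))

    def test_random_query_yields_no_long_hsps(self):
        rng = np.random.default_rng(2)
        query = _random_seq(rng, 1000)
        ref = _random_seq(np.random.default_rng(3), 300)
        hits = local_search(query, _db_with("V-REGION", ref), PARAMS)
        assert all(h.length < 30 for h in hits)

    def test_evalue_threshold_respected_per_label(self):
        rng = np.random.default_rng(4)
        ref = _random_seq(rng, 40)
        query = _random_seq(rng, 400) + ref + _random_seq(rng, 400)
        db = RefDB()
        db.add("D-REGION", RefDbEntry("d", ref[:16]))
        hits = local_search(query, db, PARAMS)
        assert all(h.evalue <= PARAMS.evalue_threshold_d for h in hits)

    def test_empty_inputs_raise(self):
        with pytest.raises(SearchError):
            local_search("", _db_with("V-EXON", "acgtacgt"), PARAMS)
        with pytest.raises(SearchError):
            local_search("acgtacgt", RefDB(), PARAMS)

    @pytest.mark.skipif(not blastn_available(), reason="blastn not on PATH")
    def test_blastn_backend_agrees_on_planted_copy(self):
        rng = np.random.default_rng(6)
        ref = _random_seq(rng, 150)
        query = _random_seq(rng, 400) + ref + _random_seq(rng, 400)
        db = _db_with("V-EXON", ref)
        internal = max(local_search(query, db, PARAMS), key=lambda h: h.score)
        external = max(
            local_search(query, db, SearchParams(backend="blastn")),
            key=lambda h: h.score,
        )
        assert external.label == internal.label
        assert external.strand == internal.strand
        inter = external.query_interval.intersect(internal.query_interval)
        assert inter is not None and len(inter) >= 0.9 * 150


class TestCompareHsps:
    def test_better_score_and_evalue_removes_other(self):
        h1 = _mk(score=100, evalue=1e-30)
        h2 = _mk(score=80, evalue=1e-20, start=50, end=150)
        g1, g2, removed = compare_hsps(h1, h2)
        assert g1 == 2 and removed is h2

    def test_full_tie_removes_second(self):
        h1, h2 = _mk(), _mk(start=10, end=110)
        g1, g2, removed = compare_hsps(h1, h2)
        assert (g1, g2) == (0, 0) and removed is h2

    def test_g1_zero_defers_to_g2(self):
        h1 = _mk(score=50, evalue=1e-10, end=80, identity=90.0)
        h2 = _mk(score=50, evalue=1e-10, start=40, end=140, identity=95.0)
        g1, g2, removed = compare_hsps(h1, h2)
        assert g1 == 0 and g2 == -2 and removed is h1

    def test_decision_table_over_all_comparator_outcomes(self):
        """All 3^4 comparator combinations against the rule as written."""
        base = dict(score=50.0, evalue=1e-10, identity=90.0)
        deltas = {-1: -1, 0: 0, 1: 1}
        for cs, ce, cl, ci in itertools.product((-1, 0, 1), repeat=4):
            h1 = _mk(start=0, end=100 + 10 * deltas[cl], score=base["score"] + cs,
                     evalue=base["evalue"] * 10 ** (-ce), identity=base["identity"] + ci)
            h2 = _mk(start=50, end=150, score=base["score"],
                     evalue=base["evalue"], identity=base["identity"])
            h2 = HSP(**{**h2.__dict__, "length": 100})
            g1, g2, removed = compare_hsps(h1, h2)
            assert g1 == cs + ce
            assert g2 == cl + ci
            expect_h2 = g1 > 0 or (g1 == 0 and g2 >= 0)
            assert (removed is h2) == expect_h2

    def test_contract_violations(self):
        with pytest.raises(SearchError):
            compare_hsps(_mk(label="V-EXON"), _mk(label="V-REGION"))
        with pytest.raises(SearchError):
            compare_hsps(_mk(start=0, end=10), _mk(start=20, end=30))


def _consistent_hsps(rng, n, label="V-EXON"):
    """Overlapping HSPs with jointly consistent statistics (higher score ==
    lower E-value == longer == more identical), making elimination
    order-independent."""
    out = []
    ranks = rng.permutation(n)
    for i in range(n):
        r = int(ranks[i])
        start = int(rng.integers(0, 40))
        out.append(
            _mk(label=label, start=start, end=start + 61 + 3 * r,
                score=float(100 + 10 * r), evalue=10.0 ** -(10 + r),
                identity=80.0 + r)
        )
    return out


def brute_force_eliminate(hsps):
    """Repeatedly remove the loser of any overlapping same-label pair until
    stable, scanning pairs in input order."""
    active = list(hsps)
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(list(active), 2):
            if a in active and b in active and a.label == b.label \
                    and a.strand == b.strand and a.overlaps(b):
                _, _, removed = compare_hsps(a, b)
                active.remove(removed)
                changed = True
    return set((h.query_interval, h.score) for h in active)


class TestFilterHsps:
    def test_three_overlapping_best_survives(self):
        hsps = [_mk(score=90, start=0, end=100),
                _mk(score=95, start=20, end=120),
                _mk(score=99, start=40, end=140)]
        survivors = filter_hsps(hsps)
        assert len(survivors) == 1 and survivors[0].score == 99

    def test_different_databases_never_filtered(self):
        hsps = [_mk(label="V-EXON"), _mk(label="V-REGION", start=10, end=90)]
        assert len(filter_hsps(hsps)) == 2

    def test_different_strands_never_filtered(self):
        hsps = [_mk(strand="+"), _mk(strand="-", start=10, end=90)]
        assert len(filter_hsps(hsps)) == 2

    def test_empty_input(self):
        assert filter_hsps([]) == []

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        hsps = _consistent_hsps(rng, 6)
        once = filter_hsps(hsps)
        assert filter_hsps(once) == once

    def test_matches_brute_force_on_small_inputs(self):
        rng = np.random.default_rng(8)
        for trial in range(30):
            hsps = _consistent_hsps(rng, int(rng.integers(2, 7)))
            got = set(
                (h.query_interval, h.score) for h in filter_hsps(hsps)
            )
            assert got == brute_force_eliminate(hsps), f"trial {trial}"

    def test_order_robust_with_distinct_statistics(self):
        rng = np.random.default_rng(9)
        hsps = _consistent_hsps(rng, 6)
        reference = set((h.query_interval, h.score) for h in filter_hsps(hsps))
        shuffler = random.Random(11)
        for _ in range(10):
            shuffled = list(hsps)
            shuffler.shuffle(shuffled)
            got = set((h.query_interval, h.score) for h in filter_hsps(shuffled))
            assert got == reference

    def test_surviving_same_database_hsps_do_not_overlap(self, small_locus):
        hsps = local_search(
            small_locus.sequence[:5000], small_locus.refdb, PARAMS
        )
        survivors = filter_hsps(hsps)
        by_group = {}
        for h in survivors:
            by_group.setdefault((h.label, h.strand), []).append(h)
        for group in by_group.values():
            group.sort(key=lambda h: h.query_interval)
            for a, b in zip(group, group[1:]):
                assert not a.overlaps(b)
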