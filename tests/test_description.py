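"""Gene description: combinations, CMSA, motif search, solutions, anchors."""

import itertools

import numpy as np
import pytest

from ligmotif.core import Interval, revcomp
from ligmotif.description import (
    Cmsa,
    DescriptionSettings,
    MotifMatch,
    STATUS_DESCRIBED,
    STATUS_UNDESCRIBED,
    delimit_cmsa,
    delimit_from_anchors,
    describe_gene,
    find_conserved_motifs,
    retain_solution,
    select_combination,
)
from ligmotif.grouping import CandidateGene, filter_candidates, group_hsps
from ligmotif.refdb import RefDB, RefDbEntry
from ligmotif.search import HSP, SearchParams, filter_hsps, local_search
from ligmotif.synthetic import LocusSpec, synth_locus


def _mk(label, start, end, score=50.0):
    return HSP(
        query_interval=Interval(start, end), strand="+", label=label,
        subject_id="s", score=score, evalue=1e-10, identity=95.0,
        length=end - start,
    )


def _cand(gene_type, *hsps):
    span = hsps[0].query_interval
    for h in hsps[1:]:
        span = span.union_span(h.query_interval)
    return CandidateGene(gene_type, "+", span, tuple(hsps))


class TestSelectCombination:
    def test_full_v_combination_preferred(self):
        cand = _cand("V", _mk("L-PART1", 0, 50), _mk("V-EXON", 400, 700),
                     _mk("V-RS", 710, 750), _mk("FR1-IMGT", 420, 500))
        assert select_combination(cand) == ("L-PART1", "V-EXON", "V-RS")

    def test_order_walk_to_v_exon(self):
        cand = _cand("V", _mk("V-EXON", 400, 700), _mk("FR2-IMGT", 500, 550))
        assert select_combination(cand) == ("V-EXON",)

    def test_j_rs_only(self):
        cand = _cand("J", _mk("J-RS", 100, 128))
        assert select_combination(cand) == ("J-RS",)

    def test_d_rs_pair_beats_singletons(self):
        cand = _cand("D", _mk("5'D-RS", 0, 28), _mk("3'D-RS", 44, 83),
                     _mk("D-REGION", 28, 44))
        assert select_combination(cand) == ("5'D-RS", "3'D-RS")

    def test_no_listed_combination(self):
        cand = _cand("V", _mk("FR2-IMGT", 500, 550))
        assert select_combination(cand) is None


class TestDelimitCmsa:
    def test_rs_extended_by_40(self):
        cmsas = delimit_cmsa(("V-RS",), [_mk("V-RS", 10_300, 10_340)], "V", 50_000)
        assert cmsas[0].interval == Interval(10_260, 10_380)

    def test_v_exon_extended_by_375(self):
        cmsas = delimit_cmsa(("V-EXON",), [_mk("V-EXON", 10_000, 10_300)], "V", 50_000)
        assert cmsas[0].interval == Interval(9_625, 10_675)

    def test_clamped_at_sequence_start(self):
        cmsas = delimit_cmsa(("J-REGION",), [_mk("J-REGION", 0, 60)], "J", 1_000)
        assert cmsas[0].interval == Interval(0, 180)

    def test_core_projected_through_subject_coordinates(self):
        db = RefDB()
        db.add("V-RS", RefDbEntry("r", "cacagtg" + "a" * 23 + "acaaaaacc"))
        hsp = HSP(
            query_interval=Interval(1_000, 1_030), strand="+", label="V-RS",
            subject_id="r", score=30.0, evalue=1e-9, identity=100.0, length=30,
            subject_interval=Interval(0, 30),
        )
        cmsas = delimit_cmsa(("V-RS",), [hsp], "V", 50_000, db=db)
        # the hit covers the first 30 of 39 reference nt: 9 nt project 3'-ward
        assert cmsas[0].core == Interval(1_000, 1_039)

    def test_expected_ranks_by_architecture(self, ontology):
        cmsas = delimit_cmsa(
            ("L-PART1", "V-EXON", "V-RS"),
            [_mk("L-PART1", 0, 46), _mk("V-EXON", 166, 501), _mk("V-RS", 501, 540)],
            "V", 50_000,
        )
        by_label = {c.source_label: c.expected_ranks for c in cmsas}
        assert by_label["L-PART1"] == (1, 2)
        assert 3 in by_label["V-EXON"] and 7 in by_label["V-EXON"]
        assert by_label["V-RS"] == (7, 8)


class TestFindConservedMotifs:
    def _area(self, iv, ranks):
        return Cmsa(interval=iv, expected_ranks=ranks, source_label="x")

    def test_exact_heptamer_membership(self, ontology):
        db = RefDB()
        db.add("V-HEPTAMER", RefDbEntry("h", "cacagtg"))
        seq = "t" * 50 + "cacagtg" + "t" * 50
        matches = find_conserved_motifs(
            seq, [self._area(Interval(0, 107), (7,))], ontology.patterns["V"], db
        )
        exact = [m for m in matches if m.source == "exact"]
        assert len(exact) == 1
        assert exact[0].interval == Interval(50, 57)

    def test_pssm_match_for_one_mismatch(self, ontology):
        db = RefDB()
        db.add("V-HEPTAMER", RefDbEntry("h", "cacagtg"))
        seq = "t" * 50 + "cacactg" + "t" * 50  # one mismatch, not in the set
        matches = find_conserved_motifs(
            seq, [self._area(Interval(40, 70), (7,))], ontology.patterns["V"], db
        )
        pssm = [m for m in matches if m.source == "pssm"]
        assert any(m.interval == Interval(50, 57) for m in pssm)

    def test_no_trp_codon_in_trp_free_area(self, ontology):
        seq = "ac" * 60
        matches = find_conserved_motifs(
            seq, [self._area(Interval(0, 120), (5,))], ontology.patterns["V"], RefDB()
        )
        assert matches == []

    def test_j_alternatives_resolve_label(self, ontology):
        seq = "a" * 30 + "ttc" + "a" * 30 + "tgg" + "a" * 30
        matches = find_conserved_motifs(
            seq, [self._area(Interval(0, 96), (3,))], ontology.patterns["J"], RefDB()
        )
        labels = {(m.label, m.interval.start) for m in matches}
        assert ("J-PHE", 30) in labels and ("J-TRP", 63) in labels


def _match(rank, start, length=3, source="exact", score=0.0):
    return MotifMatch(rank, f"rank{rank}", Interval(start, start + length),
                      source, score)


class TestRetainSolution:
    def test_single_motif_rejected(self, ontology):
        assert retain_solution([_match(1, 100)], ontology.patterns["V"]) is None

    def test_all_eight_planted_motifs_retained(self, ontology, family):
        t = family.templates["V"]
        f = t.features
        matches = [
            _match(1, f["INIT-CODON"].start),
            _match(2, f["DONOR-SPLICE"].start, 2),
            _match(3, f["ACCEPTOR-SPLICE"].start, 2),
            _match(4, f["1st-CYS"].start),
            _match(5, f["CONSERVED-TRP"].start),
            _match(6, f["2nd-CYS"].start),
            _match(7, f["V-HEPTAMER"].start, 7),
            _match(8, f["V-NONAMER"].start, 9),
        ]
        solution = retain_solution(matches, ontology.patterns["V"])
        assert solution is not None and len(solution.matches) == 8

    def test_spacer_gap_disambiguates(self, ontology):
        # two nonamer placements after the heptamer: gap 17 violates the
        # 12+-1 / 23+-1 spacer rule, gap 23 satisfies it
        matches = [
            _match(7, 100, 7),
            _match(8, 107 + 17, 9),
            _match(8, 107 + 23, 9),
        ]
        solution = retain_solution(matches, ontology.patterns["V"])
        assert [m.interval.start for m in solution.matches] == [100, 130]

    def test_gap_accumulates_over_skipped_ranks(self, ontology):
        # ranks 1 and 3 only: allowed distance adds rank 2's length and both
        # gap intervals
        ok = [_match(1, 0), _match(3, 3 + 40 + 2 + 100, 2)]
        bad = [_match(1, 0), _match(3, 3 + 800, 2)]
        assert retain_solution(ok, ontology.patterns["V"]) is not None
        assert retain_solution(bad, ontology.patterns["V"]) is None

    def test_exhaustive_consistency_and_maximality(self, ontology):
        """The retained solution is gap-consistent and no consistent
        assignment places more motifs (brute-force enumeration oracle)."""
        pattern = ontology.patterns["J"]
        rng = np.random.default_rng(3)
        by_rank_len = {1: 9, 2: 7, 3: 3, 4: 2}
        for trial in range(25):
            matches = []
            for rank in (1, 2, 3, 4):
                for _ in range(int(rng.integers(0, 3))):
                    matches.append(
                        _match(rank, int(rng.integers(0, 120)), by_rank_len[rank])
                    )
            solution = retain_solution(matches, pattern)

            def consistent(chain):
                from ligmotif.description import _allowed_gap

                for a, b in zip(chain, chain[1:]):
                    spans = _allowed_gap(pattern, a.rank, b.rank)
                    gap = b.interval.start - a.interval.end
                    if spans is None or not any(lo <= gap <= hi for lo, hi in spans):
                        return False
                return True

            best_n = 0
            pools = {r: [m for m in matches if m.rank == r] for r in (1, 2, 3, 4)}
            for combo in itertools.product(
                *[pools[r] + [None] for r in (1, 2, 3, 4)]
            ):
                chain = [m for m in combo if m is not None]
                if len(chain) >= 2 and consistent(chain):
                    best_n = max(best_n, len(chain))
            if solution is None:
                assert best_n < 2, f"trial {trial}"
            else:
                assert consistent(solution.matches)
                assert len(solution.matches) == best_n, f"trial {trial}"


class TestDelimitFromAnchors:
    def test_v_exon_between_acceptor_and_heptamer(self, ontology):
        matches = [
            MotifMatch(3, "ACCEPTOR-SPLICE", Interval(9_998, 10_000), "exact"),
            MotifMatch(7, "V-HEPTAMER", Interval(10_296, 10_303), "exact"),
        ]
        solution = retain_solution(matches, ontology.patterns["V"])
        feats = delimit_from_anchors(solution, "V", 50_000)
        assert feats["V-EXON"] == Interval(10_000, 10_296)

    def test_d_region_is_inter_heptamer_gap(self, ontology, family):
        t = family.templates["D"]
        f = t.features
        matches = [
            _match(1, f["5'D-NONAMER"].start, 9),
            _match(2, f["5'D-HEPTAMER"].start, 7),
            _match(3, f["3'D-HEPTAMER"].start, 7),
            _match(4, f["3'D-NONAMER"].start, 9),
        ]
        solution = retain_solution(matches, ontology.patterns["D"])
        feats = delimit_from_anchors(solution, "D", 10_000)
        assert feats["D-REGION"] == f["D-REGION"]
        assert 8 <= len(feats["D-REGION"]) <= 37
        assert feats["D-GENE-UNIT"] == f["D-GENE-UNIT"]

    def test_missing_nonamer_drops_rs_features(self, ontology):
        matches = [
            MotifMatch(3, "ACCEPTOR-SPLICE", Interval(9_998, 10_000), "exact"),
            MotifMatch(7, "V-HEPTAMER", Interval(10_296, 10_303), "exact"),
        ]
        solution = retain_solution(matches, ontology.patterns["V"])
        feats = delimit_from_anchors(solution, "V", 50_000)
        for absent in ("V-RS", "V-SPACER", "V-NONAMER", "L-V-GENE-UNIT"):
            assert absent not in feats


class TestDescribeGene:
    @pytest.fixture(scope="class")
    @staticmethod
    def described(small_locus, small_annotation):
        truth = {tuple(g.unit_interval): g for g in small_locus.genes}
        out = []
        for gene in small_annotation.cluster.genes:
            tg = truth.get(tuple(gene.unit.span))
            if tg is not None:
                out.append((gene.unit, tg))
        return out

    def test_described_v_has_24_labels(self, described):
        v_units = [u for u, tg in described
                   if u.gene_type == "V" and u.status == STATUS_DESCRIBED]
        assert v_units and all(u.label_count() == 24 for u in v_units)

    def test_described_j_has_8_labels_one_wf(self, described):
        j_units = [u for u, tg in described
                   if u.gene_type == "J" and u.status == STATUS_DESCRIBED]
        assert j_units
        for u in j_units:
            assert u.label_count() == 8
            assert len({"J-TRP", "J-PHE"} & set(u.features)) == 1

    def test_feature_nesting_follows_prototype(self, described, ontology,
                                               small_record):
        from ligmotif.ontology import relation_between

        n = len(small_record.sequence)
        for unit, _ in described:
            if unit.status != STATUS_DESCRIBED:
                continue
            # relations are defined in gene orientation
            f = {
                lbl: (iv if unit.strand == "+" else iv.mirror(n))
                for lbl, iv in unit.features.items()
            }
            if "V-REGION" in f and "V-EXON" in f:
                assert relation_between(f["V-REGION"], f["V-EXON"]) in (
                    "included_with_same_3_prime_in", "included_in"
                )
            if "V-SPACER" in f and "V-RS" in f:
                assert relation_between(f["V-SPACER"], f["V-RS"]) == "included_in"

    def test_signal_and_spacer_lengths(self, described):
        for unit, _ in described:
            for label, iv in unit.features.items():
                if "HEPTAMER" in label:
                    assert len(iv) == 7
                elif "NONAMER" in label:
                    assert len(iv) == 9
                elif "SPACER" in label:
                    assert len(iv) in {11, 12, 13, 22, 23, 24}

    def test_described_boundaries_equal_truth(self, described):
        for unit, tg in described:
            if tg.expected_status != "described":
                continue
            for label, iv in unit.features.items():
                if label in tg.features:
                    assert iv == tg.features[label], label

    def test_one_motif_only_is_undescribed(self, small_locus):
        cand = _cand("V", _mk("FR2-IMGT", 500, 550))
        unit = describe_gene(cand, "a" * 2_000, small_locus.refdb)
        assert unit.status == STATUS_UNDESCRIBED
        assert unit.features == {}


def test_strand_symmetry_of_description(family, ontology):
    """Describing the reverse complement yields mirrored feature coordinates."""
    rng = np.random.default_rng(77)
    locus = synth_locus(
        LocusSpec(n_v=1, n_d=1, n_j=1, background_length=12_000, strands="plus"),
        rng,
    )
    params = SearchParams(backend="internal")

    def units_for(seq):
        hsps = filter_hsps(local_search(seq, locus.refdb, params))
        cands = filter_candidates(group_hsps(hsps, len(seq)), locus.refdb)
        return {
            (c.gene_type, c.strand): describe_gene(c, seq, locus.refdb)
            for c in cands
        }

    fwd = units_for(locus.sequence)
    rev = units_for(revcomp(locus.sequence))
    n = len(locus.sequence)
    for (gene_type, strand), unit in fwd.items():
        mirrored = rev[(gene_type, "-" if strand == "+" else "+")]
        assert mirrored.status == unit.status
        assert set(mirrored.features) == set(unit.features)
        for label, iv in unit.features.items():
            assert mirrored.features[label] == iv.mirror(n), label


def test_v_region_annotation_transfers_boundaries(family):
    """A V-EXON diverged from a reference gets FR/CDR limits at the planted
    coordinates; an indel in CDR3 shifts only the CDR3 length."""
    from ligmotif.description import annotate_v_region
    from ligmotif.synthetic import family_refdb

    db = family_refdb(family, np.random.default_rng(55), LocusSpec(family_size=3))
    t = family.templates["V"]
    exon_iv = t.features["V-EXON"]
    rng = np.random.default_rng(5)
    seq = family.unit("V", "F", rng, divergence=0.08)[0]
    features = {"V-EXON": exon_iv, "L-PART1": t.features["L-PART1"]}
    notes = []
    annotate_v_region(seq, features, db, notes=notes)
    assert features["V-REGION"] == t.features["V-REGION"]
    assert features["L-PART2"] == t.features["L-PART2"]
    for label in ("FR1-IMGT", "CDR1-IMGT", "FR2-IMGT", "CDR2-IMGT", "FR3-IMGT"):
        assert features[label] == t.features[label], label
    assert features["1st-CYS"] == t.features["1st-CYS"]

    # delete 3 nt inside CDR3: FR boundaries unchanged, CDR3 3 nt shorter
    cdr3 = t.features["CDR3-IMGT"]
    cut = cdr3.start + 3
    seq2 = seq[:cut] + seq[cut + 3 :]
    feats2 = {"V-EXON": Interval(exon_iv.start, exon_iv.end - 3)}
    annotate_v_region(seq2, feats2, db)
    assert feats2["FR3-IMGT"] == t.features["FR3-IMGT"]
    assert len(feats2["CDR3-IMGT"]) == len(cdr3) - 3
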