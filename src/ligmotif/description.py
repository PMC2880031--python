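"""Per-candidate gene description.

For each candidate gene the most informative combination of labelled HSPs is
chosen, conserved-motif searching areas (CMSA) are delimited around it, the
pattern's conserved motifs are searched inside them (exact sequence sets
first, then a PSSM approximation for heptamers/nonamers), a consistent
"solution" respecting the pattern's inter-motif distance intervals is
retained (at least two motifs), and every remaining label is delimited by
coordinate arithmetic anchored on the solution's motifs.  For V genes the
V-EXON interior (V-REGION with its FR/CDR subdivision and conserved
Cys/Trp/Cys codons) is annotated by alignment against reference V-REGIONs
carrying known boundaries, standing in for the external V-REGION annotation
service the original workflow delegates to.

Minus-strand candidates are described on the reverse complement and their
features mirrored back to plus-strand coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from .core import GeneType, Interval, Strand, revcomp
from .grouping import CandidateGene
from .ontology import Ontology, PatternMotif, default_ontology
from .refdb import RefDB, build_pssm
from .search import HSP

logger = logging.getLogger(__name__)

STATUS_DESCRIBED = "described"
STATUS_PARTIAL = "partially_described"
STATUS_UNDESCRIBED = "undescribed"


@dataclass(frozen=True)
class DescriptionSettings:
    pssm_pseudocount: float = 0.5
    #: fraction of the PSSM min-self-score threshold a scanned window must
    #: reach (a relative cutoff keeps the admitted mismatch budget at ~2 for
    #: a heptamer/nonamer regardless of how flat the training set is)
    pssm_score_fraction: float = 0.5
    #: minimum percent identity for transferring reference V-REGION boundaries
    vquest_min_identity: float = 60.0
    #: motifs expected at an HSP-projected edge are only accepted within this
    #: distance (nt) of it; ranks without an anchor are unrestricted
    anchor_tolerance: int = 25


@dataclass(frozen=True)
class Cmsa:
    """A conserved-motif searching area with the pattern ranks expected in it.

    `core` is the unextended source-HSP interval; `rank_anchors` names, for
    ranks that abut an HSP edge, which core edge they are expected at.
    """

    interval: Interval
    expected_ranks: tuple[int, ...]
    source_label: str
    core: Interval | None = None
    rank_anchors: Mapping[int, str] | None = None


@dataclass(frozen=True)
class MotifMatch:
    rank: int
    label: str
    interval: Interval
    source: str  # exact | pssm
    score: float = 0.0
    #: distance (nt) from the HSP-edge position the motif is expected at;
    #: 0 for interior motifs
    penalty: int = 0


@dataclass(frozen=True)
class Solution:
    matches: tuple[MotifMatch, ...]  # rank-ordered
    gaps: tuple[int, ...]  # realized distances between consecutive matches

    def by_rank(self) -> dict[int, MotifMatch]:
        return {m.rank: m for m in self.matches}


@dataclass
class GeneUnit:
    """A described gene unit: labelled features plus a description status."""

    gene_type: GeneType
    strand: Strand
    status: str
    features: dict[str, Interval]
    source_candidate: CandidateGene
    solution: Solution | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        if self.features:
            return Interval(
                min(iv.start for iv in self.features.values()),
                max(iv.end for iv in self.features.values()),
            )
        return self.source_candidate.span

    def label_count(self) -> int:
        return len(self.features)


# --------------------------------------------------------------------------
# combination selection and CMSA delimitation


def select_combination(
    candidate: CandidateGene, ontology: Ontology | None = None
) -> tuple[str, ...] | None:
    """First combination (in priority order) whose labels are all present
    among the candidate's member HSPs; None if no combination applies."""
    ontology = ontology or default_ontology()
    present = {h.label for h in candidate.members}
    for combo in ontology.cmsa_combinations[candidate.gene_type]:
        if set(combo) <= present:
            return combo
    return None


def delimit_cmsa(
    combination: Sequence[str],
    members: Sequence[HSP],
    gene_type: GeneType,
    seq_length: int,
    ontology: Ontology | None = None,
    db: RefDB | None = None,
) -> list[Cmsa]:
    """One CMSA per combination label: the label's best member HSP extended
    by the configured length on both ends, clamped to the sequence.

    When the HSP's subject coordinates and the reference database are
    available, the CMSA core is the full reference motif projected onto the
    query through the local alignment (a hit covering subject positions
    [s0, s1) of an L-long reference starts s0 nt into the motif and ends
    L - s1 nt before its end), which anchors expected-motif positions far
    more precisely than the raw hit extremities.
    """
    ontology = ontology or default_ontology()
    by_label: dict[str, HSP] = {}
    for h in members:
        best = by_label.get(h.label)
        if best is None or (h.score, -h.evalue) > (best.score, -best.evalue):
            by_label[h.label] = h
    cmsas = []
    for label in combination:
        if label not in by_label:
            raise ValueError(f"combination label {label!r} has no member HSP")
        length = ontology.cmsa_lengths[label]
        hsp = by_label[label]
        core = hsp.query_interval
        subj = hsp.subject_interval
        if db is not None and len(subj):
            ref_len = next(
                (len(e.sequence) for e in db.get(label) if e.id == hsp.subject_id),
                None,
            )
            if ref_len is not None and subj.end <= ref_len:
                core = Interval(
                    max(0, core.start - subj.start),
                    min(seq_length, core.end + (ref_len - subj.end)),
                )
        cmsas.append(
            Cmsa(
                interval=core.expand(length, length, bound=seq_length),
                expected_ranks=ontology.cmsa_expected_ranks[gene_type][label],
                source_label=label,
                core=core,
                rank_anchors=ontology.cmsa_rank_anchors[gene_type].get(label, {}),
            )
        )
    return cmsas


# --------------------------------------------------------------------------
# conserved-motif search


def _exact_positions(seq: str, window: Interval, words: frozenset[str], k: int):
    lo, hi = window.start, min(window.end, len(seq))
    for pos in range(lo, hi - k + 1):
        w = seq[pos : pos + k]
        if w in words:
            yield pos, w


def find_conserved_motifs(
    seq: str,
    cmsas: Sequence[Cmsa],
    pattern: Sequence[PatternMotif],
    db: RefDB,
    settings: DescriptionSettings | None = None,
) -> list[MotifMatch]:
    """All occurrences of each expected pattern motif inside its CMSA.

    Fixed motifs (init codon, splice dinucleotides, conserved amino-acid
    codons) are matched against their exact sequence sets.  Heptamers and
    nonamers are matched exactly against the reference motif database; only
    when a rank has no exact occurrence anywhere is an approximate PSSM scan
    performed, flagged `source="pssm"`.
    """
    settings = settings or DescriptionSettings()
    windows: dict[int, list[Cmsa]] = {}
    for cmsa in cmsas:
        for rank in cmsa.expected_ranks:
            windows.setdefault(rank, []).append(cmsa)

    def penalty_for(rank: int, iv: Interval, areas: list[Cmsa]) -> int | None:
        # distance between the motif edge and the HSP-projected core edge it
        # is expected at, over the areas that define an anchor for this rank;
        # None when no expecting area defines an anchor (interior motifs)
        best = None
        for cmsa in areas:
            anchors = cmsa.rank_anchors or {}
            anchor = anchors.get(rank)
            if anchor is None or cmsa.core is None:
                continue
            core_edge, motif_edge = anchor
            ref = cmsa.core.start if core_edge == "start" else cmsa.core.end
            pos = iv.start if motif_edge == "start" else iv.end
            d = abs(pos - ref)
            best = d if best is None else min(best, d)
        return best

    matches: list[MotifMatch] = []
    for motif in pattern:
        areas = windows.get(motif.rank)
        if not areas:
            continue
        seen: set[int] = set()
        rank_matches: list[MotifMatch] = []

        def emit(pos: int, label: str, source: str, score: float = 0.0) -> None:
            iv = Interval(pos, pos + motif.length)
            penalty = penalty_for(motif.rank, iv, areas)
            # an anchored motif far from its projected position is noise, not
            # a placement alternative
            if penalty is not None and penalty > settings.anchor_tolerance:
                return
            rank_matches.append(
                MotifMatch(
                    rank=motif.rank,
                    label=label,
                    interval=iv,
                    source=source,
                    score=score,
                    penalty=penalty or 0,
                )
            )

        if motif.sequences is not None:
            words = frozenset(motif.sequences)
            label_of = {}
            if motif.alternatives:
                for lbl, alts in motif.alternatives.items():
                    for alt in alts:
                        label_of[alt] = lbl
            for cmsa in areas:
                for pos, w in _exact_positions(seq, cmsa.interval, words, motif.length):
                    if pos not in seen:
                        seen.add(pos)
                        emit(pos, label_of.get(w, motif.label), "exact")
        else:
            refs = db.sequence_set(motif.label)
            if refs:
                for cmsa in areas:
                    for pos, _ in _exact_positions(seq, cmsa.interval, refs, motif.length):
                        if pos not in seen:
                            seen.add(pos)
                            emit(pos, motif.label, "exact")
                # the approximate (PSSM) form is searched as well: a chance
                # exact occurrence elsewhere in the searching area must not
                # mask a mutated signal at the expected position -- solution
                # scoring still prefers exact matches
                pssm = build_pssm(sorted(refs), pseudocount=settings.pssm_pseudocount)
                cutoff = (
                    pssm.threshold * settings.pssm_score_fraction
                    if pssm.threshold > 0
                    else pssm.threshold
                )
                for cmsa in areas:
                    lo = cmsa.interval.start
                    hi = min(cmsa.interval.end, len(seq))
                    if hi - lo < motif.length:
                        continue
                    for off, score in pssm.scan(seq[lo:hi], cutoff):
                        pos = lo + off
                        if pos not in seen:
                            seen.add(pos)
                            emit(pos, motif.label, "pssm", score)
        matches.extend(rank_matches)
    return matches


# --------------------------------------------------------------------------
# solution retention


def _allowed_gap(pattern: Sequence[PatternMotif], r1: int, r2: int):
    """Union of allowed distances between the 3' end of rank r1 and the 5'
    start of rank r2, accumulating gap intervals and motif lengths across any
    skipped ranks."""
    by_rank = {m.rank: m for m in pattern}
    intervals = [(0, 0)]
    for r in range(r1, r2):
        gaps = by_rank[r].gap_to_next
        if gaps is None:
            return None
        skipped_len = by_rank[r + 1].length if r + 1 < r2 else 0
        intervals = [
            (lo + g_lo + skipped_len, hi + g_hi + skipped_len)
            for lo, hi in intervals
            for g_lo, g_hi in gaps
        ]
    return intervals


def retain_solution(
    matches: Sequence[MotifMatch], pattern: Sequence[PatternMotif]
) -> Solution | None:
    """Best consistent assignment of at most one match per rank.

    A chain is consistent when every realized inter-motif distance lies in
    the pattern's allowed interval (accumulated across skipped ranks).
    Chains are ranked by (number of motifs, number of exact motifs, summed
    PSSM score) and, on ties, by 5'-most placement.  Returns None when fewer
    than two motifs can be placed consistently.
    """
    by_rank: dict[int, list[MotifMatch]] = {}
    for m in matches:
        by_rank.setdefault(m.rank, []).append(m)
    ranks = sorted(by_rank)
    if not ranks:
        return None
    for r in ranks:
        by_rank[r].sort(key=lambda m: m.interval.start)

    # gap-feasibility cache between observed rank pairs
    gap_ok: dict[tuple[int, int], list[tuple[int, int]] | None] = {}

    def allowed(r1: int, r2: int):
        key = (r1, r2)
        if key not in gap_ok:
            gap_ok[key] = _allowed_gap(pattern, r1, r2)
        return gap_ok[key]

    Chain = tuple  # of MotifMatch

    def quality(chain: Chain):
        n_exact = sum(1 for m in chain if m.source == "exact")
        pssm_sum = sum(m.score for m in chain if m.source == "pssm")
        anchor_penalty = sum(m.penalty for m in chain)
        return (len(chain), n_exact, -anchor_penalty, pssm_sum)

    def better(a: Chain, b: Chain) -> bool:
        qa, qb = quality(a), quality(b)
        if qa != qb:
            return qa > qb
        return [m.interval.start for m in a] < [m.interval.start for m in b]

    # DP over matches: best chain ending at each match
    best_ending: dict[tuple[int, int], Chain] = {}
    for r in ranks:
        for mi, m in enumerate(by_rank[r]):
            best: Chain = (m,)
            for r_prev in ranks:
                if r_prev >= r:
                    break
                spans = allowed(r_prev, r)
                if spans is None:
                    continue
                for pi, p in enumerate(by_rank[r_prev]):
                    gap = m.interval.start - p.interval.end
                    if not any(lo <= gap <= hi for lo, hi in spans):
                        continue
                    cand = best_ending[(r_prev, pi)] + (m,)
                    if better(cand, best):
                        best = cand
            best_ending[(r, mi)] = best

    overall: Chain | None = None
    for chain in best_ending.values():
        if overall is None or better(chain, overall):
            overall = chain
    if overall is None or len(overall) < 2:
        return None
    gaps = tuple(
        overall[i + 1].interval.start - overall[i].interval.end
        for i in range(len(overall) - 1)
    )
    return Solution(matches=tuple(overall), gaps=gaps)


# --------------------------------------------------------------------------
# anchor-based delimitation


def delimit_from_anchors(
    solution: Solution,
    gene_type: GeneType,
    seq_length: int,
    ontology: Ontology | None = None,
    notes: list[str] | None = None,
) -> dict[str, Interval]:
    """Delimit every label whose two anchor edges exist in the solution."""
    ontology = ontology or default_ontology()
    by_rank = solution.by_rank()
    features: dict[str, Interval] = {}

    def edge(rank: int, which: str) -> int | None:
        m = by_rank.get(rank)
        if m is None:
            return None
        return m.interval.start if which == "start" else m.interval.end

    for label, ((r1, e1), (r2, e2)) in ontology.anchor_features[gene_type].items():
        a, b = edge(r1, e1), edge(r2, e2)
        if a is None or b is None:
            continue
        if a >= b:
            if notes is not None:
                notes.append(f"anchors for {label} yield an empty interval; dropped")
            continue
        features[label] = Interval(max(0, a), min(b, seq_length))

    # the mutually exclusive conserved codon of the J pattern names itself
    for m in solution.matches:
        if m.label in ("J-TRP", "J-PHE"):
            features[m.label] = m.interval
    return features


# --------------------------------------------------------------------------
# V-REGION interior annotation (surrogate for the external V-REGION service)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    # free end gaps: the reference V-REGION sits inside the (longer) V-EXON
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def _alignment_map(alignment) -> tuple[dict[int, int], float, int]:
    """ref-position -> exon-position map, identity%, n aligned columns."""
    mapping: dict[int, int] = {}
    matches = 0
    aligned_ref = 0
    target = alignment.target  # exon
    query = alignment.query  # reference V-REGION
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for k in range(q1 - q0):
            mapping[q0 + k] = t0 + k
            aligned_ref += 1
            if target[t0 + k] == query[q0 + k]:
                matches += 1
    identity = 100.0 * matches / max(1, len(query))
    return mapping, identity, aligned_ref


def _map_offset(mapping: dict[int, int], offset: int, ref_len: int) -> int | None:
    """Map a reference boundary offset through the alignment; boundaries
    falling in a deletion map to the nearest aligned position to the right."""
    for o in range(offset, ref_len):
        if o in mapping:
            return mapping[o] - (o - offset) if o == offset else mapping[o]
    # offset at/after the last aligned base: extrapolate off the rightmost one
    for o in range(min(offset, ref_len - 1), -1, -1):
        if o in mapping:
            return mapping[o] + (offset - o)
    return None


def annotate_v_region(
    seq: str,
    features: dict[str, Interval],
    db: RefDB,
    settings: DescriptionSettings | None = None,
    notes: list[str] | None = None,
) -> None:
    """Subdivide a delimited V-EXON into L-PART2 + V-REGION with FR/CDR
    boundaries and conserved codons transferred from the best-identity
    reference V-REGION; mutates `features` in place."""
    settings = settings or DescriptionSettings()
    exon_iv = features.get("V-EXON")
    if exon_iv is None:
        return
    exon = seq[exon_iv.start : exon_iv.end]
    refs = [e for e in db.get("V-REGION") if e.extras]
    if not refs:
        if notes is not None:
            notes.append("no reference V-REGION with boundary metadata; V-REGION kept whole")
        return

    aligner = _make_aligner()
    best = None  # (identity, entry, mapping)
    for entry in refs:
        alignment = aligner.align(exon, entry.sequence)[0]
        mapping, identity, _ = _alignment_map(alignment)
        if best is None or identity > best[0]:
            best = (identity, entry, mapping)
    identity, entry, mapping = best
    if identity < settings.vquest_min_identity:
        if notes is not None:
            notes.append(
                f"best reference V-REGION identity {identity:.1f}% below "
                f"{settings.vquest_min_identity:.0f}%; no FR/CDR subdivision"
            )
        return

    ref_len = len(entry.sequence)
    start_in_exon = _map_offset(mapping, 0, ref_len)
    if start_in_exon is None:
        return
    v_start = exon_iv.start + max(0, start_in_exon)
    # the germline V-REGION runs to the 3' end of the V-EXON
    features["V-REGION"] = Interval(v_start, exon_iv.end)
    if v_start > exon_iv.start:
        features["L-PART2"] = Interval(exon_iv.start, v_start)
        if "L-PART1" in features:
            features["L-INTRON-L"] = Interval(features["L-PART1"].start, v_start)

    for label, spec in entry.extras:
        try:
            a, b = (int(x) for x in spec.split("-"))
        except ValueError:
            continue
        qa, qb = _map_offset(mapping, a, ref_len), _map_offset(mapping, b, ref_len)
        if qa is None or qb is None or qa >= qb:
            continue
        lo = exon_iv.start + qa
        hi = min(exon_iv.start + qb, exon_iv.end)
        if label == "CDR3-IMGT":
            hi = exon_iv.end
        if lo < hi:
            features[label] = Interval(lo, hi)
    if notes is not None:
        notes.append(f"V-REGION boundaries transferred from {entry.id} ({identity:.1f}% identity)")


# --------------------------------------------------------------------------
# full per-candidate description


def describe_gene(
    candidate: CandidateGene,
    seq: str,
    db: RefDB,
    ontology: Ontology | None = None,
    settings: DescriptionSettings | None = None,
) -> GeneUnit:
    """Describe one candidate: combination -> CMSA -> motifs -> solution ->
    anchors -> (V only) V-REGION interior; the status records failure modes."""
    ontology = ontology or default_ontology()
    settings = settings or DescriptionSettings()
    notes: list[str] = []
    seq = seq.lower()
    n = len(seq)

    if candidate.strand == "-":
        work_seq = revcomp(seq)
        members = tuple(
            HSP(
                query_interval=h.query_interval.mirror(n),
                strand="+",
                label=h.label,
                subject_id=h.subject_id,
                score=h.score,
                evalue=h.evalue,
                identity=h.identity,
                length=h.length,
                subject_interval=h.subject_interval,
            )
            for h in candidate.members
        )
    else:
        work_seq = seq
        members = candidate.members

    combo = select_combination(candidate, ontology)
    if combo is not None:
        cmsas = delimit_cmsa(combo, members, candidate.gene_type, n, ontology, db)
    else:
        # no listed combination: search the whole candidate area
        span = members[0].query_interval
        for h in members[1:]:
            span = span.union_span(h.query_interval)
        unit_label = ontology.cmsa_combinations[candidate.gene_type][-1][0]
        length = ontology.cmsa_lengths[unit_label]
        all_ranks = tuple(m.rank for m in ontology.patterns[candidate.gene_type])
        cmsas = [Cmsa(span.expand(length, length, bound=n), all_ranks, unit_label)]
        notes.append("no HSP combination applicable; searched the whole candidate span")

    pattern = ontology.patterns[candidate.gene_type]
    matches = find_conserved_motifs(work_seq, cmsas, pattern, db, settings)
    solution = retain_solution(matches, pattern)

    if solution is None:
        notes.append("fewer than two conserved motifs could be placed consistently")
        return GeneUnit(
            gene_type=candidate.gene_type,
            strand=candidate.strand,
            status=STATUS_UNDESCRIBED,
            features={},
            source_candidate=candidate,
            notes=notes,
        )

    features = delimit_from_anchors(solution, candidate.gene_type, n, ontology, notes)
    if candidate.gene_type == "V":
        annotate_v_region(work_seq, features, db, settings, notes)

    if candidate.strand == "-":
        features = {lbl: iv.mirror(n) for lbl, iv in features.items()}

    if candidate.gene_type == "V" and "V-EXON" not in features:
        status = STATUS_PARTIAL
    elif all(b in features for b in ontology.boundary_labels[candidate.gene_type]):
        status = STATUS_DESCRIBED
    else:
        status = STATUS_PARTIAL
    return GeneUnit(
        gene_type=candidate.gene_type,
        strand=candidate.strand,
        status=status,
        features=features,
        source_candidate=candidate,
        solution=solution,
        notes=notes,
    )
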