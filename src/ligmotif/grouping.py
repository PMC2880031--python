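"""Grouping of selected HSPs into candidate V, D and J genes.

Selected HSPs from the same DNA strand carrying labels of the same gene type
are compared pairwise: if their topological relation is coherent with the
prototype's label order, each HSP is grown by a label-specific 5'/3'
extension and the two are linked when the extended intervals overlap.
Candidate genes are the connected components of this link relation; the area
from the 5'-most to the 3'-most member position contains a potential gene,
and the shared strand gives the gene orientation.

Same-label HSPs are never linked directly: after best-HSP selection they
cannot overlap, and extension-mediated contact between them is evidence of
tandem gene duplication, not of one gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .core import GeneType, Interval, Strand
from .errors import VocabularyError
from .ontology import Ontology, default_ontology
from .search import HSP

logger = logging.getLogger(__name__)

#: hard sanity limit on a candidate's genomic span (nt); larger components are
#: split at their widest internal gap
DEFAULT_MAX_SPAN = 20_000


@dataclass(frozen=True)
class CandidateGene:
    """A strand-oriented group of selected HSPs of one gene type."""

    gene_type: GeneType
    strand: Strand
    span: Interval
    members: tuple[HSP, ...]


def extend_interval(
    hsp: HSP,
    table: Mapping[str, tuple[int, int]],
    seq_length: int | None = None,
) -> Interval:
    """Grow an HSP interval by its label's 5'/3' extension, in gene
    orientation, clamped to the sequence bounds."""
    if hsp.label not in table:
        raise VocabularyError(f"label {hsp.label!r} has no extension entry")
    five, three = table[hsp.label]
    left, right = (five, three) if hsp.strand == "+" else (three, five)
    return hsp.query_interval.expand(left, right, bound=seq_length)


def _coherent(ontology: Ontology, gene_type: GeneType, a: HSP, b: HSP,
              seq_length: int) -> bool:
    """True when the 5'->3' order of the two labels on the strand is
    compatible with the prototype's label order."""
    order = ontology.label_order(gene_type, a.label, b.label)
    if order == 0:
        return True
    if a.strand == "+":
        upstream_first = a.query_interval.start <= b.query_interval.start
    else:
        upstream_first = a.query_interval.end >= b.query_interval.end
    return upstream_first if order < 0 else not upstream_first


def group_hsps(
    selected: Iterable[HSP],
    seq_length: int,
    ontology: Ontology | None = None,
    extensions: Mapping[str, tuple[int, int]] | None = None,
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[CandidateGene]:
    """Partition selected HSPs of each (strand, gene type) class into
    candidate genes by connected components of the pairwise link rule."""
    ontology = ontology or default_ontology()
    table = extensions if extensions is not None else ontology.hsp_extensions

    classes: dict[tuple[str, Strand], list[HSP]] = {}
    for h in selected:
        gene_type = ontology.gene_type_of_label(h.label)
        if gene_type is None:
            logger.debug("skipping HSP with non-specific label %s", h.label)
            continue
        classes.setdefault((gene_type, h.strand), []).append(h)

    candidates: list[CandidateGene] = []
    for (gene_type, strand), members in sorted(classes.items()):
        members = sorted(members, key=lambda h: (h.query_interval, h.label))
        extended = [
            h.query_interval
            if h.label not in table
            else extend_interval(h, table, seq_length)
            for h in members
        ]
        parent = list(range(len(members)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[i].label == members[j].label:
                    continue
                if not extended[i].overlaps(extended[j]):
                    continue
                if not _coherent(ontology, gene_type, members[i], members[j], seq_length):
                    continue
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

        comps: dict[int, list[HSP]] = {}
        for i, h in enumerate(members):
            comps.setdefault(find(i), []).append(h)
        for comp in comps.values():
            candidates.extend(_emit(gene_type, strand, comp, max_span))
    return sorted(candidates, key=lambda c: (c.span, c.strand, c.gene_type))


def filter_candidates(
    candidates: Iterable[CandidateGene],
    db=None,
    min_support_coverage: int = 45,
) -> list[CandidateGene]:
    """Drop candidates with no credible prototype support.

    The relaxed E-value needed for the very short D-prototype labels admits
    10-22 nt chance HSPs anywhere in a large sequence, occasionally close
    enough to group.  A potential gene must be supported by HSPs jointly
    covering at least `min_support_coverage` nt of the genomic area — just
    over half the shortest gene unit, beyond what clustered chance hits
    reach.
    """
    kept = []
    for cand in candidates:
        ivs = sorted(h.query_interval for h in cand.members)
        coverage, cur_start, cur_end = 0, ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start > cur_end:
                coverage += cur_end - cur_start
                cur_start, cur_end = iv.start, iv.end
            else:
                cur_end = max(cur_end, iv.end)
        coverage += cur_end - cur_start
        if coverage >= min_support_coverage:
            kept.append(cand)
        else:
            logger.debug(
                "dropping unsupported %s candidate at %s (HSP coverage %d nt)",
                cand.gene_type, cand.span, coverage,
            )
    return kept


def _emit(gene_type: GeneType, strand: Strand, comp: list[HSP],
          max_span: int) -> list[CandidateGene]:
    comp = sorted(comp, key=lambda h: h.query_interval)
    span = comp[0].query_interval
    for h in comp[1:]:
        span = span.union_span(h.query_interval)
    if len(span) <= max_span or len(comp) == 1:
        return [CandidateGene(gene_type, strand, span, tuple(comp))]
    # oversized component: split at the widest internal gap and recurse
    gaps = [
        (comp[i + 1].query_interval.start - comp[i].query_interval.end, i)
        for i in range(len(comp) - 1)
    ]
    width, at = max(gaps)
    logger.warning(
        "candidate %s span %d nt exceeds %d; splitting at a %d nt gap",
        gene_type, len(span), max_span, width,
    )
    return _emit(gene_type, strand, comp[: at + 1], max_span) + _emit(
        gene_type, strand, comp[at + 1 :], max_span
    )
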