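"""Gene delimitation and cluster assembly.

Whatever its description status, every gene unit is promoted to a gene
(V-GENE / D-GENE / J-GENE) whose boundaries are obtained by equally
distributing the distance between neighbouring units: the midpoint between
two consecutive units closes the upstream gene's 3'UTR and opens the
downstream gene's 5'UTR (an odd distance gives the extra base to the
upstream gene).  The first gene starts at the sequence start and the last
ends at the sequence end, so the genes partition the analysed sequence.  The
set of prototypes present then fixes the cluster label, and summary counts
are computed per strand, per gene type, per description status and per
functionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import Interval
from .description import GeneUnit
from .errors import AssemblyError
from .functionality import FunctionalityCall
from .ontology import ClusterLabel, Ontology, default_ontology


@dataclass
class AnnotatedGene:
    """A delimited gene: the unit plus UTRs and the gene-level label."""

    gene_level_label: str
    gene_interval: Interval
    unit: GeneUnit
    functionality: FunctionalityCall
    number: int = 0  # 1-based, assigned 5'->3' at cluster assembly

    @property
    def utr5(self) -> Interval | None:
        span = self.unit.span
        if self.unit.strand == "+":
            iv = Interval(self.gene_interval.start, span.start)
        else:
            iv = Interval(span.end, self.gene_interval.end)
        return iv if len(iv) else None

    @property
    def utr3(self) -> Interval | None:
        span = self.unit.span
        if self.unit.strand == "+":
            iv = Interval(span.end, self.gene_interval.end)
        else:
            iv = Interval(self.gene_interval.start, span.start)
        return iv if len(iv) else None


@dataclass
class ClusterAnnotation:
    cluster: ClusterLabel | None
    genes: list[AnnotatedGene]
    stats: dict = field(default_factory=dict)


_STATUS_RANK = {"described": 2, "partially_described": 1, "undescribed": 0}


def resolve_overlapping_units(
    units: Sequence[tuple[GeneUnit, FunctionalityCall]],
) -> list[tuple[GeneUnit, FunctionalityCall]]:
    """Keep the best-supported unit among units with overlapping spans.

    Recombination-signal heptamers and nonamers are near-palindromic, so a
    D gene (flanked by signals on both sides) can be described on either
    strand; the spurious orientation reads the 12/23 spacers swapped and so
    fails more functionality criteria.  Preference order: description
    status, number of labels, fewer failed functionality criteria, more
    exactly matched motifs, then the plus strand.
    """

    def quality(uf: tuple[GeneUnit, FunctionalityCall]):
        unit, call = uf
        n_exact = (
            sum(1 for m in unit.solution.matches if m.source == "exact")
            if unit.solution
            else 0
        )
        return (
            _STATUS_RANK.get(unit.status, 0),
            unit.label_count(),
            -len(call.failed_criteria),
            n_exact,
            unit.strand == "+",
        )

    ordered = sorted(units, key=lambda uf: uf[0].span)
    kept: list[tuple[GeneUnit, FunctionalityCall]] = []
    for uf in ordered:
        if kept and kept[-1][0].span.overlaps(uf[0].span):
            if quality(uf) > quality(kept[-1]):
                kept[-1] = uf
        else:
            kept.append(uf)
    return kept


def delimit_genes(
    units: Sequence[tuple[GeneUnit, FunctionalityCall]],
    seq_length: int,
    ontology: Ontology | None = None,
) -> list[AnnotatedGene]:
    """Assign gene intervals by midpoint splitting between consecutive units."""
    ontology = ontology or default_ontology()
    ordered = sorted(units, key=lambda uf: uf[0].span)
    for (a, _), (b, _) in zip(ordered, ordered[1:]):
        if a.span.overlaps(b.span):
            raise AssemblyError(
                f"overlapping gene-unit spans {a.span} ({a.gene_type}) and "
                f"{b.span} ({b.gene_type})"
            )
    genes: list[AnnotatedGene] = []
    for i, (unit, call) in enumerate(ordered):
        if i == 0:
            start = 0
        else:
            prev_end = ordered[i - 1][0].span.end  # half-open
            # midpoint of the inter-unit distance, extra base upstream
            start = (prev_end - 1 + unit.span.start) // 2 + 1
        if i == len(ordered) - 1:
            end = seq_length
        else:
            end = (unit.span.end - 1 + ordered[i + 1][0].span.start) // 2 + 1
        genes.append(
            AnnotatedGene(
                gene_level_label=ontology.gene_label(unit.gene_type),
                gene_interval=Interval(start, end),
                unit=unit,
                functionality=call,
            )
        )
    return genes


def assemble_cluster(
    genes: Sequence[AnnotatedGene],
    ontology: Ontology | None = None,
    seq_length: int | None = None,
) -> ClusterAnnotation:
    """Assign the cluster label and compute the summary statistics."""
    ontology = ontology or default_ontology()
    genes = sorted(genes, key=lambda g: g.gene_interval)
    for i, gene in enumerate(genes, start=1):
        gene.number = i
    stats = {
        "n_genes": len(genes),
        "per_strand": _count(genes, lambda g: g.unit.strand),
        "per_gene_type": _count(genes, lambda g: g.unit.gene_type),
        "per_status": _count(genes, lambda g: g.unit.status),
        "per_functionality": _count(genes, lambda g: g.functionality.value),
    }
    if seq_length is not None:
        stats["sequence_length"] = seq_length
    if not genes:
        return ClusterAnnotation(cluster=None, genes=[], stats=stats)
    cluster = ontology.cluster_label_for({g.unit.gene_type for g in genes})
    return ClusterAnnotation(cluster=cluster, genes=list(genes), stats=stats)


def _count(genes: Sequence[AnnotatedGene], key) -> dict[str, int]:
    out: dict[str, int] = {}
    for g in genes:
        out[key(g)] = out.get(key(g), 0) + 1
    return out
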