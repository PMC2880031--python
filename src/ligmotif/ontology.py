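"""Label vocabulary, prototypes, patterns and rule tables.

The vocabulary is the 47-label subset of the IMGT nucleotide labels needed to
describe germline V, D and J genes, organised into three prototypes (the
ordered label architecture of each gene type), a 12-relation algebra over
label intervals, the conserved-motif patterns with inter-motif distance
intervals, and the gene-cluster taxonomy.  All of it is loaded from a
versioned YAML resource bundled with the package; any entry can be overridden
per run.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources as _resources
from typing import Any, Iterable, Mapping

import yaml

from .core import GeneType, Interval
from .errors import RelationAmbiguityError, VocabularyError

GENE_TYPES: tuple[GeneType, ...] = ("V", "D", "J")

COMMON_LABELS = ("5'UTR", "3'UTR")


@dataclass(frozen=True)
class Label:
    name: str
    prototype_membership: frozenset[str]
    specificity: str  # specific | shared | common


@dataclass(frozen=True)
class PatternMotif:
    rank: int
    label: str
    length: int
    sequences: tuple[str, ...] | None  # fixed alternatives, or None for refdb motifs
    alternatives: Mapping[str, tuple[str, ...]] | None  # e.g. J-TRP/J-PHE codons
    gap_to_next: tuple[tuple[int, int], ...] | None  # union of closed intervals


@dataclass(frozen=True)
class ClusterLabel:
    name: str
    so_id: str | None
    prototypes: frozenset[str]


@dataclass(frozen=True)
class Prototype:
    gene_type: GeneType
    unit_labels: frozenset[str]
    gene_labels: frozenset[str]
    pattern: tuple[PatternMotif, ...]
    nominal_layout: Mapping[str, tuple[int, int]]


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


class Ontology:
    """In-memory view of the bundled ontology resource."""

    def __init__(self, overrides: Mapping[str, Any] | None = None) -> None:
        raw = yaml.safe_load(
            _resources.files("ligmotif.resources").joinpath("ontology.yaml").read_text()
        )
        if overrides:
            raw = _deep_merge(raw, overrides)
        self.version: str = raw["version"]
        self._raw = raw

        self.labels: dict[str, Label] = {
            name: Label(name, frozenset(spec["prototypes"]), spec["specificity"])
            for name, spec in raw["labels"].items()
        }
        self.relations: dict[str, str] = {}
        for rel, recip in raw["relations"].items():
            self.relations[rel] = recip
            self.relations[recip] = rel
        self.clusters: dict[str, ClusterLabel] = {
            name: ClusterLabel(name, spec["so"], frozenset(spec["prototypes"]))
            for name, spec in raw["clusters"].items()
        }
        self.exclusive_alternatives: tuple[frozenset[str], ...] = tuple(
            frozenset(group) for group in raw["exclusive_alternatives"]
        )

        self._unit_labels = {g: tuple(raw["unit_labels"][g]) for g in GENE_TYPES}
        self._gene_label = dict(raw["gene_label"])
        self.patterns: dict[str, tuple[PatternMotif, ...]] = {
            g: tuple(self._parse_motif(m) for m in raw["patterns"][g]) for g in GENE_TYPES
        }
        self.prototypes: dict[str, Prototype] = {
            g: Prototype(
                gene_type=g,
                unit_labels=frozenset(self._unit_labels[g]),
                gene_labels=frozenset(self._unit_labels[g])
                | {self._gene_label[g]}
                | set(COMMON_LABELS),
                pattern=self.patterns[g],
                nominal_layout={
                    k: tuple(v) for k, v in raw["nominal_layout"][g].items()
                },
            )
            for g in GENE_TYPES
        }

        # rule tables consumed by the grouping/description/functionality stages
        self.hsp_extensions: dict[str, tuple[int, int]] = {
            lbl: (spec["five_prime"], spec["three_prime"])
            for lbl, spec in raw["hsp_extensions"].items()
        }
        self.cmsa_combinations = {
            g: tuple(tuple(c) for c in raw["cmsa_combinations"][g]) for g in GENE_TYPES
        }
        self.cmsa_lengths: dict[str, int] = dict(raw["cmsa_lengths"])
        self.cmsa_expected_ranks = {
            g: {lbl: tuple(rk) for lbl, rk in raw["cmsa_expected_ranks"][g].items()}
            for g in GENE_TYPES
        }
        self.cmsa_rank_anchors = {
            g: {
                lbl: {rank: (a[0], a[1]) for rank, a in m.items()}
                for lbl, m in raw["cmsa_rank_anchors"][g].items()
            }
            for g in GENE_TYPES
        }
        self.anchor_features = {
            g: {
                lbl: ((a[0][0], a[0][1]), (a[1][0], a[1][1]))
                for lbl, a in raw["anchor_features"][g].items()
            }
            for g in GENE_TYPES
        }
        self.boundary_labels = {g: tuple(raw["boundary_labels"][g]) for g in GENE_TYPES}
        self.spacer_classes = {
            cls: frozenset(v) for cls, v in raw["spacer_classes"].items()
        }
        self.expected_spacer_class: dict[str, str] = dict(raw["expected_spacer_class"])

        self._validate()

    @staticmethod
    def _parse_motif(m: Mapping[str, Any]) -> PatternMotif:
        return PatternMotif(
            rank=m["rank"],
            label=m["label"],
            length=m["length"],
            sequences=tuple(m["sequences"]) if m.get("sequences") else None,
            alternatives=(
                {k: tuple(v) for k, v in m["alternatives"].items()}
                if m.get("alternatives")
                else None
            ),
            gap_to_next=(
                tuple((lo, hi) for lo, hi in m["gap_to_next"])
                if m.get("gap_to_next")
                else None
            ),
        )

    def _validate(self) -> None:
        if len(self.labels) != 47:
            raise VocabularyError(f"expected 47 labels, found {len(self.labels)}")
        for g, pattern in self.patterns.items():
            ranks = [m.rank for m in pattern]
            if ranks != list(range(1, len(ranks) + 1)):
                raise VocabularyError(f"{g} pattern ranks not consecutive: {ranks}")
        for name in self.relations:
            if self.relations[self.relations[name]] != name:
                raise VocabularyError(f"relation {name} not reciprocal")

    # ------------------------------------------------------------------ API

    def label_vocabulary(self, gene_type: str, level: str = "unit") -> frozenset[str]:
        """Concrete label set for a prototype (or the union over all three).

        Mutually exclusive alternatives (J-TRP/J-PHE) are both included; a
        described gene unit carries exactly one of them.  Use
        :meth:`label_count` for the prototype sizes that count such a pair as
        a single slot.
        """
        if level not in ("unit", "gene"):
            raise VocabularyError(f"unknown level {level!r}")
        if gene_type == "all":
            return frozenset().union(
                *(self.label_vocabulary(g, level) for g in GENE_TYPES)
            )
        if gene_type not in GENE_TYPES:
            raise VocabularyError(f"unknown gene type {gene_type!r}")
        proto = self.prototypes[gene_type]
        return frozenset(proto.unit_labels if level == "unit" else proto.gene_labels)

    def label_count(self, gene_type: str, level: str = "unit") -> int:
        """Prototype label-set size, exclusive alternatives counted once."""
        labels = self.label_vocabulary(gene_type, level)
        n = len(labels)
        for group in self.exclusive_alternatives:
            if group <= labels:
                n -= len(group) - 1
        return n

    def gene_label(self, gene_type: GeneType) -> str:
        try:
            return self._gene_label[gene_type]
        except KeyError:
            raise VocabularyError(f"unknown gene type {gene_type!r}") from None

    def gene_type_of_label(self, label: str) -> str | None:
        """The owning gene type for a specific label; None for shared/common."""
        try:
            spec = self.labels[label]
        except KeyError:
            raise VocabularyError(f"unknown label {label!r}") from None
        if spec.specificity != "specific":
            return None
        (g,) = spec.prototype_membership
        return g

    def label_order(self, gene_type: GeneType, label_a: str, label_b: str) -> int:
        """Fixed 5'->3' order of two labels in a prototype.

        Returns -1 if `label_a` is strictly upstream of `label_b`, 1 if
        strictly downstream, 0 when the nominal intervals overlap (nested or
        unordered labels impose no order constraint).
        """
        layout = self.prototypes[gene_type].nominal_layout
        a, b = layout.get(label_a), layout.get(label_b)
        if a is None or b is None:
            return 0
        if a[1] <= b[0]:
            return -1
        if b[1] <= a[0]:
            return 1
        return 0

    def cluster_label_for(self, present: Iterable[str]) -> ClusterLabel:
        """Gene-cluster label for the set of prototypes present in a sequence."""
        present = frozenset(present)
        if not present:
            raise VocabularyError("no prototypes present: no cluster can be assigned")
        if not present <= set(GENE_TYPES):
            raise VocabularyError(f"unknown prototypes {sorted(present)}")
        for cluster in self.clusters.values():
            if cluster.prototypes == present:
                return cluster
        raise VocabularyError(f"no cluster defined for {sorted(present)}")

    def spacer_lengths(self, spacer_label: str) -> frozenset[int]:
        """Admissible lengths (bp) for a recombination-signal spacer label."""
        cls = self.expected_spacer_class[spacer_label]
        return self.spacer_classes[cls]


def relation_between(a: Interval, b: Interval) -> str:
    """The unique inter-label relation holding between two intervals.

    Both intervals must be expressed in gene orientation on the same strand.
    Exactly one of the twelve relations holds for every non-identical pair;
    identity is undefined in the relation algebra and raises.
    """
    if a == b:
        raise RelationAmbiguityError(f"no relation defined for identical intervals {a}")
    if a.end < b.start:
        return "is_in_5_prime_of"
    if a.end == b.start:
        return "adjacent_at_its_3_prime_to"
    if b.end < a.start:
        return "is_in_3_prime_of"
    if b.end == a.start:
        return "adjacent_at_its_5_prime_to"
    # overlapping from here on
    if b.contains(a):
        if a.start == b.start:
            return "included_with_same_5_prime_in"
        if a.end == b.end:
            return "included_with_same_3_prime_in"
        return "included_in"
    if a.contains(b):
        if a.start == b.start:
            return "includes_with_same_5_prime"
        if a.end == b.end:
            return "includes_with_same_3_prime"
        return "includes"
    if a.start < b.start:
        return "overlaps_at_its_3_prime_with"
    return "overlaps_at_its_5_prime_with"


_DEFAULT: Ontology | None = None


def default_ontology() -> Ontology:
    """Shared read-only instance of the bundled ontology."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = Ontology()
    return _DEFAULT
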