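"""Functionality classification of described gene units.

Each fully described unit is classified as Functional, ORF (open reading
frame) or Pseudogene by a rule cascade; a unit that is not fully described
(missing specific labels or splicing sites) is Unknown, because automatic
classification then requires manual expertise.

The cascade, per gene type:

* completeness of the specific labels and splicing sites, else **Unknown**;
* coding integrity (no stop codons; for V an intact 'atg' initiation codon,
  splicing frame sf1 between leader and V-exon, and Cys/Trp/Cys in a single
  reading frame; for J an sf1 donor splice and the conserved
  ``[W,F]-[G,A]-X-G`` motif; for D at least one open reading frame), else
  **Pseudogene**;
* recombination-signal quality (expected spacer length, heptamer and nonamer
  identical to ones found in functional genes), else **ORF**;
* otherwise **Functional**.

sf1 (splicing frame 1) means the donor splice splits a codon after its first
nucleotide: the coding length upstream of the donor is congruent to 1 mod 3.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core import feature_seq, oriented_start, translate
from .description import STATUS_DESCRIBED, GeneUnit
from .ontology import Ontology, default_ontology
from .refdb import FunctionalSignalSets

FUNCTIONAL = "Functional"
ORF = "ORF"
PSEUDOGENE = "Pseudogene"
UNKNOWN = "Unknown"

_WGXG = re.compile(r"[WF][GA][^P*]G")


@dataclass(frozen=True)
class FunctionalityCall:
    value: str
    failed_criteria: tuple[str, ...] = ()
    sf: int | None = None


def splicing_frame(l_part1_coding: str) -> int:
    """Splicing frame of the donor junction: coding length mod 3 (sf1 = 1)."""
    return len(l_part1_coding) % 3


def wgxg_scan(peptide: str) -> int | None:
    """5'-most position of the conserved [W,F]-[G,A]-X-G motif (X != P)."""
    m = _WGXG.search(peptide)
    return m.start() if m else None


def _required_labels(unit: GeneUnit, ontology: Ontology) -> bool:
    vocab = ontology.label_vocabulary(unit.gene_type, "unit")
    present = set(unit.features)
    required = set(vocab)
    for group in ontology.exclusive_alternatives:
        if group <= required:
            required -= group
            if len(group & present) != 1:
                return False
    return required <= present


def coding_peptides(unit: GeneUnit, seq: str) -> dict[str, str]:
    """Amino-acid translations of the unit's coding regions, in the reading
    frames the gene architecture fixes (leader frame from the initiation
    codon, V/J region frames from their conserved codons)."""
    seq = seq.lower()
    n = len(seq)
    feats = unit.features
    out: dict[str, str] = {}

    def sense(label: str) -> str:
        return feature_seq(seq, feats[label], unit.strand)

    def pos(label: str) -> int:
        return oriented_start(feats[label], unit.strand, n)

    if "L-PART1" in feats:
        lp1 = sense("L-PART1")
        out["L-PART1"] = translate(lp1)
        if "V-EXON" in feats:
            frame = (3 - splicing_frame(lp1)) % 3
            out["V-EXON"] = translate(sense("V-EXON")[frame:])
    if "V-REGION" in feats and "1st-CYS" in feats:
        frame = (pos("1st-CYS") - pos("V-REGION")) % 3
        out["V-REGION"] = translate(sense("V-REGION")[frame:])
    if "J-REGION" in feats:
        wf = "J-TRP" if "J-TRP" in feats else ("J-PHE" if "J-PHE" in feats else None)
        if wf:
            frame = (pos(wf) - pos("J-REGION")) % 3
            out["J-REGION"] = translate(sense("J-REGION")[frame:])
    if "D-REGION" in feats:
        out["D-REGION"] = translate(sense("D-REGION"))
    return out


def classify(
    unit: GeneUnit,
    seq: str,
    signals: FunctionalSignalSets,
    ontology: Ontology | None = None,
) -> FunctionalityCall:
    """Classify a gene unit as Functional / ORF / Pseudogene / Unknown."""
    ontology = ontology or default_ontology()
    seq = seq.lower()
    if unit.status != STATUS_DESCRIBED or not _required_labels(unit, ontology):
        return FunctionalityCall(UNKNOWN, ("label_completeness",))

    n = len(seq)
    feats = unit.features

    def sense(label: str) -> str:
        return feature_seq(seq, feats[label], unit.strand)

    def pos(label: str) -> int:
        return oriented_start(feats[label], unit.strand, n)

    failed: list[str] = []
    if unit.gene_type == "V":
        lp1 = sense("L-PART1")
        sf = splicing_frame(lp1)
        if sense("INIT-CODON") != "atg":
            return FunctionalityCall(PSEUDOGENE, ("init_codon",), sf)
        vexon = sense("V-EXON")
        frame = (3 - sf) % 3
        if "*" in translate(lp1) or "*" in translate(vexon[frame:]):
            return FunctionalityCall(PSEUDOGENE, ("stop_codon",), sf)
        if sf != 1:
            return FunctionalityCall(PSEUDOGENE, ("splicing_frame",), sf)
        c1, w, c2 = pos("1st-CYS"), pos("CONSERVED-TRP"), pos("2nd-CYS")
        if (w - c1) % 3 or (c2 - c1) % 3:
            return FunctionalityCall(PSEUDOGENE, ("frameshift",), sf)
        if len(feats["V-SPACER"]) not in ontology.spacer_lengths("V-SPACER"):
            failed.append("spacer_length")
        if not signals.contains("V-HEPTAMER", sense("V-HEPTAMER")):
            failed.append("heptamer")
        if not signals.contains("V-NONAMER", sense("V-NONAMER")):
            failed.append("nonamer")
        return FunctionalityCall(ORF if failed else FUNCTIONAL, tuple(failed), sf)

    if unit.gene_type == "J":
        jr = sense("J-REGION")
        wf_label = "J-TRP" if "J-TRP" in feats else "J-PHE"
        frame = (pos(wf_label) - pos("J-REGION")) % 3
        pep = translate(jr[frame:])
        if "*" in pep:
            return FunctionalityCall(PSEUDOGENE, ("stop_codon",))
        sf = (len(jr) - frame) % 3
        if sf != 1:
            return FunctionalityCall(PSEUDOGENE, ("splicing_frame",), sf)
        if wgxg_scan(pep) is None:
            return FunctionalityCall(PSEUDOGENE, ("wgxg_motif",), sf)
        if len(feats["J-SPACER"]) not in ontology.spacer_lengths("J-SPACER"):
            failed.append("spacer_length")
        if not signals.contains("J-HEPTAMER", sense("J-HEPTAMER")):
            failed.append("heptamer")
        if not signals.contains("J-NONAMER", sense("J-NONAMER")):
            failed.append("nonamer")
        return FunctionalityCall(ORF if failed else FUNCTIONAL, tuple(failed), sf)

    # D
    dr = sense("D-REGION")
    if not any("*" not in translate(dr[f:]) for f in range(3)):
        return FunctionalityCall(PSEUDOGENE, ("stop_codon",))
    if len(feats["5'D-SPACER"]) not in ontology.spacer_lengths("5'D-SPACER"):
        failed.append("spacer_length_5")
    if len(feats["3'D-SPACER"]) not in ontology.spacer_lengths("3'D-SPACER"):
        failed.append("spacer_length_3")
    for lbl in ("5'D-HEPTAMER", "3'D-HEPTAMER", "5'D-NONAMER", "3'D-NONAMER"):
        if not signals.contains(lbl, sense(lbl)):
            failed.append(lbl)
    return FunctionalityCall(ORF if failed else FUNCTIONAL, tuple(failed))
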