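"""Functionality classification of germline gene units.

Builds one subgroup template family, derives a functional V unit and three
lesioned siblings — a stop codon (pseudogene), a corrupted recombination
heptamer (ORF) and a destroyed nonamer (label-incomplete, hence Unknown) —
and shows the rule cascade's verdicts.  The cascade checks, in order: label
completeness, coding integrity (stops, initiation codon, splicing frame sf1,
Cys/Trp/Cys frame), and recombination-signal quality (spacer length,
heptamer/nonamer identical to ones found in functional genes).
"""

import numpy as np

from ligmotif import classify, functional_signal_sets
from ligmotif.core import Interval
from ligmotif.description import GeneUnit, STATUS_DESCRIBED, STATUS_PARTIAL
from ligmotif.grouping import CandidateGene
from ligmotif.synthetic import LocusSpec, TemplateFamily, family_refdb

rng = np.random.default_rng(11)
family = TemplateFamily(rng)
signals = functional_signal_sets(family_refdb(family, rng, LocusSpec(family_size=4)))

for title, functionality, status in [
    ("intact unit", "F", STATUS_DESCRIBED),
    ("stop codon in FR3", "P", STATUS_DESCRIBED),
    ("heptamer 2 mismatches", "ORF", STATUS_DESCRIBED),
    ("nonamer destroyed", "U", STATUS_PARTIAL),
]:
    seq, template = family.unit("V", functionality, rng, divergence=0.08)
    features = dict(template.features)
    if functionality == "U":  # the destroyed signal cannot be delimited
        for lbl in ("V-NONAMER", "V-SPACER", "V-RS", "L-V-GENE-UNIT"):
            features.pop(lbl)
    unit = GeneUnit(
        "V", "+", status, features,
        CandidateGene("V", "+", Interval(0, len(seq)), ()),
    )
    call = classify(unit, seq, signals)
    failed = ",".join(call.failed_criteria) or "-"
    print(f"{title:24s} -> {call.value:10s} (failed criteria: {failed})")
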