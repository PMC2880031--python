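"""From raw similarity hits to a described gene unit.

Plants one functional J gene in 8 kb of random background, searches it
against the reference motif databases (labelled HSPs on both strands),
filters overlapping same-database hits with the g1/g2 rule, groups the
survivors into a candidate gene, and describes it: recombination-signal
nonamer/heptamer, spacer, J-REGION, the conserved Trp/Phe codon and the
donor splice, each with exact coordinates.
"""

import numpy as np

from ligmotif import describe_gene, filter_hsps, local_search
from ligmotif.grouping import filter_candidates, group_hsps
from ligmotif.synthetic import LocusSpec, synth_locus

locus = synth_locus(
    LocusSpec(n_v=0, n_d=0, n_j=1, background_length=8_000, strands="plus",
              plan=(("J", "F"),)),
    np.random.default_rng(21),
)

hsps = local_search(locus.sequence, locus.refdb)
selected = filter_hsps(hsps)
print(f"{len(hsps)} HSPs, {len(selected)} after same-database selection")

candidates = filter_candidates(
    group_hsps(selected, len(locus.sequence)), locus.refdb
)
candidate = candidates[0]
print(f"candidate {candidate.gene_type} gene on strand {candidate.strand}, "
      f"area {candidate.span.start + 1}..{candidate.span.end}, "
      f"{len(candidate.members)} member HSPs")

unit = describe_gene(candidate, locus.sequence, locus.refdb)
print(f"status: {unit.status}; {unit.label_count()} labels delimited")
# display convention: 5'->3', the longest label first at equal starts
for label, iv in sorted(unit.features.items(),
                        key=lambda kv: (kv[1].start, -len(kv[1]))):
    print(f"  {label:14s} {iv.start + 1:5d}..{iv.end:5d} ({len(iv)} nt)")

truth = locus.genes[0]
print("\ntruth J unit:", truth.unit_interval.start + 1, "..",
      truth.unit_interval.end, f"({truth.functionality})")
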