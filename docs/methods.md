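# Methods

## The annotation model

`ligmotif` treats a germline IG/TR locus as a succession of V, D and J genes
drawn from three *prototypes* — ordered label architectures:

* **V**: `L-PART1` (leader exon, starting with the `atg` initiation codon) —
  donor splice `gt` — `V-INTRON` — acceptor splice `ag` — `V-EXON`
  (= `L-PART2` + `V-REGION`, the latter subdivided into FR1/CDR1/FR2/CDR2/
  FR3/CDR3 with conserved 1st-CYS, CONSERVED-TRP and 2nd-CYS codons) —
  `V-RS` (heptamer, spacer, nonamer).
* **D**: `5'D-RS` (nonamer, spacer, heptamer) — `D-REGION` (8–37 bp) —
  `3'D-RS` (heptamer, spacer, nonamer).
* **J**: `J-RS` (nonamer, spacer, heptamer) — `J-REGION` (37–69 bp, carrying
  the conserved `[W,F]-[G,A]-X-G` motif) — donor splice.

The vocabulary holds 47 labels (43 specific to one prototype, the splice
sites shared, the UTRs common); J-TRP and J-PHE are mutually exclusive
within one described unit and count as a single slot in the prototype sizes
(24/10/8 at unit level, 27/13/11 at gene level with the gene label and
UTRs). Twelve reciprocal relations order label intervals; identical
intervals are undefined in the algebra and raise rather than guess.
Recombination-signal spacers are admissible at 12 ± 1 or 23 ± 1 bp; the
default per-signal expectation follows the 12/23 rule (23-spacer V-RS and
3'D-RS, 12-spacer 5'D-RS and J-RS) and is configurable per locus.

All rule tables — label sets, patterns with inter-motif distance intervals,
HSP extension lengths, CMSA lengths and expected ranks, anchor arithmetic,
cluster taxonomy — live in a versioned YAML resource
(`ligmotif/resources/ontology.yaml`) and can be overridden per run.

## Key algorithmic choices

**Search.** Default parameters: word size 4, E-value threshold 0.01, relaxed
to 5 for the D-prototype labels (their reference motifs are too short to
reach small E-values). The internal backend seeds on exact 4-mers and runs
ungapped X-drop extension (+1/−2, X = 20), with Karlin–Altschul E-values
(λ solved numerically for the scoring system, K = 0.62, the standard
ungapped value); the external backend wraps NCBI `blastn` with the same
parameters. Both satisfy the same contract; the pipeline auto-selects
`blastn` when available. HSPs carry their subject (reference) coordinates.

**Best-HSP selection.** Overlapping same-database HSPs fight pairwise
tournaments in descending (score, −E-value, length, identity, 5' position)
order; the fully tied case removes the later-sorted HSP so selection is
deterministic and, with distinct statistics, independent of input order.

**Grouping.** Candidates are connected components of the pairwise link rule
(label order coherent with the prototype + extended-interval overlap);
same-label HSPs are never linked directly — extension-mediated contact
between them is evidence of tandem duplication. Components wider than 20 kb
are split at their widest internal gap with a warning. Candidates whose
member HSPs jointly cover < 45 nt (just over half the shortest gene unit,
83 nt) are discarded: the relaxed D E-value admits 10–22 nt chance hits
over a large background, and these occasionally cluster.

**Description.** The CMSA core is the *full reference motif projected
through the HSP's subject coordinates* (a hit covering subject positions
`[s0, s1)` of an L-long reference starts `s0` nt into the motif and ends
`L − s1` nt before its end). This anchors expected motif positions far more
precisely than raw hit extremities, whose X-drop ends wander by a few
nucleotides. Motifs expected at a projected edge are only accepted within
25 nt of it; interior motifs (the V Cys/Trp codons, the J conserved codon)
are unrestricted. Heptamers/nonamers are matched exactly against the
reference sets and *additionally* by PSSM (log-odds with pseudocount 0.5,
uniform background; scan cutoff = 50% of the matrix's minimum self-score —
a relative cutoff keeps the admitted budget near two mismatches whatever
the training-set diversity; exactness is preferred in solution scoring
rather than gating the approximate search, so a chance exact occurrence
elsewhere in the area cannot mask a mutated signal at the expected
position). The retained solution maximizes (motifs placed, exact motifs,
−total anchor distance, PSSM score), ties broken 5'-most; at least two
motifs are required, otherwise the gene is *undescribed*. Distance
constraints between non-adjacent placed ranks accumulate the skipped ranks'
gap intervals and motif lengths.

**V-exon interior.** The V-REGION and its FR/CDR limits and conserved
codons are transferred from the best-identity reference V-REGION (global
alignment with free end gaps, ≥ 60% identity required), an internal
annotator standing in for an external V-REGION analysis service; the
V-REGION 3' end is the V-EXON 3' end, and `L-PART2` is the stretch between
the acceptor splice and the V-REGION start.

**Status.** *described* requires the gene-unit boundary labels
(L-V-GENE-UNIT/L-PART1/V-RS; D-GENE-UNIT/both RS; J-GENE-UNIT/J-RS/
J-REGION). A V without V-EXON, or any unit missing a boundary label (e.g. a
destroyed nonamer), is *partially described* — and hence **Unknown** in the
functionality stage, which requires label completeness.

**Functionality.** The cascade is evaluated in order (completeness →
Pseudogene criteria → ORF criteria → Functional). sf1 is defined as coding
length ≡ 1 mod 3 upstream of the donor junction (the donor splits a codon
after its first nucleotide); the definition is isolated in
`splicing_frame` for easy correction. The D open-reading-frame check
accepts any of the three forward frames of D-REGION. Unconventional splice
sites (e.g. `nag` donors) are not recognized.

**Assembly.** Before delimitation, overlapping unit spans are resolved by
keeping the best-supported unit (status, label count, fewer failed
functionality criteria, exact motifs, then the plus strand): RS heptamers
and nonamers are near-palindromic, so a D gene also validates on the
reverse strand, where the swapped 12/23 spacers betray the wrong
orientation. Midpoint splitting gives the extra base of an odd inter-unit
distance to the upstream gene's 3'UTR.

## The synthetic-data generator

One subgroup ancestor per gene type is synthesized per locus; the reference
database is built from 4 family variants at 3%/site divergence while
planted genes diverge 10%/site (within the > 75% identity of a real
subgroup) — so search and description must tolerate subgroup-level
divergence, and the reference never contains the planted copies.
Substitutions only: truth coordinates equal template coordinates. Protected
positions (conserved motifs, splice sites, signals, and small guard windows
where a substitution would create a second, equally pattern-consistent
anchor — e.g. a `gt` just upstream of the true donor, a W/F codon between
the J heptamer and the true conserved codon) are never mutated; coding
positions are resampled rather than allowed to become stops. Lesions define
the planned class: a stop codon in FR3 or the leader (V pseudogene), loss
of `[W,F]-[G,A]-X-G` (J pseudogene), stops in all three D-REGION frames
(D pseudogene), a 2-mismatch heptamer (ORF — approximately detectable but
absent from the functional signal sets), a fully scrambled V nonamer
(Unknown, verified to leave no ≤ 2-mismatch 9-mer at any admissible spacer
distance). Each sampled unit is validated against cheap class predicates
and resampled if a mutation defeats the plan. Background is i.i.d.
nucleotides at 40% GC; genes are planted with ≥ 1.5 kb separation so that
extension-based grouping cannot fuse neighbours.

The default locus — the standing study condition for end-to-end tests and
the acceptance script — carries 10 V (6 F, 2 P, 1 ORF, 1 Unknown-class),
3 D (2 F, 1 P) and 5 J (3 F, 1 P, 1 ORF) genes on random strands in 200 kb.
The test suite uses a 2 V + 1 D + 2 J locus in 30 kb as its standing
fixture; both sizes keep the default test run and the acceptance script in
the tens of seconds on one CPU.

**What passing these tests does and does not show.** The generator has no
indels, no gene conversion, no orphons, no nested or overlapping genes, no
unconventional splice sites and fully regular RS architecture; recovery at
100% with exact boundaries on this material demonstrates the correctness of
the algorithmic chain (selection, grouping, anchoring arithmetic, cascade
logic), not the sensitivity of the tool on degenerate real pseudogenes,
whose boundary evidence can be genuinely absent. Real-locus validation
additionally depends on the content and version of curated reference
databases.

## Known limitations

* Pattern-only description cannot disambiguate a chance conserved-codon
  occurrence between the J heptamer and the true `[W,F]` codon; the
  generator keeps that window codon-free, a real annotator would need
  reference-alignment evidence (as the V exon interior already uses).
* The subject-coordinate projection assumes (near-)colinear alignments;
  large indels between query and reference would blur the anchors beyond
  the 25 nt tolerance.
* E-values of the internal backend use ungapped Karlin–Altschul statistics
  without edge-effect or sum-statistics corrections; thresholds are
  comparable, not identical, to NCBI BLAST's.
* Constant (C) genes, locus-level nomenclature, orphon detection and
  regulatory elements are out of scope.
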