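# ligmotif

Annotation of germline immunoglobulin (IG) and T cell receptor (TR) V, D and
J genes in large genomic DNA sequences.

Antigen-receptor loci defeat conventional gene finders: their genes are
split into unusual pieces (a two-exon leader for V genes, coding regions of
only 8–37 bp for D and 37–69 bp for J), occur as multigene subgroups sharing
more than 75% identity, are littered with pseudogenes, and are flanked by
recombination signals (RS) — a conserved heptamer and nonamer separated by a
12 ± 1 or 23 ± 1 bp spacer — instead of ordinary regulatory landmarks.
`ligmotif` annotates such loci (up to ~2.5 Mbp) with a standardized label
vocabulary, in four stages:

1. **Gene identification** — BLAST-style local search of the sequence (both
   strands) against per-label reference motif databases; overlapping hits
   from the same database are reduced with the pairwise *g1/g2* rule
   (g1 = score + E-value comparators, g2 = length + identity comparators;
   hsp2 is removed when g1 > 0, or g1 = 0 and g2 ≥ 0); surviving hits are
   grouped into candidate genes by label-specific extensions and topological
   coherence with the V/D/J prototypes.
2. **Gene description** — the best labelled-HSP combination delimits
   conserved-motif searching areas (CMSA); the pattern motifs (initiation
   codon, splice dinucleotides, conserved Cys/Trp/Phe codons, RS heptamers
   and nonamers — exact reference match first, position-specific scoring
   matrix otherwise) are placed subject to the pattern's inter-motif
   distance intervals; at least two motifs are required, and every other
   label is then delimited by coordinate arithmetic anchored on them.
   A V gene's exon interior (V-REGION with FR1–FR3/CDR1–CDR3 and the
   conserved codons) is annotated by alignment to reference V-REGIONs with
   known boundaries.
3. **Functionality identification** — each fully described unit is
   classified **Functional**, **ORF** or **Pseudogene** through a rule
   cascade (label completeness, stop codons, initiation codon, splicing
   frame sf1, Cys/Trp frame, the J `[W,F]-[G,A]-X-G` motif, spacer lengths,
   signals identical to ones found in functional genes); incompletely
   described units are **Unknown**.
4. **Gene delimitation and cluster assembly** — neighbouring gene units are
   promoted to V-GENE/D-GENE/J-GENE by splitting the inter-unit distance at
   its midpoint (UTRs), the prototype combination fixes the cluster label
   (V-CLUSTER … V-D-J-CLUSTER, with Sequence Ontology accessions), and
   summary statistics are computed per strand, type, status and
   functionality.

A synthetic-locus generator (`ligmotif.synthetic`) emulates the genomic
architecture with full ground truth — subgroup families, divergent planted
copies, and per-class lesions — so every stage is testable without any
external database.

## Worked example

`examples/annotate_synthetic_locus.py` generates a 30 kb locus with five
planted genes and annotates it:

```
sequence: 30000 nt
cluster:  V-D-J-CLUSTER (SO:0000532)
genes:    5 | per type {'V': 2, 'D': 1, 'J': 2} | per strand {'-': 5}
functionality: {'Functional': 3, 'Pseudogene': 1, 'ORF': 1}

N  Description    Positions     Strand  Functionality  Number of labels
1  L-V-GENE-UNIT  4742..5281    -       Functional     24
2  L-V-GENE-UNIT  9983..10522   -       Pseudogene     24
3  D-GENE-UNIT    15303..15385  -       Functional     10
4  J-GENE-UNIT    20223..20303  -       Functional     8
5  J-GENE-UNIT    25116..25196  -       ORF            8
```

Each row is one delimited gene, 5'→3' in the analysed sequence: its
description status (a fully described V gene unit carries 24 labels, D 10,
J 8), position, strand, functionality call, and label count. All five rows
match the planted truth exactly, including the Pseudogene (a stop codon in
FR3) and the ORF (a mutated recombination heptamer). The other examples
show the ontology layer (`relations_and_clusters.py`), the functionality
cascade on lesioned units (`classify_functionality.py`) and the raw
HSP-to-description path (`search_and_describe.py`).

A thin CLI wraps the same library:

```bash
ligmotif simulate --seed 42 --out sim/           # locus.fasta + truth.gff3 + refdb/
ligmotif annotate --in sim/locus.fasta --refdb sim/refdb --out results/
ligmotif build-refdb --fasta units.fasta --gff3 units.gff3 --out refdb/
```

`annotate` writes GFF3 (1-based, feature type = label name), a main TSV
table, a per-label detail TSV (nucleotide and, for coding regions, amino
acid sequences) and a JSON summary.

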