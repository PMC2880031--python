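"""Synthetic germline loci with known truth.

The generator emulates the genomic architecture the annotator assumes: V
genes with a split leader (L-PART1, intron, L-PART2) followed by a V-REGION
and a 3' recombination signal; D genes with a very short coding region (8-37
bp) flanked by two recombination signals; J genes with a 5' recombination
signal, a 37-69 bp J-REGION carrying the conserved [W,F]-[G,A]-X-G motif and
a 3' donor splice.  Recombination-signal spacers follow the 12/23 rule
(23-spacer V-RS and 3'D-RS, 12-spacer 5'D-RS and J-RS).

For each gene type a subgroup ancestor is synthesised once per locus; the
reference database is built from low-divergence family variants of the
ancestor while planted genes diverge further (default 10%/site, i.e. within
the >75% identity that members of one subgroup share), so that search and
description must tolerate subgroup divergence.  Mutations are substitutions
only, leaving truth coordinates equal to template coordinates, and protected
positions (conserved motifs, splice sites, signal sequences) are never
touched; lesions defining non-functional classes are applied afterwards:

* Pseudogene: a stop codon in the V FR3 or leader, loss of the J
  [W,F]-[G,A]-X-G motif, or stop codons in every D-REGION frame;
* ORF: a 2-mismatch lesion of a recombination-signal heptamer (detectable
  approximately, but absent from the functional signal sets);
* Unknown: a destroyed V-NONAMER, leaving the unit undescribable in full.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .core import Interval, Strand, revcomp, translate, STOP_CODONS
from .errors import LigmotifError
from .refdb import AnnotatedRecord, RefDB, build_refdb

_BASES = "acgt"
_NONSTOP = sorted(set(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
) - STOP_CODONS)

#: consensus recombination-signal motifs used by every synthetic subgroup
HEPTAMER_CODING_SIDE = "cacagtg"   # abuts V / 3'D coding 3' ends
HEPTAMER_REGION_SIDE = "cactgtg"   # abuts J / D coding 5' ends
NONAMER_3 = "acaaaaacc"
NONAMER_5 = "ggtttttgt"

_SCRAMBLE = str.maketrans("acgt", "cagt"[::-1])  # a<->t-ish full mismatch map


@dataclass(frozen=True)
class PlantedGene:
    gene_type: str
    strand: Strand
    functionality: str  # F | ORF | P | U (planned truth class)
    expected_status: str  # described | partially_described
    features: dict[str, Interval]  # plus-strand locus coordinates
    unit_interval: Interval

    def feature(self, label: str) -> Interval:
        return self.features[label]


@dataclass(frozen=True)
class LocusSpec:
    """Study conditions for one synthetic locus."""

    n_v: int = 10
    n_d: int = 3
    n_j: int = 5
    background_length: int = 200_000
    gc: float = 0.40
    divergence: float = 0.10  # planted genes vs subgroup ancestor, per site
    family_divergence: float = 0.03  # reference family vs ancestor
    family_size: int = 4
    min_separation: int = 1_500  # nt between consecutive unit ends/starts
    strands: str = "both"  # both | plus | minus
    plan: tuple[tuple[str, str], ...] | None = None  # explicit (type, class)

    def __post_init__(self) -> None:
        if not 0 <= self.divergence <= 0.4:
            raise LigmotifError("divergence must be within [0, 0.4]")
        if min(self.n_v, self.n_d, self.n_j) < 0:
            raise LigmotifError("gene counts must be >= 0")

    def gene_plan(self) -> tuple[tuple[str, str], ...]:
        if self.plan is not None:
            return self.plan
        return tuple(
            [("V", _default_mix(i, self.n_v, "V")) for i in range(self.n_v)]
            + [("D", _default_mix(i, self.n_d, "D")) for i in range(self.n_d)]
            + [("J", _default_mix(i, self.n_j, "J")) for i in range(self.n_j)]
        )


def _default_mix(i: int, n: int, gene_type: str) -> str:
    """Default functionality composition: mostly functional, plus one each of
    the lesion classes when the count allows."""
    lesions = {"V": ("P", "P", "ORF", "U"), "D": ("P",), "J": ("P", "ORF")}[gene_type]
    # the last len(lesions) genes of each type carry the lesions
    idx_from_end = n - 1 - i
    if idx_from_end < len(lesions):
        return lesions[idx_from_end]
    return "F"


@dataclass(frozen=True)
class _Template:
    sequence: str
    features: dict[str, Interval]
    protected: frozenset[int]
    coding_codon_starts: tuple[int, ...]  # first-nt offsets of guarded codons


class SyntheticLocus:
    def __init__(self, sequence: str, genes: list[PlantedGene], refdb: RefDB,
                 spec: LocusSpec, name: str = "synthetic_locus"):
        self.sequence = sequence
        self.genes = genes
        self.refdb = refdb
        self.spec = spec
        self.name = name

    def fasta_text(self) -> str:
        lines = [f">{self.name}"]
        lines += [self.sequence[i : i + 70] for i in range(0, len(self.sequence), 70)]
        return "\n".join(lines) + "\n"

    def truth_gff3_text(self) -> str:
        rows = ["##gff-version 3",
                f"##sequence-region {self.name} 1 {len(self.sequence)}"]
        for i, g in enumerate(sorted(self.genes, key=lambda g: g.unit_interval), 1):
            order = sorted(g.features.items(), key=lambda kv: (kv[1].start, -len(kv[1])))
            for label, iv in order:
                attrs = (f"ID=gene{i}.{label};gene_type={g.gene_type};"
                         f"functionality={g.functionality}")
                rows.append("\t".join([
                    self.name, "ligmotif_synthetic", label,
                    str(iv.start + 1), str(iv.end), ".", g.strand, ".", attrs,
                ]))
        return "\n".join(rows) + "\n"


# --------------------------------------------------------------------------
# templates


def _fill_codons(rng: np.random.Generator, n: int, exclude: frozenset[str] = frozenset()):
    pool = [c for c in _NONSTOP if c not in exclude]
    return "".join(pool[rng.integers(0, len(pool))] for _ in range(n))


_LEADER_EXCLUDE = frozenset({"atg"})
_JREGION_EXCLUDE = frozenset({"tgg", "ttt", "ttc"})


def _v_template(rng: np.random.Generator) -> _Template:
    leader = "atg" + _fill_codons(rng, 18, _LEADER_EXCLUDE)  # 57 nt, sf1 split at 46
    lp1, lp2 = leader[:46], leader[46:]
    region_codons = [None] * 108
    region_codons[22], region_codons[40], region_codons[103] = "tgc", "tgg", "tgt"
    region = "".join(
        c if c is not None else _fill_codons(rng, 1) for c in region_codons
    )
    # intron interior: pyrimidine tail keeps the acceptor the 5'-most feasible 'ag'
    interior = "".join(_BASES[rng.integers(0, 4)] for _ in range(71)) + "".join(
        "ct"[rng.integers(0, 2)] for _ in range(45)
    )
    intron = "gt" + interior + "ag"  # 120 nt
    spacer = "".join(_BASES[rng.integers(0, 4)] for _ in range(23))
    seq = lp1 + intron + lp2 + region + HEPTAMER_CODING_SIDE + spacer + NONAMER_3
    f = {
        "L-PART1": Interval(0, 46), "INIT-CODON": Interval(0, 3),
        "DONOR-SPLICE": Interval(46, 48), "V-INTRON": Interval(46, 166),
        "ACCEPTOR-SPLICE": Interval(164, 166), "V-EXON": Interval(166, 501),
        "L-PART2": Interval(166, 177), "L-INTRON-L": Interval(0, 177),
        "V-REGION": Interval(177, 501),
        "FR1-IMGT": Interval(177, 255), "CDR1-IMGT": Interval(255, 291),
        "FR2-IMGT": Interval(291, 342), "CDR2-IMGT": Interval(342, 372),
        "FR3-IMGT": Interval(372, 489), "CDR3-IMGT": Interval(489, 501),
        "1st-CYS": Interval(243, 246), "CONSERVED-TRP": Interval(297, 300),
        "2nd-CYS": Interval(486, 489),
        "V-RS": Interval(501, 540), "V-HEPTAMER": Interval(501, 508),
        "V-SPACER": Interval(508, 531), "V-NONAMER": Interval(531, 540),
        "L-V-GENE-UNIT": Interval(0, 540), "V-GENE-UNIT": Interval(166, 540),
    }
    protected = set()
    for label in ("INIT-CODON", "DONOR-SPLICE", "ACCEPTOR-SPLICE", "1st-CYS",
                  "CONSERVED-TRP", "2nd-CYS", "V-HEPTAMER", "V-NONAMER"):
        protected.update(range(*f[label]))
    protected.update(range(33, 48))    # no spurious donor 'gt' at the leader 3' end
    protected.update(range(151, 166))  # keep the acceptor-proximal tail 'ag'-free
    codon_starts = tuple(range(0, 45, 3)) + tuple(range(168, 501, 3))
    return _Template(seq, f, frozenset(protected), codon_starts)


def _j_template(rng: np.random.Generator) -> _Template:
    spacer = "".join(_BASES[rng.integers(0, 4)] for _ in range(12))
    codons = [None] * 16
    codons[8], codons[9], codons[10], codons[11] = "ttc", "gga", "act", "ggt"
    while True:
        body = "".join(c if c is not None else _fill_codons(rng, 1, _JREGION_EXCLUDE)
                       for c in codons)
        # the stretch between the heptamer-gap minimum and the conserved Phe
        # must hold no W/F codon in any phase, or the pattern cannot anchor it
        window = body[13:26]
        if not any(w in window for w in ("tgg", "ttt", "ttc")):
            break
    jregion = "".join(_BASES[rng.integers(0, 4)] for _ in range(2)) + body \
        + _BASES[rng.integers(0, 4)]  # 51 nt, sf1 donor
    seq = NONAMER_5 + spacer + HEPTAMER_REGION_SIDE + jregion + "gt"
    f = {
        "J-RS": Interval(0, 28), "J-NONAMER": Interval(0, 9),
        "J-SPACER": Interval(9, 21), "J-HEPTAMER": Interval(21, 28),
        "J-REGION": Interval(28, 79), "J-PHE": Interval(54, 57),
        "DONOR-SPLICE": Interval(79, 81), "J-GENE-UNIT": Interval(0, 79),
    }
    protected = set()
    for label in ("J-NONAMER", "J-HEPTAMER", "J-PHE", "DONOR-SPLICE"):
        protected.update(range(*f[label]))
    protected.update(range(57, 66))  # the [G,A]-X-G codons after the conserved Phe
    protected.update(range(43, 54))  # keep the pre-Phe window free of W/F codons
    codon_starts = tuple(range(30, 78, 3))
    return _Template(seq, f, frozenset(protected), codon_starts)


def _d_template(rng: np.random.Generator) -> _Template:
    spacer5 = "".join(_BASES[rng.integers(0, 4)] for _ in range(12))
    spacer3 = "".join(_BASES[rng.integers(0, 4)] for _ in range(23))
    while True:  # D-REGION must keep at least one open reading frame
        dregion = "".join(_BASES[rng.integers(0, 4)] for _ in range(16))
        if any("*" not in translate(dregion[k:]) for k in range(3)):
            break
    seq = (NONAMER_5 + spacer5 + HEPTAMER_REGION_SIDE + dregion
           + HEPTAMER_CODING_SIDE + spacer3 + NONAMER_3)
    f = {
        "5'D-RS": Interval(0, 28), "5'D-NONAMER": Interval(0, 9),
        "5'D-SPACER": Interval(9, 21), "5'D-HEPTAMER": Interval(21, 28),
        "D-REGION": Interval(28, 44),
        "3'D-RS": Interval(44, 83), "3'D-HEPTAMER": Interval(44, 51),
        "3'D-SPACER": Interval(51, 74), "3'D-NONAMER": Interval(74, 83),
        "D-GENE-UNIT": Interval(0, 83),
    }
    protected = set()
    for label in ("5'D-NONAMER", "5'D-HEPTAMER", "3'D-HEPTAMER", "3'D-NONAMER"):
        protected.update(range(*f[label]))
    return _Template(seq, f, frozenset(protected), ())


_TEMPLATE_BUILDERS = {"V": _v_template, "J": _j_template, "D": _d_template}


# --------------------------------------------------------------------------
# mutation and lesions


def _mutate(template: _Template, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only divergence; protected positions untouched, guarded
    codons never become stops."""
    seq = list(template.sequence)
    guarded = {c: True for c in template.coding_codon_starts}
    for p in range(len(seq)):
        if p in template.protected or rng.random() >= rate:
            continue
        old = seq[p]
        new = _BASES[rng.integers(0, 4)]
        while new == old:
            new = _BASES[rng.integers(0, 4)]
        seq[p] = new
        c = p - (p % 3)
        for start in (p - 2, p - 1, p):
            if start in guarded and "".join(seq[start : start + 3]) in STOP_CODONS:
                seq[p] = old
                break
    return "".join(seq)


def _lesion(gene_type: str, functionality: str, seq: str, t: _Template,
            rng: np.random.Generator, variant: int = 0) -> str:
    s = list(seq)

    def put(iv: Interval, text: str) -> None:
        s[iv.start : iv.end] = list(text)

    if functionality == "F":
        pass
    elif gene_type == "V" and functionality == "P":
        if variant % 2 == 0:
            put(Interval(417, 420), "taa")  # stop codon inside FR3-IMGT
        else:
            put(Interval(15, 18), "taa")  # stop codon inside L-PART1
    elif gene_type == "V" and functionality == "ORF":
        hep = list(seq[t.features["V-HEPTAMER"].start : t.features["V-HEPTAMER"].end])
        for k in (2, 5):
            hep[k] = {"a": "c", "c": "a", "g": "t", "t": "g"}[hep[k]]
        put(t.features["V-HEPTAMER"], "".join(hep))
    elif gene_type == "V" and functionality == "U":
        nona = seq[t.features["V-NONAMER"].start : t.features["V-NONAMER"].end]
        put(t.features["V-NONAMER"], nona.translate(_SCRAMBLE))
    elif gene_type == "J" and functionality == "P":
        put(Interval(57, 60), "cca")  # Gly -> Pro kills [W,F]-[G,A]-X-G
    elif gene_type == "J" and functionality == "ORF":
        hep = list(seq[t.features["J-HEPTAMER"].start : t.features["J-HEPTAMER"].end])
        for k in (2, 5):
            hep[k] = {"a": "c", "c": "a", "g": "t", "t": "g"}[hep[k]]
        put(t.features["J-HEPTAMER"], "".join(hep))
    elif gene_type == "D" and functionality == "P":
        while True:  # stop codons in all three D-REGION frames
            dr = "".join(_BASES[rng.integers(0, 4)] for _ in range(16))
            if all("*" in translate(dr[k:]) for k in range(3)):
                break
        put(t.features["D-REGION"], dr)
    elif gene_type == "D" and functionality == "ORF":
        hep = list(seq[t.features["5'D-HEPTAMER"].start : t.features["5'D-HEPTAMER"].end])
        for k in (2, 5):
            hep[k] = {"a": "c", "c": "a", "g": "t", "t": "g"}[hep[k]]
        put(t.features["5'D-HEPTAMER"], "".join(hep))
    else:
        raise LigmotifError(
            f"no lesion defined for gene type {gene_type} class {functionality}"
        )
    return "".join(s)


def _class_holds(gene_type: str, functionality: str, seq: str, t: _Template) -> bool:
    """Cheap post-hoc predicates ensuring the planted class is realized."""
    f = t.features
    if gene_type == "V":
        lp1 = seq[f["L-PART1"].start : f["L-PART1"].end]
        exon = seq[f["V-EXON"].start : f["V-EXON"].end]
        clean = "*" not in translate(lp1) and "*" not in translate(exon[2:])
        if functionality == "U":
            # the destroyed nonamer must leave no close 9-mer at any
            # admissible spacer distance, or the unit stays describable
            hept_end = f["V-HEPTAMER"].end
            for gap in (11, 12, 13, 22, 23, 24):
                w = seq[hept_end + gap : hept_end + gap + 9]
                if len(w) == 9 and sum(a != b for a, b in zip(w, NONAMER_3)) < 3:
                    return False
        if functionality in ("F", "ORF", "U"):
            return clean and lp1.startswith("atg")
        return True
    if gene_type == "J":
        jr = seq[f["J-REGION"].start : f["J-REGION"].end]
        pep = translate(jr[2:])
        import re

        has_motif = re.search(r"[WF][GA][^P*]G", pep) is not None
        if functionality == "P":
            return "*" not in pep and not has_motif
        return "*" not in pep and has_motif
    dr = seq[f["D-REGION"].start : f["D-REGION"].end]
    frames_open = any("*" not in translate(dr[k:]) for k in range(3))
    return not frames_open if functionality == "P" else frames_open


class TemplateFamily:
    """Per-locus subgroup ancestors plus variant/unit samplers."""

    def __init__(self, rng: np.random.Generator):
        self.templates = {g: _TEMPLATE_BUILDERS[g](rng) for g in ("V", "D", "J")}

    def variant(self, gene_type: str, rng: np.random.Generator, rate: float) -> str:
        t = self.templates[gene_type]
        for _ in range(60):
            seq = _mutate(t, rate, rng)
            if _class_holds(gene_type, "F", seq, t):
                return seq
        raise LigmotifError("could not realize a functional family variant")

    def unit(self, gene_type: str, functionality: str, rng: np.random.Generator,
             divergence: float, variant: int = 0) -> tuple[str, _Template]:
        t = self.templates[gene_type]
        for _ in range(60):
            seq = _lesion(gene_type, functionality, _mutate(t, divergence, rng),
                          t, rng, variant)
            if _class_holds(gene_type, functionality, seq, t):
                return seq, t
        raise LigmotifError(
            f"could not realize a {gene_type}/{functionality} unit"
        )


def synth_gene_unit(
    gene_type: str, functionality: str, rng: np.random.Generator,
    divergence: float = 0.10, family: TemplateFamily | None = None,
) -> tuple[str, dict[str, Interval]]:
    """One synthetic gene unit (sequence + truth features, unit coordinates)."""
    family = family or TemplateFamily(rng)
    seq, template = family.unit(gene_type, functionality, rng, divergence)
    return seq, dict(template.features)


def family_refdb(family: TemplateFamily, rng: np.random.Generator,
                 spec: LocusSpec) -> RefDB:
    """Reference motif databases built from the template family variants."""
    records = []
    for gene_type in ("V", "D", "J"):
        t = family.templates[gene_type]
        for k in range(spec.family_size):
            seq = family.variant(gene_type, rng, spec.family_divergence)
            records.append(
                AnnotatedRecord(
                    id=f"{gene_type}.fam{k}",
                    sequence=seq,
                    features=tuple(t.features.items()),
                    species="synthetic",
                    locus="SYN",
                    gene_type=gene_type,
                    functionality="F",
                )
            )
    return build_refdb(records)


def synth_locus(spec: LocusSpec, rng: np.random.Generator,
                name: str = "synthetic_locus") -> SyntheticLocus:
    """A full synthetic locus: background, planted genes on both strands,
    truth features and the matching reference database."""
    family = TemplateFamily(rng)
    refdb = family_refdb(family, rng, spec)

    plan = spec.gene_plan()
    units = []
    per_class_counter: dict[tuple[str, str], int] = {}
    for gene_type, functionality in plan:
        k = per_class_counter.get((gene_type, functionality), 0)
        per_class_counter[(gene_type, functionality)] = k + 1
        seq, template = family.unit(gene_type, functionality, rng,
                                    spec.divergence, variant=k)
        units.append((gene_type, functionality, seq, template))

    total_units = sum(len(u[2]) for u in units)
    n_gaps = len(units) + 1
    free = spec.background_length - total_units - n_gaps * spec.min_separation
    if free < 0:
        raise LigmotifError(
            f"locus of {spec.background_length} nt cannot hold {len(units)} genes "
            f"with {spec.min_separation} nt separation"
        )
    extra = rng.multinomial(free, [1.0 / n_gaps] * n_gaps) if free else [0] * n_gaps

    p_gc = spec.gc / 2.0
    probs = [0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]  # a, c, g, t

    def background(n: int) -> str:
        idx = rng.choice(4, size=n, p=probs)
        return "".join(_BASES[i] for i in idx)

    chunks: list[str] = []
    genes: list[PlantedGene] = []
    pos = 0
    for i, (gene_type, functionality, unit_seq, template) in enumerate(units):
        gap = spec.min_separation + int(extra[i])
        chunks.append(background(gap))
        pos += gap
        if spec.strands == "plus":
            strand = "+"
        elif spec.strands == "minus":
            strand = "-"
        else:
            strand = "+-"[rng.integers(0, 2)]
        if strand == "+":
            placed = unit_seq
            feats = {lbl: Interval(pos + iv.start, pos + iv.end)
                     for lbl, iv in template.features.items()}
        else:
            placed = revcomp(unit_seq)
            n = len(unit_seq)
            feats = {lbl: Interval(pos + n - iv.end, pos + n - iv.start)
                     for lbl, iv in template.features.items()}
        chunks.append(placed)
        genes.append(
            PlantedGene(
                gene_type=gene_type,
                strand=strand,
                functionality=functionality,
                expected_status=(
                    "partially_described" if functionality == "U" else "described"
                ),
                features=feats,
                unit_interval=Interval(pos, pos + len(unit_seq)),
            )
        )
        pos += len(unit_seq)
    tail = spec.min_separation + int(extra[-1])
    chunks.append(background(tail))
    sequence = "".join(chunks)
    return SyntheticLocus(sequence, genes, refdb, spec, name=name)
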