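"""Sequence input and annotation output.

Reads FASTA or EMBL flat files (multi-record FASTA becomes a batch), and
writes the annotated cluster as GFF3 (1-based inclusive coordinates, feature
type = label name, Sequence Ontology terms where a mapping exists), a main
TSV table (one gene per row, 5'->3'), a per-gene label detail TSV, and a
machine-readable JSON summary mirroring the result-page statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from Bio import SeqIO

from .assembly import AnnotatedGene, ClusterAnnotation
from .core import Interval, feature_seq
from .description import STATUS_DESCRIBED
from .errors import ParseError
from .functionality import coding_peptides
from .refdb import AnnotatedRecord

_ALPHABET = frozenset("acgtn")

_UNIT_LABEL = {"V": "L-V-GENE-UNIT", "D": "D-GENE-UNIT", "J": "J-GENE-UNIT"}


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str  # lower-case, {a,c,g,t,n}

    @property
    def n_count(self) -> int:
        return self.sequence.count("n")


def read_sequence(source: str | Path, format: str = "auto") -> list[SequenceRecord]:
    """Parse FASTA or EMBL input (a path or the raw text itself)."""
    text = None
    path = Path(str(source))
    try:
        if path.exists() and path.is_file():
            text = path.read_text()
    except OSError:
        text = None
    if text is None:
        text = str(source)
    stripped = text.lstrip()
    if not stripped:
        raise ParseError("empty input")
    if format == "auto":
        format = "fasta" if stripped.startswith(">") else "embl"
    if format not in ("fasta", "embl"):
        raise ParseError(f"unknown sequence format {format!r}")
    try:
        seqio_records = list(SeqIO.parse(StringIO(text), format))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise ParseError(f"cannot parse {format} input: {exc}") from exc
    if not seqio_records:
        raise ParseError(f"no sequence records found in {format} input")
    records = []
    for rec in seqio_records:
        seq = str(rec.seq).lower()
        bad = set(seq) - _ALPHABET
        if bad:
            pos = next(i for i, b in enumerate(seq) if b in bad)
            line = text[:pos].count("\n") + 1  # approximate source line
            raise ParseError(
                f"record {rec.id}: invalid character {seq[pos]!r} "
                f"(sequence position {pos + 1}, near input line {line})"
            )
        if not seq:
            raise ParseError(f"record {rec.id} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def read_annotated_records(fasta: str | Path, gff3: str | Path) -> list[AnnotatedRecord]:
    """Truth input for database building: one FASTA record per gene unit
    (header `id|species|locus|gene_type|functionality`) plus a GFF3 whose
    seqids match the record ids and whose types are vocabulary labels."""
    feats: dict[str, list[tuple[str, Interval]]] = {}
    for line in Path(gff3).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ParseError(f"malformed GFF3 row: {line[:80]}")
        seqid, _, label, start, end = cols[0], cols[1], cols[2], cols[3], cols[4]
        feats.setdefault(seqid, []).append((label, Interval(int(start) - 1, int(end))))
    records = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        parts = (rec.description or rec.id).split("|")
        parts += [""] * (5 - len(parts))
        records.append(
            AnnotatedRecord(
                id=parts[0],
                sequence=str(rec.seq).lower(),
                features=tuple(feats.get(parts[0], ())),
                species=parts[1],
                locus=parts[2],
                gene_type=parts[3],
                functionality=parts[4],
            )
        )
    return records


# --------------------------------------------------------------------------
# writers


def _esc(value: str) -> str:
    out = []
    for ch in str(value):
        if ch in "%;=&,\t\n":
            out.append(f"%{ord(ch):02X}")
        else:
            out.append(ch)
    return "".join(out)


def ordered_features(gene: AnnotatedGene) -> list[tuple[str, Interval]]:
    """Unit labels plus UTRs, 5'->3'; at equal starts the longest first."""
    items = list(gene.unit.features.items())
    if gene.utr5 is not None:
        items.append(("5'UTR", gene.utr5))
    if gene.utr3 is not None:
        items.append(("3'UTR", gene.utr3))
    return sorted(items, key=lambda kv: (kv[1].start, -len(kv[1]), kv[0]))


def gene_description(gene: AnnotatedGene) -> str:
    unit = gene.unit
    if unit.status == STATUS_DESCRIBED:
        return _UNIT_LABEL[unit.gene_type]
    return f"{unit.gene_type} {unit.status.replace('_', ' ')}"


def gff3_text(cluster: ClusterAnnotation, record: SequenceRecord) -> str:
    n = len(record.sequence)
    rows = ["##gff-version 3", f"##sequence-region {record.id} 1 {n}"]

    def row(ftype, start, end, strand, attrs):
        rows.append(
            "\t".join(
                [record.id, "ligmotif", ftype, str(start + 1), str(end), ".",
                 strand, ".", ";".join(f"{k}={_esc(v)}" for k, v in attrs)]
            )
        )

    if cluster.cluster is not None:
        attrs = [("ID", "cluster1")]
        if cluster.cluster.so_id:
            attrs.append(("Ontology_term", cluster.cluster.so_id))
        row(cluster.cluster.name, 0, n, ".", attrs)
    for gene in cluster.genes:
        gid = f"gene{gene.number}"
        row(
            gene.gene_level_label,
            gene.gene_interval.start,
            gene.gene_interval.end,
            gene.unit.strand,
            [("ID", gid), ("Number", str(gene.number)),
             ("status", gene.unit.status),
             ("functionality", gene.functionality.value)],
        )
        for label, iv in ordered_features(gene):
            row(label, iv.start, iv.end, gene.unit.strand,
                [("ID", f"{gid}.{label}"), ("Parent", gid)])
    return "\n".join(rows) + "\n"


def main_table_text(cluster: ClusterAnnotation) -> str:
    rows = ["\t".join(["N", "Description", "Positions", "Strand",
                       "Functionality", "Number of labels"])]
    for gene in cluster.genes:
        span = gene.unit.span
        rows.append(
            "\t".join([
                str(gene.number),
                gene_description(gene),
                f"{span.start + 1}..{span.end}",
                gene.unit.strand,
                gene.functionality.value,
                str(gene.unit.label_count()),
            ])
        )
    return "\n".join(rows) + "\n"


def labels_table_text(cluster: ClusterAnnotation, record: SequenceRecord) -> str:
    rows = ["\t".join(["N", "Label", "Start", "End", "Length", "Strand",
                       "Sequence", "AA"])]
    for gene in cluster.genes:
        peptides = coding_peptides(gene.unit, record.sequence)
        for label, iv in ordered_features(gene):
            rows.append(
                "\t".join([
                    str(gene.number), label, str(iv.start + 1), str(iv.end),
                    str(len(iv)), gene.unit.strand,
                    feature_seq(record.sequence, iv, gene.unit.strand),
                    peptides.get(label, ""),
                ])
            )
    return "\n".join(rows) + "\n"


def summary_dict(cluster: ClusterAnnotation, record: SequenceRecord) -> dict:
    return {
        "sequence_id": record.id,
        "sequence_length": len(record.sequence),
        "n_bases": record.n_count,
        "cluster": cluster.cluster.name if cluster.cluster else None,
        "cluster_so_id": cluster.cluster.so_id if cluster.cluster else None,
        "stats": cluster.stats,
        "genes": [
            {
                "number": g.number,
                "description": gene_description(g),
                "gene_type": g.unit.gene_type,
                "strand": g.unit.strand,
                "status": g.unit.status,
                "functionality": g.functionality.value,
                "failed_criteria": list(g.functionality.failed_criteria),
                "unit_start": g.unit.span.start + 1,
                "unit_end": g.unit.span.end,
                "gene_start": g.gene_interval.start + 1,
                "gene_end": g.gene_interval.end,
                "n_labels": g.unit.label_count(),
            }
            for g in cluster.genes
        ],
    }


def write_annotations(
    cluster: ClusterAnnotation,
    record: SequenceRecord,
    outdir: str | Path,
    stem: str | None = None,
) -> dict[str, Path]:
    """Write GFF3 + main TSV + label detail TSV + JSON summary; returns the
    paths keyed by kind."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or record.id
    paths = {
        "gff3": outdir / f"{stem}.gff3",
        "tsv": outdir / f"{stem}.tsv",
        "labels": outdir / f"{stem}.labels.tsv",
        "summary": outdir / f"{stem}.summary.json",
    }
    paths["gff3"].write_text(gff3_text(cluster, record))
    paths["tsv"].write_text(main_table_text(cluster))
    paths["labels"].write_text(labels_table_text(cluster, record))
    paths["summary"].write_text(
        json.dumps(summary_dict(cluster, record), indent=2, sort_keys=True) + "\n"
    )
    return paths
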