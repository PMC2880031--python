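"""Reference motif databases and position-specific scoring matrices.

The annotator is driven by per-label collections of reference nucleotide
sequences: 26 label databases feed the BLAST-stage similarity search (gene
identification) and 8 heptamer/nonamer databases (plus V-EXON, which serves
both stages) feed the conserved-motif search of gene description and the
functionality check "signals identical to ones found in functional genes".
Databases are built from annotated records (sequence + labelled truth
features + provenance metadata) and stored on disk as one FASTA per label
with a YAML manifest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .core import Interval
from .errors import RefDBError

logger = logging.getLogger(__name__)

#: labels searched by the local-alignment (BLAST) stage of gene identification
BLAST_LABELS: frozenset[str] = frozenset(
    {
        "L-V-GENE-UNIT", "V-GENE-UNIT", "L-PART1", "V-INTRON", "L-INTRON-L",
        "V-EXON", "L-PART2", "V-REGION", "FR1-IMGT", "CDR1-IMGT", "FR2-IMGT",
        "CDR2-IMGT", "FR3-IMGT", "CDR3-IMGT", "V-RS", "V-SPACER",
        "D-GENE-UNIT", "5'D-RS", "5'D-SPACER", "D-REGION", "3'D-RS", "3'D-SPACER",
        "J-GENE-UNIT", "J-RS", "J-SPACER", "J-REGION",
    }
)

#: heptamer/nonamer labels used by gene description and functionality
MOTIF_LABELS: frozenset[str] = frozenset(
    {
        "V-HEPTAMER", "V-NONAMER",
        "5'D-NONAMER", "5'D-HEPTAMER", "3'D-HEPTAMER", "3'D-NONAMER",
        "J-NONAMER", "J-HEPTAMER",
    }
)

ALL_DB_LABELS: frozenset[str] = BLAST_LABELS | MOTIF_LABELS

_MOTIF_LENGTH = {lbl: (7 if "HEPTAMER" in lbl else 9) for lbl in MOTIF_LABELS}

_ALPHABET = frozenset("acgtn")


@dataclass(frozen=True)
class RefDbEntry:
    id: str
    sequence: str
    species: str = ""
    locus: str = ""
    gene_type: str = ""
    functionality: str = ""  # F | ORF | P | ""
    extras: tuple[tuple[str, str], ...] = ()

    def extras_dict(self) -> dict[str, str]:
        return dict(self.extras)


@dataclass(frozen=True)
class AnnotatedRecord:
    """A truth-annotated sequence from which label databases are extracted."""

    id: str
    sequence: str
    features: tuple[tuple[str, Interval], ...]
    species: str = ""
    locus: str = ""
    gene_type: str = ""
    functionality: str = ""
    poorly_conserved: bool = False


@dataclass
class RefDB:
    entries: dict[str, list[RefDbEntry]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add(self, label: str, entry: RefDbEntry) -> None:
        if label not in ALL_DB_LABELS:
            raise RefDBError(f"unknown reference database label {label!r}")
        seq = entry.sequence
        if not seq or not set(seq) <= _ALPHABET:
            raise RefDBError(f"bad sequence for {label}/{entry.id}")
        expected = _MOTIF_LENGTH.get(label)
        if expected is not None and len(seq) != expected:
            raise RefDBError(
                f"{label} entry {entry.id} has length {len(seq)}, expected {expected}"
            )
        self.entries.setdefault(label, []).append(entry)

    def labels(self) -> list[str]:
        return sorted(self.entries)

    def get(self, label: str) -> list[RefDbEntry]:
        return self.entries.get(label, [])

    def sequences(self, label: str) -> list[str]:
        return [e.sequence for e in self.get(label)]

    def sequence_set(self, label: str) -> frozenset[str]:
        return frozenset(self.sequences(label))

    def is_empty(self) -> bool:
        return not any(self.entries.values())

    def n_entries(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def select(
        self,
        species: Iterable[str] | None = None,
        locus: Iterable[str] | None = None,
        gene_type: Iterable[str] | None = None,
        functionality: Iterable[str] | None = None,
    ) -> "RefDB":
        """A filtered view (new RefDB) restricted on provenance metadata."""
        crit = {
            "species": frozenset(species) if species else None,
            "locus": frozenset(locus) if locus else None,
            "gene_type": frozenset(gene_type) if gene_type else None,
            "functionality": frozenset(functionality) if functionality else None,
        }
        out = RefDB(metadata=dict(self.metadata))
        for label, entries in self.entries.items():
            kept = [
                e for e in entries
                if all(v is None or getattr(e, k) in v for k, v in crit.items())
            ]
            if kept:
                out.entries[label] = kept
        return out

    # ----------------------------------------------------------- persistence

    def write(self, directory: str | Path) -> None:
        """One `<LABEL>.fasta` per label plus a `refdb.yaml` manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"labels": {}, "metadata": self.metadata}
        for label in self.labels():
            fname = f"{label}.fasta"
            manifest["labels"][label] = fname
            with open(directory / fname, "w") as fh:
                for e in self.entries[label]:
                    fields = [e.id, e.species, e.locus, e.gene_type, e.functionality]
                    fields += [f"{k}={v}" for k, v in e.extras]
                    fh.write(">" + "|".join(fields) + "\n")
                    fh.write(e.sequence + "\n")
        with open(directory / "refdb.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    @classmethod
    def load(cls, directory: str | Path) -> "RefDB":
        directory = Path(directory)
        manifest_path = directory / "refdb.yaml"
        if not manifest_path.exists():
            raise RefDBError(f"no refdb.yaml manifest under {directory}")
        manifest = yaml.safe_load(manifest_path.read_text())
        db = cls(metadata=manifest.get("metadata") or {})
        for label, fname in manifest["labels"].items():
            for header, seq in _iter_fasta(directory / fname):
                parts = header.split("|")
                core, kv = parts[:5], parts[5:]
                core += [""] * (5 - len(core))
                extras = tuple(tuple(p.split("=", 1)) for p in kv if "=" in p)
                db.add(
                    label,
                    RefDbEntry(core[0], seq.lower(), core[1], core[2], core[3], core[4], extras),
                )
        return db


def _iter_fasta(path: Path):
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header, chunks = line[1:], []
            else:
                chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


#: V-REGION internal features whose offsets are stored on V-REGION entries so
#: the V-exon annotator can transfer them onto a query exon
_V_REGION_INTERNAL = (
    "FR1-IMGT", "CDR1-IMGT", "FR2-IMGT", "CDR2-IMGT", "FR3-IMGT", "CDR3-IMGT",
    "1st-CYS", "CONSERVED-TRP", "2nd-CYS",
)


def build_refdb(
    records: Iterable[AnnotatedRecord],
    filters: Mapping[str, Iterable[str]] | None = None,
    exclude_poorly_conserved: bool = True,
) -> RefDB:
    """Extract per-label sequence collections from annotated records.

    `filters` may restrict on `species`, `locus`, `gene_type` and
    `functionality` (each a collection of accepted values).  Pseudogenes too
    poorly conserved to be assigned to subgroups are excluded by default.
    """
    filters = {k: frozenset(v) for k, v in (filters or {}).items()}
    db = RefDB(metadata={"filters": {k: sorted(v) for k, v in filters.items()}})
    n_records = 0
    for rec in records:
        if exclude_poorly_conserved and rec.poorly_conserved:
            continue
        if any(
            getattr(rec, key) not in accepted for key, accepted in filters.items()
        ):
            continue
        n_records += 1
        feats: dict[str, list[Interval]] = {}
        for label, iv in rec.features:
            feats.setdefault(label, []).append(iv)
        for label, iv in rec.features:
            if label not in ALL_DB_LABELS:
                continue
            if iv.start < 0 or iv.end > len(rec.sequence):
                raise RefDBError(
                    f"feature {label} {iv} outside record {rec.id} "
                    f"(length {len(rec.sequence)})"
                )
            extras: list[tuple[str, str]] = []
            if label == "V-REGION":
                for internal in _V_REGION_INTERNAL:
                    for sub in feats.get(internal, []):
                        if iv.contains(sub):
                            extras.append(
                                (internal, f"{sub.start - iv.start}-{sub.end - iv.start}")
                            )
            db.add(
                label,
                RefDbEntry(
                    id=rec.id,
                    sequence=rec.sequence[iv.start : iv.end].lower(),
                    species=rec.species,
                    locus=rec.locus,
                    gene_type=rec.gene_type,
                    functionality=rec.functionality,
                    extras=tuple(extras),
                ),
            )
    db.metadata["n_records"] = n_records
    if db.is_empty():
        logger.warning("reference motif database is empty: no record passed the filters")
    return db


@dataclass(frozen=True)
class FunctionalSignalSets:
    """Heptamer/nonamer sequences observed in functional genes, per RS label."""

    sets: Mapping[str, frozenset[str]]

    def contains(self, label: str, sequence: str) -> bool:
        return sequence.lower() in self.sets.get(label, frozenset())


def functional_signal_sets(db: RefDB) -> FunctionalSignalSets:
    """Restrict each signal database to entries from functional (F) genes."""
    return FunctionalSignalSets(
        sets={
            label: frozenset(
                e.sequence for e in db.get(label) if e.functionality == "F"
            )
            for label in MOTIF_LABELS
        }
    )


_BASE_INDEX = {"a": 0, "c": 1, "g": 2, "t": 3}


@dataclass(frozen=True)
class PSSM:
    """Ungapped log-odds position-specific scoring matrix over {a,c,g,t}.

    `matrix[i, b] = log2((count(b, i) + pc) / (N + 4 pc)) - log2(background_b)`.
    'n' in a scanned window contributes 0 bits (scores as background).  The
    default threshold is the minimum self-score of the training motifs, so
    every training motif matches its own matrix.
    """

    matrix: np.ndarray  # shape (L, 4)
    background: tuple[float, float, float, float]
    threshold: float

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def score(self, word: str) -> float:
        if len(word) != self.length:
            raise ValueError(f"word length {len(word)} != motif length {self.length}")
        total = 0.0
        for i, base in enumerate(word.lower()):
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                total += self.matrix[i, idx]
        return float(total)

    def scan(self, seq: str, min_score: float | None = None) -> list[tuple[int, float]]:
        """All window positions scoring at or above `min_score` (default: the
        calibrated threshold)."""
        cutoff = self.threshold if min_score is None else min_score
        out = []
        for pos in range(len(seq) - self.length + 1):
            s = self.score(seq[pos : pos + self.length])
            if s >= cutoff:
                out.append((pos, s))
        return out


def build_pssm(
    sequences: Sequence[str],
    pseudocount: float = 0.5,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> PSSM:
    """Build a PSSM from an equal-length motif training set."""
    if not sequences:
        raise RefDBError("cannot build a PSSM from an empty motif set")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise RefDBError("ragged motif lengths in PSSM training set")
    if pseudocount <= 0:
        raise RefDBError("pseudocount must be positive")
    counts = np.zeros((length, 4))
    n_eff = np.zeros(length)
    for seq in sequences:
        for i, base in enumerate(seq.lower()):
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                counts[i, idx] += 1
                n_eff[i] += 1
    bg = np.asarray(background, dtype=float)
    matrix = np.log2(
        (counts + pseudocount) / (n_eff[:, None] + 4.0 * pseudocount)
    ) - np.log2(bg[None, :])
    pssm = PSSM(matrix=matrix, background=tuple(bg), threshold=-math.inf)
    threshold = min(pssm.score(s) for s in sequences)
    return PSSM(matrix=matrix, background=tuple(bg), threshold=threshold)
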