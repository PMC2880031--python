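"""Labelled local-similarity search and best-HSP selection.

Stage 1a-1b of gene identification: the genomic query is aligned on both
strands against each reference motif database, yielding HSPs tagged with the
label of the database they came from; overlapping HSPs from the *same*
database are then reduced to the locally best one by the pairwise g1/g2 rule
(HSPs from different databases are expected components of one prototype and
are never filtered against each other).

Two interchangeable backends satisfy the same contract: a self-contained
seed-and-extend aligner (word hits, ungapped X-drop extension, Karlin-Altschul
E-values for the +1/-2 scoring system) and a wrapper around the NCBI blastn
binary.  The pipeline auto-selects blastn when it is on PATH; the internal
backend keeps the package dependency-free for small analyses and tests.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

from scipy.optimize import brentq

from .core import Interval, Strand, revcomp
from .errors import SearchError
from .refdb import BLAST_LABELS, RefDB

logger = logging.getLogger(__name__)

#: labels of the D prototype, searched at the relaxed E-value threshold
#: because of their very short length
D_LABELS: frozenset[str] = frozenset(
    {"D-GENE-UNIT", "5'D-RS", "5'D-SPACER", "D-REGION", "3'D-RS", "3'D-SPACER",
     "5'D-NONAMER", "5'D-HEPTAMER", "3'D-HEPTAMER", "3'D-NONAMER"}
)


@dataclass(frozen=True)
class HSP:
    """A labelled local-alignment hit, plus-strand query coordinates.

    `subject_interval` records which part of the reference motif the local
    alignment covers (forward subject coordinates); it lets downstream
    stages project reference boundaries onto the query.  A zero-length
    interval means the subject coordinates are unknown.
    """

    query_interval: Interval
    strand: Strand
    label: str
    subject_id: str
    score: float
    evalue: float
    identity: float  # percent, 0-100
    length: int  # alignment length in bp
    subject_interval: Interval = Interval(0, 0)

    def overlaps(self, other: "HSP") -> bool:
        return self.query_interval.overlaps(other.query_interval)


@dataclass(frozen=True)
class SearchParams:
    word_size: int = 4
    evalue_threshold: float = 0.01
    evalue_threshold_d: float = 5.0  # D-GENE-UNIT and its component labels
    backend: str = "auto"  # auto | internal | blastn
    match: int = 1
    mismatch: int = -2
    xdrop: int = 20

    def __post_init__(self) -> None:
        if self.word_size < 2:
            raise SearchError("word size must be >= 2")
        if self.evalue_threshold <= 0 or self.evalue_threshold_d <= 0:
            raise SearchError("E-value thresholds must be > 0")

    def threshold_for(self, label: str) -> float:
        return self.evalue_threshold_d if label in D_LABELS else self.evalue_threshold


@lru_cache(maxsize=None)
def _karlin_altschul(match: int, mismatch: int) -> tuple[float, float]:
    """Ungapped (lambda, K) for a match/mismatch system at uniform base
    frequencies; lambda solves sum_ij p_i p_j exp(lambda s_ij) = 1."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    lam = float(brentq(f, 1e-6, 10.0))
    return lam, 0.62


# --------------------------------------------------------------------------
# internal seed-and-extend backend


def _extend(query: str, subject: str, qpos: int, spos: int, w: int,
            match: int, mismatch: int, xdrop: int) -> tuple[int, int, int, int]:
    """Ungapped X-drop extension of a word hit; returns (qstart, qend, score,
    n_matches) on the query, half-open."""
    score = best = w * match
    n_match = best_match = w
    # right
    qi, si = qpos + w, spos + w
    best_q = qi
    cur, curm = score, n_match
    while qi < len(query) and si < len(subject):
        if query[qi] == subject[si]:
            cur += match
            curm += 1
        else:
            cur += mismatch
        if cur > best:
            best, best_q, best_match = cur, qi + 1, curm
        if best - cur > xdrop:
            break
        qi += 1
        si += 1
    qend = best_q
    score, n_match = best, best_match
    # left
    qi, si = qpos - 1, spos - 1
    best = score
    best_q = qpos
    cur, curm = score, n_match
    best_match = n_match
    while qi >= 0 and si >= 0:
        if query[qi] == subject[si]:
            cur += match
            curm += 1
        else:
            cur += mismatch
        if cur > best:
            best, best_q, best_match = cur, qi, curm
        if best - cur > xdrop:
            break
        qi -= 1
        si -= 1
    return best_q, qend, best, best_match


def _internal_search_one_strand(
    target: str,
    db: RefDB,
    params: SearchParams,
    strand: Strand,
    full_length: int,
) -> list[HSP]:
    w = params.word_size
    lam, kappa = _karlin_altschul(params.match, params.mismatch)
    index: dict[str, list[int]] = {}
    for pos in range(len(target) - w + 1):
        index.setdefault(target[pos : pos + w], []).append(pos)

    hsps: dict[tuple, HSP] = {}
    for label in sorted(BLAST_LABELS & set(db.entries)):
        entries = db.get(label)
        db_len = sum(len(e.sequence) for e in entries)
        threshold = params.threshold_for(label)
        for entry in entries:
            subject = entry.sequence
            covered: dict[int, int] = {}  # diagonal -> extended-through qend
            for spos in range(len(subject) - w + 1):
                positions = index.get(subject[spos : spos + w])
                if not positions:
                    continue
                for qpos in positions:
                    diag = qpos - spos
                    if covered.get(diag, -1) >= qpos + w:
                        continue
                    qstart, qend, score, n_match = _extend(
                        target, subject, qpos, spos, w,
                        params.match, params.mismatch, params.xdrop,
                    )
                    covered[diag] = max(covered.get(diag, -1), qend)
                    length = qend - qstart
                    if length < w:
                        continue
                    evalue = kappa * len(target) * db_len * math.exp(-lam * score)
                    if evalue > threshold:
                        continue
                    iv = Interval(qstart, qend)
                    if strand == "-":
                        iv = iv.mirror(full_length)
                    sstart = spos - (qpos - qstart)  # ungapped: same offsets
                    key = (label, strand, iv.start, iv.end, entry.id)
                    hsp = HSP(
                        query_interval=iv,
                        strand=strand,
                        label=label,
                        subject_id=entry.id,
                        score=float(score),
                        evalue=evalue,
                        identity=100.0 * n_match / length,
                        length=length,
                        subject_interval=Interval(sstart, sstart + length),
                    )
                    prev = hsps.get(key)
                    if prev is None or hsp.score > prev.score:
                        hsps[key] = hsp
    return list(hsps.values())


def _internal_search(query: str, db: RefDB, params: SearchParams) -> list[HSP]:
    out = _internal_search_one_strand(query, db, params, "+", len(query))
    out += _internal_search_one_strand(revcomp(query), db, params, "-", len(query))
    return out


# --------------------------------------------------------------------------
# external blastn backend


def blastn_available() -> bool:
    return shutil.which("blastn") is not None and shutil.which("makeblastdb") is not None


def _blastn_search(query: str, db: RefDB, params: SearchParams) -> list[HSP]:
    if not blastn_available():
        raise SearchError("blastn/makeblastdb not found on PATH")
    id_map: dict[str, tuple[str, str]] = {}
    with tempfile.TemporaryDirectory(prefix="ligmotif_blast_") as tmp:
        tmp = Path(tmp)
        dbfa = tmp / "refdb.fasta"
        with open(dbfa, "w") as fh:
            n = 0
            for label in sorted(BLAST_LABELS & set(db.entries)):
                for entry in db.get(label):
                    sid = f"s{n}"
                    id_map[sid] = (label, entry.id)
                    fh.write(f">{sid}\n{entry.sequence}\n")
                    n += 1
        if not id_map:
            raise SearchError("empty reference database")
        qfa = tmp / "query.fasta"
        qfa.write_text(">query\n" + query + "\n")
        _run([
            "makeblastdb", "-dbtype", "nucl", "-in", str(dbfa),
            "-out", str(tmp / "refdb"),
        ])
        out = _run([
            "blastn",
            "-query", str(qfa),
            "-db", str(tmp / "refdb"),
            "-task", "blastn",
            "-word_size", str(params.word_size),
            "-evalue", str(max(params.evalue_threshold, params.evalue_threshold_d)),
            "-dust", "no",
            "-soft_masking", "false",
            "-outfmt", "6 sseqid qstart qend sstart send evalue score pident length",
            "-num_threads", "1",
        ])
    hsps = []
    for line in out.splitlines():
        parts = line.split("\t")
        if len(parts) != 9:
            continue
        sid, qstart, qend, sstart, send, evalue, score, pident, length = parts
        label, subject_id = id_map[sid]
        evalue = float(evalue)
        if evalue > params.threshold_for(label):
            continue
        s_lo, s_hi = sorted((int(sstart), int(send)))
        hsps.append(
            HSP(
                query_interval=Interval(int(qstart) - 1, int(qend)),
                strand="+" if int(sstart) <= int(send) else "-",
                label=label,
                subject_id=subject_id,
                score=float(score),
                evalue=evalue,
                identity=float(pident),
                length=int(length),
                subject_interval=Interval(s_lo - 1, s_hi),
            )
        )
    return hsps


def _run(cmd: list[str]) -> str:
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise SearchError(
            f"backend command failed ({cmd[0]}, exit {proc.returncode}): "
            f"{proc.stderr.strip()[:500]}"
        )
    return proc.stdout


# --------------------------------------------------------------------------
# public API


def local_search(query: str, db: RefDB, params: SearchParams | None = None) -> list[HSP]:
    """Search the query against every BLAST-stage label database, both strands.

    Returns labelled HSPs whose E-value passes the threshold applicable to
    their label (0.01 by default, 5 for the very short D-prototype labels).
    """
    params = params or SearchParams()
    query = query.lower()
    if len(query) < params.word_size:
        raise SearchError("query shorter than the search word size")
    if db.is_empty():
        raise SearchError("cannot search an empty reference database")
    backend = params.backend
    if backend == "auto":
        backend = "blastn" if blastn_available() else "internal"
    if backend == "internal":
        hsps = _internal_search(query, db, params)
    elif backend == "blastn":
        hsps = _blastn_search(query, db, params)
    else:
        raise SearchError(f"unknown search backend {backend!r}")
    logger.debug("local_search: %d HSPs (backend=%s)", len(hsps), backend)
    return hsps


def _cmp(a: float, b: float) -> int:
    return (a > b) - (a < b)


def compare_hsps(hsp1: HSP, hsp2: HSP) -> tuple[int, int, HSP]:
    """Pairwise selection between two overlapping same-database HSPs.

    g1 sums the score and E-value comparators, g2 the length and identity
    comparators (each +1 when hsp1 is better, -1 when worse, 0 on a tie).
    If g1 > 0, or g1 = 0 and g2 > 0, hsp2 is removed; if g1 < 0, or g1 = 0
    and g2 < 0, hsp1 is removed.  The fully tied case removes hsp2 so that
    selection is deterministic.  Returns (g1, g2, removed_hsp).
    """
    if hsp1.label != hsp2.label:
        raise SearchError("compare_hsps is only defined within one reference database")
    if not hsp1.overlaps(hsp2):
        raise SearchError("compare_hsps requires overlapping HSPs")
    g1 = _cmp(hsp1.score, hsp2.score) + _cmp(hsp2.evalue, hsp1.evalue)
    g2 = _cmp(hsp1.length, hsp2.length) + _cmp(hsp1.identity, hsp2.identity)
    if g1 > 0 or (g1 == 0 and g2 >= 0):
        return g1, g2, hsp2
    return g1, g2, hsp1


def _sort_key(h: HSP):
    return (-h.score, h.evalue, -h.length, -h.identity, h.query_interval.start,
            h.query_interval.end, h.subject_id)


def filter_hsps(hsps: list[HSP]) -> list[HSP]:
    """Select the best HSPs at a given location, per reference database.

    Same-database, same-strand overlapping HSPs fight pairwise tournaments in
    descending (score, -evalue, length, identity, 5' position) order; HSPs
    from different databases are never removed for mutual overlap.
    """
    survivors: list[HSP] = []
    groups: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        groups.setdefault((h.label, h.strand), []).append(h)
    for _, group in sorted(groups.items()):
        group = sorted(group, key=_sort_key)
        active = [True] * len(group)
        for i in range(len(group)):
            if not active[i]:
                continue
            for j in range(i + 1, len(group)):
                if not active[j] or not group[i].overlaps(group[j]):
                    continue
                _, _, removed = compare_hsps(group[i], group[j])
                if removed is group[j]:
                    active[j] = False
                else:
                    active[i] = False
                    break
        survivors.extend(h for h, keep in zip(group, active) if keep)
    return sorted(survivors, key=_sort_key)
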