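"""End-to-end annotation pipeline.

Composes the four analysis modules — gene identification (search +
grouping), gene description, functionality identification, and gene
delimitation / cluster assembly — over each input record, and hands the
result to the writers.  A failure on one record of a batch is recorded and
the batch continues.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from .assembly import (
    ClusterAnnotation,
    assemble_cluster,
    delimit_genes,
    resolve_overlapping_units,
)
from .description import DescriptionSettings, describe_gene
from .errors import LigmotifError
from .functionality import classify
from .grouping import DEFAULT_MAX_SPAN, filter_candidates, group_hsps
from .io import SequenceRecord, read_sequence, write_annotations
from .ontology import Ontology, default_ontology
from .refdb import RefDB, functional_signal_sets
from .search import SearchParams, filter_hsps, local_search

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    refdb: RefDB | str | Path
    input: str | Path | None = None  # FASTA/EMBL path or raw text
    input_format: str = "auto"
    search: SearchParams = field(default_factory=SearchParams)
    description: DescriptionSettings = field(default_factory=DescriptionSettings)
    ontology_overrides: Mapping[str, Any] | None = None
    #: reference-database selection (species / locus / gene_type / functionality)
    select: Mapping[str, Sequence[str]] | None = None
    max_candidate_span: int = DEFAULT_MAX_SPAN
    #: minimum joint HSP coverage (nt) for a candidate to count as a
    #: potential gene (chance-HSP suppression at the relaxed D-prototype
    #: E-value threshold)
    min_support_coverage: int = 45
    outdir: str | Path | None = None
    seed: int = 0


@dataclass
class RunResult:
    record: SequenceRecord
    cluster: ClusterAnnotation | None
    error: str | None = None
    timings: dict[str, float] = field(default_factory=dict)


def _resolve_refdb(config: RunConfig) -> RefDB:
    db = config.refdb
    if not isinstance(db, RefDB):
        db = RefDB.load(db)
    if config.select:
        db = db.select(**{k: v for k, v in config.select.items() if v})
    return db


def annotate_record(
    record: SequenceRecord,
    db: RefDB,
    config: RunConfig,
    ontology: Ontology | None = None,
) -> RunResult:
    """Run the full four-module analysis on one sequence record."""
    ontology = ontology or default_ontology()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if db.is_empty():
        logger.warning("empty reference database: no genes can be identified")
        hsps = []
    else:
        hsps = local_search(record.sequence, db, config.search)
    timings["search"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    selected = filter_hsps(hsps)
    candidates = group_hsps(
        selected, len(record.sequence), ontology, max_span=config.max_candidate_span
    )
    candidates = filter_candidates(
        candidates, db, config.min_support_coverage
    )
    timings["grouping"] = time.perf_counter() - t0
    logger.info(
        "%s: %d HSPs, %d selected, %d candidate genes",
        record.id, len(hsps), len(selected), len(candidates),
    )

    t0 = time.perf_counter()
    units = [
        describe_gene(c, record.sequence, db, ontology, config.description)
        for c in candidates
    ]
    timings["description"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    signals = functional_signal_sets(db)
    calls = [classify(u, record.sequence, signals, ontology) for u in units]
    resolved = resolve_overlapping_units(list(zip(units, calls)))
    genes = delimit_genes(resolved, len(record.sequence), ontology)
    cluster = assemble_cluster(genes, ontology, seq_length=len(record.sequence))
    timings["assembly"] = time.perf_counter() - t0
    return RunResult(record=record, cluster=cluster, timings=timings)


def run_pipeline(config: RunConfig) -> list[RunResult]:
    """Annotate every record of the configured input; write outputs if an
    output directory is configured."""
    if config.input is None:
        raise LigmotifError("run configuration has no input")
    ontology = Ontology(config.ontology_overrides) if config.ontology_overrides \
        else default_ontology()
    db = _resolve_refdb(config)
    records = read_sequence(config.input, config.input_format)
    results: list[RunResult] = []
    for record in records:
        try:
            result = annotate_record(record, db, config, ontology)
        except LigmotifError as exc:
            logger.error("record %s failed: %s", record.id, exc)
            results.append(RunResult(record=record, cluster=None, error=str(exc)))
            continue
        if config.outdir is not None:
            write_annotations(result.cluster, record, config.outdir)
        results.append(result)
    return results
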