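import warnings

import numpy as np
import pytest

from ligmotif.io import SequenceRecord
from ligmotif.synthetic import LocusSpec, SyntheticLocus, TemplateFamily, synth_locus

warnings.filterwarnings("ignore", category=DeprecationWarning)

#: truth functionality code -> classifier value
F2V = {"F": "Functional", "P": "Pseudogene", "ORF": "ORF", "U": "Unknown"}


def check_recovery(locus, cluster):
    """Every planted gene identified once (type, strand), status and
    functionality as planted, exact boundaries/features for described units,
    and no extra genes."""
    genes = cluster.genes
    truth = sorted(locus.genes, key=lambda g: g.unit_interval)
    assert len(genes) == len(truth)
    for tg in truth:
        hits = [
            g for g in genes
            if g.unit.span.overlaps(tg.unit_interval)
            and g.unit.gene_type == tg.gene_type
            and g.unit.strand == tg.strand
        ]
        assert len(hits) == 1, f"{tg.gene_type}@{tuple(tg.unit_interval)}"
        g = hits[0]
        assert g.unit.status == tg.expected_status
        assert g.functionality.value == F2V[tg.functionality]
        if tg.expected_status == "described":
            assert tuple(g.unit.span) == tuple(tg.unit_interval)
            for label, iv in g.unit.features.items():
                if label in tg.features:
                    assert tuple(iv) == tuple(tg.features[label]), label


@pytest.fixture(scope="session")
def recovery_checker():
    return check_recovery


@pytest.fixture(scope="session")
def ontology():
    from ligmotif.ontology import default_ontology

    return default_ontology()


@pytest.fixture(scope="session")
def family():
    return TemplateFamily(np.random.default_rng(1234))


@pytest.fixture(scope="session")
def small_locus() -> SyntheticLocus:
    """2 V + 1 D + 2 J in 30 kb: the standing end-to-end fixture."""
    return synth_locus(
        LocusSpec(n_v=2, n_d=1, n_j=2, background_length=30_000),
        np.random.default_rng(7),
    )


@pytest.fixture(scope="session")
def small_record(small_locus) -> SequenceRecord:
    return SequenceRecord("small_locus", small_locus.sequence)


@pytest.fixture(scope="session")
def small_annotation(small_locus, small_record):
    """The small locus run end-to-end once (internal backend)."""
    from ligmotif.pipeline import RunConfig, annotate_record
    from ligmotif.search import SearchParams

    config = RunConfig(
        refdb=small_locus.refdb, search=SearchParams(backend="internal")
    )
    return annotate_record(small_record, small_locus.refdb, config)
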