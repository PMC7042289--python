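import random

import pytest

from colnet.occurrence_io import OccurrenceRecord


def make_record(rid, collectors, taxon, rank="species", family=None, raw=None):
    """A resolved record, bypassing name cleaning for model-level tests."""
    return OccurrenceRecord(
        record_id=rid,
        recorded_by_raw=raw if raw is not None else "; ".join(collectors),
        taxon_name=taxon,
        taxon_rank=rank,
        family=family,
        collector_ids=tuple(collectors),
    )


def random_records(rng: random.Random, n_records=30, n_collectors=8, n_taxa=6, max_team=4):
    """Random resolved records for oracle-equivalence checks."""
    collectors = [f"c{i},x" for i in range(n_collectors)]
    taxa = [f"Genus sp{j}" for j in range(n_taxa)]
    records = []
    for k in range(n_records):
        team = rng.sample(collectors, rng.randint(1, min(max_team, n_collectors)))
        records.append(make_record(f"r{k}", team, rng.choice(taxa)))
    return records


@pytest.fixture
def five_record_fixture():
    """Small hand-checkable dataset used across SCN tests."""
    return [
        make_record("r0", ["a,x", "b,y"], "Myrtia alba", family="Myrtaceae"),
        make_record("r1", ["a,x"], "Myrtia alba", family="Myrtaceae"),
        make_record("r2", ["a,x"], "Myrtia nitida", family="Myrtaceae"),
        make_record("r3", ["b,y", "c,z"], "Fabia minor", family="Fabaceae"),
        make_record("r4", ["c,z"], "Fabia minor", family="Fabaceae"),
    ]
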