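import numpy as np
import pytest
from hypothesis import settings

from pavcomp.coverage import classify_all, group_mean_coverage, horizontal_coverage
from pavcomp.io import naive_map
from pavcomp.synthetic import (
    build_reference_panel,
    plant_query_genome,
    simulate_reads,
)

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_panel():
    """3 species x 30 single-copy groups, fast enough for unit tests."""
    return build_reference_panel(3, 30, (300, 600), 0.05, seed=7)


@pytest.fixture(scope="session")
def recovery_run():
    """Full synthetic presence/absence study at the standard conditions:

    5 reference species x 300 orthologue groups at 5% interspecies
    divergence, a query genome with 20% of groups deleted (query divergence
    2%), 10x paired 150 bp reads with 1% substitution error, built-in mapper
    defaults, classification thresholds 2/50.
    """
    catalog, groups = build_reference_panel(5, 300, (300, 1500), 0.05, seed=42)
    genome, truth = plant_query_genome(catalog, groups, 0.2, 0.02, 200, seed=43)
    pairs = simulate_reads(genome, 10, 150, 400, 0.01, seed=44)
    reads = [(rid, seq) for pair in pairs for rid, seq, _ in pair]
    hits = naive_map(reads, catalog, k=21, min_match_fraction=0.9)
    records = horizontal_coverage(hits, catalog)
    calls = classify_all(group_mean_coverage(records, groups), 2.0, 50.0)
    return truth, {c.group_id: c.status for c in calls}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
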