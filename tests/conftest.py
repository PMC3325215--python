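import numpy as np
import pandas as pd
import pytest

from turnoverseq import SimulationConfig, build_profiles, pair_and_filter, simulate_experiment
from turnoverseq.index import index_records


@pytest.fixture(scope="session")
def small_experiment():
    """A small two-condition simulation shared across tests (read-only)."""
    # multiplier scaled down with the gene-count ratio so the organellar
    # read share stays realistic (~35%) at miniature scale
    cfg = SimulationConfig(
        n_control=300, n_targets=40, n_chloroplast=20,
        library_size=60_000, seed=11,
        chloroplast_expression_multiplier=10.0,
    )
    transcripts, reads, molecules = simulate_experiment(cfg)
    all_reads = pd.concat(reads.values(), ignore_index=True)
    profiles = build_profiles(all_reads, transcripts)
    return {
        "config": cfg,
        "transcripts": transcripts,
        "reads": reads,
        "molecules": molecules,
        "profiles": profiles,
    }


@pytest.fixture(scope="session")
def small_table(small_experiment):
    """Paired, filtered index table of the shared small experiment."""
    profiles = small_experiment["profiles"]
    records = {s: index_records(profiles[s]) for s in profiles}
    return pair_and_filter(
        records["wt"], records["mut"], small_experiment["transcripts"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
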