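import numpy as np
import pytest

from nucvar.synthetic import (SimulationConfig, simulate_genome,
                              simulate_probe_tracks, write_simulation)


@pytest.fixture(scope="session")
def small_config():
    """A 200-kb study, small enough for per-module tests."""
    return SimulationConfig(genome_length=200_000, n_genes=40, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_tracks(small_config, small_truth):
    return simulate_probe_tracks(small_truth, small_config)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, small_config, small_truth, small_tracks):
    """The small study written to disk in all its standard formats."""
    outdir = tmp_path_factory.mktemp("study")
    write_simulation(small_truth, small_tracks, small_config, outdir)
    return outdir


@pytest.fixture(scope="session")
def bench_sim():
    """The 2-Mb benchmark: 5,000 planted 147-bp nucleosomes, noise SD 0.3."""
    config = SimulationConfig(seed=42)
    truth = simulate_genome(config)
    tracks = simulate_probe_tracks(truth, config)
    return config, truth, tracks


def match_within(queries, references, tol=20):
    """Boolean mask: which query centers lie within tol of a reference."""
    queries = np.sort(np.asarray(queries, dtype=float))
    references = np.sort(np.asarray(references, dtype=float))
    j = np.searchsorted(references, queries)
    ok = np.zeros(len(queries), dtype=bool)
    for i, x in enumerate(queries):
        for k in (j[i] - 1, j[i]):
            if 0 <= k < len(references) and abs(references[k] - x) <= tol:
                ok[i] = True
    return ok
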