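import numpy as np
import pytest

from concatmap import SegmentCountModel, SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_result():
    """Small simulated dataset shared across tests (deterministic)."""
    config = SimulationConfig(
        seed=11, n_reads=300,
        chrom_lengths={"chr1": 400_000, "chr2": 250_000},
        segments_per_read=SegmentCountModel(median=6, dispersion=3.0),
    )
    return simulate(config)


@pytest.fixture(scope="session")
def truth_by_read(sim_result):
    grouped = {}
    for rec in sim_result.truth:
        grouped.setdefault(rec.read_id, []).append(rec)
    for recs in grouped.values():
        recs.sort(key=lambda r: r.segment_index)
    return grouped
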