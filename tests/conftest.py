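import pandas as pd
import pytest

from iresmpra.quant import CountMatrix
from iresmpra.readproc import process_pairs
from iresmpra.simulate import (
    SimConfig,
    build_truth,
    generate_read_pairs,
    random_library,
    stream_read_pairs,
)


@pytest.fixture(scope="session")
def toy_library():
    """Small deterministic library: 2 positives, 3 scrambles, 12 candidates, 3 spikes."""
    return random_library(12, 120, seed=7)


@pytest.fixture(scope="session")
def toy_truth(toy_library):
    cfg = SimConfig(reads_per_sample=20000, epsilon=0.0)
    return build_truth(toy_library, cfg, seed=7)


def simulate_sample(truth, library, role, sample_id, condition="control", n_reads=None):
    """Materialise reads and sidecar truth for a sample."""
    reads, sidecar = [], []
    for rid, s1, s2, cid, cls, umi, mol in generate_read_pairs(
        truth, library, role, sample_id, condition, n_reads
    ):
        reads.append((rid, s1, s2))
        sidecar.append((rid, cid, cls, umi, mol))
    return reads, sidecar


@pytest.fixture(scope="session")
def toy_processed(toy_library, toy_truth):
    """Error-free input/IP samples processed end to end, with sidecars."""
    out = {}
    for role, sid in (("input", "in1"), ("IP", "ip1")):
        reads, sidecar = simulate_sample(toy_truth, toy_library, role, sid)
        res = process_pairs(iter(reads), toy_library, sid, collect_assignments=True)
        out[sid] = {"reads": reads, "sidecar": sidecar, "result": res}
    return out


@pytest.fixture(scope="session")
def toy_countmatrix(toy_processed):
    counts = pd.concat(
        [toy_processed[s]["result"].counts for s in ("in1", "ip1")], ignore_index=True
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["in1", "ip1"],
            "role": ["input", "IP"],
            "condition": ["control", "control"],
            "bio_rep": ["1", "1"],
            "tech_rep": ["1", "1"],
        }
    )
    return CountMatrix(counts, samples)


__all__ = ["simulate_sample", "stream_read_pairs"]
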