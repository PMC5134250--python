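import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ampmerge.fastq_io import ReadPair, ReadRecord
from ampmerge.simulate import SimParams, make_templates, simulate_pairs

SIM_LENGTHS = (471, 487, 503, 519, 612, 650)
SIM_SEED = 7


def make_read(read_id: str, sequence: str, quals=None) -> ReadRecord:
    if quals is None:
        quals = np.full(len(sequence), 30)
    return ReadRecord(read_id, sequence, np.asarray(quals))


def rc_str(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def error_free_pair(template: str, read_len: int, pair_id: str = "p", q: int = 35) -> ReadPair:
    """Exact 2xL mates from a template, uniform quality."""
    fwd = make_read(f"{pair_id}/1", template[:read_len], np.full(read_len, q))
    rev = make_read(f"{pair_id}/2", rc_str(template[-read_len:]), np.full(read_len, q))
    return ReadPair(fwd, rev)


@pytest.fixture(scope="session")
def sim_sample():
    """The scaled-down simulated sample: 600 pairs, 6 templates, 2x300,
    polynomial error model (1/200 of the full-scale design)."""
    templates = make_templates(list(SIM_LENGTHS), seed=SIM_SEED)
    params = SimParams(n_pairs_per_template=100, seed=SIM_SEED)
    fwd, rev, truths = simulate_pairs(templates, params)
    pairs = [ReadPair(f, r) for f, r in zip(fwd, rev)]
    return {"templates": templates, "params": params, "pairs": pairs, "truths": truths}
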