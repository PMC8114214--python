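import numpy as np
import pytest
from hypothesis import settings

from sahapep import PeptideRecord

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_records(seq_reps, cell_line="fibroblasts", intensity=None):
    """Build records from (sequence, replicate) pairs or bare sequences."""
    records = []
    for item in seq_reps:
        if isinstance(item, str):
            seq, rep = item, 1
        else:
            seq, rep = item
        records.append(
            PeptideRecord(
                sequence=seq, cell_line=cell_line, replicate=rep, intensity=intensity
            )
        )
    return records


@pytest.fixture
def small_synthetic_config():
    """A fast, down-scaled copy of the default study configuration."""
    from sahapep import default_config

    cfg = default_config(seed=11)
    for line in cfg.cell_lines:
        line.n_unique_target = 600
    cfg.n_source_proteins = 200
    cfg.allele_universe.n_db = 20
    cfg.digest.n_peptides_per_replicate = 200
    return cfg
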