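import numpy as np
import pytest
from hypothesis import settings

from circsplice_shift.io_formats import CircRecord
from circsplice_shift.synthetic_data import SimConfig

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sim():
    """Reduced-size study conditions for fast end-to-end runs."""
    return SimConfig(
        seed=11,
        n_shared=200,
        n_condition_specific=40,
        n_intron_pairs=12,
        n_circ_sequences=12,
        n_interactions_per_gene=25,
    )


def make_record(i: int = 0, **kwargs) -> CircRecord:
    defaults = dict(
        chrom="chr1",
        start=1000 + i * 10_000,
        end=3000 + i * 10_000,
        strand="+",
        gene_symbol=f"G{i}",
        exon_indices=(2, 3),
        reads_control=5,
        reads_treated=5,
    )
    defaults.update(kwargs)
    return CircRecord(**defaults)
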