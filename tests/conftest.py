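import numpy as np
import pytest

from depthmeta import synthetic_community as sc
from depthmeta.pipeline import PipelineConfig, run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dna(rng, length, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


@pytest.fixture
def small_truth():
    truth = sc.generate_genomes(
        3,
        length_range=(20_000, 30_000),
        n_markers=4,
        repeat_spec=[(2_000, 2, (0,))],
        seed=11,
    )
    truth.abundances = sc.sample_abundances(3, profile=4.0, seed=11)
    return truth


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    """The standard seeded demo community, run once per session.

    Used by the acceptance suite (parameter recovery and directional
    claims) and by pipeline-level assertions.
    """
    out = tmp_path_factory.mktemp("demo_run")
    cfg = PipelineConfig(out_dir=out, seed=42)
    return run_pipeline(cfg)
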