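import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from genexpand.model import ExpansionList, ExpansionParams, ExpansionRecord
from genexpand.synthetic import get_fixture, sample_expression


def make_list(seed, rows, **params):
    """Build an ExpansionList from (gene, f_rel, pearson_r) rows.

    Rows must already be in descending-f_rel order; counts are synthesized
    from a denominator of 1000 runs.
    """
    records = []
    for rank, (gene, f_rel, pearson_r) in enumerate(rows, start=1):
        out = round(f_rel * 1000)
        records.append(
            ExpansionRecord(
                gene=gene, input_count=1000, output_count=out,
                f_rel=out / 1000, pearson_r=pearson_r, rank=rank,
            )
        )
    return ExpansionList(seed=seed, records=records, params=ExpansionParams(**params))


@pytest.fixture(scope="session")
def collider_truth():
    return get_fixture("tiny-collider")


@pytest.fixture(scope="session")
def collider_matrix(collider_truth):
    # n=5000: large enough that the collider skeleton is recovered reliably
    return sample_expression(collider_truth, n_samples=5000)


@pytest.fixture(scope="session")
def dag20_truth():
    return get_fixture("dag-20")


@pytest.fixture(scope="session")
def dag20_matrix(dag20_truth):
    return sample_expression(dag20_truth, n_samples=1000)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
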