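import numpy as np
import pandas as pd
import pytest

from photocoord.types import ExpressionMatrix


@pytest.fixture
def small_expr():
    """3 transcripts x 4 samples, two sites."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 2.0, 6.0, 6.0],
         [10.0, 30.0, 5.0, 7.0]],
        index=["t1", "t2", "t3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    site_of = {"s1": "JH", "s2": "JH", "s3": "QG", "s4": "QG"}
    return ExpressionMatrix(values, site_of)


@pytest.fixture
def random_expr_factory():
    def make(n_transcripts=10, n_per_site=5, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"JH_{i}" for i in range(n_per_site)] + [
            f"QG_{i}" for i in range(n_per_site)
        ]
        values = pd.DataFrame(
            rng.lognormal(3, 1, size=(n_transcripts, 2 * n_per_site)),
            index=[f"t{i}" for i in range(n_transcripts)],
            columns=samples,
        )
        site_of = {s: s.split("_")[0] for s in samples}
        return ExpressionMatrix(values, site_of)

    return make


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """Session-wide synthetic fixture bundle (study-shaped)."""
    from photocoord.pipeline import make_demo_dataset

    out = tmp_path_factory.mktemp("demo")
    truth = make_demo_dataset(out, seed=7)
    return out, truth
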