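import warnings

import numpy as np
import pytest

from softsense.preprocess import preprocess_pipeline
from softsense.synth import Benchmark, benchmark_pairs, make_paired_benchmark


def pytest_configure(config):
    # the pipeline legitimately warns (CARS tail collapse, CV truncation);
    # keep test output readable
    warnings.filterwarnings("ignore", category=UserWarning, module="softsense")


@pytest.fixture(scope="session")
def small_benchmark() -> Benchmark:
    """A reduced multi-batch fixture for plumbing tests (fast to generate)."""
    return make_paired_benchmark(seed=11, n_batches=2, days=5, refs_per_day=2,
                                 n_channels=300)


@pytest.fixture(scope="session")
def paper_scale_benchmark() -> Benchmark:
    """The full-size 4-batch, 3000-channel fixture (generated once per session)."""
    return make_paired_benchmark(seed=0)


@pytest.fixture(scope="session")
def glucose_pairs(paper_scale_benchmark):
    """Preprocessed glucose calibration pairs pooled over the 4 batches."""
    X, y, ids, is_out = benchmark_pairs(paper_scale_benchmark, "glucose",
                                        preprocess_fn=preprocess_pipeline)
    return X, y, ids, np.asarray(is_out)
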