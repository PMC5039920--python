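import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chipseg.simulator import SimConfig, default_truth_params, simulate

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A 1200-window, 2-replicate simulation with well-separated states."""
    config = SimConfig(chrom_windows={"chr1": 1200}, seed=42)
    return simulate(config)


@pytest.fixture(scope="session")
def qc_corpus():
    """The default 200 positive / 200 negative synthetic QC corpus."""
    import warnings

    from chipseg.qc_classifier import build_training_corpus

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_training_corpus(200, 200, seed=101)


@pytest.fixture(scope="session")
def toy_hmm_params():
    """Hand-specified, well-conditioned 3-state parameters (r=1)."""
    return default_truth_params(pi=0.1, alpha=2.0, r=1, state_means=(1.0, 4.0, 12.0))
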