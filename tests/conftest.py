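import numpy as np
import pytest

from kip2mt import AssayConfig, DynamicsParams, generate_assay


@pytest.fixture(scope="session")
def porcine_0nM() -> DynamicsParams:
    """Motor-free porcine condition: the densest-event row of the
    reference table (growth 0.32, catastrophe 0.166, shrink 27.6,
    rescue 0.88)."""
    return DynamicsParams(0.32, 0.166, 27.6, 0.88)


@pytest.fixture(scope="session")
def noisy_0nM_assay(porcine_0nM):
    """One full-size noisy assay at the 0 nM porcine condition, with the
    generating trajectories for oracle comparisons."""
    cfg = AssayConfig(species="porcine", kip2_conc=0.0, n_microtubules=76,
                      seed=11)
    traces, truths = generate_assay(cfg, porcine_0nM, return_truth=True)
    return cfg, traces, truths
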