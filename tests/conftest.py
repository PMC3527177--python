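import numpy as np
import pytest
from hypothesis import settings

from hetsnp import FilterParams, SimConfig, discover
from hetsnp.simulate import simulate_pileup, simulate_references

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_reference():
    from hetsnp.io import ReferenceSeq

    return ReferenceSeq("bes1", "ACGTACGTAC", [40] * 10, annotation="genic")


@pytest.fixture(scope="session")
def e2e_dataset():
    """Shared synthetic study: 600 references, repeats at 3x depth, known truth."""
    cfg = SimConfig(n_refs=600, seed=42)
    rng = cfg.rng()
    refs, truth = simulate_references(cfg, rng)
    columns = list(simulate_pileup(refs, truth, cfg, rng))
    return cfg, refs, truth, columns


@pytest.fixture(scope="session")
def e2e_results(e2e_dataset):
    """Adjusted-preset and initial-preset discovery over the shared study."""
    cfg, refs, truth, columns = e2e_dataset
    ann = {r.id: r.annotation for r in refs}
    adjusted = discover(refs, columns, annotation=ann, params=FilterParams.adjusted(),
                        fit_depth_cutoff=True)
    initial = discover(refs, columns, annotation=ann, params=FilterParams.initial(),
                       fit_depth_cutoff=False)
    return cfg, refs, truth, adjusted, initial
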