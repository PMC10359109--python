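import numpy as np
import pytest

from csea import (
    TStatMatrix,
    build_reference,
    build_signature_panel,
    filter_tag_length,
    select_signatures,
    simulate_panel,
    simulate_tags,
)


@pytest.fixture(scope="session")
def sim_bundle():
    """Standard synthetic panel: 2000 genes, 4 x 100 cells, 20 markers/TC,
    4-fold marker lift — plus its derived signature panel and truth."""
    panel, truth = simulate_panel(seed=1)
    sp = build_signature_panel(panel)
    return panel, truth, sp


@pytest.fixture(scope="session")
def small_reference(sim_bundle):
    """200 simulated TAGs precomputed against the standard panel."""
    _, _, sp = sim_bundle
    tags = filter_tag_length(simulate_tags(200, sp.universe, seed=2))
    return tags, build_reference(tags, [sp])


@pytest.fixture
def toy_signature_panel():
    """Hand-sized panel: 20-gene universe, 2 TCs, 5-gene signatures."""
    genes = [f"X{i:02d}" for i in range(20)]
    rng = np.random.default_rng(3)
    values = rng.normal(size=(20, 2))
    tstats = TStatMatrix(values, genes, ["left", "right"])
    return select_signatures(tstats, top_fraction=0.25, panel_id="TOY")
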