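import numpy as np
import pytest

import genodyn as g


@pytest.fixture(scope="session")
def small_ltr_bundle():
    """A compact scenario with the full LTR landscape (decoys included) and
    no gene content; shared by the detection and dating tests."""
    cfg = g.wgd_preset(seed=11)
    cfg.n_scaffolds = 8
    cfg.scaffold_length = 250_000
    cfg.wgd.n_retained_pairs = 0
    cfg.ltr.n_intact = 12
    cfg.ltr.n_truncated = 6
    cfg.ltr.n_solo = 30
    cfg.ltr.n_nonautonomous = 4
    cfg.decoys = g.DecoyConfig(3, 3, 3, 3)
    return g.generate_scenario(cfg)


@pytest.fixture(scope="session")
def gene_bundle():
    """A gene-only scenario (WGD blocks, no LTR content) shared by the
    collinearity tests."""
    cfg = g.wgd_preset(seed=12)
    cfg.wgd.n_retained_pairs = 100
    cfg.ltr.n_intact = 0
    cfg.ltr.n_truncated = 0
    cfg.ltr.n_solo = 0
    cfg.ltr.n_nonautonomous = 0
    cfg.decoys = g.DecoyConfig(0, 0, 0, 0)
    return g.generate_scenario(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
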