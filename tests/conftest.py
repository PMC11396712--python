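import numpy as np
import pytest

from plexcompo import gating, synthetic
from plexcompo.panels import MACROPHAGE_PANEL, T_CELL_PANEL


@pytest.fixture(scope="session")
def small_cohort():
    """Two-panel cohort, 2 samples x 400 cells per subtype (fast)."""
    cfg = synthetic.default_cohort_config(
        samples_per_subtype=2, cells_per_sample=400, seed=11
    )
    return synthetic.simulate_two_panel_cohort(cfg)


@pytest.fixture(scope="session")
def gated_small_cohort(small_cohort):
    """Both panels of the small cohort gated in pooled mode."""
    out = {}
    for panel in (T_CELL_PANEL, MACROPHAGE_PANEL):
        gated, fits = gating.gate_cells(
            small_cohort.tables[panel.name],
            panel,
            mode="pooled",
            families=("normal", "lognormal"),
            seed=5,
        )
        out[panel.name] = (gated, fits)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
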