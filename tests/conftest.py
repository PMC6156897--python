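import numpy as np
import pytest

from dtiscope.profiles import TrialSet
from dtiscope.synthetic import PanelConfig, simulate_panel


@pytest.fixture
def small_panel():
    """A small seeded panel exercising multi-trial structure quickly."""
    cfg = PanelConfig(
        n_landmark=16,
        n_genes=8,
        n_drugs=4,
        targets_per_drug=(1, 2),
        trials_per_entity=(1, 8),
        druggable_fraction=0.5,
        seed=42,
    )
    return simulate_panel(cfg)


def make_trialset(rng, n_trials, n_features=12, entity_id="E0"):
    return TrialSet(
        entity_id=entity_id,
        trials=rng.standard_normal((n_trials, n_features)),
        feature_ids=[f"L{j}" for j in range(n_features)],
    )
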