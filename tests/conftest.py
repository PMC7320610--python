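import numpy as np
import pytest

import somadriver as sd

ZERO_EFFECTS = {g: 0.0 for g in sd.GROUP_NAMES}


def make_sim(seed: int, effects: dict | None = None, **overrides) -> sd.SimResult:
    es = dict(ZERO_EFFECTS)
    if effects:
        es.update(effects)
    return sd.simulate(sd.SimConfig(seed=seed, effect_sizes=es, **overrides))


def feature_groups_for(sim: sd.SimResult, ds: sd.LabeledDataset) -> dict:
    return sd.compute_feature_groups(
        ds.variants, sim.genome, sim.annotation,
        sim.conservation_tracks, sim.uniqueness_tracks,
        sim.elements, sim.somatic,
    )


@pytest.fixture(scope="session")
def sim_signal() -> sd.SimResult:
    """Synthetic cohort with a 2 SD shift planted in Conservation and
    Uniqueness and no other class differences."""
    return make_sim(11, {"Conservation": 2.0, "Uniqueness": 2.0})


@pytest.fixture(scope="session")
def signal_run(sim_signal):
    """(dataset, feature groups, pooled LOCO report) for the signal cohort."""
    ds = sd.build_dataset(sim_signal.somatic, sd.DatasetConfig(region_mode="noncoding"))
    groups = feature_groups_for(sim_signal, ds)
    report = sd.run_loco(
        ds, groups, sd.NONCODING_GROUPS,
        cautious_cfg=sd.CautiousConfig(0.9), n_per_class=300, seed=11,
    )
    return ds, groups, report


@pytest.fixture(scope="session")
def sim_null() -> sd.SimResult:
    """Synthetic cohort with all effect sizes zero (exact null)."""
    return make_sim(12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
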