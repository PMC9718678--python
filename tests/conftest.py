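import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import nanomil as nm

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def small_sim():
    """Small dataset with injected basecall mismatches, used across modules."""
    cfg = nm.GeneratorConfig(n_transcripts=4, sites_per_transcript=2,
                             coverage=25, mismatch_rate=0.05, seed=1)
    return nm.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_obs(small_sim):
    return nm.collapse_table(small_sim.events)


@pytest.fixture(scope="session")
def small_bags(small_sim, small_obs):
    table = nm.fit_normalization(small_obs)
    normed = nm.normalize_observations(small_obs, table)
    return nm.build_site_bags(normed, small_sim.sequences, min_reads=20)


def split_bags(bags, labels, fractions=(0.75, 0.25), seed=0):
    """Gene-level split of a bag dataset, returning (train, val) subsets."""
    pieces = nm.gene_level_split(labels, fractions, seed=seed)
    keys = list(map(tuple, bags.index[["transcript_id", "position"]]
                    .itertuples(index=False)))
    train_keys = set(map(tuple, pieces[0][["transcript_id", "position"]]
                         .itertuples(index=False)))
    tr = [i for i, k in enumerate(keys) if k in train_keys]
    va = [i for i, k in enumerate(keys) if k not in train_keys]
    return bags.subset(tr), bags.subset(va)


@pytest.fixture(scope="session")
def trained():
    """A model trained on clearly separable data, shared by model-level tests.

    180 sites at coverage 30 with a 4-sd mean shift and 0.5 stoichiometry;
    25 epochs suffice at this scale.
    """
    cfg = nm.GeneratorConfig(n_transcripts=60, sites_per_transcript=3,
                             coverage=30, delta=(4.0, 0.0, 0.0),
                             stoichiometry=0.5, seed=2)
    sim = nm.simulate_dataset(cfg)
    obs = nm.collapse_table(sim.events)
    table = nm.fit_normalization(obs)
    bags = nm.build_site_bags(nm.normalize_observations(obs, table),
                              sim.sequences)
    train, val = split_bags(bags, sim.site_truth)
    model = nm.MILSiteModel(train, sim.site_truth, val, sim.site_truth,
                            nm.TrainingConfig(epochs=25, seed=3))
    results = model.fit()
    return {"sim": sim, "obs": obs, "table": table, "bags": bags,
            "train": train, "val": val, "results": results}
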