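"""Shared fixtures.

The expensive fixtures (trained desk-scale model and its derived physiology)
are session-scoped so the training cost is paid once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from lateralpred import netmodel as nm
from lateralpred import synthetic_data as sd


@pytest.fixture(scope="session")
def small_corpus():
    params = sd.MovieGenParams(n_clips=60, seed=7)
    return sd.generate_movie_corpus(params)


@pytest.fixture(scope="session")
def tiny_net():
    cfg = nm.NetworkConfig(n_input=4, n_hidden=5, frac_inhibitory=0.2, seed=3)
    return nm.init_network(cfg), cfg


@pytest.fixture(scope="session")
def desk_corpus():
    """The study-condition corpus: 2,000 drifting-texture clips, 16x16 px."""
    params = sd.MovieGenParams(n_clips=2000, seed=1)
    return sd.generate_movie_corpus(params)


@pytest.fixture(scope="session")
def trained_desk_model(desk_corpus):
    """Desk-profile model (16x16 input, 512 hidden) trained on 2,000 clips."""
    train_clips, val_clips = desk_corpus
    cfg = nm.NetworkConfig.desk_profile(seed=0)
    model = nm.init_network(cfg)
    model, history = nm.train(model, train_clips, cfg, validation=val_clips)
    return {"model": model, "config": cfg, "history": history,
            "train_clips": train_clips, "val_clips": val_clips}


@pytest.fixture(scope="session")
def desk_physiology(trained_desk_model):
    """RWA maps, Gabor fits, inclusion mask and tuning for the trained model."""
    from lateralpred import receptive_fields as rfmod
    from lateralpred import tuning as tn

    model = trained_desk_model["model"]
    rfs = rfmod.response_weighted_average(model, 25000, seed=11)
    fits = rfmod.fit_gabors(rfs, seed=3)
    included, summary = rfmod.apply_inclusion_criteria(fits)
    resp, grid = tn.grating_battery(model)
    profiles = [tn.unit_tuning(resp[i], grid) for i in range(model.n_hidden)]
    for p in profiles:
        tn.classify_selectivity(p, "ko")
    return {"rfs": rfs, "fits": fits, "included": included,
            "summary": summary, "profiles": profiles, "grid": grid}
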