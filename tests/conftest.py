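"""Shared fixtures: small synthetic bundles and feature matrices."""

import numpy as np
import pytest

from helixclass.features import build_feature_matrix
from helixclass.synthetic import (PlantedEffect, SyntheticConfig,
                                  generate_bundle, tp53_preset)


def small_config(seed=0, **overrides) -> SyntheticConfig:
    """Tiny 25-mer bundle: 2 hotspot + 2 nonhotspot sites, 2 replicates,
    short trajectories."""
    defaults = dict(
        gene="TOY",
        hotspot_sites=("h1", "h2"),
        nonhotspot_sites=("n1", "n2"),
        replicates=2,
        n_frames=60,
        t_end=6.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def small_bundle():
    return generate_bundle(small_config(seed=3))


@pytest.fixture(scope="session")
def tp53_bundle():
    """Reference-scale bundle: 72 records, 1000 frames, 25-mers."""
    return generate_bundle(tp53_preset(seed=7))


@pytest.fixture(scope="session")
def tp53_features(tp53_bundle):
    return build_feature_matrix(tp53_bundle)


#: Broad regional effects: the adduct shifts tip and the hotspot state
#: shifts roll across every retained base, so the four classes are
#: separable even from small samples.
SEPARABLE_EFFECTS = tuple(
    [PlantedEffect("tip", b, "adducted", mean_shift=40.0)
     for b in range(3, 24)]
    + [PlantedEffect("roll", b, "hotspot", mean_shift=40.0)
       for b in range(3, 24)]
)


@pytest.fixture(scope="session")
def separable_features():
    """Small matrix whose four classes are separable by construction."""
    cfg = small_config(seed=11, replicates=6,
                       planted_effects=SEPARABLE_EFFECTS,
                       replicate_offset_scale=0.05)
    return build_feature_matrix(generate_bundle(cfg))
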