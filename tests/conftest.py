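import numpy as np
import pytest
from hypothesis import settings

from wmhflow import synthetic as syn
from wmhflow.graph import build_network, skeletonize

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def depth3_tree():
    return syn.generate_arterial_tree(depth=3, root_radius=1.5, tortuosity_amp=1.0, seed=2)


@pytest.fixture(scope="session")
def voxelized_depth3(depth3_tree):
    shape, origin = syn.fit_grid(depth3_tree, 0.4, margin_mm=3.0)
    vol = syn.voxelize_tree(depth3_tree, 0.4, shape, origin)
    return vol


@pytest.fixture(scope="session")
def recovered_network(depth3_tree, voxelized_depth3):
    root = depth3_tree.branch(depth3_tree.root_ids[0])
    # thinning retracts the free end by about one tube radius, so allow the
    # seed at the true root origin to snap a little farther than the default
    return build_network(skeletonize(voxelized_depth3), voxelized_depth3,
                         [root.start], snap_dist=5.0)


@pytest.fixture(scope="session")
def straight_tube_tree():
    return syn.generate_arterial_tree(depth=1, root_radius=1.0, tortuosity_amp=0.0,
                                      seed=0, root_length=20.0)


@pytest.fixture(scope="session")
def straight_tube_volume(straight_tube_tree):
    shape, origin = syn.fit_grid(straight_tube_tree, 0.4, margin_mm=3.0)
    return syn.voxelize_tree(straight_tube_tree, 0.4, shape, origin)


def random_tree(rng):
    """A random synthetic tree for solver property tests."""
    return syn.generate_arterial_tree(
        depth=int(rng.integers(2, 7)),
        root_radius=float(rng.uniform(1.0, 2.0)),
        radius_ratios=(float(rng.uniform(0.7, 0.9)), float(rng.uniform(0.55, 0.75))),
        tortuosity_amp=float(rng.uniform(0.0, 1.5)),
        seed=int(rng.integers(0, 2 ** 31)),
        root_length=float(rng.uniform(20.0, 35.0)),
    )
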