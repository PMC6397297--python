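import math

import numpy as np
import pytest
from hypothesis import settings

import cytodose as cd
from cytodose.synthetic import render_fibre, CYTOPLASM_LEVEL

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_population():
    """A dozen noiseless default-condition cells with ground truth."""
    cfg = cd.PopulationConfig(n_cells=12, seed=2)
    image_sets, truth = cd.generate_population(cfg)
    return cfg, image_sets, truth


@pytest.fixture(scope="session")
def baseline_population():
    """Cells confined to the no-effect regime (narrow, low expression)."""
    cfg = cd.PopulationConfig(n_cells=6, gfp_log_mean=3.0, gfp_log_sd=0.3,
                              seed=7)
    image_sets, truth = cd.generate_population(cfg)
    return cfg, image_sets, truth


def make_fibre_field(angles_deg, centers, width=4.0, length=60.0,
                     shape=(128, 128), cyto=CYTOPLASM_LEVEL):
    """A rectangular cell containing rendered fibres on a flat cytoplasm."""
    cell = np.zeros(shape, dtype=bool)
    cell[8:shape[0] - 8, 8:shape[1] - 8] = True
    stain = np.zeros(shape)
    truth_mask = np.zeros(shape, dtype=bool)
    for ang, c in zip(angles_deg, centers):
        img, m = render_fibre(shape, c, math.radians(ang), length, width)
        stain += img
        truth_mask |= m
    stain = stain * cell + cyto * cell
    return cell, stain, truth_mask & cell


@pytest.fixture
def single_fibre_field():
    return make_fibre_field([30.0], [(64.0, 64.0)])
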