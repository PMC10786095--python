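"""Shared fixtures: small rendered stimulus sets and synthetic groups."""

import numpy as np
import pytest

from bmrsa import (DesignSpec, GaborBank, build_stimulus_set, define_searchlights,
                   SearchlightSpec, simulate_group, stimulus_feature,
                   theoretical_rdms, v1_rdm, STIMULUS_LABELS)
from bmrsa.glm import condition_tmaps, make_design_matrix
from bmrsa.simulate import default_effects


@pytest.fixture(scope="session")
def stimuli():
    """The 8 stimuli at a reduced frame count (speed; one gait cycle)."""
    return build_stimulus_set(n_frames=4)


@pytest.fixture(scope="session")
def bank():
    return GaborBank()


@pytest.fixture(scope="session")
def v1_model_rdm(stimuli, bank):
    feats = [stimulus_feature(s, bank) for s in stimuli]
    return v1_rdm(feats, labels=tuple(s.label for s in stimuli))


@pytest.fixture(scope="session")
def theo_rdms():
    return theoretical_rdms(STIMULUS_LABELS)


def _glm_all(group):
    out = []
    for s in group:
        dms = [make_design_matrix(t, n) for t, n in zip(s.timelines, s.nuisance)]
        out.append(condition_tmaps(s.runs, dms))
    return out


@pytest.fixture(scope="session")
def small_group():
    """4 subjects on an 8-cube grid with 3-cube ROIs at comfortable SNR."""
    design = DesignSpec()
    effects = default_effects(grid_shape=(8, 8, 8), roi_size=3,
                              target_pattern_snr=1.0)
    group = simulate_group(4, design, effects, base_seed=42)
    return design, effects, group


@pytest.fixture(scope="session")
def small_glm(small_group):
    _, _, group = small_group
    return _glm_all(group)


@pytest.fixture(scope="session")
def small_searchlights(small_group):
    _, _, group = small_group
    return define_searchlights(group[0].mask, SearchlightSpec(k=40))
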