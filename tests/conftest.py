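"""Shared fixtures: small synthetic duplexes and ensembles."""

import numpy as np
import pandas as pd
import pytest

from ptgg.structure_io import Ensemble, infer_duplex_topology
from ptgg.synthetic import (FIXTURE_SEQUENCE_I, GeneratorSpec, attach_platinum,
                            build_duplex, sample_ensemble)


@pytest.fixture(scope="session")
def bform_spec():
    return GeneratorSpec()


@pytest.fixture(scope="session")
def bform_model(bform_spec):
    """Ideal straight B-form 12-mer (twist 36 deg, rise 3.38 A)."""
    return build_duplex(bform_spec.pair_means, bform_spec.step_means)


@pytest.fixture(scope="session")
def bform_topology(bform_model):
    return infer_duplex_topology(bform_model)


@pytest.fixture(scope="session")
def bform_ensemble(bform_model, bform_topology):
    return Ensemble.from_models([bform_model], topology=bform_topology)


@pytest.fixture(scope="session")
def pt_model():
    """pt_gg-distorted duplex with the Pt moiety aimed at both contacts."""
    spec = GeneratorSpec(pt=True, preset="pt_gg")
    bare = build_duplex(spec.pair_means, spec.step_means)
    return attach_platinum(bare, aim="both")


@pytest.fixture(scope="session")
def noisy_family():
    """Small NMR-family-like ensemble (14 conformers, free-DNA noise)."""
    return sample_ensemble(GeneratorSpec(n_frames=14, seed=42)).ensemble


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
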