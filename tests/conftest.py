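"""Shared fixtures: scenario bundles and the packaged null/calibration."""

import numpy as np
import pytest

from gluescreen import (NullModel, ScenarioSpec, default_calibration_table,
                        generate_decoys, generate_glue_scenario)
from gluescreen.cli import DEFAULT_NULL_PATH


@pytest.fixture(scope="session")
def null_model() -> NullModel:
    return NullModel.from_json(DEFAULT_NULL_PATH)


@pytest.fixture(scope="session")
def calibration_table():
    return default_calibration_table()


@pytest.fixture(scope="session")
def exact_bundle():
    """One noise-free glue scenario reused across unit tests."""
    return generate_glue_scenario(ScenarioSpec(rng_seed=2))


@pytest.fixture(scope="session")
def decoy_signatures():
    return generate_decoys(40, size_range=(10, 25), rng_seed=7)


@pytest.fixture(scope="session")
def small_decoys():
    """Small pockets (≤8 residues) for assignment-oracle checks."""
    return generate_decoys(12, size_range=(4, 8), rng_seed=13)


def rigid_copy(signature, rng_seed=0):
    """Rotate+translate a signature; returns (copy, rotation, translation)."""
    from gluescreen.pocket_alignment import PocketSignature
    from gluescreen.synthetic_fixtures import _random_rotation

    rng = np.random.default_rng(rng_seed)
    R = _random_rotation(rng)
    v = rng.uniform(-30.0, 30.0, 3)
    return PocketSignature(
        signature.pocket_id + "_moved",
        signature.rep_points @ R.T + v,
        signature.side_points @ R.T + v,
        signature.aa, source_model=signature.source_model,
        parent_sequences=signature.parent_sequences), R, v
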