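"""Shared fixtures: the default study phantom and montage are built (and
the two electrode-pair fields solved) once per session, since every
exposure/steering test reuses the same 1 mA-normalized solutions."""

from __future__ import annotations

import numpy as np
import pytest

from tistim.config import default_run_config
from tistim.montage import place_electrode_pairs, symmetric_rule_spec
from tistim.pipeline import build_montage, build_phantom, cortical_rois
from tistim.solver import (
    build_conductivity_tensors,
    normalize_to_current,
    solve_montage_pair,
)


@pytest.fixture(scope="session")
def default_config():
    return default_run_config()


@pytest.fixture(scope="session")
def default_phantom(default_config):
    return build_phantom(default_config)


@pytest.fixture(scope="session")
def default_montage(default_phantom, default_config):
    return build_montage(default_phantom, default_config)


@pytest.fixture(scope="session")
def default_tensors(default_phantom):
    return build_conductivity_tensors(default_phantom)


@pytest.fixture(scope="session")
def pair_solutions(default_phantom, default_tensors, default_montage):
    """Both default-montage pair fields, normalized to 1 mA."""
    return [
        normalize_to_current(
            solve_montage_pair(
                default_phantom, default_tensors, default_montage, k, tolerance=1e-8
            ),
            1.0,
        )
        for k in range(2)
    ]


@pytest.fixture(scope="session")
def symmetric_montage(default_phantom):
    return place_electrode_pairs(default_phantom, symmetric_rule_spec())


@pytest.fixture(scope="session")
def symmetric_solutions(default_phantom, default_tensors, symmetric_montage):
    """Pair fields for the mirror-symmetric steering montage, 1 mA each."""
    return [
        normalize_to_current(
            solve_montage_pair(
                default_phantom, default_tensors, symmetric_montage, k, tolerance=1e-8
            ),
            1.0,
        )
        for k in range(2)
    ]


@pytest.fixture(scope="session")
def cortex_rois(default_phantom, default_montage):
    return cortical_rois(default_phantom, default_montage)
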