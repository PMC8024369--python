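"""Shared fixtures.

Expensive objects (the synthetic screen structure and its SASA table, the
on-disk study bundle) are built once per session; everything they feed is
deterministic, so sharing them does not couple tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from bundlestab import sasa
from bundlestab.synthetic_data import (build_helix_bundle, gen_study,
                                       synthetic_buried_screen_standin)


@pytest.fixture(scope="session")
def standin():
    """The synthetic buried-screen stand-in structure (designed object)."""
    return synthetic_buried_screen_standin()


@pytest.fixture(scope="session")
def standin_accessibility(standin):
    """Per-residue relative ASA of the stand-in at package defaults."""
    return sasa.residue_relative_asa(standin)


@pytest.fixture(scope="session")
def small_bundle():
    """A small four-helix bundle with backbone + Cβ atoms."""
    return build_helix_bundle(4, 20)


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory):
    """On-disk synthetic study bundle written once with the default seed."""
    out = tmp_path_factory.mktemp("bundle") / "study"
    truth = gen_study(out, master_seed=42)
    return out, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
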