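"""Shared fixtures: synthetic structures and a lazily populated PDB cache.

Deposited-structure tests fetch entries into ``scratch/pdb_cache`` on first
use; with no network access they fail with the underlying URL error, which is
the honest outcome for checks that require the public archive.
"""

import os

import pytest

from rbdcompare.structure_io import ResidueSelection, fetch_pdb
from rbdcompare.synthetic_data import make_helix, perturb_to_rmsd, two_domain_complex

CACHE_DIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "pdb_cache")


@pytest.fixture(scope="session")
def pdb_cache():
    """Fetch-by-accession helper backed by a local cache directory."""

    def get(code: str) -> str:
        return fetch_pdb(code, CACHE_DIR)

    return get


@pytest.fixture()
def helix10():
    return make_helix(10)


@pytest.fixture()
def helix20():
    return make_helix(20)


@pytest.fixture()
def sel_a():
    return ResidueSelection("A")


@pytest.fixture()
def perturbed_helix(helix20):
    return perturb_to_rmsd(helix20, 1.0, seed=7)


@pytest.fixture()
def binary_complex():
    return two_domain_complex(seed=3)
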