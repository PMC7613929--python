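"""Shared fixtures: synthetic protomers, filaments and domain splits.

Everything is generated programmatically with fixed seeds; no stored
coordinate fixtures are needed for the synthetic suite.  Deposited
accession files, when a user has downloaded them, are looked for under
``data/accessions/`` (see tests/test_acceptance.py).
"""

from pathlib import Path

import numpy as np
import pytest

from filageom import synthetic
from filageom.domains import DomainDefinition

REPO_ROOT = Path(__file__).resolve().parent.parent
ACCESSION_DIR = REPO_ROOT / "data" / "accessions"


@pytest.fixture(scope="session")
def protomer():
    return synthetic.make_protomer(120, seed=1)


@pytest.fixture(scope="session")
def pseudo_domains():
    """An arbitrary contiguous split of the 30 pseudo-residues into the
    actin-fold subdomain names, so domain-aware code paths run on
    synthetic chains."""
    return DomainDefinition({"IA": [(1, 8)], "IC": [(9, 16)],
                             "IIA": [(17, 24)], "IIB": [(25, 30)]},
                            provenance="synthetic pseudo-domains")


@pytest.fixture(scope="session")
def double_filament(protomer):
    return synthetic.build_double_filament(protomer, n_per_protofilament=3)


@pytest.fixture(scope="session")
def helix_filament(protomer):
    return synthetic.build_helical_filament(
        protomer, rise=48.0, twist_deg=27.7, helical_radius=100.0, n=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def accession(name: str):
    """Path to a user-downloaded deposited coordinate file.

    The deposited crystal structures are not redistributed with the
    package; place e.g. 7q6f.cif / 7q6i.cif (from the public archive)
    under data/accessions/ to run the regression checks against them.
    """
    path = ACCESSION_DIR / name
    if not path.exists():
        raise FileNotFoundError(
            f"deposited coordinate file {name} not found under "
            f"{ACCESSION_DIR}; download it from the public PDB archive to "
            "run this regression check")
    return path
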