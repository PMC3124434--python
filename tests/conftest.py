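import numpy as np
import pytest

from stereocheck.fixtures import BuildSpec, build_peptide, write_fixture_set

HELIX_SEQ = "AAQAAAAQAAAAQAA"


@pytest.fixture(scope="session")
def clean_helix():
    return build_peptide(BuildSpec(HELIX_SEQ))


@pytest.fixture(scope="session")
def one_cis_helix():
    return build_peptide(BuildSpec(HELIX_SEQ, cis_bonds=(8,)))


@pytest.fixture(scope="session")
def one_d_helix():
    return build_peptide(BuildSpec(HELIX_SEQ, d_residues=(8,)))


@pytest.fixture(scope="session")
def combined_helix():
    return build_peptide(BuildSpec(HELIX_SEQ, cis_bonds=(8,), d_residues=(8,)))


@pytest.fixture(scope="session")
def battery_dir(tmp_path_factory):
    directory = tmp_path_factory.mktemp("battery")
    write_fixture_set(directory)
    return directory


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
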