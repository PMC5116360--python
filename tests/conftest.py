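"""Shared fixtures.

The heavy objects (the 1024-sample dictionary, the 69-subject study
cohort and its feature table) are session-scoped so the unit tests and
the end-to-end acceptance tests share one computation.
"""

import numpy as np
import pytest

import hrvmp


@pytest.fixture(scope="session")
def dict64():
    return hrvmp.build_dictionary(64)


@pytest.fixture(scope="session")
def dict128():
    return hrvmp.build_dictionary(128)


@pytest.fixture(scope="session")
def dict1024():
    return hrvmp.build_dictionary(1024)


@pytest.fixture(scope="session")
def cohort69():
    """The study-sized synthetic cohort: 40 NSR + 29 CHF subjects."""
    return hrvmp.generate_study_cohort(40, 29, seed=20160)


@pytest.fixture(scope="session")
def cohort69_features(cohort69, dict1024):
    """Feature table of the study cohort (computed once per session)."""
    return hrvmp.extract_feature_table(cohort69, dictionary=dict1024)


def planted_disjoint_atoms(dictionary, n_atoms=3):
    """Dictionary atoms with pairwise disjoint effective supports.

    Small scale (s=8) atoms translated far apart: the Gaussian envelopes
    overlap only at the 1e-40 level, so the atoms are numerically
    orthogonal and matching pursuit recovers an exact combination in
    n_atoms iterations.
    """
    n = dictionary.n
    spacing = n // n_atoms
    atoms = []
    for i in range(n_atoms):
        u = 4 * round((spacing // 2 + i * spacing) / 4)  # on the s=8 grid
        w = np.pi * (2 + i) / 8.0
        atom = hrvmp.GaborAtom(
            s=8.0, u=float(u), w=w, phi=0.3 * i,
            waveform=hrvmp.gabor_waveform(8.0, float(u), w, 0.3 * i, n),
        )
        atoms.append(atom)
    return atoms
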