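"""Shared fixtures: synthetic ensembles and matched NMR data.

Everything is generated programmatically; session scope keeps the heavier
default fixture to a single construction.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from nmrselect.model_io import ConformerEnsemble, ConformerModel
from nmrselect.synthdata import FixtureSpec, make_synthetic_nmr, make_two_state_ensemble


def make_model(model_id, coords, resnames=None, plddt=None, ptm=0.9, atom="CA"):
    """Minimal single-atom-per-residue model from an (L, 3) array."""
    coords = np.asarray(coords, float)
    L = coords.shape[0]
    resnames = resnames or ["ALA"] * L
    rows = [
        ("A", i + 1, resnames[i], atom, atom[0], *coords[i]) for i in range(L)
    ]
    atoms = pd.DataFrame(
        rows, columns=["chain", "resnum", "resname", "atom", "element", "x", "y", "z"]
    )
    idx = pd.MultiIndex.from_tuples([("A", i + 1) for i in range(L)])
    pl = pd.Series(plddt if plddt is not None else 80.0, index=idx)
    return ConformerModel(model_id=model_id, atoms=atoms, plddt=pl, ptm=ptm)


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(
        n_residues=18, n_models_per_state=4, hinge_angle_deg=25.0,
        noise_sigma=0.3, seed=11,
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_two_state_ensemble(small_spec)


@pytest.fixture(scope="session")
def small_nmr(small_fixture):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_synthetic_nmr(small_fixture)


@pytest.fixture(scope="session")
def default_fixture():
    """The default study conditions (30 residues, 20 models/state)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_two_state_ensemble(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def default_nmr(default_fixture):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_synthetic_nmr(default_fixture)


def single_model_ensemble(model, label="single"):
    return ConformerEnsemble(label, [model])
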