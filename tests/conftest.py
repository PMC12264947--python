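"""Shared fixtures: small synthetic ensembles and hand-built toys."""

import numpy as np
import pytest

from ensembledecomp import Ensemble, GeneratorSpec, gen_backbone_ensemble, gen_heterogeneous_ensemble


def make_toy_ensemble(coords, residue_index=None, atom_names=None):
    """Ensemble from raw coordinates with a minimal linear topology.

    coords: (n_frames, n_atoms, 3). Defaults: one residue per atom,
    alternating N/C atom names so elements resolve.
    """
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    if residue_index is None:
        residue_index = np.arange(1, n_atoms + 1)
    residue_index = np.asarray(residue_index)
    if atom_names is None:
        atom_names = np.array(["N" if i % 2 == 0 else "C" for i in range(n_atoms)])
    n_res = int(residue_index.max())
    return Ensemble(
        coords=coords,
        atom_names=np.asarray(atom_names),
        residue_index=residue_index,
        residue_names=np.array(["GLY"] * n_res),
    )


@pytest.fixture(scope="session")
def small_ensemble():
    """8-residue, 6-frame mixed-basin backbone with ground truth."""
    spec = GeneratorSpec(n_residues=8, n_frames=6, compactness=0.4, seed=3)
    return gen_backbone_ensemble(spec)


@pytest.fixture(scope="session")
def hetero():
    """38-residue heterogeneous ensemble spanning compact to extended."""
    spec = GeneratorSpec(n_residues=38, n_frames=400, seed=7)
    return gen_heterogeneous_ensemble(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
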