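import numpy as np
import pytest

import quatfit as qf
from quatfit.pdb_io import CoordinateBatch, ReferenceFrame


@pytest.fixture(scope="session")
def backbone50():
    return qf.make_backbone(50, seed=7)


@pytest.fixture(scope="session")
def frame50(backbone50):
    return qf.build_reference_frame(backbone50, qf.SelectionSpec())


def make_rotated_batch(frame, n, seed, noise_sigma=0.0, deletion_fraction=0.0):
    """Rotated+translated copies of the reference CA set, as a CoordinateBatch,
    built directly from arrays (no PDB round-trip).  Returns (batch, quaternions)."""
    rng = np.random.default_rng(seed)
    L = len(frame)
    raw_ref = frame.ref_coords + frame.ref_centroid
    quats = qf.random_quaternions(n, rng)
    rots = qf.quaternion_matrix(quats)
    coords = np.zeros((n, L, 3))
    mask = np.ones((n, L))
    for i in range(n):
        c = raw_ref @ rots[i].T + rng.uniform(-10, 10, 3)
        if noise_sigma:
            c = c + rng.normal(0.0, noise_sigma, c.shape)
        if deletion_fraction:
            drop = rng.choice(L, size=round(deletion_fraction * L), replace=False)
            mask[i, drop] = 0.0
        coords[i] = c * mask[i][:, None]
    return CoordinateBatch(coords=coords, mask=mask, names=[f"copy{i}" for i in range(n)]), quats


def subset_kabsch_rmsd(coords_centered, frame, mask_row):
    """Closed-form optimal RMSD over the unmasked residues, with the reference
    centered over that same subset (the translation-optimal rigid fit)."""
    ref = frame.ref_coords - (mask_row @ frame.ref_coords) / mask_row.sum()
    return qf.kabsch_superimpose(coords_centered, ref, mask_row)[1]


@pytest.fixture()
def fixture_dir(tmp_path):
    """10 rotated/translated copies of a 30-residue reference, on disk."""
    spec = qf.SynthSpec(n_residues=30, n_structures=10, seed=11)
    return qf.write_fixture_dir(tmp_path / "fixtures", spec)
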