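"""Gradient descent vs the closed-form optimum on one noisy batch.

Creates 10 noisy, partially deleted copies of a 50-residue reference and
superimposes them twice: with the two-phase quaternion gradient descent, and
with the exact Kabsch SVD solution.  The two RMSD columns should agree to
well under 1e-3 Å on every structure — the gradient route reaches the
provable optimum, it does not approximate it.
"""

import numpy as np

import quatfit as qf
from quatfit.pdb_io import CoordinateBatch

rng = np.random.default_rng(3)
base = qf.make_backbone(50, seed=3)
frame = qf.build_reference_frame(base)
raw_ref = frame.ref_coords + frame.ref_centroid

coords, mask = np.zeros((10, 50, 3)), np.ones((10, 50))
for i in range(10):
    R = qf.quaternion_matrix(qf.random_quaternions(1, rng))[0]
    c = raw_ref @ R.T + rng.uniform(-10, 10, 3) + rng.normal(0, 0.5, (50, 3))
    mask[i, rng.choice(50, size=10, replace=False)] = 0  # simulate deletions
    coords[i] = c * mask[i][:, None]

batch = CoordinateBatch(coords, mask, [f"model_{i}" for i in range(10)])
centered, centroids = qf.center_batch(batch)
result = qf.optimize(centered, frame, centroids=centroids)

print(f"{'structure':<10}{'GD RMSD (Å)':>14}{'Kabsch RMSD (Å)':>18}{'difference':>14}")
for i, name in enumerate(batch.names):
    _, exact = qf.kabsch_superimpose(centered.coords[i], frame.ref_coords, mask[i])
    print(f"{name:<10}{result.rmsd[i]:>14.6f}{exact:>18.6f}{result.rmsd[i] - exact:>14.2e}")
print("\nRMSDs are over the 40 surviving residues; the ~0.5 Å level is the")
print("coordinate noise, and the difference column is the optimizer's error.")
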