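# Methods

## Model and assumptions

`quatfit` performs rigid-body *superimposition*, not structural *alignment*:
the residue–residue correspondence between each model and the reference is
assumed known and is taken from identical residue numbering — a model residue
corresponds to the reference residue with the same `(chain id, residue
number, insertion code)` key. Models produced by simulation, docking, or
modelling pipelines from one template satisfy this; homology models with
shifted numbering do not, and should be renumbered with a multiple-sequence
alignment before use (out of scope here).

For each model `i` the fitted quantity is a single rotation, parameterized
as a quaternion `q_i`, minimizing the masked mean-squared CA deviation

    loss_i = (1 / Σ_j m_ij) Σ_j m_ij · || R(q_i / |q_i|) p_ij − r_ij ||²

* `p_ij` — model CA coordinates at the reference's residue slots, centered
  on the model's mask-weighted centroid; slots the model lacks (deletions)
  are zero-filled and masked out.
* `r_ij` — reference CA coordinates, re-centered per structure over that
  structure's unmasked residues.
* `m_ij` — the binary deletion mask. Residues present in a model but absent
  from the reference (insertions) never enter the arrays at all.

Descending on the mean-squared deviation rather than the RMSD itself leaves
the minimizer unchanged while keeping gradients smooth near zero; the
reported figure is always the RMSD. Because translation is eliminated by the
paired centroids and the centering is per-mask on *both* sides, the
rotation-only optimum coincides with the full rigid-body optimum over the
surviving residues — the same quantity the closed-form Kabsch solution
yields, which is how the two routes can be compared at 1e-3 Å per structure.

A deliberate consequence of per-mask reference centering: each structure's
`RigidTransform.ref_centroid` is the centroid of the reference residues that
structure actually has, so two models with different deletion patterns are
translated to marginally different positions (each optimally for its own
common subset). With no deletions this reduces to the single full-selection
centroid.

## Optimization

Quaternions are stored unconstrained and normalized *inside* the rotation:
the matrix is built as `R = M(q) / |q|²` (Hamilton convention), which is
exact for any nonzero `q`, always proper orthogonal (no reflections), and
makes the parameterization projection-free — plain gradient descent needs no
re-normalization step. Gradients are analytic: with `G = (2/m) Σ_j m_j (R
p_j − r_j) p_jᵀ` the chain rule through `M(q)/|q|²` gives a closed form per
component, verified against finite differences in the tests. `q` and `−q`
encode the same rotation; reported quaternions are canonicalized to `w ≥ 0`.

Initial quaternions are i.i.d. uniform on [0, 1) per component (seeded,
reproducible), normalized implicitly by the rotation.

The descent has two phases with fixed step counts and no early stopping:

| parameter | default | meaning |
|---|---|---|
| `phase1_lr` | 0.5 | coarse step size (dimensionless, see scaling below) |
| `phase2_lr` | 0.05 | fine-tuning step size |
| `phase1_steps(L)` | `clamp(round(30000 / L), 900, 3000)` | coarse steps; decreases with residue count L |
| `phase2_steps` | 100 | fixed fine-tuning length |

Two numerical choices make these four numbers size-independent:

* **Coordinate scaling.** Inside `optimize` all coordinates are divided by
  the RMS radius of the centered reference selection, so the loss and its
  curvature are O(1) whether the protein has 4 residues or 1000. Step sizes
  are therefore dimensionless; the final RMSD is computed on unscaled
  coordinates.
* **Coarse-phase length.** The loss over SO(3) has one global minimum and a
  few saddle points (at 180° rotations about the covariance eigenvectors).
  An unlucky initialization near a saddle escapes at a rate set by the local
  curvature gap, so the required coarse length is governed by the worst-case
  initialization, not the typical one. Small selections need more steps
  (their loss is less well conditioned), hence the `1/L` shape with a high
  floor. With the defaults, the worst deviation from the Kabsch optimum
  observed over 15 000 random structures per size class (L = 4…300) is
  below 1e-4 Å, comfortably inside the 1e-3 Å contract; the fixed 900-step
  floor is what pushes the rare saddle-adjacent starts (~1 in 10⁴ at 600
  steps) under it.

The fine-tuning phase always runs its full fixed length so results are
deterministic functions of (inputs, seed) — bitwise, since the arithmetic is
pure double-precision NumPy with no reductions whose order varies.

All heavy operations are batched array primitives (elementwise ops, `einsum`
contractions, reductions over the residue axis) over `[N × L × 3]` tensors,
so an accelerated array backend could be substituted without touching the
algorithm; the in-tree backend is NumPy on CPU. Structures are processed in
batches (default 50 000) so peak memory follows the batch size, not the
ensemble size.

## The Kabsch oracle

`kabsch_superimpose` implements the closed-form optimum: SVD of the masked
covariance `H = Σ_j m_j p_j r_jᵀ`, `R = V diag(1, 1, det(VUᵀ)) Uᵀ`. The
determinant correction guarantees a proper rotation even when the unmasked
point set is nearly planar (a mirror would otherwise fit better). Collinear
point sets are rejected (`rank-deficient`) since the optimal rotation is not
unique there. The oracle is used in tests and available as an exact
single-structure backend; the gradient route never calls it.

## PDB handling

Parsing is fixed-column and line-preserving: every ATOM/HETATM record keeps
its original 80-column text, and writing a transformed structure rewrites
only the three 8.3f coordinate fields — all other bytes, including headers,
TER records, odd alt-loc or occupancy formatting, round-trip identically.
Rules for corner cases, chosen for determinism and documented here because
the format itself does not fix them:

* Alt-loc CA records: the highest-occupancy conformer wins; ties go to the
  first in file order.
* Multi-MODEL files: only the first model is read.
* HETATM records never provide a CA for the fit but are transformed and
  written like every other atom.
* Files that fail to parse, or share fewer than 3 residues with the
  reference selection, are skipped with a logged warning rather than
  aborting a large run; a run fails only if *no* input survives.
* Coordinates are PDB orthogonal ångströms throughout; the printed precision
  of the format (0.001 Å) is the accuracy floor for anything measured from
  written files.

Selections use a small grammar (`"A"`, `"A:10-120"`, `"A:10-20,30-40"`,
comma-separated; a bare range applies to the last named chain, or all
chains) and restrict which residues drive the fit; all atoms are still
transformed and written.

## Synthetic data

The fixture generator produces what the method needs to be tested against
and nothing more:

* **Backbones** are compact self-avoiding persistent random walks: 3.8 ± 0.1 Å
  CA steps, ≥ 2.5 Å between non-consecutive CAs, confined to a sphere of
  radius `3.0·n^(1/3)` Å so the moment-of-inertia anisotropy matches
  globular proteins rather than an extended chain (an extended chain makes
  rotation about its long axis nearly unconstrained, which is both
  unrealistic and numerically adversarial). Each residue carries dummy
  N/C/O atoms at fixed offsets so files are ordinary all-atom PDB.
* **Perturbed copies** get an independent rotation drawn uniformly on SO(3)
  (normalized 4-D Gaussian quaternions; mean rotation angle ≈ 126.5°, which
  the tests check), a translation uniform in ±10 Å per component, optional
  isotropic Gaussian coordinate noise on every atom, and an optional random
  deletion of a fixed fraction of whole residues. Ground truth (quaternion,
  translation, deleted keys) is recorded in a manifest.

What this does *not* emulate: side chains, realistic sequences, secondary
structure, correlated conformational change, insertion-code numbering, or
homolog-level divergence. Passing tests therefore demonstrate correctness of
the rigid-fit machinery under known ground truth — not robustness to
mis-numbered or conformationally heterogeneous real-world ensembles, where
the residue-numbering assumption itself is the binding constraint.

## Problem sizes used in the checks

The test suite exercises L ∈ {4, 20, 50, 300} with noise σ ∈ {0, 0.5, 2} Å
and deletion fractions {0, 0.2} (120 structure instances) for oracle
equivalence; 1000 exact rigid copies at L = 100 for rotation recovery; and a
10 000-structure, L = 20 end-to-end run at batch size 500 whose outputs are
re-read with an independent parser (gemmi) and whose RMSDs are recomputed
directly from the written files. `scripts/acceptance.py` repeats the same
measurements from scratch at a seed of the caller's choosing, with the
end-to-end stage at 2000 structures.

## Known limitations

* Correspondence is by residue key only; no sequence-based matching.
* CA-only loss; backbone or all-atom selections would be a straightforward
  extension of the slot-building step but are not implemented.
* Single rotation per structure: flexible or domain-wise alignment is out of
  scope.
* CPU/NumPy only; the batched-primitive structure is backend-ready but no
  accelerated backend ships in-tree.
* I/O is serial; the `--workers` flag is accepted for interface stability
  and validated, but reads/writes are sequential (results are independent of
  worker count by construction).
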