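# quatfit

Fast, memory-bounded superimposition of large ensembles of protein structure
models onto a reference, by gradient descent on rotation quaternions.

## The problem

Molecular dynamics, docking, and large-scale modelling pipelines routinely
produce thousands to millions of conformations of the same protein. Before
any clustering or per-residue analysis, every model must be rigidly
superimposed onto a common reference. Classical tools solve each structure's
optimal rotation independently via an SVD of its covariance matrix, which is
exact but awkward to batch — especially when models have residues deleted or
inserted relative to the reference, which breaks the uniform array layout.

`quatfit` is written for exactly this regime: models whose residue–residue
correspondence with the reference is already known (identical residue
numbering). It extracts one α-carbon per residue, builds a binary mask
marking which reference residues each model actually has, and then optimizes
**one unit quaternion per structure, jointly over the whole batch**, by
plain two-phase gradient descent on the masked deviation

$$\mathrm{loss}_i \;=\; \frac{1}{\sum_j m_{ij}} \sum_j m_{ij}\,
\lVert R(q_i)\,p_{ij} - r_{ij} \rVert^2 ,$$

where $p_{ij}$ are the model's centered CA coordinates, $r_{ij}$ the
reference CA coordinates centered over the same surviving residues,
$m_{ij}\in\{0,1\}$ the deletion mask, and $R(q_i)$ the rotation matrix of
the (normalized) quaternion $q_i$. Minimizing this mean-squared deviation
minimizes the RMSD, which is what gets reported. The learned rigid
transform — model centroid, reference centroid, quaternion — is then applied
to *all* atoms of each input file and written back out as PDB.

Everything is dense batched array arithmetic over `[structures × residues × 3]`
tensors, so memory is proportional to the batch size (default 50 000
structures per batch), not the ensemble size. Deletions cost nothing beyond
the mask; insertions are simply ignored.

The exact closed-form solution (Kabsch: SVD of the covariance matrix with a
reflection correction) is included as `kabsch_superimpose` and serves as the
independent per-structure oracle in the test suite: the gradient route must
reproduce it to better than 1e-3 Å on every structure, across protein sizes,
noise levels, and deletion fractions.

## Worked example

```bash
python examples/oracle_check.py
```

builds 10 noisy copies of a 50-residue synthetic reference, each randomly
rotated, translated, and with 10 residues deleted, and superimposes them with
both routes:

```
structure    GD RMSD (Å)   Kabsch RMSD (Å)    difference
model_0         0.925213          0.925213     -1.11e-16
model_1         1.083387          1.083387      4.44e-16
model_2         0.904322          0.904322      0.00e+00
...
```

The ~1 Å RMSD is the injected coordinate noise (σ = 0.5 Å on both point
sets); the `difference` column shows the gradient optimizer landing on the
provably optimal rotation to machine precision. `examples/superimpose_ensemble.py`
runs the full file pipeline (50 rigid copies come back at
`RMSD mean ± sd : 0.000492 ± 0.000016 Å`, the PDB print-precision floor),
and `examples/deletions_and_insertions.py` walks through the masking rules.

## Command line

```bash
quatfit synth -o fixtures --residues 60 --structures 1000          # make a test ensemble
quatfit align fixtures -r fixtures/reference.pdb -o aligned \
        --selection "A:1-60" --batch-size 50000 --seed 0
```

`align` writes one superimposed PDB per input plus `superimposition.tsv`
(name, RMSD, quaternion, translation per structure) and prints
`loaded/skipped/written` counts with the RMSD mean ± sd. Unreadable files
are skipped with a warning, not fatal.

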