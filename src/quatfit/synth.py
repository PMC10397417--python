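"""Synthetic PDB fixtures with known ground-truth rigid transforms.

The generator emulates what matters for superimposition — a protein-like CA
trace, random rigid motion, per-structure whole-residue deletions, and small
coordinate noise — and nothing else (no side chains, no realistic sequences,
no conformational change).  Backbones are compact self-avoiding persistent
random walks with 3.8 Å CA-CA steps, confined to a sphere matching globular
protein density (R ≈ 3.0 · n^(1/3) Å), so their moment-of-inertia anisotropy
resembles real proteins rather than an extended chain; each residue carries
dummy N/C/O atoms so files are ordinary all-atom PDB records.  Rotations are
sampled uniformly on SO(3) via normalized 4-component Gaussian quaternions.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import RigidTransform, quaternion_matrix
from .pdb_io import ResidueKey, StructureRecord, parse_pdb_text

__all__ = [
    "SynthSpec",
    "make_backbone",
    "perturb",
    "random_quaternions",
    "rotation_angle_deg",
    "write_structure",
    "write_fixture_dir",
]

_CA_STEP = 3.8  # Å, mean consecutive CA-CA distance
_STEP_JITTER = 0.1  # Å, uniform half-width on the step length
_MIN_SEPARATION = 2.5  # Å, excluded-volume radius between non-consecutive CAs


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one perturbed-ensemble fixture.

    ``deletion_fraction`` removes that fraction of whole residues (rounded)
    from each copy, independently chosen per copy; it must leave at least 3
    residues.  ``translation_scale`` is the half-width of the uniform
    per-component translation, ``noise_sigma`` the Gaussian coordinate noise
    applied to every atom.
    """

    n_residues: int
    n_structures: int
    translation_scale: float = 10.0
    deletion_fraction: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if not (0.0 <= self.deletion_fraction < 1.0):
            raise ValueError("deletion_fraction must be in [0, 1)")
        if self.n_residues - round(self.deletion_fraction * self.n_residues) < 3:
            raise ValueError("deletion_fraction leaves fewer than 3 residues")


def random_quaternions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-on-SO(3) unit quaternions (normalized 4D Gaussians), w >= 0."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    q[q[:, 0] < 0] *= -1.0
    return q


def rotation_angle_deg(q: np.ndarray) -> np.ndarray:
    """Rotation angle of each unit quaternion, degrees in [0, 180]."""
    w = np.clip(np.abs(np.asarray(q)[..., 0]), 0.0, 1.0)
    return np.degrees(2.0 * np.arccos(w))


def _backbone_ca(n_residues: int, rng: np.random.Generator) -> np.ndarray:
    # persistent self-avoiding walk confined to a sphere at globular density
    confine_radius = max(3.0 * n_residues ** (1.0 / 3.0), 6.0)
    for _ in range(20):  # fresh restarts if the walk traps itself
        points = np.empty((n_residues, 3))
        points[0] = 0.0
        direction = _random_unit(rng)
        trapped = False
        for i in range(1, n_residues):
            placed = False
            for _attempt in range(200):
                candidate_dir = 0.5 * direction + _random_unit(rng)
                # steer back toward the centre near the confinement boundary
                radial = np.linalg.norm(points[i - 1])
                if radial > 0.7 * confine_radius:
                    candidate_dir -= (points[i - 1] / radial) * (radial / confine_radius)
                candidate_dir /= np.linalg.norm(candidate_dir)
                step = _CA_STEP + rng.uniform(-_STEP_JITTER, _STEP_JITTER)
                candidate = points[i - 1] + candidate_dir * step
                clash = points[: max(i - 1, 0)]
                if clash.size and np.min(np.linalg.norm(clash - candidate, axis=1)) < _MIN_SEPARATION:
                    continue
                points[i] = candidate
                direction = candidate_dir
                placed = True
                break
            if not placed:
                trapped = True
                break
        if not trapped:
            return points - points.mean(axis=0)
    raise RuntimeError(f"could not grow a self-avoiding {n_residues}-residue trace")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


# fixed dummy offsets from CA for the N, C, O backbone atoms
_DUMMY_OFFSETS = {
    "N": np.array([-1.20, 0.80, 0.00]),
    "C": np.array([1.25, 0.85, 0.00]),
    "O": np.array([1.80, 1.90, 0.30]),
}


def _atom_lines(coords_by_residue: list[tuple[int, dict[str, np.ndarray]]], chain: str) -> list[str]:
    lines = []
    serial = 1
    for res_seq, atoms in coords_by_residue:
        for name in ("N", "CA", "C", "O"):
            x, y, z = atoms[name]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} ALA {chain}{res_seq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{name[0]:>2s}"
            )
            serial += 1
    lines.append("END")
    return lines


def _structure_from_ca(
    ca: np.ndarray, res_seqs: np.ndarray, chain: str, source: str
) -> StructureRecord:
    residues = []
    for res_seq, ca_pos in zip(res_seqs, ca):
        atoms = {"CA": ca_pos}
        for name, off in _DUMMY_OFFSETS.items():
            atoms[name] = ca_pos + off
        residues.append((int(res_seq), atoms))
    text = "\n".join(_atom_lines(residues, chain)) + "\n"
    return parse_pdb_text(text, source_path=source)


def make_backbone(n_residues: int, seed: int, chain: str = "A") -> StructureRecord:
    """A self-avoiding CA trace (consecutive spacing 3.8 ± 0.2 Å) with dummy
    N/C/O atoms per residue, numbered 1..n, as a parsed structure."""
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    ca = _backbone_ca(n_residues, rng)
    return _structure_from_ca(ca, np.arange(1, n_residues + 1), chain, f"<synthetic n={n_residues}>")


def perturb(
    base: StructureRecord, spec: SynthSpec
) -> tuple[list[StructureRecord], list[RigidTransform], list[set[ResidueKey]]]:
    """Independent rigid-motion + noise + deletion copies of ``base``.

    Each copy i gets coordinates ``R_i (p - c0) + c0 + t_i`` (c0 the base CA
    centroid), then Gaussian noise on every atom, then a random
    ``deletion_fraction`` of whole residues removed.  The returned ground-truth
    transform maps base coordinates onto the copy exactly (noise aside):
    ``model_centroid = c0``, ``ref_centroid = c0 + t_i``.
    """
    rng = np.random.default_rng(spec.seed)
    keys = list(base.ca_index.keys())
    L = len(keys)
    n_delete = round(spec.deletion_fraction * L)

    c0 = base.ca_coords().mean(axis=0)
    all_coords = base.coords
    quats = random_quaternions(spec.n_structures, rng)
    rots = quaternion_matrix(quats)

    structures: list[StructureRecord] = []
    truths: list[RigidTransform] = []
    deletions: list[set[ResidueKey]] = []
    for i in range(spec.n_structures):
        t = rng.uniform(-spec.translation_scale, spec.translation_scale, size=3)
        moved = (all_coords - c0) @ rots[i].T + c0 + t
        if spec.noise_sigma > 0:
            moved = moved + rng.normal(0.0, spec.noise_sigma, size=moved.shape)
        drop = set()
        if n_delete:
            drop = {keys[j] for j in rng.choice(L, size=n_delete, replace=False)}
        residues: dict[ResidueKey, dict[str, np.ndarray]] = {}
        order: list[ResidueKey] = []
        for atom, pos in zip(base.atoms, moved):
            key = (atom.chain_id, atom.res_seq, atom.i_code)
            if key in drop:
                continue
            if key not in residues:
                residues[key] = {}
                order.append(key)
            residues[key][atom.atom_name] = pos
        lines = _atom_lines(
            [(key[1], residues[key]) for key in order], chain=order[0][0]
        )
        structures.append(parse_pdb_text("\n".join(lines) + "\n", source_path=f"<synthetic copy {i}>"))
        truths.append(
            RigidTransform(model_centroid=c0.copy(), ref_centroid=c0 + t, quaternion=quats[i].copy())
        )
        deletions.append(drop)
    return structures, truths, deletions


def write_structure(struct: StructureRecord, path: str | os.PathLike) -> None:
    """Write a structure's lines verbatim to ``path``."""
    with open(path, "w") as handle:
        handle.write("\n".join(struct.lines))
        handle.write("\n")


def write_fixture_dir(out_dir: str | os.PathLike, spec: SynthSpec) -> Path:
    """Emit ``reference.pdb``, ``model_NNNN.pdb`` copies and a ground-truth
    manifest (``manifest.tsv``: filename, quaternion, translation, deleted keys).

    Returns the output directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = make_backbone(spec.n_residues, seed=spec.seed)
    write_structure(base, out / "reference.pdb")
    structures, truths, deletions = perturb(base, spec)
    with open(out / "manifest.tsv", "w") as manifest:
        manifest.write("filename\tqw\tqx\tqy\tqz\ttx\tty\ttz\tdeleted\n")
        for i, (struct, truth, deleted) in enumerate(zip(structures, truths, deletions)):
            name = f"model_{i:04d}.pdb"
            write_structure(struct, out / name)
            q = truth.quaternion
            t = truth.ref_centroid - truth.model_centroid
            dropped = ";".join(f"{c}{r}{ic}".strip() for c, r, ic in sorted(deleted))
            manifest.write(
                f"{name}\t{q[0]:.9f}\t{q[1]:.9f}\t{q[2]:.9f}\t{q[3]:.9f}"
                f"\t{t[0]:.6f}\t{t[1]:.6f}\t{t[2]:.6f}\t{dropped}\n"
            )
    return out
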