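"""Quaternion gradient-descent superimposition and the Kabsch SVD oracle.

One rotation quaternion is optimized per structure, jointly over the whole
batch as dense array operations, by plain gradient descent on the masked mean
squared CA deviation from the reference (same minimizer as the RMSD, smoother
near zero; the reported figure is the RMSD).  Quaternions are stored
unconstrained and normalized inside the rotation, so no projection step is
needed; the rotation matrix is built from ``q / |q|`` (Hamilton convention)
and is always proper orthogonal — chirality is never mirrored.

The descent has two phases: a coarse phase with a large step whose length
shrinks with the number of selected residues, then a fixed-length fine-tuning
phase with a small step.  Coordinates are rescaled internally by the RMS
radius of the reference selection so the same step sizes work for 4-residue
peptides and 1000-residue complexes alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pdb_io import CoordinateBatch, ReferenceFrame

__all__ = [
    "QuaternionBatch",
    "RigidTransform",
    "OptimizerSchedule",
    "SuperimpositionResult",
    "center_batch",
    "init_quaternions",
    "quaternion_matrix",
    "rotate",
    "masked_rmsd",
    "optimize",
    "kabsch_superimpose",
    "quaternion_angle",
    "apply_transform",
    "invert_transform",
]


@dataclass
class QuaternionBatch:
    """N rotation quaternions, components ordered (w, x, y, z), rows not
    necessarily unit norm until :meth:`normalized` is taken."""

    q: np.ndarray  # (N, 4)

    def normalized(self) -> "QuaternionBatch":
        norms = np.linalg.norm(self.q, axis=1, keepdims=True)
        if np.any(norms == 0.0):
            raise ValueError("degenerate quaternion: zero norm row")
        return QuaternionBatch(self.q / norms)

    def __len__(self) -> int:
        return self.q.shape[0]


@dataclass(frozen=True)
class RigidTransform:
    """Per-structure rigid map: ``p -> R(quaternion) @ (p - model_centroid) + ref_centroid``."""

    model_centroid: np.ndarray  # (3,)
    ref_centroid: np.ndarray  # (3,)
    quaternion: np.ndarray  # (4,), unit norm


@dataclass(frozen=True)
class OptimizerSchedule:
    """Two-phase gradient-descent schedule.

    ``phase1_steps(L)`` decreases with the residue count L — more residues
    give a better-conditioned loss, needing fewer coarse steps — and is
    clamped to [phase1_min_steps, phase1_max_steps].  The fine-tuning phase
    always runs exactly ``phase2_steps`` steps (no early stopping), ensuring
    complete convergence at the small step size.
    """

    phase1_lr: float = 0.5
    phase2_lr: float = 0.05
    phase1_scale: float = 30_000.0
    phase1_min_steps: int = 900
    phase1_max_steps: int = 3000
    phase2_steps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.phase1_lr > self.phase2_lr > 0):
            raise ValueError("require phase1_lr > phase2_lr > 0")
        if self.phase2_steps < 1 or self.phase1_min_steps < 1:
            raise ValueError("step counts must be positive")

    def phase1_steps(self, n_residues: int) -> int:
        steps = round(self.phase1_scale / max(n_residues, 1))
        return int(min(max(steps, self.phase1_min_steps), self.phase1_max_steps))


@dataclass
class SuperimpositionResult:
    """Outcome of :func:`optimize`: one transform and final masked RMSD per structure."""

    transforms: list[RigidTransform]
    rmsd: np.ndarray  # (N,), Å
    iterations_used: np.ndarray  # (N,)
    quaternions: np.ndarray  # (N, 4), unit norm, w >= 0
    loss_history: np.ndarray | None = None  # (steps, N) mean-squared loss, if tracked


# --- primitives ---------------------------------------------------------------


def center_batch(batch: CoordinateBatch) -> tuple[CoordinateBatch, np.ndarray]:
    """Subtract each structure's mask-weighted CA centroid; masked rows reset to zero.

    Returns the centered batch and the (N, 3) centroids.
    """
    mask = batch.mask
    counts = mask.sum(axis=1)
    if np.any(counts == 0):
        bad = int(np.argmax(counts == 0))
        raise ValueError(f"structure {batch.names[bad]!r} has no unmasked residues")
    centroids = (batch.coords * mask[:, :, None]).sum(axis=1) / counts[:, None]
    centered = (batch.coords - centroids[:, None, :]) * mask[:, :, None]
    return CoordinateBatch(coords=centered, mask=mask, names=batch.names), centroids


def init_quaternions(n: int, seed: int) -> QuaternionBatch:
    """Initial quaternions: each component i.i.d. uniform on [0, 1), not normalized.

    Normalization happens inside the rotation, so the raw draws double as the
    optimizer's unconstrained starting parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return QuaternionBatch(rng.random((n, 4)))


def quaternion_matrix(q: np.ndarray) -> np.ndarray:
    """(N, 4) quaternions (any nonzero norm) -> (N, 3, 3) proper rotation matrices.

    Uses the norm-homogeneous form R = M(q) / |q|^2, exact for non-unit
    quaternions, Hamilton convention.
    """
    q = np.asarray(q, dtype=np.float64)
    s = (q * q).sum(axis=1)
    if np.any(s == 0.0):
        raise ValueError("degenerate quaternion: zero norm row")
    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    R = np.empty((q.shape[0], 3, 3), dtype=np.float64)
    R[:, 0, 0] = w * w + x * x - y * y - z * z
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = w * w - x * x + y * y - z * z
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = w * w - x * x - y * y + z * z
    return R / s[:, None, None]


def rotate(q: QuaternionBatch | np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Apply per-structure rotations R(q/|q|) to (N, L, 3) coordinates."""
    arr = q.q if isinstance(q, QuaternionBatch) else np.asarray(q, dtype=np.float64)
    R = quaternion_matrix(arr)
    return np.einsum("nab,nlb->nla", R, coords)


def masked_rmsd(coords: np.ndarray, ref: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-structure RMSD over unmasked residue slots only, in Å.

    ``coords`` is (N, L, 3), ``ref`` (L, 3), ``mask`` (N, L).  Values at
    masked slots never influence the result.
    """
    mask = np.asarray(mask, dtype=np.float64)
    counts = mask.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("mask row with zero unmasked residues")
    sq = ((coords - ref[None]) ** 2).sum(axis=2)
    return np.sqrt((sq * mask).sum(axis=1) / counts)


# --- gradient descent ---------------------------------------------------------


def _loss_and_grad(
    q: np.ndarray, coords: np.ndarray, ref: np.ndarray, mask: np.ndarray, counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Masked mean-squared deviation and its analytic gradient w.r.t. the raw
    (unnormalized) quaternions.  ``ref`` is per-structure, (N, L, 3).

    With R = M(q)/s, s = |q|^2 and M quadratic in q, the chain rule gives
    dL/dq_k = (<G, dM/dq_k> - 2 q_k <G, R>) / s where G = (2/m) Σ_j mask_j
    (R p_j - r_j) p_j^T is the gradient of the loss in R.
    """
    s = (q * q).sum(axis=1)
    R = quaternion_matrix(q)
    rotated = np.einsum("nab,nlb->nla", R, coords)
    diff = (rotated - ref) * mask[:, :, None]
    loss = (diff * diff).sum(axis=(1, 2)) / counts
    G = 2.0 * np.einsum("nla,nlb->nab", diff, coords) / counts[:, None, None]

    w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    g00, g01, g02 = G[:, 0, 0], G[:, 0, 1], G[:, 0, 2]
    g10, g11, g12 = G[:, 1, 0], G[:, 1, 1], G[:, 1, 2]
    g20, g21, g22 = G[:, 2, 0], G[:, 2, 1], G[:, 2, 2]

    a_w = w * (g00 + g11 + g22) + x * (g21 - g12) + y * (g02 - g20) + z * (g10 - g01)
    a_x = x * (g00 - g11 - g22) + y * (g01 + g10) + z * (g02 + g20) + w * (g21 - g12)
    a_y = y * (-g00 + g11 - g22) + x * (g01 + g10) + z * (g12 + g21) + w * (g02 - g20)
    a_z = z * (-g00 - g11 + g22) + x * (g02 + g20) + y * (g12 + g21) + w * (g10 - g01)
    A = 2.0 * np.stack([a_w, a_x, a_y, a_z], axis=1)

    GR = np.einsum("nab,nab->n", G, R)
    grad = (A - 2.0 * q * GR[:, None]) / s[:, None]
    return loss, grad


def optimize(
    batch: CoordinateBatch,
    frame: ReferenceFrame,
    sched: OptimizerSchedule | None = None,
    centroids: np.ndarray | None = None,
    track_loss: bool = False,
    init: np.ndarray | None = None,
) -> SuperimpositionResult:
    """Two-phase batched gradient descent on the masked CA deviation.

    ``batch`` must already be centered per its masks (see :func:`center_batch`)
    and ``frame.ref_coords`` centered over the full selection; pass the
    centroids from :func:`center_batch` so the returned transforms carry them.
    Internally the reference is re-centered per structure over that
    structure's unmasked residues, so the fit is translation-optimal for the
    surviving subset and the RMSD matches a classical optimal superimposition
    of the common residues; each transform's ``ref_centroid`` is accordingly
    the masked reference centroid for that structure (equal to
    ``frame.ref_centroid`` when nothing is deleted).

    Returns unit quaternions (sign-canonicalized to w >= 0), the two centroids
    per structure, and the final masked RMSD in Å.  ``init`` overrides the
    seeded (N, 4) starting quaternions, e.g. to optimize one structure from
    the same start it had inside a larger batch.
    """
    if sched is None:
        sched = OptimizerSchedule()
    coords = np.asarray(batch.coords, dtype=np.float64)
    mask = np.asarray(batch.mask, dtype=np.float64)
    ref = np.asarray(frame.ref_coords, dtype=np.float64)
    n, L = mask.shape
    counts = mask.sum(axis=1)
    if np.any(counts < 3):
        bad = int(np.argmax(counts < 3))
        raise ValueError(f"structure index {bad} has fewer than 3 unmasked residues")
    if centroids is None:
        centroids = np.zeros((n, 3))

    # re-center the reference per structure over its unmasked residues, so the
    # rotation-only fit is also translation-optimal for the surviving subset
    ref_offsets = (mask @ ref) / counts[:, None]  # (N, 3)
    refs_full = ref[None] - ref_offsets[:, None, :]

    # size-independent step sizes: work in units of the reference RMS radius
    scale = float(np.sqrt((ref * ref).sum() / len(frame)))
    if scale == 0.0:
        raise ValueError("reference selection is a single point; rotation undefined")
    P = coords / scale
    refs = refs_full / scale

    if init is None:
        q = init_quaternions(n, sched.seed).q.copy()
    else:
        q = np.array(init, dtype=np.float64)
        if q.shape != (n, 4):
            raise ValueError(f"init must have shape ({n}, 4), got {q.shape}")
    steps1 = sched.phase1_steps(L)
    plan = [(steps1, sched.phase1_lr), (sched.phase2_steps, sched.phase2_lr)]
    history = [] if track_loss else None
    total = 0
    for n_steps, lr in plan:
        for _ in range(n_steps):
            loss, grad = _loss_and_grad(q, P, refs, mask, counts)
            if not np.all(np.isfinite(loss)):
                bad = int(np.argmax(~np.isfinite(loss)))
                raise FloatingPointError(
                    f"non-finite loss for structure index {bad} ({batch.names[bad]!r})"
                )
            if history is not None:
                history.append(loss)
            q -= lr * grad
            total += 1

    qb = QuaternionBatch(q).normalized()
    q_unit = qb.q
    # q and -q are one rotation; fix the sign for stable reporting
    flip = q_unit[:, 0] < 0
    q_unit[flip] *= -1.0

    final = rotate(q_unit, coords)
    sq = ((final - refs_full) ** 2).sum(axis=2)
    rmsd = np.sqrt((sq * mask).sum(axis=1) / counts)
    transforms = [
        RigidTransform(
            model_centroid=centroids[i].copy(),
            ref_centroid=frame.ref_centroid + ref_offsets[i],
            quaternion=q_unit[i].copy(),
        )
        for i in range(n)
    ]
    return SuperimpositionResult(
        transforms=transforms,
        rmsd=rmsd,
        iterations_used=np.full(n, total, dtype=np.int64),
        quaternions=q_unit,
        loss_history=np.array(history) * scale * scale if history is not None else None,
    )


# --- closed-form oracle -------------------------------------------------------


def kabsch_superimpose(
    coords: np.ndarray, ref: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Optimal proper rotation (SVD with reflection correction) and its RMSD.

    ``coords`` and ``ref`` are (L, 3) point sets, both centered over the mask;
    the rotation maps ``coords`` onto ``ref``.  This is the exact closed-form
    solution, used as the independent check on the gradient-descent route and
    available as an exact backend.  Raises on collinear (rank-deficient) sets,
    where the optimal rotation is not unique.
    """
    coords = np.asarray(coords, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if mask is None:
        mask = np.ones(coords.shape[0])
    mask = np.asarray(mask, dtype=np.float64)
    m = mask.sum()
    if m < 3:
        raise ValueError("need at least 3 unmasked points")
    H = (coords * mask[:, None]).T @ ref  # covariance Σ m_j p_j r_j^T
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-9 * max(S[0], 1.0):
        raise ValueError("rank-deficient point set (collinear): rotation not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    rotated = coords @ R.T
    sq = ((rotated - ref) ** 2).sum(axis=1)
    rmsd = float(np.sqrt((sq * mask).sum() / m))
    return R, rmsd


# --- small transform utilities ------------------------------------------------


def quaternion_angle(q1: np.ndarray, q2: np.ndarray) -> float:
    """Geodesic angle in degrees between two rotations given as unit quaternions.

    Sign-insensitive: q and -q are the same rotation.
    """
    dot = abs(float(np.dot(q1, q2)))
    return math.degrees(2.0 * math.acos(min(dot, 1.0)))


def apply_transform(t: RigidTransform, coords: np.ndarray) -> np.ndarray:
    """Apply ``R(q) @ (p - model_centroid) + ref_centroid`` to (.., 3) coordinates."""
    R = quaternion_matrix(np.asarray(t.quaternion)[None])[0]
    return (np.asarray(coords, dtype=np.float64) - t.model_centroid) @ R.T + t.ref_centroid


def invert_transform(t: RigidTransform) -> RigidTransform:
    """The rigid map undoing ``t`` (conjugate quaternion, swapped centroids)."""
    q = np.asarray(t.quaternion, dtype=np.float64)
    conj = np.array([q[0], -q[1], -q[2], -q[3]])
    return RigidTransform(
        model_centroid=np.asarray(t.ref_centroid, dtype=np.float64).copy(),
        ref_centroid=np.asarray(t.model_centroid, dtype=np.float64).copy(),
        quaternion=conj,
    )
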