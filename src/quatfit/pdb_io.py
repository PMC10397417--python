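"""Batched PDB reading, CA extraction against a reference frame, and all-atom writing.

The parser keeps every source line verbatim (``raw_line``) so that writing a
transformed structure only rewrites the three fixed coordinate columns of
ATOM/HETATM records; every other byte round-trips identically.  Residue
correspondence with the reference is by ``(chain_id, res_seq, i_code)`` key
equality — the model and reference are assumed to number equivalent residues
identically.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureRecord",
    "ReferenceFrame",
    "CoordinateBatch",
    "SelectionSpec",
    "PDBFormatError",
    "parse_pdb",
    "parse_pdb_text",
    "build_reference_frame",
    "load_batch",
    "write_transformed",
    "format_atom_line",
]

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be interpreted (no ATOM records, bad columns)."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM line, parsed plus verbatim.

    ``raw_line`` is the original line without trailing newline; non-coordinate
    columns are never regenerated from the parsed fields, so odd formatting
    survives a read/transform/write cycle byte-identically.
    """

    record_kind: str  # "ATOM" or "HETATM"
    serial: int
    atom_name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    x: float
    y: float
    z: float
    occupancy: float
    b_factor: float
    element: str
    raw_line: str
    line_index: int  # position in StructureRecord.lines


@dataclass
class StructureRecord:
    """A parsed PDB model: all lines, the atom table, and a per-residue CA lookup.

    ``ca_index`` maps ``(chain_id, res_seq, i_code)`` to an index into ``atoms``;
    each target is an ATOM record named CA.  For multi-MODEL files only the
    first model is retained.
    """

    source_path: str
    lines: list[str]
    atoms: list[AtomRecord]
    ca_index: dict[ResidueKey, int]

    @property
    def coords(self) -> np.ndarray:
        """All-atom coordinates, shape (n_atoms, 3), Å."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=np.float64)

    def ca_coords(self) -> np.ndarray:
        """CA coordinates in ca_index (file) order, shape (n_residues, 3)."""
        return np.array(
            [[self.atoms[i].x, self.atoms[i].y, self.atoms[i].z] for i in self.ca_index.values()],
            dtype=np.float64,
        )


@dataclass
class ReferenceFrame:
    """The reference selection: ordered residue keys and centered CA coordinates."""

    residue_keys: list[ResidueKey]
    ref_coords: np.ndarray  # (L, 3), centered
    ref_centroid: np.ndarray  # (3,)

    def __len__(self) -> int:
        return len(self.residue_keys)


@dataclass
class CoordinateBatch:
    """CA coordinates of N structures at the reference's L residue slots.

    ``mask[i, j] == 1`` iff structure i has a CA for ``residue_keys[j]``; rows
    with mask 0 are filled with the zero vector (downstream code must not
    depend on the fill value).
    """

    coords: np.ndarray  # (N, L, 3)
    mask: np.ndarray  # (N, L), float 0/1
    names: list[str]

    def __len__(self) -> int:
        return len(self.names)


# --- selections ---------------------------------------------------------------


@dataclass(frozen=True)
class SelectionSpec:
    """Chain/residue-range filter, parsed from strings like ``"A:10-120"``.

    Grammar: comma-separated tokens.  A token is either a chain id (``"A"``,
    selecting the whole chain), a chain with ranges (``"A:10-120"``), or a bare
    range (``"30-40"``) which applies to the most recently named chain, or to
    all chains if none was named.  ``None``/empty selects everything.
    """

    # each term: (chain_id or None, lo or None, hi or None)
    terms: tuple[tuple[str | None, int | None, int | None], ...] = ()

    @classmethod
    def parse(cls, text: str | None) -> "SelectionSpec":
        if text is None or not text.strip():
            return cls(())
        terms: list[tuple[str | None, int | None, int | None]] = []
        current_chain: str | None = None
        for token in text.split(","):
            token = token.strip()
            if not token:
                raise ValueError(f"empty token in selection {text!r}")
            if ":" in token:
                chain_part, range_part = token.split(":", 1)
                current_chain = chain_part.strip()
                if not current_chain:
                    raise ValueError(f"missing chain id in selection token {token!r}")
                terms.append((current_chain, *cls._parse_range(range_part, token)))
            elif token[0].isdigit() or token[0] == "-":
                terms.append((current_chain, *cls._parse_range(token, token)))
            else:
                current_chain = token
                terms.append((current_chain, None, None))
        return cls(tuple(terms))

    @staticmethod
    def _parse_range(text: str, token: str) -> tuple[int, int]:
        text = text.strip()
        if "-" in text[1:]:
            split_at = text.index("-", 1)
            lo, hi = int(text[:split_at]), int(text[split_at + 1 :])
        else:
            lo = hi = int(text)
        if hi < lo:
            raise ValueError(f"inverted residue range in selection token {token!r}")
        return lo, hi

    @property
    def is_all(self) -> bool:
        return not self.terms

    def matches(self, chain_id: str, res_seq: int) -> bool:
        if self.is_all:
            return True
        for chain, lo, hi in self.terms:
            if chain is not None and chain != chain_id:
                continue
            if lo is not None and not (lo <= res_seq <= hi):
                continue
            return True
        return False

    def __str__(self) -> str:
        if self.is_all:
            return "all"
        parts = []
        for chain, lo, hi in self.terms:
            c = chain if chain is not None else "*"
            parts.append(c if lo is None else f"{c}:{lo}-{hi}")
        return ",".join(parts)


# --- parsing ------------------------------------------------------------------


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError as exc:
        raise PDBFormatError(f"malformed {what} field {text!r} at line {lineno}") from exc
    if not math.isfinite(value):
        raise PDBFormatError(f"non-finite {what} at line {lineno}")
    return value


def parse_pdb_text(text: str, source_path: str = "<string>") -> StructureRecord:
    """Parse PDB-format text; see :func:`parse_pdb`."""
    lines: list[str] = []
    atoms: list[AtomRecord] = []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6]
        if record.startswith("MODEL"):
            if in_model:  # only the first MODEL of an ensemble file is read
                break
            in_model = True
        elif record.startswith("ENDMDL"):
            if in_model:
                lines.append(line)
                break
        lines.append(line)
        if record not in ("ATOM  ", "HETATM"):
            continue
        # PDB v3.3 fixed columns (0-based slices)
        x = _parse_float(line[30:38], "x coordinate", lineno)
        y = _parse_float(line[38:46], "y coordinate", lineno)
        z = _parse_float(line[46:54], "z coordinate", lineno)
        occ_text = line[54:60].strip()
        bfac_text = line[60:66].strip()
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = 0  # hybrid-36 or overflowed serials are carried via raw_line
        try:
            res_seq = int(line[22:26])
        except ValueError as exc:
            raise PDBFormatError(
                f"malformed residue number {line[22:26]!r} at line {lineno}"
            ) from exc
        atoms.append(
            AtomRecord(
                record_kind=record.strip(),
                serial=serial,
                atom_name=line[12:16].strip(),
                alt_loc=line[16:17],
                res_name=line[17:20].strip(),
                chain_id=line[21:22],
                res_seq=res_seq,
                i_code=line[26:27],
                x=x,
                y=y,
                z=z,
                occupancy=float(occ_text) if occ_text else 1.0,
                b_factor=float(bfac_text) if bfac_text else 0.0,
                element=line[76:78].strip(),
                raw_line=line,
                line_index=len(lines) - 1,
            )
        )
    if not any(a.record_kind == "ATOM" for a in atoms):
        raise PDBFormatError(f"no ATOM records in {source_path}")
    return StructureRecord(
        source_path=source_path,
        lines=lines,
        atoms=atoms,
        ca_index=_build_ca_index(atoms),
    )


def _build_ca_index(atoms: Sequence[AtomRecord]) -> dict[ResidueKey, int]:
    # Alt-loc rule: highest occupancy wins; ties go to the earliest line.
    index: dict[ResidueKey, int] = {}
    for i, atom in enumerate(atoms):
        if atom.record_kind != "ATOM" or atom.atom_name != "CA":
            continue
        key = (atom.chain_id, atom.res_seq, atom.i_code)
        if key in index and atoms[index[key]].occupancy >= atom.occupancy:
            continue
        index[key] = i
    # re-insert in file order of the chosen atoms so iteration order is stable
    return dict(sorted(index.items(), key=lambda kv: kv[1]))


def parse_pdb(path: str | os.PathLike) -> StructureRecord:
    """Read one PDB file into a :class:`StructureRecord`.

    Only the first MODEL of a multi-model file is parsed.  Raises
    :class:`PDBFormatError` if the file holds no ATOM records or has malformed
    coordinate/residue-number columns, and ``OSError`` if it cannot be read.
    """
    path = os.fspath(path)
    try:
        with open(path, "r") as handle:
            text = handle.read()
    except OSError as exc:
        raise OSError(f"cannot read PDB file {path}: {exc}") from exc
    return parse_pdb_text(text, source_path=path)


# --- reference frame & batching ----------------------------------------------


def build_reference_frame(ref: StructureRecord, sel: SelectionSpec | None = None) -> ReferenceFrame:
    """Extract the reference's selected CA residues, centered on their centroid.

    ``residue_keys`` keep reference file order; ``ref_coords`` rows correspond
    1:1 and have the centroid subtracted.
    """
    if sel is None:
        sel = SelectionSpec()
    keys = [k for k in ref.ca_index if sel.matches(k[0], k[1])]
    if not keys:
        raise ValueError(f"selection {sel} matches no residues in {ref.source_path}")
    if len(keys) < 3:
        raise ValueError(
            f"selection too small: {len(keys)} residue(s) selected, need at least 3"
        )
    coords = np.array(
        [[ref.atoms[ref.ca_index[k]].x, ref.atoms[ref.ca_index[k]].y, ref.atoms[ref.ca_index[k]].z] for k in keys],
        dtype=np.float64,
    )
    centroid = coords.mean(axis=0)
    return ReferenceFrame(residue_keys=keys, ref_coords=coords - centroid, ref_centroid=centroid)


def structure_row(struct: StructureRecord, frame: ReferenceFrame) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinates of ``struct`` at the frame's residue slots, plus the mask row.

    Residues of the structure absent from the frame (insertions relative to the
    reference) are ignored; frame residues absent from the structure
    (deletions) get mask 0 and a zero coordinate row.
    """
    L = len(frame)
    coords = np.zeros((L, 3), dtype=np.float64)
    mask = np.zeros(L, dtype=np.float64)
    for j, key in enumerate(frame.residue_keys):
        idx = struct.ca_index.get(key)
        if idx is None:
            continue
        atom = struct.atoms[idx]
        coords[j] = (atom.x, atom.y, atom.z)
        mask[j] = 1.0
    return coords, mask


def load_batch(
    paths: Sequence[str | os.PathLike],
    frame: ReferenceFrame,
    batch_size: int = 50_000,
    skipped: list[tuple[str, str]] | None = None,
) -> Iterator[CoordinateBatch]:
    """Stream :class:`CoordinateBatch` objects of at most ``batch_size`` structures.

    Files that fail to parse, or that share fewer than 3 residues with the
    reference selection, are skipped with a logged warning (and appended to
    ``skipped`` as ``(path, reason)`` if given) rather than aborting the run.
    Raises ``ValueError`` if every path fails.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    coords_buf: list[np.ndarray] = []
    mask_buf: list[np.ndarray] = []
    names_buf: list[str] = []
    n_ok = 0

    def flush() -> CoordinateBatch:
        batch = CoordinateBatch(
            coords=np.stack(coords_buf), mask=np.stack(mask_buf), names=list(names_buf)
        )
        coords_buf.clear()
        mask_buf.clear()
        names_buf.clear()
        return batch

    n_paths = 0
    for path in paths:
        n_paths += 1
        path = os.fspath(path)
        try:
            struct = parse_pdb(path)
        except (PDBFormatError, OSError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            if skipped is not None:
                skipped.append((path, str(exc)))
            continue
        coords, mask = structure_row(struct, frame)
        if mask.sum() < 3:
            reason = f"only {int(mask.sum())} residue(s) in common with the reference selection"
            logger.warning("skipping %s: %s", path, reason)
            if skipped is not None:
                skipped.append((path, reason))
            continue
        coords_buf.append(coords)
        mask_buf.append(mask)
        names_buf.append(path)
        n_ok += 1
        if len(names_buf) == batch_size:
            yield flush()
    if names_buf:
        yield flush()
    if n_paths == 0:
        raise ValueError("no input paths given")
    if n_ok == 0:
        raise ValueError("all input files failed to load")


# --- writing ------------------------------------------------------------------


def format_atom_line(line: str, x: float, y: float, z: float) -> str:
    """Rewrite the coordinate columns (31-54) of an ATOM/HETATM line, %8.3f each."""
    if len(line) < 54:
        line = line.ljust(54)
    for v in (x, y, z):
        if not (-1000.0 < v < 10000.0):
            raise ValueError(f"coordinate {v:.3f} does not fit PDB fixed columns")
    return f"{line[:30]}{x:8.3f}{y:8.3f}{z:8.3f}{line[54:]}"


def write_transformed(struct: StructureRecord, transform, out_path: str | os.PathLike) -> None:
    """Apply a rigid transform to every atom and write a PDB file.

    Each coordinate becomes ``R(q) @ (p - model_centroid) + ref_centroid``;
    all non-coordinate columns and non-atom lines are copied byte-identically.
    HETATM and non-CA atoms are transformed like any other atom.
    """
    from .core import quaternion_matrix  # local import to avoid a cycle

    q = np.asarray(transform.quaternion, dtype=np.float64)
    norm = float(np.linalg.norm(q))
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"quaternion norm {norm:.8f} deviates from 1 by more than 1e-6")
    rot = quaternion_matrix(q[None])[0]
    model_centroid = np.asarray(transform.model_centroid, dtype=np.float64)
    ref_centroid = np.asarray(transform.ref_centroid, dtype=np.float64)

    coords = struct.coords
    new_coords = (coords - model_centroid) @ rot.T + ref_centroid

    out_lines = list(struct.lines)
    for atom, (x, y, z) in zip(struct.atoms, new_coords):
        out_lines[atom.line_index] = format_atom_line(atom.raw_line, x, y, z)
    try:
        with open(out_path, "w") as handle:
            handle.write("\n".join(out_lines))
            handle.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write {os.fspath(out_path)}: {exc}") from exc
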