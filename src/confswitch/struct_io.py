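"""Macromolecular structure I/O, Cα extraction, superposition, and geometry.

Structures are read from PDB or mmCIF via biotite and held in a light
``Structure`` wrapper around a ``biotite.structure.AtomArray``.  Analysis
operations work on ``CalphaModel``, a labeled Cα coordinate set with
per-residue domain annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io import pdb as bio_pdb
from biotite.structure.io import pdbx as bio_pdbx


class StructureParseError(ValueError):
    """File could not be parsed under the named standard."""


class DegenerateGeometryError(ValueError):
    """Superposition input has fewer than 3 usable pairs or is collinear."""


@dataclass
class Structure:
    """Polymer atoms of a macromolecular model.

    Wraps a biotite AtomArray restricted (by default) to polymer atoms.
    ``scalar`` is an optional per-atom channel used for map exports
    (written to the PDB temperature-factor column).
    """

    atoms: bst.AtomArray
    scalar: np.ndarray | None = None

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms.chain_id.tolist()))

    def sequence(self, chain: str) -> list[str]:
        """Residue names (3-letter) for one chain, in order."""
        mask = self.atoms.chain_id == chain
        sub = self.atoms[mask]
        _, idx = np.unique(sub.res_id, return_index=True)
        return [sub.res_name[i] for i in np.sort(idx)]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("non-finite coordinates in structure")
        keys = set()
        for ch, rid, name in zip(
            self.atoms.chain_id, self.atoms.res_id, self.atoms.atom_name
        ):
            k = (ch, int(rid), name)
            if k in keys:
                raise ValueError(f"duplicate atom record {k}")
            keys.add(k)


@dataclass
class CalphaModel:
    """Labeled Cα coordinate set — the substrate of ENM and assembly operations."""

    coords: np.ndarray  # (N, 3) Å
    chain_ids: np.ndarray  # (N,) str
    res_ids: np.ndarray  # (N,) int
    domains: np.ndarray  # (N,) str domain label per residue

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.domains = np.asarray(self.domains, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self) < 2:
            raise ValueError("CalphaModel requires N >= 2 residues")
        for arr in (self.chain_ids, self.res_ids, self.domains):
            if len(arr) != len(self):
                raise ValueError("per-residue arrays must match coords length")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self)

    def domain_mask(self, label: str) -> np.ndarray:
        return self.domains == label

    def copy(self) -> "CalphaModel":
        return CalphaModel(
            self.coords.copy(),
            self.chain_ids.copy(),
            self.res_ids.copy(),
            self.domains.copy(),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CalphaModel":
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out


@dataclass
class Superposition:
    """Least-squares rigid superposition result."""

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_matched: int

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation is improper (det < 0)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class GapReport:
    """Residues that were selected but lack a Cα atom."""

    missing: list[tuple[str, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.missing)

    def to_text(self) -> str:
        lines = ["chain\tres_id"]
        lines += [f"{c}\t{r}" for c, r in self.missing]
        return "\n".join(lines) + "\n"


def read_structure(
    path: str | Path, fmt: str | None = None, include_hetero: bool = False
) -> Structure:
    """Read a PDB or mmCIF file into a Structure of polymer atoms.

    ``fmt`` is "pdb" or "cif"/"mmcif"; inferred from the suffix if omitted.
    Heteroatoms and waters are excluded unless ``include_hetero``.
    Keeps the highest-occupancy altloc conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            f = bio_pdb.PDBFile.read(str(path))
            atoms = f.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])
        elif fmt in {"cif", "mmcif"}:
            f = bio_pdbx.CIFFile.read(str(path))
            atoms = bio_pdbx.get_structure(f, model=1, altloc="occupancy")
        else:
            raise ValueError(f"unknown structure format {fmt!r}")
    except ValueError:
        raise
    except Exception as exc:  # biotite raises various parse exceptions
        raise StructureParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not include_hetero:
        atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise StructureParseError(f"{path}: no polymer atoms found")
    return Structure(atoms=atoms)


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as PDB; the scalar channel fills the B-factor column."""
    path = Path(path)
    atoms = s.atoms.copy()
    b = np.zeros(atoms.array_length())
    if s.scalar is not None:
        b = np.asarray(s.scalar, dtype=float)
    atoms.set_annotation("b_factor", b)
    f = bio_pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def extract_calpha(
    s: Structure,
    chains: Sequence[str] | None = None,
    domain_map: Mapping[tuple[int, int], str] | None = None,
    default_label: str = "body",
) -> tuple[CalphaModel, GapReport]:
    """Extract the Cα trace of the selected chains with domain labels.

    ``domain_map`` maps inclusive residue-number ranges ``(start, end)`` to
    labels; unmapped residues get ``default_label``.  Residues lacking a Cα
    atom go to the gap report; ordering is preserved.
    """
    atoms = s.atoms
    if chains is None:
        chains = list(dict.fromkeys(atoms.chain_id.tolist()))
    if len(chains) == 0:
        raise ValueError("empty chain selection")
    sel = np.isin(atoms.chain_id, list(chains))
    if not sel.any():
        raise ValueError(f"selection {chains!r} matches no atoms")
    sub = atoms[sel]

    coords, chain_ids, res_ids = [], [], []
    gaps = GapReport()
    for ch in chains:
        chmask = sub.chain_id == ch
        chsub = sub[chmask]
        if chsub.array_length() == 0:
            continue
        seen: dict[int, int] = {}
        order: list[int] = []
        for i in range(chsub.array_length()):
            rid = int(chsub.res_id[i])
            if rid not in seen:
                seen[rid] = -1
                order.append(rid)
            if chsub.atom_name[i] == "CA" and seen[rid] == -1:
                seen[rid] = i
        for rid in order:
            i = seen[rid]
            if i == -1:
                gaps.missing.append((ch, rid))
            else:
                coords.append(chsub.coord[i])
                chain_ids.append(ch)
                res_ids.append(rid)
    if not coords:
        raise ValueError("no Cα atoms in selection")

    labels = [default_label] * len(res_ids)
    if domain_map:
        for i, rid in enumerate(res_ids):
            for (start, end), lab in domain_map.items():
                if start <= rid <= end:
                    labels[i] = lab
                    break
    model = CalphaModel(
        np.array(coords), np.array(chain_ids, dtype=object),
        np.array(res_ids), np.array(labels, dtype=object),
    )
    return model, gaps


def kabsch_superpose(
    mobile: CalphaModel,
    target: CalphaModel,
    pairing: Sequence[tuple[int, int]] | None = None,
) -> Superposition:
    """Optimal least-squares rigid superposition of mobile onto target.

    ``pairing`` is a sequence of (mobile index, target index) pairs; by
    default residues are paired by identical residue number present in both
    models (the common-construct convention for comparing related crystal
    structures).
    """
    if pairing is None:
        tgt_index = {int(r): i for i, r in enumerate(target.res_ids)}
        pairing = [
            (i, tgt_index[int(r)])
            for i, r in enumerate(mobile.res_ids)
            if int(r) in tgt_index
        ]
    pairing = list(pairing)
    if len(pairing) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 paired residues, got {len(pairing)}"
        )
    P = mobile.coords[[i for i, _ in pairing]]
    Q = target.coords[[j for _, j in pairing]]
    # collinearity check on either set
    for X in (P, Q):
        c = X - X.mean(axis=0)
        if np.linalg.matrix_rank(c, tol=1e-8) < 2:
            raise DegenerateGeometryError("paired points are collinear")

    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(pairing)))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_matched=len(pairing))


def min_interdomain_distance(m: CalphaModel, label_a: str, label_b: str) -> float:
    """Minimum Cα–Cα distance between two labeled domains (symmetric)."""
    a = m.coords[m.domain_mask(label_a)]
    b = m.coords[m.domain_mask(label_b)]
    if len(a) == 0:
        raise ValueError(f"domain label {label_a!r} not present")
    if len(b) == 0:
        raise ValueError(f"domain label {label_b!r} not present")
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def write_residue_map(
    s: Structure,
    values: Mapping[tuple[str, int], float],
    path: str | Path,
    sentinel: float = -1.0,
) -> None:
    """Write a PDB whose temperature-factor column carries per-residue scalars.

    ``values`` is keyed by (chain id, residue number); unmapped residues get
    ``sentinel``.  Values outside the PDB B-factor column range [-99.99,
    999.99] are clamped with a warning.
    """
    atoms = s.atoms
    b = np.full(atoms.array_length(), sentinel, dtype=float)
    for i in range(atoms.array_length()):
        key = (atoms.chain_id[i], int(atoms.res_id[i]))
        if key in values:
            b[i] = float(values[key])
    lo, hi = -99.99, 999.99
    if (b < lo).any() or (b > hi).any():
        warnings.warn("residue-map values clamped to B-factor column range")
        b = np.clip(b, lo, hi)
    write_structure(Structure(atoms=atoms, scalar=b), path)


def read_residue_map(path: str | Path) -> dict[tuple[str, int], float]:
    """Read back a per-residue scalar map from the B-factor column."""
    f = bio_pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1, extra_fields=["b_factor"])
    out: dict[tuple[str, int], float] = {}
    for i in range(atoms.array_length()):
        out[(atoms.chain_id[i], int(atoms.res_id[i]))] = float(atoms.b_factor[i])
    return out


def calpha_to_structure(m: CalphaModel, res_name: str = "ALA") -> Structure:
    """Build a Cα-only Structure from a CalphaModel (for PDB export)."""
    n = len(m)
    atoms = bst.AtomArray(n)
    atoms.coord = m.coords.astype(np.float32)
    atoms.chain_id = np.array([str(c) for c in m.chain_ids])
    atoms.res_id = m.res_ids.copy()
    atoms.res_name = np.array([res_name] * n)
    atoms.atom_name = np.array(["CA"] * n)
    atoms.element = np.array(["C"] * n)
    atoms.hetero = np.zeros(n, dtype=bool)
    return Structure(atoms=atoms)


def write_multimodel_pdb(models: Sequence[CalphaModel], path: str | Path) -> None:
    """Write a Cα trajectory as a multi-model PDB."""
    stack_arrays = []
    for m in models:
        stack_arrays.append(calpha_to_structure(m).atoms)
    stack = bst.stack(stack_arrays)
    f = bio_pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def write_assembly_pdb(chains: Sequence[CalphaModel], path: str | Path) -> None:
    """Write a multi-chain Cα assembly (chains A, B, ...) as one PDB model."""
    arrays = [calpha_to_structure(c).atoms for c in chains]
    merged = arrays[0]
    for arr in arrays[1:]:
        merged = merged + arr
    f = bio_pdb.PDBFile()
    f.set_structure(merged)
    f.write(str(path))


def fetch_pdb(pdb_id: str, directory: str | Path, timeout: float = 30.0) -> Path:
    """Opt-in helper: download a PDB entry (requires network access)."""
    from urllib.request import urlopen

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dest = directory / f"{pdb_id.lower()}.pdb"
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urlopen(url, timeout=timeout) as resp:
        dest.write_bytes(resp.read())
    return dest
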