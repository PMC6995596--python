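"""Atomic models, rigid transforms, and FXIII-A domain annotation.

Coordinates are stored in Angstrom throughout; conversion to nm happens only
at the AFM-topograph boundary (see :mod:`tetra.afmdock`). Residue numbering is
1-based inclusive, matching the conventions of PDB files and of the FXIII
literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation


class StructureError(ValueError):
    """Raised for malformed or inconsistent atomic models."""


@dataclass(frozen=True)
class Atom:
    """A single atom record."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    position: np.ndarray  # (3,) Angstrom

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"non-finite or malformed position: {pos!r}")
        if self.residue_index < 1:
            raise StructureError(f"residue index must be >= 1, got {self.residue_index}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R @ x + t.

    The translation unit follows the coordinates it is applied to (Angstrom
    for atomic models, nm for topograph frames).
    """

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float)
        trans = np.asarray(self.translation, dtype=float)
        if rot.shape != (3, 3) or trans.shape != (3,):
            raise StructureError("rotation must be 3x3 and translation length 3")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
            raise StructureError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(rot) - 1.0) > 1e-6:
            raise StructureError("rotation determinant must be +1 (proper rotation)")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", trans)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_z(cls, angle_deg: float, translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        rot = Rotation.from_euler("z", angle_deg, degrees=True).as_matrix()
        return cls(rot, np.asarray(translation, dtype=float))

    @classmethod
    def from_euler(cls, angles_deg: Sequence[float], translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        rot = Rotation.from_euler("zyz", angles_deg, degrees=True).as_matrix()
        return cls(rot, np.asarray(translation, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class AtomicModel:
    """Ordered atom collection backed by parallel numpy arrays."""

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray  # (n, 3) Angstrom
    title: str = ""

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype="U8")
        self.res_ids = np.asarray(self.res_ids, dtype=np.int64)
        self.res_names = np.asarray(self.res_names, dtype="U8")
        self.atom_names = np.asarray(self.atom_names, dtype="U8")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chain_ids)
        if not (len(self.res_ids) == len(self.res_names) == len(self.atom_names) == n and self.coords.shape == (n, 3)):
            raise StructureError("field arrays have inconsistent lengths")
        if n and not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if n and self.res_ids.min() < 1:
            raise StructureError("residue indices must be >= 1")
        triples = list(zip(self.chain_ids, self.res_ids, self.atom_names))
        if len(set(triples)) != n:
            raise StructureError("duplicate (chain, residue, atom) triple")

    # -- basic queries ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.chain_ids)

    def __len__(self) -> int:
        return self.n_atoms

    def atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                str(self.chain_ids[i]),
                int(self.res_ids[i]),
                str(self.res_names[i]),
                str(self.atom_names[i]),
                self.coords[i],
            )

    def _require_nonempty(self) -> None:
        if self.n_atoms == 0:
            raise StructureError("operation requires a non-empty model")

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            self.chain_ids[mask],
            self.res_ids[mask],
            self.res_names[mask],
            self.atom_names[mask],
            self.coords[mask],
            self.title,
        )

    def find_atom(self, chain_id: str, residue_index: int, atom_name: str) -> int | None:
        """Index of the matching atom, or None."""
        mask = (
            (self.chain_ids == chain_id)
            & (self.res_ids == residue_index)
            & (self.atom_names == atom_name)
        )
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None

    def residue_name(self, chain_id: str, residue_index: int) -> str | None:
        mask = (self.chain_ids == chain_id) & (self.res_ids == residue_index)
        idx = np.flatnonzero(mask)
        return str(self.res_names[idx[0]]) if idx.size else None

    def transformed(self, transform: RigidTransform) -> "AtomicModel":
        self._require_nonempty()
        return replace(self, coords=transform.apply(self.coords))

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            self.chain_ids.copy(),
            self.res_ids.copy(),
            self.res_names.copy(),
            self.atom_names.copy(),
            self.coords.copy(),
            self.title,
        )


# -- PDB I/O ---------------------------------------------------------------


def read_pdb(path: str) -> AtomicModel:
    """Read the first model of a PDB file into an :class:`AtomicModel`.

    Alternate locations are resolved by highest occupancy (first on tie, the
    biotite default); insertion codes are rejected because every numbering
    convention downstream assumes plain integer residue indices.
    """
    pdb = PDBFile.read(path)
    try:
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises on files without coordinates
        raise StructureError(f"no parseable ATOM/HETATM records in {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise StructureError(f"no ATOM/HETATM records in {path}")
    if np.any(arr.ins_code != ""):
        raise StructureError("insertion codes are not supported; renumber the input")
    return AtomicModel(
        arr.chain_id.astype("U8"),
        arr.res_id.astype(np.int64),
        arr.res_name.astype("U8"),
        arr.atom_name.astype("U8"),
        arr.coord.astype(float),
        title="",
    )


_ELEMENT_GUESS = {"C": "C", "N": "N", "O": "O", "S": "S", "P": "P", "H": "H"}


def write_pdb(model: AtomicModel, path: str) -> None:
    """Write the model as a fixed-width PDB file (coordinates to 3 decimals)."""
    model._require_nonempty()
    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = model.coords.astype(np.float32)
    arr.chain_id = model.chain_ids.astype("U4")
    arr.res_id = model.res_ids
    arr.res_name = model.res_names.astype("U5")
    arr.atom_name = model.atom_names.astype("U6")
    arr.hetero = np.zeros(n, dtype=bool)
    elements = [_ELEMENT_GUESS.get(name.lstrip("0123456789")[:1], "C") for name in model.atom_names]
    arr.element = np.array(elements, dtype="U2")
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)


# -- domain architecture ----------------------------------------------------


@dataclass(frozen=True)
class DomainRange:
    name: str
    chain_id: str
    start: int
    end: int  # inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise StructureError(f"domain {self.name}: start {self.start} > end {self.end}")


@dataclass
class DomainMap:
    """Named, non-overlapping residue ranges per chain."""

    entries: list[DomainRange] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chain: dict[str, list[DomainRange]] = {}
        for e in self.entries:
            by_chain.setdefault(e.chain_id, []).append(e)
        for chain, ranges in by_chain.items():
            ordered = sorted(ranges, key=lambda r: r.start)
            for a, b in zip(ordered, ordered[1:]):
                if b.start <= a.end:
                    raise StructureError(
                        f"overlapping domains {a.name}/{b.name} on chain {chain}"
                    )

    def domain_of(self, chain_id: str, residue_index: int) -> str:
        for e in self.entries:
            if e.chain_id == chain_id and e.start <= residue_index <= e.end:
                return e.name
        return "unassigned"

    def domain_of_residue(self, residue_index: int) -> str:
        """Chain-agnostic lookup (first matching range in entry order)."""
        for e in self.entries:
            if e.start <= residue_index <= e.end:
                return e.name
        return "unassigned"


#: FXIII-A architecture: activation peptide then four folded domains.
FXIII_A_DOMAINS: tuple[tuple[str, int, int], ...] = (
    ("activation peptide", 1, 37),
    ("beta-sandwich", 38, 183),
    ("catalytic core", 184, 515),
    ("beta-barrel-1", 516, 627),
    ("beta-barrel-2", 628, 731),
)


def fxiii_a_domains(chain_ids: Sequence[str] = ("A",)) -> DomainMap:
    """Domain map of the catalytic FXIII-A subunit.

    The subunit comprises the activation peptide (residues 1-37) followed by
    the beta-sandwich (38-183), catalytic core (184-515), beta-barrel-1
    (516-627) and beta-barrel-2 (628-731).
    """
    entries = [
        DomainRange(name, chain, start, end)
        for chain in chain_ids
        for name, start, end in FXIII_A_DOMAINS
    ]
    return DomainMap(entries)


def uniform_domain_map(
    chain_ids: Sequence[str],
    n_domains: int,
    domain_length: int,
    prefix: str = "S",
    start: int = 1,
) -> DomainMap:
    """Equal-length consecutive domains (e.g. ten ~60-residue sushi modules).

    The carrier FXIII-B subunit has no published residue boundaries for its
    sushi domains, so maps like this are supplied by the user rather than
    hard-coded.
    """
    entries = []
    for chain in chain_ids:
        pos = start
        for k in range(1, n_domains + 1):
            entries.append(DomainRange(f"{prefix}{k}", chain, pos, pos + domain_length - 1))
            pos += domain_length
    return DomainMap(entries)


# -- renumbering ------------------------------------------------------------


def renumber_continuum(
    model: AtomicModel, chain_order: Sequence[str]
) -> tuple[AtomicModel, dict[tuple[str, int], int]]:
    """Merge chains into one continuously numbered chain.

    Chain k's residue indices are offset by the cumulative maximum residue
    index of the preceding chains, so two 731-residue monomers become one
    chain numbered 1-1462. Returns the renumbered single-chain model and the
    bijection (old chain, old index) -> new index.
    """
    model._require_nonempty()
    present = set(model.chains())
    for c in chain_order:
        if c not in present:
            raise StructureError(f"chain {c!r} not present in model")
    new_chain = str(chain_order[0])
    new_res_ids = np.empty_like(model.res_ids)
    new_chain_ids = np.full(model.n_atoms, new_chain, dtype="U8")
    index_map: dict[tuple[str, int], int] = {}
    offset = 0
    covered = np.zeros(model.n_atoms, dtype=bool)
    for chain in chain_order:
        mask = model.chain_ids == chain
        covered |= mask
        old = model.res_ids[mask]
        new_res_ids[mask] = old + offset
        for o in np.unique(old):
            index_map[(str(chain), int(o))] = int(o + offset)
        offset += int(old.max())
    if not covered.all():
        extra = sorted(set(model.chain_ids[~covered]))
        raise StructureError(f"chain_order must cover all chains; missing {extra}")
    out = AtomicModel(
        new_chain_ids, new_res_ids, model.res_names.copy(), model.atom_names.copy(),
        model.coords.copy(), model.title,
    )
    return out, index_map


def invert_index_map(index_map: Mapping[tuple[str, int], int]) -> dict[int, tuple[str, int]]:
    inv = {v: k for k, v in index_map.items()}
    if len(inv) != len(index_map):
        raise StructureError("index map is not a bijection")
    return inv


# -- RMSD -------------------------------------------------------------------


def _ca_selection(model: AtomicModel) -> tuple[np.ndarray, list[tuple[str, int]]]:
    mask = model.atom_names == "CA"
    keys = [(str(c), int(r)) for c, r in zip(model.chain_ids[mask], model.res_ids[mask])]
    return model.coords[mask], keys


def ca_rmsd(model_a: AtomicModel, model_b: AtomicModel, superpose: bool = False) -> float:
    """Root-mean-square C-alpha deviation between two models, in Angstrom.

    Without superposition the deviation is taken in the shared frame (the
    convention for comparing docked poses); with ``superpose=True`` the
    optimal (Kabsch) rotation/translation is removed first.
    """
    xa, keys_a = _ca_selection(model_a)
    xb, keys_b = _ca_selection(model_b)
    if len(xa) == 0:
        raise StructureError("no C-alpha atoms to compare")
    if keys_a != keys_b:
        raise StructureError("C-alpha atom sets differ between models")
    if superpose:
        ca = xa - xa.mean(axis=0)
        cb = xb - xb.mean(axis=0)
        rot, _ = Rotation.align_vectors(ca, cb)
        cb = rot.apply(cb)
        diff = ca - cb
    else:
        diff = xa - xb
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
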