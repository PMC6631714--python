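"""Domain types for sites, ligands and docked poses.

All coordinates live in a single fixed "site frame": the rigid protein site
defines the reference system and docked poses are assumed pre-aligned to it,
so RMSD and contact geometry never require superposition.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii (Å); 1.2 Å for H.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "He": 1.40,
    "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "Ne": 1.54,
    "Na": 2.27, "Mg": 1.73, "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75,
    "K": 2.75, "Ca": 2.31, "Zn": 1.39, "Se": 1.90, "Br": 1.85, "I": 1.98,
}

SUPPORTED_ELEMENTS = frozenset(BONDI_RADII)

#: approximate single-bond covalent radii (Å), used only to infer H attachment
#: when a structure carries no explicit bond table.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84, "Se": 1.20,
    "Si": 1.11, "Na": 1.66, "K": 2.03, "Mg": 1.41, "Ca": 1.76, "Zn": 1.22,
}


@dataclass
class Atom:
    """One atom with the properties the contact fingerprint consumes.

    ``is_hbd`` is carried by the donor *hydrogen* (an H bonded to N/O/S);
    ``is_hba`` by N/O acceptors of non-positive formal charge.
    """

    index: int
    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    vdw_radius: float | None = None
    is_hbd: bool = False
    is_hba: bool = False
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.index}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: non-finite coordinates")
        el = self.element.capitalize() if len(self.element) <= 2 else self.element
        if el not in SUPPORTED_ELEMENTS:
            raise ValueError(f"atom {self.index}: unsupported element {self.element!r}")
        self.element = el
        if self.vdw_radius is None:
            self.vdw_radius = BONDI_RADII[el]
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.index}: vdw_radius must be > 0")


@dataclass
class SiteModel:
    """A rigid, typed protein site.

    ``key_atom_indices`` is the ordered list of solvent-exposed wall atoms
    anchoring the contact-fingerprint slots; its order is frozen once set.
    """

    atoms: list[Atom]
    key_atom_indices: tuple[int, ...] = ()
    hot_spots: tuple[int, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.key_atom_indices = tuple(self.key_atom_indices)
        self.hot_spots = tuple(self.hot_spots)
        n = len(self.atoms)
        if len(set(self.key_atom_indices)) != len(self.key_atom_indices):
            raise ValueError("key_atom_indices must be unique")
        for i in self.key_atom_indices:
            if not 0 <= i < n:
                raise ValueError(f"key atom index {i} out of range")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def with_key_atoms(self, indices) -> "SiteModel":
        if self.key_atom_indices and tuple(indices) != self.key_atom_indices:
            raise ValueError("key_atom_indices already set; order is frozen")
        return replace(self, key_atom_indices=tuple(indices))


@dataclass
class Ligand:
    """A ligand: typed atoms plus a bond graph (i, j, order)."""

    ligand_id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"ligand {self.ligand_id}: bond ({i},{j}) out of range")
        if n and self.bonds is not None and not self._connected():
            warnings.warn(f"ligand {self.ligand_id}: bond graph is disconnected")

    def _connected(self) -> bool:
        n = len(self.atoms)
        if n <= 1:
            return True
        adj = {i: set() for i in range(n)}
        for i, j, _ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        seen, stack = {0}, [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == n

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.element != "H" for a in self.atoms])

    def neighbor_map(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj


@dataclass
class Pose:
    """One conformer of a ligand in the site frame."""

    ligand_id: str
    conformer_id: str
    coords: np.ndarray
    energy: float
    run_id: str = "A"
    rmsd_to_native: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("pose coords must be (n_atoms, 3)")
        if not np.isfinite(self.energy):
            raise ValueError(f"pose {self.conformer_id}: energy not finite")


def infer_h_attachments(atoms: list[Atom], bonds=None) -> dict[int, int]:
    """Map each hydrogen index to its bonded heavy atom.

    Uses the explicit bond table when given, otherwise a covalent-distance
    rule (|d| < r_cov(i)+r_cov(j)+0.4 Å, nearest heavy atom).
    """
    attach: dict[int, int] = {}
    h_idx = [a.index for a in atoms if a.element == "H"]
    if bonds:
        for i, j, _ in bonds:
            ei, ej = atoms[i].element, atoms[j].element
            if ei == "H" and ej != "H":
                attach[i] = j
            elif ej == "H" and ei != "H":
                attach[j] = i
        return attach
    heavy = [a for a in atoms if a.element != "H"]
    if not heavy:
        return attach
    hcoords = np.array([a.coords for a in heavy])
    for hi in h_idx:
        d = np.linalg.norm(hcoords - atoms[hi].coords, axis=1)
        k = int(np.argmin(d))
        r_max = _COVALENT_RADII["H"] + _COVALENT_RADII.get(heavy[k].element, 1.0) + 0.4
        if d[k] <= r_max:
            attach[hi] = heavy[k].index
    return attach


def assign_hbond_roles(atoms: list[Atom], bonds=None) -> None:
    """Assign donor/acceptor flags in place.

    Donor: an H covalently bound to N, O or S (the H carries the flag).
    Acceptor: any N or O with formal charge <= 0, except an N that itself
    binds an H (amide-like / protonated aromatic N).
    """
    attach = infer_h_attachments(atoms, bonds)
    n_with_h = {j for j in attach.values() if atoms[j].element == "N"}
    for a in atoms:
        a.is_hbd = a.element == "H" and a.index in attach and atoms[attach[a.index]].element in ("N", "O", "S")
        a.is_hba = (
            a.element in ("N", "O")
            and a.formal_charge <= 0
            and not (a.element == "N" and a.index in n_with_h)
        )
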