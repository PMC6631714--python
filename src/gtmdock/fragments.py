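"""Ligand circular-fragment counts and Hybrid (CF + fragment) vectors.

Circular fragments are rooted, radius-bounded environments on the
hydrogen-suppressed bond graph — the Morgan-fingerprint-like counted
descriptor family.  Each fragment is named by a radius-tagged canonical
rooted-subtree string (children sorted lexicographically), e.g. ethanol
C-C-O at radius 1 yields ``r1:C(C)``, ``r1:C(C,O)`` and ``r1:O(C)``.
Atoms may be labeled by chemical element, element plus a formal-charge
flag, or a pharmacophore type.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .contact_fp import CFVector
from .structures import Ligand

logger = logging.getLogger(__name__)

ATOM_LABEL_MODES = ("element", "element_charge", "pharmacophore")


@dataclass(frozen=True)
class FragmentScheme:
    min_sphere: int = 1
    max_sphere: int = 2
    atom_label: str = "element_charge"
    id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.min_sphere <= self.max_sphere <= 4:
            raise ValueError("require 0 <= min_sphere <= max_sphere <= 4")
        if self.atom_label not in ATOM_LABEL_MODES:
            raise ValueError(f"atom_label must be one of {ATOM_LABEL_MODES}")
        if not self.id:
            object.__setattr__(
                self, "id", f"circ-{self.atom_label}-{self.min_sphere}-{self.max_sphere}"
            )


def default_scheme_grid() -> list[FragmentScheme]:
    """The configurable pool of candidate schemes for map optimization."""
    return [
        FragmentScheme(lo, hi, lab)
        for lo, hi in ((1, 1), (1, 2), (2, 2), (1, 3))
        for lab in ATOM_LABEL_MODES
    ]


def _atom_label(ligand: Ligand, idx: int, mode: str, donor_heavy: set[int]) -> str:
    a = ligand.atoms[idx]
    if mode == "element":
        return a.element
    if mode == "element_charge":
        if a.formal_charge > 0:
            return a.element + "+"
        if a.formal_charge < 0:
            return a.element + "-"
        return a.element
    # pharmacophore
    if a.formal_charge > 0:
        return "P"
    if a.formal_charge < 0:
        return "N"
    d, acc = idx in donor_heavy, a.is_hba
    if d and acc:
        return "DA"
    if d:
        return "D"
    if acc:
        return "A"
    return "X"


def circular_fragments(ligand: Ligand, scheme: FragmentScheme) -> dict[str, int]:
    """Count canonical circular fragments rooted at every heavy atom.

    For each heavy atom and each radius in [min_sphere, max_sphere] one
    fragment name is emitted; radius >= 1 fragments require at least one
    heavy neighbour (methane has none).  Disconnected ligands are handled
    per component (a warning is logged at construction time).
    """
    adj_all = ligand.neighbor_map()
    heavy = [i for i, a in enumerate(ligand.atoms) if a.element != "H"]
    heavy_set = set(heavy)
    adj = {i: sorted(j for j in adj_all[i] if j in heavy_set) for i in heavy}
    donor_heavy = {
        nb
        for a in ligand.atoms
        if a.element == "H" and a.is_hbd
        for nb in adj_all[a.index]
        if nb in heavy_set
    }
    labels = {i: _atom_label(ligand, i, scheme.atom_label, donor_heavy) for i in heavy}

    def subtree(idx: int, depth: int, parent: int) -> str:
        children = [j for j in adj[idx] if j != parent]
        if depth == 0 or not children:
            return labels[idx]
        parts = sorted(subtree(j, depth - 1, idx) for j in children)
        return labels[idx] + "(" + ",".join(parts) + ")"

    counts: dict[str, int] = {}
    for root in heavy:
        for radius in range(scheme.min_sphere, scheme.max_sphere + 1):
            if radius >= 1 and not adj[root]:
                continue
            name = f"r{radius}:{subtree(root, radius, -1)}"
            counts[name] = counts.get(name, 0) + 1
    return counts


@dataclass
class FragmentVocabulary:
    """Frozen fragment-name -> column mapping fixed before any map fitting."""

    names: tuple[str, ...]
    scheme: FragmentScheme

    @classmethod
    def from_ligands(cls, ligands, scheme: FragmentScheme) -> "FragmentVocabulary":
        seen: set[str] = set()
        for lig in ligands:
            seen.update(circular_fragments(lig, scheme))
        return cls(tuple(sorted(seen)), scheme)

    def __len__(self) -> int:
        return len(self.names)

    def vectorize(self, counts: dict[str, int]) -> tuple[np.ndarray, int]:
        """Counts as a vocabulary-ordered vector; returns (vector, n_oov)."""
        index = {n: i for i, n in enumerate(self.names)}
        vec = np.zeros(len(self.names))
        oov = 0
        for name, c in counts.items():
            if name in index:
                vec[index[name]] = c
            else:
                oov += 1
        if oov:
            logger.warning("dropped %d out-of-vocabulary fragments", oov)
        return vec, oov

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "names": list(self.names),
                    "scheme": {
                        "min_sphere": self.scheme.min_sphere,
                        "max_sphere": self.scheme.max_sphere,
                        "atom_label": self.scheme.atom_label,
                        "id": self.scheme.id,
                    },
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "FragmentVocabulary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(tuple(d["names"]), FragmentScheme(**d["scheme"]))


@dataclass
class HyVector:
    """CF slots first, then fragment slots in vocabulary (lexicographic) order."""

    cf: CFVector
    fragment_part: np.ndarray
    vocabulary: FragmentVocabulary

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.cf.values, self.fragment_part])

    def __len__(self) -> int:
        return len(self.cf.values) + len(self.fragment_part)


def build_hy(cf: CFVector, counts: dict[str, int], vocabulary: FragmentVocabulary) -> HyVector:
    """Concatenate a CF vector with vocabulary-aligned fragment counts.

    Out-of-vocabulary fragments of new ligands are dropped (logged); no
    scaling is applied between the two blocks.
    """
    vec, _ = vocabulary.vectorize(counts)
    return HyVector(cf, vec, vocabulary)
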