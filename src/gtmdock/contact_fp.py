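"""Site-anchored fuzzy Contact Fingerprints (CF).

A pose is described from the site's point of view: for every solvent-exposed
"key" wall atom, every ligand atom receives a sigmoidal association score to
a *direct* contact list (cutoff = sum of van der Waals radii + tolerance) and
to a *long-range* list (direct cutoff + one water radius, capturing putative
water-displacing contacts; it extends the direct list, so long-range scores
are computed over the full long-range cutoff, not the increment).  Each list
yields five channels per key atom:

    n_contacts      sum of association scores
    n_hbd           scores of donor hydrogens among contacts
    n_hba           scores of acceptor atoms among contacts
    sum_charge      score-weighted signed partial charge
    sum_abs_charge  score-weighted absolute partial charge

Slot order is key-atom major, then range (direct, long_range), then channel,
for a vector of length |key atoms| x 2 x 5.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structures import Ligand, Pose, SiteModel

CHANNELS = ("n_contacts", "n_hbd", "n_hba", "sum_charge", "sum_abs_charge")
RANGES = ("direct", "long_range")


@dataclass(frozen=True)
class CFSchema:
    """Fixed slot layout of a CF vector for one prepared site."""

    key_atom_indices: tuple[int, ...]

    @classmethod
    def from_site(cls, site: SiteModel) -> "CFSchema":
        if not site.key_atom_indices:
            raise ValueError("site has no key atoms; run select_key_atoms first")
        return cls(tuple(site.key_atom_indices))

    def __len__(self) -> int:
        return len(self.key_atom_indices) * len(RANGES) * len(CHANNELS)

    def slot_index(self, key_atom: int, rng: str, channel: str) -> int:
        """Flat index of (site atom index, range, channel)."""
        try:
            pos = self.key_atom_indices.index(key_atom)
        except ValueError:
            raise KeyError(
                f"atom {key_atom} is not a key atom; valid: {self.key_atom_indices}"
            ) from None
        if rng not in RANGES:
            raise KeyError(f"unknown range {rng!r}; valid: {RANGES}")
        if channel not in CHANNELS:
            raise KeyError(f"unknown channel {channel!r}; valid: {CHANNELS}")
        return (pos * len(RANGES) + RANGES.index(rng)) * len(CHANNELS) + CHANNELS.index(channel)

    def slot_names(self) -> list[str]:
        return [
            f"a{k}_{r}_{c}"
            for k in self.key_atom_indices
            for r in RANGES
            for c in CHANNELS
        ]


@dataclass
class CFVector:
    values: np.ndarray
    schema: CFSchema
    ligand_id: str = ""
    conformer_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schema),):
            raise ValueError(
                f"CF length {self.values.shape} does not match schema ({len(self.schema)})"
            )


def contact_score(distance, cutoff: float, steepness: float = 5.0):
    """Fuzzy contact association score in (0, 1).

    A sigmoid with its inflexion point at ``cutoff``:
    score = 1 / (1 + exp(steepness * (distance - cutoff))); strictly
    decreasing in distance, -> 1 well inside, -> 0 well outside.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if cutoff <= 0 or steepness <= 0:
        raise ValueError("cutoff and steepness must be > 0")
    # clip the exponent: exp overflows for far-away atoms, score is 0 anyway
    z = np.clip(steepness * (d - cutoff), -500.0, 500.0)
    out = 1.0 / (1.0 + np.exp(z))
    return float(out) if np.isscalar(distance) else out


def compute_cf(
    pose: Pose,
    ligand: Ligand,
    site: SiteModel,
    schema: CFSchema | None = None,
    tolerance: float = 0.5,
    water_radius: float = 1.4,
    steepness: float = 5.0,
) -> CFVector:
    """Contact fingerprint of one pose.

    Direct cutoff per (key atom i, ligand atom j) pair is
    r_vdw(i) + r_vdw(j) + tolerance; long-range adds ``water_radius``.
    Hydrogens participate as ligand contact atoms (donor counting needs them).
    """
    if schema is None:
        schema = CFSchema.from_site(site)
    for k in schema.key_atom_indices:
        if not 0 <= k < len(site.atoms):
            raise ValueError(f"schema key atom {k} not present in site")
    if pose.coords.shape[0] != len(ligand.atoms):
        raise ValueError("pose atom count does not match ligand")

    key_idx = np.array(schema.key_atom_indices, dtype=int)
    site_coords = site.coords[key_idx]
    site_radii = site.vdw_radii[key_idx]
    lig_radii = np.array([a.vdw_radius for a in ligand.atoms])
    q = np.array([a.partial_charge for a in ligand.atoms])
    hbd = np.array([a.is_hbd for a in ligand.atoms], dtype=float)
    hba = np.array([a.is_hba for a in ligand.atoms], dtype=float)

    dist = cdist(site_coords, pose.coords)  # (n_key, n_lig)
    cut_direct = site_radii[:, None] + lig_radii[None, :] + tolerance

    n_key = len(key_idx)
    vec = np.empty((n_key, len(RANGES), len(CHANNELS)))
    for ri, extra in enumerate((0.0, water_radius)):
        z = np.clip(steepness * (dist - (cut_direct + extra)), -500.0, 500.0)
        s = 1.0 / (1.0 + np.exp(z))
        vec[:, ri, 0] = s.sum(axis=1)
        vec[:, ri, 1] = s @ hbd
        vec[:, ri, 2] = s @ hba
        vec[:, ri, 3] = s @ q
        vec[:, ri, 4] = s @ np.abs(q)
    return CFVector(vec.reshape(-1), schema, pose.ligand_id, pose.conformer_id)


def compute_cf_matrix(poses, ligand, site, schema=None, **kwargs) -> np.ndarray:
    """Stack CF vectors of many poses into an (N, L) matrix."""
    if schema is None:
        schema = CFSchema.from_site(site)
    return np.array(
        [compute_cf(p, ligand, site, schema, **kwargs).values for p in poses]
    )


def contact_intensity(cf: CFVector, key_atom: int, rng: str = "direct", channel: str = "n_contacts") -> float:
    """Value of one named CF slot (e.g. direct contact count at a hot spot)."""
    return float(cf.values[cf.schema.slot_index(key_atom, rng, channel)])


def contact_product(cf: CFVector, key_atom_a: int, key_atom_b: int) -> float:
    """Product of direct contact counts at two key atoms.

    Marks how strongly ligand atoms sit near *both* spots simultaneously,
    e.g. the carbonyl O and amide H of the kinase hinge residue.
    """
    return contact_intensity(cf, key_atom_a) * contact_intensity(cf, key_atom_b)
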