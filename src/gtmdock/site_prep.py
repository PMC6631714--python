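"""Key-atom selection: site atoms near any overlaid ligand that expose at
least a minimum fraction of their surface to solvent."""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .sasa import SasaResult, shrake_rupley_sasa
from .structures import SiteModel


def select_key_atoms(
    site: SiteModel,
    ligand_coord_sets: list[np.ndarray],
    expansion: float = 4.0,
    min_exposed_fraction: float = 0.05,
    sasa: SasaResult | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SiteModel:
    """Return a copy of ``site`` with key atoms assigned.

    A site atom becomes a key atom when it lies within ``expansion`` (closed
    cutoff, <=) of any atom of any overlaid ligand coordinate set AND its
    ligand-free solvent-exposed fraction exceeds ``min_exposed_fraction``
    (strict >).  Key atoms are ordered by ascending atom index; the call is
    idempotent on an already-prepared site with the same parameters.
    """
    if not ligand_coord_sets:
        raise ValueError("ligand_coord_sets is empty: no selection basis")
    if sasa is None:
        sasa = shrake_rupley_sasa(site, probe_radius=probe_radius, n_points=n_points)
    lig = np.vstack([np.asarray(c, dtype=float).reshape(-1, 3) for c in ligand_coord_sets])
    tree = cKDTree(lig)
    dmin, _ = tree.query(site.coords, k=1)
    near = dmin <= expansion
    exposed = sasa.fractions > min_exposed_fraction
    keys = tuple(int(i) for i in np.nonzero(near & exposed)[0])
    if site.key_atom_indices and site.key_atom_indices == keys:
        return site
    out = SiteModel(
        atoms=site.atoms,
        key_atom_indices=keys,
        hot_spots=site.hot_spots,
        provenance=dict(site.provenance, key_atom_selection={
            "expansion": expansion,
            "min_exposed_fraction": min_exposed_fraction,
            "probe_radius": probe_radius,
            "n_points": n_points,
        }),
    )
    return out


def write_key_atoms(site: SiteModel, path) -> None:
    """Export the key-atom index list, one 0-based index per line."""
    with open(path, "w") as fh:
        for i in site.key_atom_indices:
            fh.write(f"{i}\n")


def read_key_atoms(path) -> tuple[int, ...]:
    with open(path) as fh:
        return tuple(int(line) for line in fh if line.strip())
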