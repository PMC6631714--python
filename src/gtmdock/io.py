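"""File I/O: TRIPOS Mol2 / PDB sites, SDF/Mol2 pose ensembles, CSV tables.

Reading goes through MDAnalysis (Mol2, PDB) and RDKit (SDF).  Small
TRIPOS-Mol2 and V2000-SDF writers are included for exporting synthetic
fixtures (partial charges travel in the Mol2 charge column and in a
``partial_charges`` SD tag respectively, so round-trips preserve them
bit-exact).  All CSVs are RFC-4180 via pandas.
"""
from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import (
    Atom,
    Ligand,
    Pose,
    SiteModel,
    assign_hbond_roles,
    infer_h_attachments,
)

logger = logging.getLogger(__name__)


class FileFormatError(ValueError):
    """A structure file could not be parsed in the requested format."""


# ----------------------------------------------------------- charges -------

_FALLBACK_CHARGES = {"O": -0.40, "N": -0.35, "S": -0.15, "C": 0.02, "P": 0.10}


def fallback_partial_charges(atoms: list[Atom], bonds=None) -> str:
    """Assign Gasteiger-type partial charges in place; returns a provenance tag.

    Tries RDKit's iterative Gasteiger procedure on the bond graph; structures
    it cannot type (protein fragments, exotic valences) fall back to an
    electronegativity-based per-element table.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import rdPartialCharges

        mol = Chem.RWMol()
        for a in atoms:
            ra = Chem.Atom(a.element)
            ra.SetFormalCharge(a.formal_charge)
            ra.SetNoImplicit(True)
            mol.AddAtom(ra)
        for i, j, order in bonds or []:
            mol.AddBond(i, j, Chem.BondType.values.get(order, Chem.BondType.SINGLE))
        m = mol.GetMol()
        m.UpdatePropertyCache(strict=False)
        rdPartialCharges.ComputeGasteigerCharges(m, throwOnParamFailure=True)
        q = [float(at.GetDoubleProp("_GasteigerCharge")) for at in m.GetAtoms()]
        if all(np.isfinite(q)):
            for a, qi in zip(atoms, q):
                a.partial_charge = qi
            return "gasteiger"
    except Exception:  # noqa: BLE001 - any typing failure falls through
        pass
    attach = infer_h_attachments(atoms, bonds)
    for a in atoms:
        if a.element == "H":
            heavy = attach.get(a.index)
            a.partial_charge = 0.30 if heavy is not None and atoms[heavy].element in (
                "N", "O", "S") else 0.05
        else:
            a.partial_charge = _FALLBACK_CHARGES.get(a.element, 0.0)
    return "element-table"


# ------------------------------------------------------------- sites -------

def _element_from_mol2_type(t: str) -> str:
    return t.split(".")[0]


def read_site(path, format: str | None = None) -> SiteModel:
    """Read a rigid site structure (Mol2 with charges, or PDB).

    Mol2 must carry partial charges (an explicit error otherwise; an
    all-zero charge column is accepted with a warning).  PDB carries no
    charges, so the fallback assigner runs and the provenance records it.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("mol2", "pdb"):
        raise ValueError(f"unsupported site format {fmt!r}")
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=fmt)
    except Exception as exc:  # pragma: no cover - message passthrough
        raise FileFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    ag = u.atoms
    if fmt == "mol2":
        if not hasattr(ag, "charges"):
            raise FileFormatError(f"{path}: Mol2 charges absent")
        # MDAnalysis keeps charges in float32; re-read the charge column at
        # full precision so file round-trips stay bit-exact
        charges = _mol2_charge_column(path, len(ag))
        if charges is None:
            charges = np.asarray(ag.charges, dtype=float)
        if np.allclose(charges, 0.0):
            warnings.warn(f"{path}: all Mol2 charges are zero")
        elements = [_element_from_mol2_type(t) for t in ag.types]
        provenance = {"source": str(path), "format": "mol2", "charges": "file"}
    else:
        charges = None
        elements = _pdb_elements(ag)
        provenance = {"source": str(path), "format": "pdb"}

    atoms = [
        Atom(i, el, pos, partial_charge=0.0 if charges is None else float(charges[i]))
        for i, (el, pos) in enumerate(zip(elements, ag.positions.astype(float)))
    ]
    bonds = []
    if hasattr(u, "bonds"):
        try:
            bonds = [(int(b[0].index), int(b[1].index), 1) for b in u.bonds]
        except Exception:  # noqa: BLE001
            bonds = []
    if charges is None:
        method = fallback_partial_charges(atoms, bonds)
        provenance["charges"] = f"fallback:{method}"
        logger.warning("%s: no charges in PDB, assigned by %s", path, method)
    assign_hbond_roles(atoms, bonds)
    return SiteModel(atoms=atoms, provenance=provenance)


def _mol2_charge_column(path, n_atoms: int) -> np.ndarray | None:
    """Charge column of the first @<TRIPOS>ATOM block, parsed as float64."""
    charges = []
    in_atoms = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("@<TRIPOS>"):
                if in_atoms:
                    break
                in_atoms = s == "@<TRIPOS>ATOM"
                continue
            if in_atoms and s:
                parts = s.split()
                if len(parts) < 9:
                    return None
                charges.append(float(parts[8]))
    return np.array(charges) if len(charges) == n_atoms else None


def _pdb_elements(ag) -> list[str]:
    try:
        els = [str(e).capitalize() for e in ag.elements]
        if all(els):
            return els
    except Exception:  # noqa: BLE001
        pass
    out = []
    for name in ag.names:
        base = "".join(c for c in name if c.isalpha())
        el = base[:2].capitalize()
        from .structures import SUPPORTED_ELEMENTS

        out.append(el if el in SUPPORTED_ELEMENTS else base[0].upper())
    return out


def write_site_mol2(site: SiteModel, path) -> None:
    """Minimal TRIPOS Mol2 export of a site, charge column included."""
    with open(path, "w") as fh:
        fh.write("@<TRIPOS>MOLECULE\nsite\n")
        fh.write(f"{len(site.atoms)} 0 0 0 0\nSMALL\nUSER_CHARGES\n")
        fh.write("@<TRIPOS>ATOM\n")
        for a in site.atoms:
            x, y, z = a.coords
            fh.write(
                f"{a.index + 1:>6} {a.element}{a.index + 1:<6} "
                f"{x:>12.6f} {y:>12.6f} {z:>12.6f} {a.element:<5} 1 SITE "
                f"{a.partial_charge!r}\n"
            )
        fh.write("@<TRIPOS>BOND\n")


# -------------------------------------------------------------- poses ------

def read_poses(
    path,
    format: str | None = None,
    energy_tag: str = "energy",
    energy_csv=None,
    run_id: str = "A",
) -> list[Pose]:
    """Read a multi-record pose file (SDF, or Mol2 with a sidecar energy CSV).

    One pose per record in file order.  Every record must carry an energy
    (the SD tag named ``energy_tag``, or a ``conformer_id,energy`` row of
    ``energy_csv`` for Mol2).  Records of one ligand must agree in atom
    count, otherwise RMSDs would be ill-defined (hard error).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "sdf":
        poses = _read_poses_sdf(path, energy_tag, run_id)
    elif fmt == "mol2":
        poses = _read_poses_mol2(path, energy_csv, run_id)
    else:
        raise ValueError(f"unsupported pose format {fmt!r}")
    counts: dict[str, int] = {}
    for i, p in enumerate(poses):
        n = counts.setdefault(p.ligand_id, p.coords.shape[0])
        if p.coords.shape[0] != n:
            raise FileFormatError(
                f"{path}: record {i} of ligand {p.ligand_id} has "
                f"{p.coords.shape[0]} atoms, expected {n}"
            )
    if not poses:
        warnings.warn(f"{path}: no pose records found")
    return poses


def _read_poses_sdf(path, energy_tag, run_id) -> list[Pose]:
    from rdkit import Chem

    if Path(path).stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    poses = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise FileFormatError(f"{path}: record {i} unparseable")
        if not mol.HasProp(energy_tag):
            raise FileFormatError(f"{path}: record {i} missing energy tag {energy_tag!r}")
        energy = float(mol.GetProp(energy_tag))
        lig_id = mol.GetProp("ligand_id") if mol.HasProp("ligand_id") else (
            mol.GetProp("_Name") or "LIG")
        conf_id = mol.GetProp("conformer_id") if mol.HasProp("conformer_id") else f"rec{i}"
        rid = mol.GetProp("run_id") if mol.HasProp("run_id") else run_id
        coords = mol.GetConformer().GetPositions()
        poses.append(Pose(lig_id, conf_id, coords, energy, run_id=rid))
    return poses


def _read_poses_mol2(path, energy_csv, run_id) -> list[Pose]:
    import MDAnalysis as mda

    if energy_csv is None:
        raise ValueError("Mol2 poses need a sidecar energy CSV (conformer_id,energy)")
    table = pd.read_csv(energy_csv, dtype={"conformer_id": str})
    energies = dict(zip(table["conformer_id"], table["energy"].astype(float)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="mol2")
    poses = []
    lig_id = Path(path).stem
    for i, _ in enumerate(u.trajectory):
        conf_id = f"rec{i}"
        if conf_id not in energies:
            raise FileFormatError(f"{path}: record {i} has no energy in {energy_csv}")
        poses.append(Pose(lig_id, conf_id, u.atoms.positions.astype(float),
                          float(energies[conf_id]), run_id=run_id))
    return poses


def read_ligand(path, format: str | None = None) -> Ligand:
    """Build a Ligand (typed atoms + bond graph) from an SDF's first record.

    Partial charges come from a ``partial_charges`` SD tag when present,
    else from the Gasteiger-type fallback.
    """
    from rdkit import Chem

    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mol = next(iter(supplier), None)
    if mol is None:
        raise FileFormatError(f"{path}: no parseable record")
    coords = mol.GetConformer().GetPositions()
    atoms = [
        Atom(i, at.GetSymbol(), coords[i], formal_charge=at.GetFormalCharge())
        for i, at in enumerate(mol.GetAtoms())
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), int(b.GetBondTypeAsDouble()) or 1)
        for b in mol.GetBonds()
    ]
    if mol.HasProp("partial_charges"):
        q = [float(v) for v in mol.GetProp("partial_charges").split()]
        for a, qi in zip(atoms, q):
            a.partial_charge = qi
    else:
        fallback_partial_charges(atoms, bonds)
    assign_hbond_roles(atoms, bonds)
    lig_id = mol.GetProp("ligand_id") if mol.HasProp("ligand_id") else (
        mol.GetProp("_Name") or path.stem)
    return Ligand(lig_id, atoms, bonds)


def write_poses_sdf(path, ligand: Ligand, poses: list[Pose],
                    energy_tag: str = "energy") -> None:
    """Write a pose ensemble as a V2000 multi-record SDF.

    Each record stores the ligand's bond graph with that pose's coordinates
    plus ``ligand_id``, ``conformer_id``, ``run_id``, the energy tag and a
    ``partial_charges`` tag (space-separated, repr precision).
    """
    charges = " ".join(repr(a.partial_charge) for a in ligand.atoms)
    with open(path, "w") as fh:
        for p in poses:
            fh.write(f"{p.conformer_id}\n  gtmdock           3D\n\n")
            fh.write(f"{len(ligand.atoms):>3}{len(ligand.bonds):>3}  0  0  0  0  0  0  0  0999 V2000\n")
            for a, (x, y, z) in zip(ligand.atoms, p.coords):
                fh.write(f"{x:>10.4f}{y:>10.4f}{z:>10.4f} {a.element:<3} 0  0  0  0  0  0  0  0  0  0  0  0\n")
            for i, j, order in ligand.bonds:
                fh.write(f"{i + 1:>3}{j + 1:>3}{min(order, 3):>3}  0\n")
            chg = [(a.index, a.formal_charge) for a in ligand.atoms if a.formal_charge]
            if chg:
                fh.write(f"M  CHG{len(chg):>3}" + "".join(
                    f"{i + 1:>4}{c:>4}" for i, c in chg) + "\n")
            fh.write("M  END\n")
            for tag, val in (
                ("ligand_id", p.ligand_id),
                ("conformer_id", p.conformer_id),
                ("run_id", p.run_id),
                (energy_tag, repr(p.energy)),
                ("partial_charges", charges),
            ):
                fh.write(f"> <{tag}>\n{val}\n\n")
            fh.write("$$$$\n")


# ------------------------------------------------------------- tables ------

def write_node_table(landscape, path) -> None:
    """Export a coloured landscape as a node-level CSV.

    Columns: node_index, grid_x, grid_y, density, then ``value`` (regression
    / fuzzy) and any per-class ``density_<class>`` columns.  Undefined
    values become empty cells; densities are always written.
    """
    from .gtm import _square_grid

    if hasattr(landscape, "node_values_"):
        values = landscape.node_values_
        class_density = None
    elif hasattr(landscape, "class_density_"):
        values = landscape.fuzzy_values_
        class_density = landscape.class_density_
    else:
        raise ValueError("landscape is not coloured; fit it first")
    density = landscape.node_density_
    K = density.shape[0]
    if landscape.gtm is not None:
        grid = landscape.gtm.node_coords_
    else:
        grid = _square_grid(int(round(np.sqrt(K))))
        if grid.shape[0] != K:
            grid = np.full((K, 2), np.nan)
    data = {
        "node_index": np.arange(K),
        "grid_x": grid[:, 0],
        "grid_y": grid[:, 1],
        "density": density,
    }
    if values is not None:
        data["value"] = values
    if class_density is not None:
        for c, row in zip(landscape.classes_, class_density):
            data[f"density_{c}"] = row
    # %.17g guarantees float64 round-trips bit-exact through the CSV
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_node_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_pose_table(path, pool, native_threshold: float = 2.0) -> None:
    """Per-pose CSV: conformer_id, energy, rmsd, native_like flag."""
    rows = [
        {
            "conformer_id": p.conformer_id,
            "energy": p.energy,
            "rmsd": p.rmsd_to_native,
            "native_like": (p.rmsd_to_native is not None
                            and p.rmsd_to_native < native_threshold),
        }
        for p in pool.poses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cf_csv(path, matrix: np.ndarray, schema, pose_ids=None) -> None:
    """CF/Hy matrix as CSV: rows = poses, columns = slot names."""
    df = pd.DataFrame(np.asarray(matrix), columns=schema.slot_names())
    if pose_ids is not None:
        df.insert(0, "pose_id", list(pose_ids))
    df.to_csv(path, index=False)


def read_cf_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    ids = df.pop("pose_id").tolist() if "pose_id" in df.columns else []
    return df.to_numpy(dtype=float), ids


def write_cf_svmlight(path, matrix: np.ndarray, y=None) -> None:
    """CF matrix in SVM-light sparse format (labels default to zero)."""
    from sklearn.datasets import dump_svmlight_file

    X = np.asarray(matrix)
    labels = np.zeros(X.shape[0]) if y is None else np.asarray(y, dtype=float)
    dump_svmlight_file(X, labels, path, zero_based=True)
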