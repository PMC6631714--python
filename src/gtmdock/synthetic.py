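"""Synthetic fixtures emulating every external input of the pipeline.

A toy active site (a spherical shell of typed atoms with two designated
hot-spot atoms mimicking a hinge residue's carbonyl O and amide H), a small
ligand docked natively against both hot spots, pose ensembles with exactly
controlled RMSD-to-native and funnel-shaped energies
(E = E0 + a·RMSD + N(0, σ²)), paired run-A/run-B ensembles with a controlled
mode overlap, and compound sets whose pK correlates with the hot-spot
contact pattern.  All generators are seed-deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pose_pool import PosePool, pose_rmsd
from .sasa import fibonacci_sphere
from .structures import Atom, Ligand, Pose, SiteModel, assign_hbond_roles


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generators.

    The funnel model E = E0 + a·RMSD + N(0, σ²) ties pose energies to pose
    quality; ``compound_energy_sd`` adds a per-compound energy offset that
    models the limited cross-compound comparability of raw docking scores.
    """

    seed: int = 0
    n_site_atoms: int = 150
    shell_radius: float = 8.0  # Å
    n_poses: int = 200
    funnel_e0: float = -50.0  # kcal/mol
    funnel_slope: float = 1.5  # kcal/mol per Å of RMSD
    energy_noise: float = 1.0  # kcal/mol
    native_fraction: float = 0.2
    overlap: float = 1.0
    n_modes: int = 8
    effect_size: float = 1.0
    n_top: int = 100
    n_weak: int = 91
    n_decoy: int = 101
    poses_per_compound: int = 30
    compound_energy_sd: float = 2.0  # kcal/mol

    def __post_init__(self) -> None:
        for name in ("n_site_atoms", "n_poses", "n_modes", "n_top", "n_weak",
                     "n_decoy", "poses_per_compound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.energy_noise < 0 or not 0.0 <= self.overlap <= 1.0:
            raise ValueError("energy_noise >= 0 and overlap in [0, 1] required")


# ------------------------------------------------------------- toy site ----

def make_toy_site(spec: SyntheticSpec) -> tuple[SiteModel, Ligand, Pose]:
    """Build the toy site, its ligand and the native pose.

    Site atoms sit on a spherical shell around an empty cavity.  Two shell
    atoms near the cavity "bottom" are hot spots: an acceptor carbonyl-like
    O and a donor amide-like H, ~4 Å apart.  The ligand is a small
    N-H / C / O chain placed natively so that its donor H faces the hot-spot
    O (2.6 Å) and its acceptor O faces the hot-spot H (2.8 Å).
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.shell_radius
    pts = fibonacci_sphere(spec.n_site_atoms) * R

    # hot-spot target directions ~28 deg apart near the -z pole
    u1 = np.array([0.25, 0.0, -1.0])
    u1 /= np.linalg.norm(u1)
    u2 = np.array([-0.25, 0.0, -1.0])
    u2 /= np.linalg.norm(u2)
    i_o = int(np.argmax(pts @ u1))
    i_h = int(np.argmax(pts @ u2))
    if i_h == i_o:
        i_h = int(np.argsort(pts @ u2)[-2])

    # thin the shell immediately around the hot spots (pocket-mouth
    # geometry): guarantees both anchors stay solvent-exposed
    d_hot = np.minimum(
        np.linalg.norm(pts - pts[i_o], axis=1),
        np.linalg.norm(pts - pts[i_h], axis=1),
    )
    keep = (d_hot > 2.2) | (np.arange(len(pts)) == i_o) | (np.arange(len(pts)) == i_h)
    old_to_new = -np.ones(len(pts), dtype=int)
    old_to_new[keep] = np.arange(int(keep.sum()))
    pts = pts[keep]
    i_o, i_h = int(old_to_new[i_o]), int(old_to_new[i_h])

    elements = rng.choice(["C", "C", "C", "C", "C", "C", "C", "N", "O", "H"],
                          size=len(pts))
    base_charge = {"C": 0.05, "N": -0.40, "O": -0.45, "H": 0.15}
    atoms = []
    for i in range(len(pts)):
        el = str(elements[i])
        q = base_charge[el] + rng.normal(0.0, 0.02)
        atoms.append(Atom(index=i, element=el, coords=pts[i], partial_charge=q))
    atoms[i_o] = Atom(index=i_o, element="O", coords=pts[i_o],
                      partial_charge=-0.50, is_hba=True)
    atoms[i_h] = Atom(index=i_h, element="H", coords=pts[i_h],
                      partial_charge=0.40, is_hbd=True)
    site = SiteModel(atoms=atoms, hot_spots=(i_o, i_h),
                     provenance={"generator": "make_toy_site", "seed": spec.seed})

    a = pts[i_o] / np.linalg.norm(pts[i_o])
    b = pts[i_h] / np.linalg.norm(pts[i_h])
    x0 = (R - 2.6) * a                      # donor H, faces hot-spot O
    x1 = x0 - 1.0 * a                       # amine N carrying it
    x4 = (R - 2.8) * b                      # acceptor O, faces hot-spot H
    x2 = x1 + 1.5 * _unit(x4 - x1)          # C alpha
    x3 = x4 + 1.4 * _unit(x2 - x4)          # carbonyl-like C
    x5 = x2 - 1.5 * _unit(x2)               # chain C pointing inward
    x6 = x5 - 1.1 * _unit(x5)               # its H
    lig_atoms = [
        Atom(0, "H", x0, partial_charge=0.35),
        Atom(1, "N", x1, partial_charge=-0.50),
        Atom(2, "C", x2, partial_charge=0.05),
        Atom(3, "C", x3, partial_charge=0.20),
        Atom(4, "O", x4, partial_charge=-0.45),
        Atom(5, "C", x5, partial_charge=0.05),
        Atom(6, "H", x6, partial_charge=0.10),
    ]
    bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 4, 2), (2, 5, 1), (5, 6, 1)]
    assign_hbond_roles(lig_atoms, bonds)
    ligand = Ligand("TOY", lig_atoms, bonds)
    native = Pose("TOY", "native", ligand.coords, spec.funnel_e0,
                  run_id="native", rmsd_to_native=0.0)
    return site, ligand, native


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = _unit(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def _rigid_perturb(coords: np.ndarray, heavy_mask: np.ndarray,
                   target_rmsd: float, rng: np.random.Generator) -> np.ndarray:
    """Rigidly perturb coordinates to an exact heavy-atom RMSD.

    A rotation about the heavy-atom centroid contributes r_rot; because the
    rotation leaves the centroid fixed, a translation of magnitude
    sqrt(target² − r_rot²) makes the total heavy-atom RMSD exactly the
    target (the displacement cross-term vanishes).
    """
    centroid = coords[heavy_mask].mean(axis=0)
    axis = rng.normal(size=3)
    r_rot_goal = rng.uniform(0.0, 0.7) * target_rmsd
    angle = 0.3
    rot = np.eye(3)
    for _ in range(3):  # Newton-like rescale; r_rot is ~linear in angle
        rot = _rotation(axis, angle)
        moved = (coords - centroid) @ rot.T + centroid
        r_rot = np.sqrt(np.mean(np.sum((moved - coords)[heavy_mask] ** 2, axis=1)))
        if r_rot < 1e-9:
            break
        angle = min(angle * r_rot_goal / r_rot, np.pi)
    moved = (coords - centroid) @ rot.T + centroid
    r_rot = np.sqrt(np.mean(np.sum((moved - coords)[heavy_mask] ** 2, axis=1)))
    t_mag = np.sqrt(max(target_rmsd**2 - r_rot**2, 0.0))
    direction = _unit(rng.normal(size=3))
    return moved + t_mag * direction


def _sample_target_rmsd(rng: np.random.Generator, native_fraction: float) -> float:
    if rng.random() < native_fraction:
        return rng.uniform(0.2, 1.8)
    return rng.uniform(2.3, 7.5)


def make_pose_ensemble(
    spec: SyntheticSpec,
    ligand: Ligand,
    native: Pose,
    run_id: str = "A",
    n_poses: int | None = None,
    native_fraction: float | None = None,
    seed: int | None = None,
    energy_offset: float = 0.0,
) -> PosePool:
    """Pose pool with controlled RMSD distribution and funnel energies."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_poses if n_poses is None else n_poses
    frac = spec.native_fraction if native_fraction is None else native_fraction
    mask = ligand.heavy_mask
    poses = []
    for i in range(n):
        target = _sample_target_rmsd(rng, frac)
        coords = _rigid_perturb(native.coords, mask, target, rng)
        coords = coords + rng.normal(0.0, 0.02, size=coords.shape)
        pose = Pose(ligand.ligand_id, f"{run_id}{i:04d}", coords, 0.0, run_id=run_id)
        rmsd = pose_rmsd(pose, native, ligand=ligand)
        pose.rmsd_to_native = rmsd
        pose.energy = (spec.funnel_e0 + energy_offset + spec.funnel_slope * rmsd
                       + rng.normal(0.0, spec.energy_noise))
        poses.append(pose)
    return PosePool(poses, ligand.ligand_id)


# ------------------------------------------------------------ paired runs --

def _mode_catalogue(spec: SyntheticSpec, ligand: Ligand, native: Pose) -> list[np.ndarray]:
    """2·n_modes well-separated conformational-space modes (fixed per seed)."""
    from .sasa import fibonacci_sphere

    rng = np.random.default_rng(spec.seed + 104729)
    mask = ligand.heavy_mask
    n_total = 2 * spec.n_modes
    # mode centres must be pairwise distinct in *contact* space: magnitudes
    # stay inside the contact-informative band (poses far past the site rim
    # all share a near-empty fingerprint) and displacement directions are
    # spread maximally apart instead of drawn at random
    targets = np.linspace(1.0, 4.5, n_total)
    rng.shuffle(targets)
    directions = fibonacci_sphere(n_total)
    centroid = native.coords[mask].mean(axis=0)
    modes = []
    for t, direction in zip(targets, directions):
        axis = rng.normal(size=3)
        rot = _rotation(axis, rng.uniform(0.05, 0.25))
        moved = (native.coords - centroid) @ rot.T + centroid
        r_rot = np.sqrt(np.mean(np.sum((moved - native.coords)[mask] ** 2, axis=1)))
        t_mag = np.sqrt(max(t**2 - r_rot**2, 0.25))
        modes.append(moved + t_mag * direction)
    return modes


def make_paired_runs(
    spec: SyntheticSpec,
    ligand: Ligand,
    native: Pose,
    overlap: float | None = None,
    n_poses: int | None = None,
) -> tuple[PosePool, PosePool]:
    """Two pose ensembles sharing a controlled fraction of CS modes.

    overlap = 1 means runs sample statistically identical mode mixtures;
    overlap = 0 gives fully disjoint mode sets.  Poses scatter around their
    mode centre with a small rigid + per-atom jitter.
    """
    ov = spec.overlap if overlap is None else overlap
    if not 0.0 <= ov <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    n = spec.n_poses if n_poses is None else n_poses
    modes = _mode_catalogue(spec, ligand, native)
    m = spec.n_modes
    n_shared = int(round(ov * m))
    modes_a = modes[:m]
    modes_b = modes[:n_shared] + modes[m : 2 * m - n_shared]
    pools = []
    for run_id, run_modes, sub in (("A", modes_a, 1), ("B", modes_b, 2)):
        rng = np.random.default_rng(spec.seed + sub)
        poses = []
        for i in range(n):
            base = run_modes[rng.integers(len(run_modes))]
            coords = base + rng.normal(0.0, 0.15, size=3) + rng.normal(
                0.0, 0.03, size=base.shape)
            pose = Pose(ligand.ligand_id, f"{run_id}{i:04d}", coords, 0.0, run_id=run_id)
            rmsd = pose_rmsd(pose, native, ligand=ligand)
            pose.rmsd_to_native = rmsd
            pose.energy = (spec.funnel_e0 + spec.funnel_slope * rmsd
                           + rng.normal(0.0, spec.energy_noise))
            poses.append(pose)
        pools.append(PosePool(poses, ligand.ligand_id))
    return pools[0], pools[1]


# --------------------------------------------------------- screening sets --

@dataclass
class Compound:
    compound_id: str
    ligand: Ligand
    pool: PosePool
    pk: float
    label: str  # "top" | "weak" | "decoy"
    free_min_energy: float  # unbound-ligand reference for the docking score

    @property
    def delta_e(self) -> float:
        """Docking score ΔE = min bound energy − min free energy."""
        return self.pool.min_energy - self.free_min_energy


def _variant_ligand(base: Ligand, idx: int, rng: np.random.Generator) -> Ligand:
    """Ligand variant: tweak the inert chain atom's element and charges so
    fragment descriptors vary across compounds while the anchoring donor H /
    acceptor O motif stays intact."""
    atoms = []
    swap = ["C", "N", "O"][idx % 3]
    for a in base.atoms:
        el = swap if a.index == 5 else a.element
        q = a.partial_charge + rng.normal(0.0, 0.02)
        atoms.append(Atom(a.index, el, a.coords.copy(), partial_charge=q,
                          formal_charge=a.formal_charge))
    bonds = list(base.bonds)
    assign_hbond_roles(atoms, bonds)
    return Ligand(f"{base.ligand_id}-v{idx}", atoms, bonds)


def make_screening_set(spec: SyntheticSpec, ligand: Ligand, native: Pose) -> list[Compound]:
    """Compound set for the virtual-screening benchmark.

    Actives (classes "top" and "weak") receive pose ensembles enriched in
    the native hot-spot contact pattern; decoys roam.  pK values: top from
    U(7.2, 9.0), weak from U(4.7, 5.5), decoys fixed at 3.0.  The
    enrichment scales with ``effect_size`` (0 removes all class signal).
    """
    rng = np.random.default_rng(spec.seed + 31337)
    plan = (
        [("top", 0.05 + 0.65 * spec.effect_size)] * spec.n_top
        + [("weak", 0.05 + 0.40 * spec.effect_size)] * spec.n_weak
        + [("decoy", 0.05)] * spec.n_decoy
    )
    compounds = []
    for i, (label, frac) in enumerate(plan):
        lig = _variant_ligand(ligand, i, rng)
        offset = rng.normal(0.0, spec.compound_energy_sd)
        pool = make_pose_ensemble(
            spec, lig, Pose(lig.ligand_id, "native", native.coords, spec.funnel_e0),
            run_id="S", n_poses=spec.poses_per_compound, native_fraction=frac,
            seed=int(rng.integers(2**31)), energy_offset=offset,
        )
        if label == "top":
            pk = rng.uniform(7.2, 9.0)
        elif label == "weak":
            pk = rng.uniform(4.7, 5.5)
        else:
            pk = 3.0
        free_min = offset + rng.normal(0.0, 0.5)
        compounds.append(Compound(f"{label}_{i:03d}", lig, pool, pk, label, free_min))
    return compounds
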