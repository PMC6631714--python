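"""Pose-ensemble bookkeeping: energy window, diverse subset selection,
energy convergence criterion (ECC), fixed-frame RMSD and the docking score."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Ligand, Pose

NATIVE_RMSD_THRESHOLD = 2.0  # Å, strict <
RMSD_CAP = 6.0  # Å


@dataclass
class PosePool:
    poses: list[Pose]
    ligand_id: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_id and self.poses:
            self.ligand_id = self.poses[0].ligand_id
        counts = {p.coords.shape[0] for p in self.poses}
        ids = {p.ligand_id for p in self.poses}
        if len(counts) > 1 or len(ids) > 1:
            raise ValueError("all poses of a pool must share ligand_id and atom count")

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def energies(self) -> np.ndarray:
        return np.array([p.energy for p in self.poses])

    @property
    def min_energy(self) -> float:
        if not self.poses:
            raise ValueError("empty pool has no minimum energy")
        return float(self.energies.min())


@dataclass
class ECCState:
    """Minimum energies of the independent docking simulations run so far.

    The criterion: at least ``required_count`` simulations exist and those
    ranked 2..required_count have minima within ``window`` of the best one.
    """

    minima: list[float] = field(default_factory=list)
    window: float = 1.0
    required_count: int = 5
    max_simulations: int = 20

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("ECC window must be > 0")

    def record(self, minimum: float) -> None:
        self.minima.append(float(minimum))

    @property
    def exhausted(self) -> bool:
        return len(self.minima) >= self.max_simulations


def ecc_fulfilled(state: ECCState) -> bool:
    """Energy Convergence Criterion over the recorded simulation minima."""
    if not state.minima:
        raise ValueError("no simulations recorded")
    if len(state.minima) < state.required_count:
        return False
    ranked = sorted(state.minima)
    best = ranked[0]
    return all(e <= best + state.window for e in ranked[1:state.required_count])


def energy_window_filter(pool: PosePool, window: float = 50.0) -> PosePool:
    """Keep poses whose excess energy over the pool minimum is <= window."""
    if not pool.poses:
        raise ValueError("empty pool")
    lo = pool.min_energy
    kept = [p for p in pool.poses if p.energy <= lo + window]
    return PosePool(kept, pool.ligand_id)


def select_diverse(
    pool: PosePool,
    n: int = 200,
    dissimilarity=None,
    threshold: float = 1.0,
) -> PosePool:
    """Greedy energy-ranked diverse subset.

    Repeatedly accept the energetically best remaining pose, then discard
    every pose within ``threshold`` dissimilarity of it, until ``n`` poses
    are accepted or the list is exhausted.  Energy ties break on
    conformer_id lexicographic order (deterministic).  ``dissimilarity``
    is any callable on two poses; the default is coordinate RMS distance
    (callers typically pass a CF-vector Euclidean distance).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if dissimilarity is None:
        def dissimilarity(p, q):
            return float(np.sqrt(np.mean(np.sum((p.coords - q.coords) ** 2, axis=1))))
    remaining = sorted(pool.poses, key=lambda p: (p.energy, p.conformer_id))
    accepted: list[Pose] = []
    while remaining and len(accepted) < n:
        best = remaining.pop(0)
        accepted.append(best)
        remaining = [p for p in remaining if dissimilarity(best, p) > threshold]
    return PosePool(accepted, pool.ligand_id)


def pose_rmsd(
    pose: Pose,
    native: Pose,
    cap: float | None = None,
    ligand: Ligand | None = None,
) -> float:
    """Fixed-frame RMSD between a pose and the native reference.

    No superposition is performed: both conformers live in the common site
    frame.  Atom correspondence is by stored index; when ``ligand`` is given
    only heavy atoms enter the sum.  Capped at ``cap`` (typically 6.0 Å) when
    set.
    """
    if pose.coords.shape != native.coords.shape:
        raise ValueError("atom count mismatch between pose and native")
    diff = pose.coords - native.coords
    if ligand is not None:
        mask = ligand.heavy_mask
        if mask.shape[0] != diff.shape[0]:
            raise ValueError("ligand atom count mismatch")
        diff = diff[mask]
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    if cap is not None:
        rmsd = min(rmsd, cap)
    return rmsd


def is_native_like(rmsd: float, threshold: float = NATIVE_RMSD_THRESHOLD) -> bool:
    """Strict-inequality native-like call (RMSD < 2.0 Å)."""
    return rmsd < threshold


def native_like_fraction(rmsds, threshold: float = NATIVE_RMSD_THRESHOLD) -> float:
    r = np.asarray(rmsds, dtype=float)
    if r.size == 0:
        raise ValueError("no RMSD values")
    return float(np.mean(r < threshold))


def docking_score(bound_pool: PosePool, free_pool: PosePool) -> float:
    """ΔE = min bound energy - min free-ligand energy (kcal/mol)."""
    return bound_pool.min_energy - free_pool.min_energy
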