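"""End-to-end experiment compositions on synthetic inputs.

These wire the primitive modules into the studied workflows: CF pipelines,
reproducibility (IRI) runs, GTM calibration checks and the
virtual-screening benchmark.  They are what the CLI subcommands and the
reproduction script execute; every function is deterministic under its
seed arguments.
"""
from __future__ import annotations

import numpy as np

from .contact_fp import CFSchema, compute_cf, compute_cf_matrix, contact_intensity
from .docking_maps import (
    ar_vector,
    half_split,
    iri,
    scenario_positives,
    screen,
)
from .gtm import GTM
from .landscapes import PropertyLandscape, cross_validate
from .site_prep import select_key_atoms
from .synthetic import SyntheticSpec, make_paired_runs, make_screening_set, make_toy_site
from sklearn.metrics import roc_auc_score


def prepare_toy_system(spec: SyntheticSpec):
    """Toy site with key atoms selected, its ligand, native pose and schema."""
    site, ligand, native = make_toy_site(spec)
    site = select_key_atoms(site, [ligand.coords])
    return site, ligand, native, CFSchema.from_site(site)


DEFAULT_MAP = dict(n_nodes=100, n_rbfs=16, rbf_width_factor=1.0,
                   regularization=0.1, random_state=0)


def iri_experiment(
    spec: SyntheticSpec,
    overlap: float,
    n_poses: int = 500,
    p: float = 0.85,
    gtm_params: dict | None = None,
):
    """Paired-run reproducibility: CF map of both runs, then IRI(p)."""
    site, ligand, native, schema = prepare_toy_system(spec)
    run_a, run_b = make_paired_runs(spec, ligand, native, overlap, n_poses)
    X_a = compute_cf_matrix(run_a.poses, ligand, site, schema)
    X_b = compute_cf_matrix(run_b.poses, ligand, site, schema)
    gtm = GTM(**(gtm_params or DEFAULT_MAP)).fit(np.vstack([X_a, X_b]))
    return iri(gtm.transform(X_a), gtm.transform(X_b), p=p)


def rmsd_landscape_cv(
    spec: SyntheticSpec,
    gtm_params: dict | None = None,
    seed: int = 0,
):
    """Fit a CF map on one ligand's ensemble and cross-validate its
    RMSD and energy landscapes (the map-fitness ingredients)."""
    from .pose_pool import RMSD_CAP
    from .synthetic import make_pose_ensemble

    site, ligand, native, schema = prepare_toy_system(spec)
    pool = make_pose_ensemble(spec, ligand, native, seed=seed)
    X = compute_cf_matrix(pool.poses, ligand, site, schema)
    rmsd = np.minimum([p.rmsd_to_native for p in pool.poses], RMSD_CAP)
    energy = pool.energies
    gtm = GTM(**(gtm_params or DEFAULT_MAP)).fit(X)
    return {
        "rmsd": cross_validate(gtm, X, rmsd, seed=seed),
        "energy": cross_validate(gtm, X, energy, seed=seed),
    }


def screening_experiment(
    spec: SyntheticSpec,
    beta: float = 0.0,
    scenario: str = "TvO",
    seed: int = 0,
    gtm_params: dict | None = None,
    frame_size: int = 1500,
) -> dict:
    """Virtual-screening benchmark on the synthetic compound set.

    Pools all compounds' poses in CF space, fits a map on a frame subset,
    forms per-compound Boltzmann-averaged AR vectors, colours a pK
    landscape with a stratified random half of the compounds and ranks the
    other half; compares the map AUC with the docking-score ΔE baseline
    and the two hot-spot contact baselines (single-spot averages and their
    product).
    """
    site, ligand, native, schema = prepare_toy_system(spec)
    compounds = make_screening_set(spec, ligand, native)
    mats = [compute_cf_matrix(c.pool.poses, c.ligand, site, schema) for c in compounds]
    X_all = np.vstack(mats)
    rng = np.random.default_rng(seed)
    frame_idx = rng.choice(X_all.shape[0], size=min(frame_size, X_all.shape[0]),
                           replace=False)
    gtm = GTM(**(gtm_params or DEFAULT_MAP)).fit(X_all[frame_idx])

    hot_o, hot_h = site.hot_spots
    ar, leu_o, leu_nh, leu_tot = [], [], [], []
    for c, X in zip(compounds, mats):
        R = gtm.transform(X)
        ar.append(ar_vector(R, c.pool.energies, beta, c.compound_id).ar)
        per_pose_o, per_pose_h = [], []
        for p in c.pool.poses:
            cf = compute_cf(p, c.ligand, site, schema)
            per_pose_o.append(contact_intensity(cf, hot_o))
            per_pose_h.append(contact_intensity(cf, hot_h))
        per_pose_o, per_pose_h = np.array(per_pose_o), np.array(per_pose_h)
        leu_o.append(per_pose_o.mean())
        leu_nh.append(per_pose_h.mean())
        leu_tot.append((per_pose_o * per_pose_h).mean())
    ar = np.array(ar)
    labels = np.array([c.label for c in compounds])
    pk = np.array([c.pk for c in compounds])
    delta_e = np.array([c.delta_e for c in compounds])

    color_idx, test_idx = half_split(labels, seed=seed)
    result = screen(ar[color_idx], pk[color_idx], ar[test_idx], labels[test_idx],
                    scenario=scenario)
    pos = scenario_positives(labels[test_idx], scenario)
    out = {
        "scenario": scenario,
        "beta": beta,
        "n_compounds": len(compounds),
        "n_test": len(test_idx),
        "auc_map": result.auc,
        "n_undefined": result.n_undefined,
        # lower ΔE = stronger predicted binding, so rank ascending
        "auc_delta_e": float(roc_auc_score(pos, -delta_e[test_idx])),
        "auc_hotspot_o": float(roc_auc_score(pos, np.array(leu_o)[test_idx])),
        "auc_hotspot_h": float(roc_auc_score(pos, np.array(leu_nh)[test_idx])),
        "auc_hotspot_product": float(roc_auc_score(pos, np.array(leu_tot)[test_idx])),
        "pk_pred": result.pk_pred,
        "test_labels": labels[test_idx],
    }
    return out


# ------------------------------------------------- GTM calibration checks --

def plane_reconstruction_error(seed: int = 0, n: int = 400, d: int = 10) -> float:
    """Max relative off-manifold residual for exactly planar data.

    Data on a 2D affine plane in d dimensions are exactly representable by
    the RBF manifold (bias column + planar PCA initialization), so the
    fitted manifold must stay in the plane and residuals vanish.
    """
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(2, d))
    b = rng.normal(size=d)
    latent = rng.uniform(-1, 1, size=(n, 2))
    X = latent @ A + b
    gtm = GTM(n_nodes=25, n_rbfs=9, rbf_width_factor=1.0, regularization=0.0,
              max_iter=50, random_state=seed).fit(X)
    scale = float(np.linalg.norm(X - X.mean(axis=0), axis=1).mean())
    return float(gtm.reconstruction_residuals(X).max() / scale)


def noise_precision_recovery(seed: int = 0, sigma: float = 0.1, n: int = 2000,
                             d: int = 5) -> tuple[float, float]:
    """Fit a map to data generated from a known GTM-style model.

    Samples nodes of a planar 10x10 generator uniformly, adds isotropic
    N(0, sigma^2) noise, and returns (fitted noise precision, true 1/sigma^2).
    The plane's two axes are unit-normalized so the generating grid is
    isotropic and the model class identifiable (a square fitted node grid
    cannot track an arbitrarily anisotropic generating grid).
    """
    from .gtm import _square_grid

    rng = np.random.default_rng(seed)
    A = rng.normal(size=(2, d))
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    b = rng.normal(size=d)
    images = _square_grid(10) @ A + b
    idx = rng.integers(images.shape[0], size=n)
    X = images[idx] + rng.normal(0.0, sigma, size=(n, d))
    gtm = GTM(n_nodes=100, n_rbfs=16, rbf_width_factor=1.0, regularization=1e-3,
              max_iter=200, random_state=seed).fit(X)
    return float(gtm.noise_precision_), 1.0 / sigma**2


def known_map(seed: int = 0, side: int = 4, n_rbfs: int = 9, d: int = 5,
              noise_precision: float = 1e6) -> GTM:
    """A GTM with known weights, constructed rather than fitted.

    Useful as a generative ground truth: node images are an exact RBF
    manifold, and the high default precision makes responsibilities
    essentially one-hot for items placed at node images.
    """
    rng = np.random.default_rng(seed)
    gtm = GTM(n_nodes=side * side, n_rbfs=n_rbfs, rbf_width_factor=1.0,
              regularization=0.0, random_state=seed)
    nodes, centers, sigma, phi = gtm._build_grids()
    gtm.node_coords_, gtm.rbf_centers_, gtm.rbf_sigma_, gtm.phi_ = nodes, centers, sigma, phi
    gtm.W_ = rng.normal(size=(phi.shape[1], d))
    gtm.noise_precision_ = noise_precision
    gtm.mean_ = np.zeros(d)
    gtm.scale_ = None
    gtm.n_features_in_ = d
    gtm.ll_history_ = np.array([])
    return gtm


def selfconsistent_landscape_q2(seed: int = 0, copies: int = 12) -> float:
    """Cross-validated Q2 for a noiseless, self-consistent node property.

    Items sit exactly at the node images of a known map, each node
    duplicated ``copies`` times, with the property a smooth function of the
    latent position; landscape CV must reproduce it essentially exactly.
    """
    gtm = known_map(seed)
    images = gtm.node_images() + gtm.mean_
    X = np.repeat(images, copies, axis=0)
    lat = np.repeat(gtm.node_coords_, copies, axis=0)
    y = np.sin(1.5 * lat[:, 0]) + lat[:, 1]
    report = cross_validate(gtm, X, y, seed=seed)
    return report.mean_q2
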