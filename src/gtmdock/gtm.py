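"""Generative Topographic Mapping (GTM).

A GTM is a constrained isotropic Gaussian mixture: a square grid of K latent
nodes x_k in [-1, 1]^2 maps through an RBF expansion y(x; W) = Phi(x) W into
descriptor space, each node owning a Gaussian component of shared precision
beta centred at its image y_k.  EM alternates posterior node responsibilities
(E-step) with a penalized least-squares update of W and a closed-form update
of beta (M-step).  Responsibilities R_nk — the fuzzy degree to which item n
"resides in" node k — are the sole currency of all downstream landscapes.

The estimator follows scikit-learn conventions: ``fit(X)``, ``transform(X)``
returning the N x K responsibility matrix, fitted attributes with trailing
underscores, and ``get_params``/``set_params`` for model selection.
"""
from __future__ import annotations

import json
import warnings

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


def _square_grid(side: int) -> np.ndarray:
    """side^2 points on a regular grid spanning [-1, 1]^2, row-major."""
    if side == 1:
        return np.zeros((1, 2))
    axis = np.linspace(-1.0, 1.0, side)
    gx, gy = np.meshgrid(axis, axis, indexing="xy")
    return np.column_stack([gx.ravel(), gy.ravel()])


class GTM(BaseEstimator, TransformerMixin):
    """Generative topographic map of a descriptor space.

    Parameters
    ----------
    n_nodes : int
        Number K of latent grid nodes; must be a perfect square.
    n_rbfs : int
        Number M of radial basis functions; must be a perfect square.  The
        basis matrix gains one constant bias column, so W is (M+1) x D and
        affine planes are exactly representable.
    rbf_width_factor : float
        RBF width = factor x spacing between adjacent RBF centres.
    regularization : float
        Weight-decay coefficient lambda on W (bias row excluded); enters the
        M-step as (Phi' G Phi + (lambda/beta) I) W = Phi' R T.
    scale : bool
        Optionally scale columns to unit variance (training record stored);
        descriptors are always centred on training means.
    """

    def __init__(
        self,
        n_nodes: int = 256,
        n_rbfs: int = 16,
        rbf_width_factor: float = 1.0,
        regularization: float = 0.1,
        max_iter: int = 200,
        ll_tol: float = 1e-6,
        scale: bool = False,
        random_state: int = 0,
    ):
        self.n_nodes = n_nodes
        self.n_rbfs = n_rbfs
        self.rbf_width_factor = rbf_width_factor
        self.regularization = regularization
        self.max_iter = max_iter
        self.ll_tol = ll_tol
        self.scale = scale
        self.random_state = random_state

    # -- construction helpers -------------------------------------------------

    def _build_grids(self):
        k_side = int(round(np.sqrt(self.n_nodes)))
        m_side = int(round(np.sqrt(self.n_rbfs)))
        if k_side * k_side != self.n_nodes or m_side * m_side != self.n_rbfs:
            raise ValueError("n_nodes and n_rbfs must be perfect squares")
        if self.rbf_width_factor <= 0:
            raise ValueError("rbf_width_factor must be > 0")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        nodes = _square_grid(k_side)
        centers = _square_grid(m_side)
        spacing = 2.0 / (m_side - 1) if m_side > 1 else 2.0
        sigma = self.rbf_width_factor * spacing
        d2 = cdist(nodes, centers, "sqeuclidean")
        phi = np.exp(-d2 / (2.0 * sigma**2))
        phi = np.hstack([phi, np.ones((phi.shape[0], 1))])  # bias column
        return nodes, centers, sigma, phi

    @staticmethod
    def _pca(Xc: np.ndarray):
        """Deterministic PCA: component signs fixed so the largest-magnitude
        loading of each component is positive."""
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        for i in range(vt.shape[0]):
            j = int(np.argmax(np.abs(vt[i])))
            if vt[i, j] < 0:
                vt[i] = -vt[i]
        lam = s**2 / max(Xc.shape[0] - 1, 1)
        return vt, lam

    # -- fitting --------------------------------------------------------------

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=3, ensure_min_features=2)
        nodes, centers, sigma, phi = self._build_grids()
        N, D = X.shape
        K = nodes.shape[0]
        if N < K:
            warnings.warn(f"fewer items ({N}) than nodes ({K}); map will be sparse")

        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.scale:
            self.scale_ = Xc.std(axis=0)
            self.scale_[self.scale_ == 0] = 1.0
            Xc = Xc / self.scale_
        else:
            self.scale_ = None

        # PCA initialization: node images start on the first two principal
        # axes, stretched to the component standard deviations.
        vt, lam = self._pca(Xc)
        n_pc = min(2, vt.shape[0])
        target = np.zeros((K, D))
        for i in range(n_pc):
            target += np.outer(nodes[:, i], np.sqrt(lam[i]) * vt[i])
        W, *_ = np.linalg.lstsq(phi, target, rcond=None)

        Y = phi @ W
        # noise variance init: 3rd PC variance or half nearest-neighbour
        # node-image spacing squared, whichever variance is larger
        if K > 1:
            d_nodes = cdist(Y, Y)
            np.fill_diagonal(d_nodes, np.inf)
            grid_var = (d_nodes.min(axis=1).mean() / 2.0) ** 2
        else:
            grid_var = 1.0
        pc3_var = lam[2] if len(lam) > 2 else 0.0
        beta = 1.0 / max(pc3_var, grid_var, 1e-12)

        lam_reg = np.eye(phi.shape[1])
        lam_reg[-1, -1] = 0.0  # no decay on the bias row

        ll_history = []
        obj_history = []
        obj_prev = -np.inf
        for _ in range(self.max_iter):
            # E-step: log responsibilities, numerically stable
            d2 = cdist(Y, Xc, "sqeuclidean")  # (K, N)
            log_p = -0.5 * beta * d2
            log_norm = logsumexp(log_p, axis=0)  # (N,)
            R = np.exp(log_p - log_norm)  # (K, N)
            ll = float(
                log_norm.sum() + N * (0.5 * D * np.log(beta / (2 * np.pi)) - np.log(K))
            )
            # EM guarantees monotonicity of the *penalized* objective when
            # weight decay is active (it equals the likelihood at lambda = 0)
            obj = ll - 0.5 * self.regularization * float(np.sum(W[:-1] ** 2))
            ll_history.append(ll)
            obj_history.append(obj)
            if obj + abs(obj) * 1e-9 + 1e-9 < obj_prev:
                warnings.warn("EM objective decreased (numerical)")
            if obj_prev != -np.inf and abs(obj - obj_prev) <= self.ll_tol * max(abs(obj), 1.0):
                break
            obj_prev = obj

            # M-step: weights
            g = R.sum(axis=1)  # (K,)
            A = phi.T @ (phi * g[:, None]) + (self.regularization / beta) * lam_reg
            B = phi.T @ (R @ Xc)
            try:
                W = np.linalg.solve(A, B)
            except np.linalg.LinAlgError:
                warnings.warn("singular M-step system; using least squares")
                W, *_ = np.linalg.lstsq(A, B, rcond=None)
            Y = phi @ W
            # M-step: noise precision
            d2 = cdist(Y, Xc, "sqeuclidean")
            beta = N * D / max(float((R * d2).sum()), 1e-300)

        self.node_coords_ = nodes
        self.rbf_centers_ = centers
        self.rbf_sigma_ = sigma
        self.phi_ = phi
        self.W_ = W
        self.noise_precision_ = float(beta)
        self.ll_history_ = np.array(ll_history)
        self.objective_history_ = np.array(obj_history)
        self.n_features_in_ = D
        self.n_iter_ = len(ll_history)
        return self

    # -- inference ------------------------------------------------------------

    def _center(self, X):
        Xc = X - self.mean_
        if self.scale_ is not None:
            Xc = Xc / self.scale_
        return Xc

    def node_images(self) -> np.ndarray:
        """Manifold node images y_k in (centred/scaled) descriptor space."""
        check_is_fitted(self, "W_")
        return self.phi_ @ self.W_

    def transform(self, X) -> np.ndarray:
        """Responsibilities: N x K matrix, rows summing to one.

        R_nk is the posterior probability that node k generated item n —
        the softmax over nodes of -beta/2 ||y_k - t_n||^2.
        """
        check_is_fitted(self, "W_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        Xc = self._center(X)
        d2 = cdist(Xc, self.node_images(), "sqeuclidean")  # (N, K)
        log_p = -0.5 * self.noise_precision_ * d2
        return np.exp(log_p - logsumexp(log_p, axis=1, keepdims=True))

    responsibilities = transform

    def latent_means(self, X) -> np.ndarray:
        """Posterior-mean 2D latent position of each item (for plotting)."""
        return self.transform(X) @ self.node_coords_

    def reconstruction_residuals(self, X) -> np.ndarray:
        """Per-item distance to the affine span of the fitted node images.

        Measures how far data sit off the (locally planar) manifold; exactly
        planar data fitted from a planar initialization stay at ~0.
        """
        check_is_fitted(self, "W_")
        X = check_array(X, dtype=float)
        Xc = self._center(X)
        Y = self.node_images()
        c = Y.mean(axis=0)
        _, _, vt = np.linalg.svd(Y - c, full_matrices=False)
        basis = vt[:2]
        rel = Xc - c
        proj = rel @ basis.T @ basis
        return np.linalg.norm(rel - proj, axis=1)

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Serialize the fitted map to a portable JSON archive."""
        check_is_fitted(self, "W_")
        payload = {
            "params": self.get_params(),
            "mean": self.mean_.tolist(),
            "scale": None if self.scale_ is None else self.scale_.tolist(),
            "W": self.W_.tolist(),
            "noise_precision": self.noise_precision_,
            "n_features_in": self.n_features_in_,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GTM":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(**payload["params"])
        nodes, centers, sigma, phi = model._build_grids()
        model.node_coords_ = nodes
        model.rbf_centers_ = centers
        model.rbf_sigma_ = sigma
        model.phi_ = phi
        model.mean_ = np.array(payload["mean"])
        model.scale_ = None if payload["scale"] is None else np.array(payload["scale"])
        model.W_ = np.array(payload["W"])
        model.noise_precision_ = payload["noise_precision"]
        model.n_features_in_ = payload["n_features_in"]
        model.ll_history_ = np.array([])
        return model


def cumulated_responsibility(R: np.ndarray, subset=None) -> np.ndarray:
    """CR_k = sum over the subset's items of R_nk (a K-vector).

    The total mass equals the subset size; disjoint subsets add linearly.
    An empty subset returns zeros with a warning.
    """
    R = np.asarray(R, dtype=float)
    if subset is None:
        return R.sum(axis=0)
    idx = np.asarray(list(subset), dtype=int)
    if idx.size == 0:
        warnings.warn("empty subset: zero cumulated responsibility")
        return np.zeros(R.shape[1])
    if idx.size and (idx.min() < 0 or idx.max() >= R.shape[0]):
        raise IndexError("subset index out of range")
    return R[idx].sum(axis=0)
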