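"""Docking-specific analyses on fitted maps.

* IRI(p%) — irreproducibility index of paired docking runs: the fraction of
  total map density sitting in nodes whose population stems predominantly
  (> p) from a single run.
* Explorer-based RMSD cross-prediction with Q/R/M/F verdicts.
* Native-pose ranking ROC (predicted RMSD vs. raw energy).
* Boltzmann-weighted average responsibility (AR) vectors and
  virtual-screening pK landscapes (TvO / AvD scenarios).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import balanced_accuracy_score, roc_auc_score

from .gtm import cumulated_responsibility
from .landscapes import PropertyLandscape
from .pose_pool import NATIVE_RMSD_THRESHOLD

DECOY_PK = 3.0  # presumed-inactive pK assigned to decoys


# ---------------------------------------------------------------- IRI -------

@dataclass
class IRIResult:
    p: float
    iri: float
    node_fractions: np.ndarray  # run-A density fraction per node (NaN if empty)

    def __post_init__(self) -> None:
        if not 0.0 <= self.iri <= 1.0:
            raise ValueError("IRI must lie in [0, 1]")


def iri(R_run_a: np.ndarray, R_run_b: np.ndarray, p: float = 0.85) -> IRIResult:
    """Irreproducibility index of two runs projected on one map.

    With per-node densities D_k = CR_k(A) + CR_k(B) and run-A fraction
    f_k = CR_k(A)/D_k, a node is irreproducible when max(f_k, 1-f_k) > p;
    IRI = sum of irreproducible D_k / sum of all D_k.  Empty nodes are
    excluded.  p must exceed 0.5 for dominance to be well defined.
    """
    if p <= 0.5 or p > 1.0:
        raise ValueError("p must lie in (0.5, 1]")
    if len(R_run_a) == 0 or len(R_run_b) == 0:
        raise ValueError("both runs must be non-empty")
    cr_a = cumulated_responsibility(np.asarray(R_run_a, dtype=float))
    cr_b = cumulated_responsibility(np.asarray(R_run_b, dtype=float))
    d = cr_a + cr_b
    frac = np.full_like(d, np.nan)
    occ = d > 0
    frac[occ] = cr_a[occ] / d[occ]
    dominated = occ & (np.maximum(frac, 1.0 - frac) > p)
    value = float(d[dominated].sum() / d[occ].sum())
    return IRIResult(p, value, frac)


# ------------------------------------------------- RMSD cross-prediction ----

@dataclass
class CrossPredVerdict:
    explorer_id: str
    test_id: str
    r2: float
    ba: float
    auc: float
    label: str
    degenerate: bool = False  # test set lacked one of the two classes


def qrmf_label(r2: float, ba: float, auc: float) -> str:
    """Total verdict function: Q, R, F, else M (evaluated in that order).

    Q: all three criteria > 0.75; R: otherwise ROC AUC > 0.8;
    F: none of the three > 0.6; M: every remaining situation.
    NaN criteria (degenerate test sets) simply never exceed a threshold.
    """
    crits = np.array([r2, ba, auc], dtype=float)
    avail = ~np.isnan(crits)
    if avail.all() and (crits > 0.75).all():
        return "Q"
    if not np.isnan(auc) and auc > 0.8:
        return "R"
    if not (crits[avail] > 0.6).any():
        return "F"
    return "M"


def cross_predict_rmsd(
    explorer_landscape: PropertyLandscape,
    test_R: np.ndarray,
    observed_rmsd: np.ndarray,
    explorer_id: str = "",
    test_id: str = "",
    native_threshold: float = NATIVE_RMSD_THRESHOLD,
) -> CrossPredVerdict:
    """Judge an explorer ligand's RMSD landscape on another ligand's poses.

    ``observed_rmsd`` should be capped consistently with the landscape's
    colouring (6.0 Å).  Criteria: determination coefficient
    r2 = 1 - SSE/SST, balanced accuracy of the native-like call at the
    2 Å threshold, and ROC AUC ranking poses by ascending predicted RMSD
    with observed native-likes as positives.
    """
    observed = np.asarray(observed_rmsd, dtype=float)
    ls = explorer_landscape
    pred = ls.predict(np.asarray(test_R, dtype=float))
    undef = np.isnan(pred)
    pred = np.where(undef, ls.train_mean_, pred)
    sse = float(np.sum((observed - pred) ** 2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    obs_native = observed < native_threshold
    pred_native = pred < native_threshold
    degenerate = len(np.unique(obs_native)) < 2
    if degenerate:
        ba = auc = np.nan
        warnings.warn("test set lacks both classes; BA/AUC undefined")
    else:
        ba = float(balanced_accuracy_score(obs_native, pred_native))
        auc = float(roc_auc_score(obs_native, -pred))
    return CrossPredVerdict(explorer_id, test_id, r2, ba, auc,
                            qrmf_label(r2, ba, auc), degenerate)


def native_ranking_roc(native_like, scores, ascending: bool = True) -> float:
    """ROC AUC for prioritizing native-like poses by a score.

    ``ascending=True`` means lower scores rank first (predicted RMSD or
    energy).  Ties receive midranks (sklearn convention).
    """
    y = np.asarray(native_like, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one native-like and one other pose")
    return float(roc_auc_score(y, -s if ascending else s))


# ---------------------------------------------------------- AR vectors ------

@dataclass
class ARParameters:
    """Boltzmann weighting of a compound's pose ensemble.

    beta = (k_B T)^-1 in (kcal/mol)^-1 of the *unphysical* sampling
    temperature; beta = 0 is plain averaging, large beta collapses onto the
    single most stable pose.  Distinct from the GTM noise precision.
    """

    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


#: default grid covering the plain-averaging limit up to strongly
#: stability-weighted ensembles (the interesting behaviour peaks near 0.3)
DEFAULT_BETA_GRID = (0.0, 0.1, 0.3, 1.0, 3.0)


@dataclass
class ARVector:
    compound_id: str
    ar: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        self.ar = np.asarray(self.ar, dtype=float)
        if abs(self.ar.sum() - 1.0) > 1e-9:
            raise ValueError("AR vector must sum to one")


def ar_vector(
    R: np.ndarray,
    energies,
    params: ARParameters | float = 0.0,
    compound_id: str = "",
) -> ARVector:
    """Boltzmann-weighted average responsibility vector of one compound.

    AR_k = sum_n exp(-beta E_n) R_nk / sum_n exp(-beta E_n); energies are
    shifted by their minimum before exponentiation (overflow-safe,
    mathematically identical).  Sums to one by construction.
    """
    beta = params.beta if isinstance(params, ARParameters) else float(params)
    if beta < 0:
        raise ValueError("beta must be >= 0")
    R = np.asarray(R, dtype=float)
    e = np.asarray(energies, dtype=float)
    if R.shape[0] != e.shape[0] or R.shape[0] == 0:
        raise ValueError("need one energy per pose, at least one pose")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    w = np.exp(-beta * (e - e.min()))
    ar = (w @ R) / w.sum()
    ar = ar / ar.sum()  # renormalize away rounding
    return ARVector(compound_id, ar, beta)


# ------------------------------------------------------ virtual screening ---

SCENARIOS = ("TvO", "AvD")


@dataclass
class ScreenResult:
    pk_pred: np.ndarray  # per test compound (NaN when out of domain)
    auc: float
    scenario: str
    n_undefined: int
    node_values: np.ndarray


def color_pk_landscape(
    color_ar: np.ndarray,
    color_pk,
    min_density: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Node pK values from colour compounds' AR vectors.

    v_k = sum_C AR_k^C pK_C / sum_C AR_k^C where the AR-mass denominator
    exceeds epsilon; other nodes stay undefined (NaN).
    Returns (node values, node AR density).
    """
    A = np.asarray(color_ar, dtype=float)  # (C, K)
    pk = np.asarray(color_pk, dtype=float)
    if A.shape[0] == 0:
        raise ValueError("colour set is empty")
    density = A.sum(axis=0)
    eps = min_density if min_density is not None else 1e-6 * A.shape[0] / A.shape[1]
    defined = density > eps
    v = np.full(A.shape[1], np.nan)
    v[defined] = (A[:, defined] * pk[:, None]).sum(axis=0) / density[defined]
    return v, density


def predict_pk(node_values: np.ndarray, test_ar: np.ndarray,
               coverage_min: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """pK_pred = AR-weighted mean of defined node values, renormalized over
    the defined nodes; returns (predictions, coverage)."""
    A = np.asarray(test_ar, dtype=float)
    defined = ~np.isnan(node_values)
    coverage = A[:, defined].sum(axis=1)
    pred = np.full(A.shape[0], np.nan)
    ok = coverage > 0
    pred[ok] = (A[np.ix_(ok, defined)] @ node_values[defined]) / coverage[ok]
    pred[coverage < coverage_min] = np.nan
    return pred, coverage


def scenario_positives(labels, scenario: str) -> np.ndarray:
    """Positive-class mask: TvO = top vs. the rest; AvD = top+weak vs. decoys."""
    labels = np.asarray(labels)
    if scenario == "TvO":
        return labels == "top"
    if scenario == "AvD":
        return (labels == "top") | (labels == "weak")
    raise ValueError(f"unknown scenario {scenario!r}; valid: {SCENARIOS}")


def screen(
    color_ar: np.ndarray,
    color_pk,
    test_ar: np.ndarray,
    test_labels,
    scenario: str = "TvO",
    min_density: float | None = None,
    coverage_min: float = 0.1,
) -> ScreenResult:
    """Virtual screening: colour a pK landscape, rank test compounds.

    Test compounds whose prediction is undefined (out of applicability
    domain) are excluded from the ROC rather than imputed; their count is
    reported.
    """
    node_values, _ = color_pk_landscape(color_ar, color_pk, min_density)
    pred, _ = predict_pk(node_values, test_ar, coverage_min)
    pos = scenario_positives(test_labels, scenario)
    ok = ~np.isnan(pred)
    n_undef = int((~ok).sum())
    if len(np.unique(pos[ok])) < 2:
        raise ValueError("test set needs both classes among defined predictions")
    auc = float(roc_auc_score(pos[ok], pred[ok]))
    return ScreenResult(pred, auc, scenario, n_undef, node_values)


def half_split(labels, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random half-split of compound indices, stratified by label.

    Returns (colour indices, test indices).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    color, test = [], []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        rng.shuffle(idx)
        half = idx.size // 2
        color.extend(idx[:half])
        test.extend(idx[half:])
    return np.array(sorted(color)), np.array(sorted(test))
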