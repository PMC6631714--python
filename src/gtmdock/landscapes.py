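"""Property and class landscapes on a fitted map.

A landscape assigns each node the responsibility-weighted mean of its
residents' property values (regression) or per-class cumulated
responsibilities (classification), together with a node density.  New items
acquire predictions as density-aware weighted means over *defined* nodes;
the summed responsibility they place on defined nodes is their coverage
(applicability-domain weight — "white spots" give coverage near zero).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .gtm import GTM, cumulated_responsibility


def _resolve_R(gtm: GTM | None, X, precomputed: bool) -> np.ndarray:
    if precomputed:
        return np.asarray(X, dtype=float)
    if gtm is None:
        raise ValueError("either pass a fitted GTM or precomputed responsibilities")
    return gtm.transform(X)


class PropertyLandscape(BaseEstimator, RegressorMixin):
    """Regression landscape: node values are responsibility-weighted means.

    Parameters
    ----------
    gtm : fitted GTM or None
        When None, ``fit``/``predict`` expect precomputed responsibility
        matrices instead of raw descriptors.
    min_density : float or None
        Node defined-ness threshold epsilon; defaults to 1e-6 x N/K.
    coverage_min : float
        Predictions whose coverage falls below this are returned as NaN.
    """

    def __init__(self, gtm: GTM | None = None, min_density: float | None = None,
                 coverage_min: float = 0.1):
        self.gtm = gtm
        self.min_density = min_density
        self.coverage_min = coverage_min

    def fit(self, X, y):
        R = _resolve_R(self.gtm, X, self.gtm is None)
        y = np.asarray(y, dtype=float)
        if R.shape[0] != y.shape[0]:
            raise ValueError("X and y sizes differ")
        density = R.sum(axis=0)
        eps = self.min_density
        if eps is None:
            eps = 1e-6 * R.shape[0] / R.shape[1]
        defined = density > eps
        if not defined.any():
            raise ValueError("no populated nodes: landscape undefined everywhere")
        values = np.full(R.shape[1], np.nan)
        values[defined] = (R[:, defined] * y[:, None]).sum(axis=0) / density[defined]
        self.node_values_ = values
        self.node_density_ = density
        self.defined_mask_ = defined
        self.train_mean_ = float(y.mean())
        self.n_features_in_ = None if self.gtm is None else self.gtm.n_features_in_
        return self

    def predict_with_coverage(self, X):
        """(predictions, coverage); prediction is NaN below coverage_min."""
        check_is_fitted(self, "node_values_")
        R = _resolve_R(self.gtm, X, self.gtm is None)
        d = self.defined_mask_
        coverage = R[:, d].sum(axis=1)
        pred = np.full(R.shape[0], np.nan)
        ok = coverage > 0
        pred[ok] = (R[np.ix_(ok, d)] @ self.node_values_[d]) / coverage[ok]
        pred[coverage < self.coverage_min] = np.nan
        return pred, coverage

    def predict(self, X):
        return self.predict_with_coverage(X)[0]


class ClassLandscape(BaseEstimator):
    """Classification landscape: per-class cumulated responsibilities.

    Stores CR_k^C per class; the class with maximal CR "wins" each node
    (ties break to the lower class index and are flagged).  For two-class
    problems the fuzzy value per node is the responsibility-weighted mean
    of the numeric class labels.
    """

    def __init__(self, gtm: GTM | None = None, min_density: float | None = None):
        self.gtm = gtm
        self.min_density = min_density

    def fit(self, X, labels):
        R = _resolve_R(self.gtm, X, self.gtm is None)
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if classes.size < 2:
            warnings.warn("single-class input: degenerate class landscape")
        cr = np.stack([cumulated_responsibility(R, np.nonzero(labels == c)[0])
                       for c in classes])  # (C, K)
        density = R.sum(axis=0)
        eps = self.min_density
        if eps is None:
            eps = 1e-6 * R.shape[0] / R.shape[1]
        defined = density > eps
        self.classes_ = classes
        self.class_density_ = cr
        self.node_density_ = density
        self.defined_mask_ = defined
        win = np.argmax(cr, axis=0)  # argmax takes the first (lowest) on ties
        self.winning_class_ = np.where(defined, classes[win], classes[0])
        if cr.shape[0] > 1:
            sorted_cr = np.sort(cr, axis=0)
            self.tie_mask_ = defined & np.isclose(sorted_cr[-1], sorted_cr[-2])
        else:
            self.tie_mask_ = np.zeros_like(defined)
        numeric = np.asarray(labels, dtype=float) if np.issubdtype(
            np.asarray(labels).dtype, np.number) else None
        if numeric is not None:
            vals = np.full(R.shape[1], np.nan)
            vals[defined] = (R[:, defined] * numeric[:, None]).sum(axis=0) / density[defined]
            self.fuzzy_values_ = vals
        else:
            self.fuzzy_values_ = None
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "class_density_")
        R = _resolve_R(self.gtm, X, self.gtm is None)
        node_tot = self.class_density_.sum(axis=0)  # (K,)
        with np.errstate(invalid="ignore", divide="ignore"):
            node_p = np.where(node_tot > 0, self.class_density_ / node_tot, 0.0)  # (C, K)
        raw = R @ node_p.T  # (N, C)
        s = raw.sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        return raw / s

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class CVReport:
    q2_values: list[float]
    rmse: float
    folds: int
    repeats: int
    seed: int
    n_undefined: int = 0

    @property
    def mean_q2(self) -> float:
        return float(np.mean(self.q2_values))

    @property
    def sd_q2(self) -> float:
        return float(np.std(self.q2_values, ddof=0))


@dataclass
class MapFitness:
    """Fitness of a map over one or more properties: mean Q2 minus one SD."""

    q2_by_property: dict[str, list[float]]

    @property
    def fitness(self) -> float:
        all_q2 = [q for qs in self.q2_by_property.values() for q in qs]
        return float(np.mean(all_q2) - np.std(all_q2, ddof=0))


def _quartile_strata(y: np.ndarray) -> np.ndarray:
    qs = np.quantile(y, [0.25, 0.5, 0.75])
    return np.searchsorted(qs, y)


def cross_validate(
    gtm: GTM,
    X,
    y,
    folds: int = 3,
    repeats: int = 3,
    seed: int = 0,
    refit_manifold: bool = False,
    min_density: float | None = None,
    coverage_min: float = 0.1,
) -> CVReport:
    """Repeated k-fold landscape cross-validation on a map.

    The manifold is kept fixed by default (folds re-colour the landscape
    only); ``refit_manifold`` refits the map on each training fold.
    Q2 = 1 - SSE/SST with SST around the *training* mean; left-out items
    with undefined predictions are imputed with the training mean and
    counted.  Regression folds are stratified by property quartile.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < folds:
        raise ValueError("fewer items than folds")
    q2s, sses, n_undef = [], [], 0
    strata = _quartile_strata(y)
    for rep in range(repeats):
        rng = np.random.default_rng(seed + 7919 * rep)
        fold_of = np.empty(n, dtype=int)
        for s in np.unique(strata):
            idx = np.nonzero(strata == s)[0]
            rng.shuffle(idx)
            fold_of[idx] = np.arange(idx.size) % folds
        for f in range(folds):
            test = fold_of == f
            train = ~test
            model = gtm
            if refit_manifold:
                model = GTM(**gtm.get_params()).fit(X[train])
            ls = PropertyLandscape(model, min_density=min_density,
                                   coverage_min=coverage_min)
            ls.fit(X[train], y[train])
            pred = ls.predict(X[test])
            undef = np.isnan(pred)
            n_undef += int(undef.sum())
            pred[undef] = ls.train_mean_
            sse = float(np.sum((y[test] - pred) ** 2))
            sst = float(np.sum((y[test] - ls.train_mean_) ** 2))
            q2s.append(1.0 - sse / sst if sst > 0 else 0.0)
            sses.append((sse, test.sum()))
    rmse = float(np.sqrt(sum(s for s, _ in sses) / sum(m for _, m in sses)))
    return CVReport(q2s, rmse, folds, repeats, seed, n_undef)


def map_fitness(
    gtm_params: dict,
    X,
    properties: dict[str, np.ndarray],
    folds: int = 3,
    repeats: int = 3,
    seed: int = 0,
) -> MapFitness:
    """Fit a map with the given parameters and cross-validate each property."""
    gtm = GTM(**gtm_params).fit(X)
    q2 = {
        name: cross_validate(gtm, X, y, folds=folds, repeats=repeats, seed=seed).q2_values
        for name, y in properties.items()
    }
    return MapFitness(q2)


def optimize_map(
    search_space: dict[str, list],
    datasets: dict[str, np.ndarray],
    properties: dict[str, np.ndarray],
    budget: int = 200,
    seed: int = 0,
    population: int = 20,
    tournament: int = 3,
    mutation_rate: float = 0.2,
    crossover_rate: float = 0.5,
    folds: int = 3,
    repeats: int = 3,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Elitist genetic search over map hyper-parameters and descriptor scheme.

    ``search_space`` maps parameter names to candidate values; the special
    key ``"descriptor"`` selects among the matrices in ``datasets`` (this is
    how the fragment-scheme choice of Hybrid maps enters the search).  The
    fitness of a candidate is mean cross-validated Q2 minus one SD over all
    properties.  Deterministic under ``seed``; ``budget`` counts fitness
    evaluations.  Returns (best candidate, evaluation trace).
    """
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ValueError("empty search space")
    if not properties:
        raise ValueError("at least one property is required")
    keys = sorted(search_space)
    rng = np.random.default_rng(seed)
    cache: dict[tuple, float] = {}
    trace: list[tuple[dict, float]] = []
    evals = 0

    def evaluate(cand: dict) -> float:
        nonlocal evals
        sig = tuple(cand[k] for k in keys)
        if sig in cache:
            return cache[sig]
        params = {k: v for k, v in cand.items() if k != "descriptor"}
        X = datasets[cand["descriptor"]] if "descriptor" in cand else next(iter(datasets.values()))
        try:
            fit = map_fitness(params, X, properties, folds=folds, repeats=repeats, seed=seed)
            score = fit.fitness
        except (ValueError, np.linalg.LinAlgError):
            score = -np.inf
        cache[sig] = score
        trace.append((dict(cand), score))
        evals += 1
        return score

    def random_candidate() -> dict:
        return {k: search_space[k][rng.integers(len(search_space[k]))] for k in keys}

    # exhaustive space smaller than the population: just enumerate
    total = int(np.prod([len(search_space[k]) for k in keys]))
    if total <= population:
        from itertools import product

        cands = [dict(zip(keys, vals)) for vals in product(*(search_space[k] for k in keys))]
        for c in cands:
            if evals >= budget:
                break
            evaluate(c)
        best = max(trace, key=lambda t: t[1])
        return best[0], trace

    pop = [random_candidate() for _ in range(population)]
    scores = [evaluate(c) for c in pop[: min(population, budget)]]
    pop = pop[: len(scores)]
    while evals < budget:
        def pick() -> dict:
            idx = rng.integers(len(pop), size=tournament)
            return pop[max(idx, key=lambda i: scores[i])]

        a, b = pick(), pick()
        child = {
            k: (a[k] if rng.random() >= crossover_rate else b[k]) for k in keys
        }
        for k in keys:
            if rng.random() < mutation_rate:
                child[k] = search_space[k][rng.integers(len(search_space[k]))]
        s = evaluate(child)
        worst = int(np.argmin(scores))
        if s > scores[worst]:  # elitist replacement
            pop[worst] = child
            scores[worst] = s
    best = max(trace, key=lambda t: t[1])
    return best[0], trace
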