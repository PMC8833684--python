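"""Eliminative feature-selection algorithms.

All selectors share one contract: consume a feature table (and, for the
supervised ones, a binary label vector plus parameters), return a
:class:`SelectionResult` whose ``selected`` list is a subset of the input
features. Families:

``select_random``
    uniform subset of size p — the reference any engineered selector
    must beat.
``select_hcfr``
    unsupervised decorrelation: single-linkage clustering of features at
    affinity 1 - |r|, one random representative per cluster, so no two
    selected features have |r| above the threshold.
``select_rfe`` / ``select_rfe_cv_auto``
    recursive feature elimination under the linear-discriminant wrapper:
    repeatedly refit, drop the least important features by |omega|, until
    a target count (explicit) or an accuracy/feature-count trade-off on
    the cross-validated path (implicit) is reached.
``haff_filter``
    preprocessing that repeatedly removes the weaker member of every
    strongly anti-correlated feature pair (r < -T); such pairs carry
    large opposing weights that corrupt |omega| as an importance signal.
``select_sda``
    sparse discriminant analysis: elastic-net penalized optimal scoring,
    with the L1 weight tuned by bisection until exactly p coefficients
    are non-zero.
``select_ga`` / ``ga_fitness``
    binary-mask genetic algorithm minimizing a weighted sum of a
    cardinality-excess penalty and the negative cross-validated balanced
    accuracy.
``dual_phase``
    SDAqGAp / RFEqGAp: a fast first-phase reduction to ~q features
    followed by combinatorial GA refinement down to p, optionally after
    the anti-correlation prefilter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.linear_model import ElasticNet

from .catalog_io import FeatureTable
from .classify import (
    CVScheme,
    balanced_accuracy,
    cv_bacc,
    feature_importance,
    fit_lda,
    predict,
)

__all__ = [
    "SelectionResult",
    "HCFRParams",
    "RFEParams",
    "SDAParams",
    "GAParams",
    "HAFFParams",
    "select_random",
    "select_hcfr",
    "select_rfe",
    "select_rfe_cv_auto",
    "haff_filter",
    "select_sda",
    "ga_fitness",
    "select_ga",
    "dual_phase",
]


@dataclass
class SelectionResult:
    selected: list[str]
    selector_name: str
    params: dict = field(default_factory=dict)
    #: (active_feature_count, bacc_mean, bacc_sd) per step
    trace: list[tuple[int, float, float]] = field(default_factory=list)
    seed: Optional[int] = None
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected features must be unique")


@dataclass
class HCFRParams:
    max_correlation: float = 0.95
    seed: int = 0


@dataclass
class HAFFParams:
    threshold: float = 0.95


@dataclass
class RFEParams:
    target_p: int
    step_n: int = 1
    cv: Optional[CVScheme] = None
    haff: Optional[HAFFParams] = None


@dataclass
class SDAParams:
    target_p: int
    gamma: float = 0.1
    lambda_bracket: Optional[tuple[float, float]] = None
    tol: float = 1e-8


@dataclass
class GAParams:
    target_p: int
    lambda1: float = 1.0
    lambda2: float = 1.0
    population: int = 60
    generations: int = 150
    crossover_prob: float = 0.7
    mutation_prob: Optional[float] = None  # default 1/d
    seed: int = 0
    #: "corrected_max" penalizes exceeding p; "printed_min" is the
    #: alternative form that rewards subsets smaller than p
    penalty_form: str = "corrected_max"


# ---------------------------------------------------------------- random


def select_random(table: FeatureTable, p: int, seed: int = 0) -> SelectionResult:
    """Uniform random subset of exactly p features, without replacement."""
    d = table.n_features
    if not 1 <= p <= d:
        raise ValueError(f"p={p} out of range 1..{d}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(d, size=p, replace=False))
    return SelectionResult(
        [table.feature_names[j] for j in idx],
        "RND",
        {"p": p},
        seed=seed,
    )


# ----------------------------------------------------------------- HCFR


def _abs_corr(values: np.ndarray) -> np.ndarray:
    C = np.corrcoef(values, rowvar=False)
    return np.clip(np.abs(C), 0.0, 1.0)


def select_hcfr(table: FeatureTable, params: HCFRParams) -> SelectionResult:
    """Highly-correlated-feature removal.

    Single linkage guarantees that after cutting the dendrogram at
    distance 1 - S every cross-cluster pair has distance > 1 - S, i.e.
    |r| < S, so picking one representative per cluster enforces the
    pairwise correlation bound exactly. Zero-variance features have no
    defined correlation and become singleton clusters, flagged in
    ``details``.
    """
    S = params.max_correlation
    if not 0 < S < 1:
        raise ValueError("max_correlation must be in (0, 1)")
    d = table.n_features
    if d < 2:
        raise ValueError("need at least two features")
    std = table.values.std(axis=0)
    varying = np.flatnonzero(std > 0)
    constant = np.flatnonzero(std == 0)

    clusters: list[list[int]] = [[int(j)] for j in constant]
    if varying.size >= 2:
        D = 1.0 - _abs_corr(table.values[:, varying])
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="single")
        assign = fcluster(Z, t=1.0 - S, criterion="distance")
        for c in np.unique(assign):
            clusters.append([int(varying[i]) for i in np.flatnonzero(assign == c)])
    elif varying.size == 1:
        clusters.append([int(varying[0])])

    clusters.sort(key=min)
    rng = np.random.default_rng(params.seed)
    chosen = sorted(int(rng.choice(members)) for members in clusters)
    return SelectionResult(
        [table.feature_names[j] for j in chosen],
        "HCFR",
        {"max_correlation": S},
        seed=params.seed,
        details={
            "n_clusters": len(clusters),
            "constant_features": [table.feature_names[j] for j in constant],
        },
    )


# ------------------------------------------------------------------ RFE


def _step_importance_and_bacc(
    values: np.ndarray, y: np.ndarray, cv: Optional[CVScheme]
) -> tuple[np.ndarray, float, float]:
    """Importance plus accuracy for one elimination step.

    Without CV: a single fit, resubstitution accuracy. With CV: per-fold
    importances are averaged as mean(|omega|) — not |mean(omega)| — so
    sign flips across folds cannot cancel, and accuracy is the held-out
    fold mean/sd.
    """
    if cv is None:
        model = fit_lda(values, y)
        bacc = balanced_accuracy(y, predict(model, values))
        return feature_importance(model), bacc, 0.0
    imps, baccs = [], []
    for train, test in cv.splits(y):
        model = fit_lda(values[train], y[train])
        imps.append(feature_importance(model))
        baccs.append(balanced_accuracy(y[test], predict(model, values[test])))
    baccs = np.asarray(baccs)
    return np.mean(imps, axis=0), float(baccs.mean()), float(baccs.std())


def _rfe_path(
    table: FeatureTable,
    y: np.ndarray,
    target_p: int,
    step_n: int,
    cv: Optional[CVScheme],
    record_subsets: bool = False,
):
    """Eliminate down to target_p; ties on |omega| drop the larger index."""
    y = np.asarray(y, dtype=int).ravel()
    active = list(range(table.n_features))
    trace: list[tuple[int, float, float]] = []
    subsets: dict[int, list[int]] = {}
    while len(active) > target_p:
        imp, mean, sd = _step_importance_and_bacc(
            table.values[:, active], y, cv
        )
        trace.append((len(active), mean, sd))
        if record_subsets:
            subsets[len(active)] = list(active)
        n_drop = min(step_n, len(active) - target_p)
        # sort by importance ascending, breaking ties toward larger index
        order = np.lexsort((-np.asarray(active), imp))
        drop = {active[i] for i in order[:n_drop]}
        active = [j for j in active if j not in drop]
    if record_subsets:
        imp, mean, sd = _step_importance_and_bacc(table.values[:, active], y, cv)
        trace.append((len(active), mean, sd))
        subsets[len(active)] = list(active)
    return active, trace, subsets


def select_rfe(table: FeatureTable, y, params: RFEParams) -> SelectionResult:
    """Recursive feature elimination to exactly ``target_p`` features.

    With ``params.cv`` set this is RFE-CV: importances and accuracies are
    fold averages. With ``params.haff`` set the anti-correlated-pair
    filter runs first and elimination proceeds on the survivors.
    """
    if not 1 <= params.target_p <= table.n_features:
        raise ValueError("target_p out of range")
    work = table
    haff_trace: list[tuple[int, float, float]] = []
    if params.haff is not None:
        pre = haff_filter(table, y, params.haff)
        work = table.subset(pre.selected)
        haff_trace = pre.trace
    active, trace, _ = _rfe_path(work, y, params.target_p, params.step_n, params.cv)
    name = "RFECV" if params.cv is not None else "RFE"
    return SelectionResult(
        [work.feature_names[j] for j in active],
        name,
        {
            "target_p": params.target_p,
            "step_n": params.step_n,
            "haff": params.haff is not None,
        },
        trace=haff_trace + trace,
    )


def select_rfe_cv_auto(
    table: FeatureTable,
    y,
    scheme: CVScheme,
    trade_off_sd: float = 1.0,
) -> SelectionResult:
    """RFE-CV with the feature count chosen from the accuracy path.

    Runs the full elimination path down to one feature, then returns the
    smallest feature count whose fold-mean accuracy is within
    ``trade_off_sd`` fold-sds (at the best step) of the best fold-mean.
    With trade_off_sd = 0 this is the count achieving the maximum mean,
    smallest count on ties.
    """
    _, trace, subsets = _rfe_path(table, y, 1, 1, scheme, record_subsets=True)
    means = {count: mean for count, mean, _ in trace}
    sds = {count: sd for count, _, sd in trace}
    best_mean = max(means.values())
    best_count = min(c for c, m in means.items() if m == best_mean)
    cutoff = best_mean - trade_off_sd * sds[best_count]
    chosen = min(c for c, m in means.items() if m >= cutoff)
    return SelectionResult(
        [table.feature_names[j] for j in subsets[chosen]],
        "RFECV",
        {"trade_off_sd": trade_off_sd, "k": scheme.k},
        trace=trace,
        details={"chosen_count": chosen, "best_count": best_count,
                 "best_mean": best_mean},
    )


# ----------------------------------------------------------------- HAFF


def haff_filter(table: FeatureTable, y, params: HAFFParams) -> SelectionResult:
    """Highly anti-weighted feature elimination filter.

    Anti-correlated feature pairs (r < -T) drive linear discriminants to
    large opposing weights, so at least one pair member looks far more
    important than it is. The filter repeatedly finds every pair below
    -T among the active features, removes from each pair the member with
    the smaller fitted |omega| (ties drop the larger column index),
    refits, and stops when no such pair remains.
    """
    T = params.threshold
    if not 0 < T < 1:
        raise ValueError("threshold must be in (0, 1)")
    y = np.asarray(y, dtype=int).ravel()
    active = list(range(table.n_features))
    trace: list[tuple[int, float, float]] = []
    removed: list[str] = []
    while len(active) >= 2:
        vals = table.values[:, active]
        std = vals.std(axis=0)
        varying = std > 0
        C = np.corrcoef(vals[:, varying], rowvar=False) if varying.sum() >= 2 else np.empty((0, 0))
        vmap = np.flatnonzero(varying)
        pairs = [
            (int(vmap[i]), int(vmap[j]))
            for i, j in zip(*np.nonzero(np.triu(C < -T, k=1)))
        ]
        if not pairs:
            break
        model = fit_lda(vals, y)
        imp = feature_importance(model)
        trace.append(
            (len(active), balanced_accuracy(y, predict(model, vals)), 0.0)
        )
        drop_local: set[int] = set()
        for i, j in pairs:
            if imp[i] < imp[j] or (imp[i] == imp[j] and active[i] > active[j]):
                drop_local.add(i)
            else:
                drop_local.add(j)
        removed.extend(table.feature_names[active[i]] for i in sorted(drop_local))
        active = [a for k, a in enumerate(active) if k not in drop_local]
    return SelectionResult(
        [table.feature_names[j] for j in active],
        "HAFF",
        {"threshold": T},
        trace=trace,
        details={"removed": removed},
    )


# ------------------------------------------------------------------ SDA


def _sda_design(table: FeatureTable, y: np.ndarray):
    """Standardized feature matrix and centered class-indicator response."""
    X = table.values
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0.0] = 1.0
    Z = (X - mean) / std
    yc = y - y.mean()
    return Z, yc


def _sda_solve(Z: np.ndarray, yc: np.ndarray, lam: float, gamma: float) -> np.ndarray:
    """Minimize ||yc - Z b||^2 + lam ||b||_1 + gamma ||b||_2^2."""
    n, d = Z.shape
    if lam <= 0.0:
        if gamma <= 0.0:
            return np.linalg.lstsq(Z, yc, rcond=None)[0]
        return np.linalg.solve(Z.T @ Z + gamma * np.eye(d), Z.T @ yc)
    a_l1 = lam / (2.0 * n)
    a_l2 = gamma / n
    alpha = a_l1 + a_l2
    enet = ElasticNet(
        alpha=alpha,
        l1_ratio=a_l1 / alpha,
        fit_intercept=False,
        max_iter=50000,
        tol=1e-8,
    )
    enet.fit(Z, yc)
    return enet.coef_.copy()


def select_sda(table: FeatureTable, y, params: SDAParams) -> SelectionResult:
    """Sparse discriminant analysis via penalized optimal scoring.

    For the two-class problem the discriminant direction is obtained by
    elastic-net regression of the centered class indicator on the
    standardized features; the L1 weight lambda is tuned by bisection so
    that exactly ``target_p`` coefficients are non-zero, and a linear
    discriminant is then refit on the support to record its accuracy. If
    no lambda in the bracket attains the exact cardinality (the support
    size jumps past p), the closest achievable support is returned and
    ``details["cardinality_miss"]`` is set.
    """
    y = np.asarray(y, dtype=int).ravel()
    d = table.n_features
    p = params.target_p
    if not 1 <= p <= d:
        raise ValueError("target_p out of range")
    Z, yc = _sda_design(table, y)

    if p == d:
        beta = _sda_solve(Z, yc, 0.0, params.gamma)
        support = np.arange(d)
        lam = 0.0
        miss = False
    else:
        lam_max = 2.0 * float(np.max(np.abs(Z.T @ yc))) * 1.001
        if params.lambda_bracket is not None:
            lo, hi = params.lambda_bracket
        else:
            lo, hi = lam_max * 1e-8, lam_max

        def support_of(lam: float) -> np.ndarray:
            return np.flatnonzero(np.abs(_sda_solve(Z, yc, lam, params.gamma)) > 1e-10)

        if params.lambda_bracket is None:
            # widen the lower edge until the support covers p (elastic-net
            # ridge keeps the saturated support above the sample size)
            for _ in range(8):
                if support_of(lo).size >= p:
                    break
                lo /= 100.0
        best_lam, best_supp = None, None
        lo_s, hi_s = support_of(lo), support_of(hi)
        candidates = [(lo, lo_s), (hi, hi_s)]
        for _ in range(80):
            mid = np.sqrt(lo * hi) if lo > 0 else (lo + hi) / 2.0
            supp = support_of(mid)
            candidates.append((mid, supp))
            if supp.size == p:
                best_lam, best_supp = mid, supp
                break
            if supp.size > p:
                lo = mid
            else:
                hi = mid
            if hi - lo < params.tol * max(hi, 1.0):
                break
        miss = best_lam is None
        if miss:
            best_lam, best_supp = min(
                candidates, key=lambda c: (abs(c[1].size - p), c[0])
            )
        lam, support = best_lam, best_supp
        beta = _sda_solve(Z, yc, lam, params.gamma)

    selected = [table.feature_names[j] for j in support]
    details: dict = {"beta": beta, "lambda": lam, "gamma": params.gamma}
    if p != d and miss:
        details["cardinality_miss"] = (
            f"support size {len(selected)} != target {p}: exact cardinality "
            "unattainable within the lambda bracket"
        )
    trace: list[tuple[int, float, float]] = []
    if len(selected) >= 1 and np.unique(y).size == 2:
        sub = table.subset(selected)
        model = fit_lda(sub, y)
        bacc = balanced_accuracy(y, predict(model, sub))
        trace.append((len(selected), bacc, 0.0))
        details["refit_bacc"] = bacc
    return SelectionResult(
        selected,
        "SDA",
        {"target_p": p, "gamma": params.gamma},
        trace=trace,
        details=details,
    )


# ------------------------------------------------------------------- GA


def ga_fitness(
    mask: np.ndarray,
    table: FeatureTable,
    y,
    params: GAParams,
    scheme: CVScheme,
) -> float:
    """Weighted-sum GA objective, minimized.

    c1 penalizes the cardinality relative to the soft target p
    (default: excess only, max(|P| - p, 0)); c2 is the negative
    cross-validated balanced accuracy of the discriminant on the masked
    features, with the empty mask pinned at chance (-0.5).
    """
    mask = np.asarray(mask, dtype=bool)
    size = int(mask.sum())
    if params.penalty_form == "corrected_max":
        c1 = max(size - params.target_p, 0)
    elif params.penalty_form == "printed_min":
        c1 = min(size - params.target_p, 0)
    else:
        raise ValueError(f"unknown penalty_form {params.penalty_form!r}")
    if size == 0:
        c2 = -0.5
    else:
        c2 = -cv_bacc(table.values[:, mask], y, scheme).mean
    return params.lambda1 * c1 + params.lambda2 * c2


def _tournament(rng, fitnesses: np.ndarray, size: int = 3) -> int:
    contenders = rng.integers(0, len(fitnesses), size=size)
    return int(contenders[np.argmin(fitnesses[contenders])])


def select_ga(
    table: FeatureTable,
    y,
    params: GAParams,
    scheme: CVScheme,
) -> SelectionResult:
    """Binary-mask genetic algorithm over feature subsets.

    Tournament selection (size 3), uniform crossover, per-bit flip
    mutation and single-individual elitism; fully deterministic given
    (data, params, seed). The feature-count limit is soft: the returned
    subset may be smaller than p, and larger only if the penalized
    fitness still wins.
    """
    if params.population < 4:
        raise ValueError("population must be at least 4")
    y = np.asarray(y, dtype=int).ravel()
    d = table.n_features
    pm = params.mutation_prob if params.mutation_prob is not None else 1.0 / d
    rng = np.random.default_rng(params.seed)
    cache: dict[bytes, tuple[float, float, float]] = {}

    def evaluate(mask: np.ndarray) -> tuple[float, float, float]:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            size = int(mask.sum())
            if size == 0:
                mean, sd = 0.5, 0.0
            else:
                res = cv_bacc(table.values[:, mask.astype(bool)], y, scheme)
                mean, sd = res.mean, res.sd
            if params.penalty_form == "corrected_max":
                c1 = max(size - params.target_p, 0)
            else:
                c1 = min(size - params.target_p, 0)
            cache[key] = (params.lambda1 * c1 - params.lambda2 * mean, mean, sd)
        return cache[key]

    pop = rng.integers(0, 2, size=(params.population, d)).astype(bool)
    fits = np.array([evaluate(ind)[0] for ind in pop])
    trace: list[tuple[int, float, float]] = []
    best_per_gen: list[float] = []

    for _ in range(params.generations):
        elite_idx = int(np.argmin(fits))
        elite = pop[elite_idx].copy()
        children = [elite]
        while len(children) < params.population:
            p1 = pop[_tournament(rng, fits)].copy()
            p2 = pop[_tournament(rng, fits)].copy()
            if rng.random() < params.crossover_prob:
                swap = rng.random(d) < 0.5
                p1[swap], p2[swap] = p2[swap], p1[swap].copy()
            for child in (p1, p2):
                flip = rng.random(d) < pm
                child[flip] = ~child[flip]
                children.append(child)
        pop = np.array(children[: params.population])
        fits = np.array([evaluate(ind)[0] for ind in pop])
        b = int(np.argmin(fits))
        fit_b, mean_b, sd_b = evaluate(pop[b])
        best_per_gen.append(fit_b)
        trace.append((int(pop[b].sum()), mean_b, sd_b))

    best = pop[int(np.argmin(fits))]
    best_fit, best_mean, best_sd = evaluate(best)
    return SelectionResult(
        [table.feature_names[j] for j in np.flatnonzero(best)],
        "GA",
        {
            "target_p": params.target_p,
            "population": params.population,
            "generations": params.generations,
        },
        trace=trace,
        seed=params.seed,
        details={
            "best_fitness": best_fit,
            "best_fitness_per_generation": best_per_gen,
            "best_cv_bacc": best_mean,
            "n_unique_masks_evaluated": len(cache),
        },
    )


# ----------------------------------------------------------- dual phase


def dual_phase(
    table: FeatureTable,
    y,
    phase1: str,
    q: int,
    ga_params: GAParams,
    scheme: CVScheme,
    haff: Optional[HAFFParams] = None,
    seed: int = 0,
    phase1_params=None,
) -> SelectionResult:
    """Two-phase elimination: SDA or RFE down to q, then GA down to p.

    The optional anti-correlation prefilter runs before phase 1. The GA
    operates only on the phase-1 survivors, so its search space shrinks
    from 2^d to 2^q.
    """
    if phase1 not in ("SDA", "RFE"):
        raise ValueError("phase1 must be 'SDA' or 'RFE'")
    if not ga_params.target_p <= q <= table.n_features:
        raise ValueError("require p <= q <= d")
    y = np.asarray(y, dtype=int).ravel()
    trace: list[tuple[int, float, float]] = []
    details: dict = {}
    work = table
    if haff is not None:
        pre = haff_filter(table, y, haff)
        work = table.subset(pre.selected)
        trace += pre.trace
        details["haff_removed"] = pre.details["removed"]

    if q >= work.n_features:
        phase1_selected = list(work.feature_names)
    elif phase1 == "SDA":
        p1 = phase1_params or SDAParams(target_p=q)
        res1 = select_sda(work, y, p1)
        phase1_selected = res1.selected
        trace += res1.trace
        details["phase1"] = {k: v for k, v in res1.details.items() if k != "beta"}
    else:
        p1 = phase1_params or RFEParams(target_p=q)
        res1 = select_rfe(work, y, p1)
        phase1_selected = res1.selected
        trace += res1.trace

    reduced = work.subset(phase1_selected)
    ga = GAParams(**{**ga_params.__dict__, "seed": seed})
    res2 = select_ga(reduced, y, ga, scheme)
    trace += res2.trace
    details["ga"] = res2.details

    from .benchmark import make_run_name  # late import avoids a cycle

    name = make_run_name(phase1, q, "GA", ga.target_p, haff is not None, "BACC")
    return SelectionResult(
        res2.selected,
        name,
        {"phase1": phase1, "q": q, "p": ga.target_p, "haff": haff is not None},
        trace=trace,
        seed=seed,
        details=details,
    )
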