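"""Stage-specific interaction network identification.

For every target protein i, the levels of its candidate interactors form the
regression design and the model

    y_i = sum_k alpha_ik y_k + beta_i + eps_i,   beta_i >= 0

is identified by constrained least squares. The model order (how many of the
candidate interactors are real) is chosen by minimizing

    AIC_i(L) = log(RSS / M) + 2 L / M

via greedy forward selection with interleaved backward elimination, after
which each retained activity alpha_ik is tested against zero with a Student
t-test and dropped when p >= 0.05. Assembling the per-target coefficients
yields the weighted directed stage network N[i, k] = alpha_ik.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .preprocess import ExpressionMatrix

Edge = tuple[str, str]  # (target, interactor)


@dataclass
class CandidateNetwork:
    """Undirected candidate interactions restricted to measured proteins."""

    proteins: list[str]
    neighbors: dict[str, set[str]]

    def __post_init__(self) -> None:
        for p, ns in self.neighbors.items():
            if p in ns:
                raise ValueError(f"self pair on {p}")
            for q in ns:
                if p not in self.neighbors.get(q, set()):
                    raise ValueError(f"asymmetric candidate pair ({p},{q})")

    @property
    def n_pairs(self) -> int:
        return sum(len(ns) for ns in self.neighbors.values()) // 2

    def pairs(self) -> set[tuple[str, str]]:
        out = set()
        for p, ns in self.neighbors.items():
            for q in ns:
                out.add((p, q) if p <= q else (q, p))
        return out


def assemble_candidate_network(edges, measured_genes) -> CandidateNetwork:
    """Intersect a candidate pair list with the measured gene universe.

    Pairs with an unmeasured endpoint, self pairs and duplicates are dropped;
    the surviving endpoints become the candidate network's proteins.
    """
    measured = set(measured_genes)
    neighbors: dict[str, set[str]] = {}
    for a, b in edges:
        if a == b or a not in measured or b not in measured:
            continue
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    return CandidateNetwork(proteins=sorted(neighbors), neighbors=neighbors)


@dataclass
class ProteinModelFit:
    """Identified interaction model for one target protein."""

    target: str
    selected: tuple[str, ...]
    alpha: dict[str, float]
    beta: float
    rss: float
    aic: float
    n_samples: int
    pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def order(self) -> int:
        return len(self.selected)


def fit_constrained_lsq(design: np.ndarray, y: np.ndarray):
    """Least squares with a nonnegative intercept.

    ``design`` is S x (L+1) with the interactor profiles in the first L
    columns and the intercept column (ones) last. Minimizes ||design @ theta
    - y||^2 subject to theta[-1] >= 0; the activities are unconstrained. With
    a single inequality constraint the active-set solution is closed-form:
    take the unconstrained minimizer, and if its intercept is negative clamp
    the intercept to zero and re-solve for the activities.

    Returns ``(alpha, beta, rss)``. A rank-deficient design yields the
    minimum-norm solution with a warning.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design/response shape mismatch")
    n_cols = X.shape[1]
    theta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < n_cols:
        warnings.warn("rank-deficient design: returning minimum-norm solution")
    if theta[-1] < 0:
        if n_cols == 1:
            theta = np.zeros(1)
        else:
            a, _, rank_a, _ = np.linalg.lstsq(X[:, :-1], y, rcond=None)
            if rank_a < n_cols - 1:
                warnings.warn("rank-deficient design: returning minimum-norm solution")
            theta = np.append(a, 0.0)
    resid = y - X @ theta
    return theta[:-1].copy(), float(theta[-1]), float(resid @ resid)


def aic(rss: float, n_samples: int, order: int) -> float:
    """AIC of an identified model: log(rss / M) + 2 L / M (natural log).

    A perfect fit (rss = 0) returns -inf so that it dominates any imperfect
    fit; ties between perfect fits are broken elsewhere by preferring the
    smaller order.
    """
    if rss < 0:
        raise ValueError("rss must be nonnegative")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if order < 0:
        raise ValueError("order must be nonnegative")
    if rss == 0:
        return float("-inf")
    return math.log(rss / n_samples) + 2.0 * order / n_samples


class _Workspace:
    """Cached constrained fits over subsets of one target's candidates."""

    def __init__(self, profiles: dict[str, np.ndarray], y: np.ndarray):
        self.ids = sorted(profiles)
        self.y = np.asarray(y, dtype=float)
        S = self.y.shape[0]
        self.S = S
        self.cols = {k: np.asarray(profiles[k], dtype=float) for k in self.ids}
        for k, col in self.cols.items():
            if col.shape != (S,):
                raise ValueError(f"profile {k} has wrong length")
        self.ones = np.ones(S)
        self.rss_tol = 1e-12 * (float(self.y @ self.y) + 1.0)
        self._cache: dict[frozenset, tuple] = {}

    def design(self, subset) -> np.ndarray:
        return np.column_stack([self.cols[k] for k in subset] + [self.ones])

    def fit(self, subset) -> tuple:
        """(alpha_vec, beta, rss_clamped, aic, key) for a candidate subset."""
        subset = tuple(sorted(subset))
        cache_key = frozenset(subset)
        hit = self._cache.get(cache_key)
        if hit is not None:
            return hit
        with warnings.catch_warnings():
            # collinear trial designs are routine during the subset search
            warnings.simplefilter("ignore")
            alpha_vec, beta, rss = fit_constrained_lsq(self.design(subset), self.y)
        if rss <= self.rss_tol:
            rss = 0.0
        value = aic(rss, self.S, len(subset))
        out = (alpha_vec, beta, rss, value, (value, len(subset)))
        self._cache[cache_key] = out
        return out

    def as_fit(self, target: str, subset) -> ProteinModelFit:
        subset = tuple(sorted(subset))
        alpha_vec, beta, rss, value, _ = self.fit(subset)
        return ProteinModelFit(
            target=target,
            selected=subset,
            alpha={k: float(a) for k, a in zip(subset, alpha_vec)},
            beta=beta,
            rss=rss,
            aic=value,
            n_samples=self.S,
        )


def stepwise_select(
    candidate_profiles: dict[str, np.ndarray],
    y: np.ndarray,
    target: str = "target",
    max_order: int | None = None,
) -> ProteinModelFit:
    """Choose the interaction model order by greedy AIC search.

    Forward selection adds, at each step, the candidate whose inclusion most
    decreases the AIC (ties broken by lexicographically smallest id, via the
    sorted scan order); after each addition beyond the first, backward passes
    remove any selected candidate whose removal does not increase the AIC.
    Model order is capped at M - 2 so the coefficient t-test keeps at least
    one degree of freedom. Comparisons use the lexicographic key (AIC, order)
    so that among perfect fits the smaller model wins.
    """
    ws = _Workspace(candidate_profiles, y)
    if ws.S < 2:
        raise ValueError("need at least 2 samples")
    cap = min(len(ws.ids), ws.S - 2)
    if max_order is not None:
        cap = min(cap, max_order)
    cap = max(cap, 0)

    selected: list[str] = []
    current_key = ws.fit(selected)[4]
    while len(selected) < cap:
        best_id, best_key = None, None
        for cid in ws.ids:
            if cid in selected:
                continue
            key = ws.fit(selected + [cid])[4]
            if best_key is None or key < best_key:
                best_id, best_key = cid, key
        if best_id is None or not best_key < current_key:
            break
        selected.append(best_id)
        current_key = best_key
        while len(selected) >= 2:
            drop_id, drop_key = None, None
            for rid in sorted(selected):
                key = ws.fit([s for s in selected if s != rid])[4]
                if key < current_key and (drop_key is None or key < drop_key):
                    drop_id, drop_key = rid, key
            if drop_id is None:
                break
            selected.remove(drop_id)
            current_key = drop_key
    return ws.as_fit(target, selected)


def coefficient_pvalues(
    fit: ProteinModelFit, candidate_profiles: dict[str, np.ndarray], y: np.ndarray
) -> dict[str, float]:
    """Two-sided t-test p-value per retained activity (H0: alpha_ik = 0).

    Standard errors come from the unconstrained OLS covariance
    sigma^2 (X'X)^-1 with sigma^2 = rss / (M - L - 1); only the activities
    are tested — the nonnegativity constraint binds on the intercept alone.
    """
    L = fit.order
    df = fit.n_samples - L - 1
    if L == 0:
        return {}
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    ws = _Workspace({k: candidate_profiles[k] for k in fit.selected}, y)
    X = ws.design(fit.selected)
    theta = np.append([fit.alpha[k] for k in fit.selected], fit.beta)
    resid = ws.y - X @ theta
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))[:L]
    out = {}
    for j, k in enumerate(fit.selected):
        a = fit.alpha[k]
        if se[j] > 0:
            out[k] = float(2.0 * stats.t.sf(abs(a) / se[j], df))
        else:
            out[k] = 0.0 if a != 0 else 1.0
    return out


def prune_by_ttest(
    fit: ProteinModelFit,
    candidate_profiles: dict[str, np.ndarray],
    y: np.ndarray,
    alpha_level: float = 0.05,
) -> ProteinModelFit:
    """Drop retained activities that fail the t-test and refit once.

    Coefficients with p >= ``alpha_level`` are deleted and the model is
    refit on the survivors (no further selection). With no residual degrees
    of freedom the pruning step is skipped with a warning; ``alpha_level >=
    1`` records the p-values but deletes nothing.
    """
    if fit.order == 0:
        return fit
    if fit.n_samples - fit.order - 1 <= 0:
        warnings.warn("no residual degrees of freedom: skipping t-test pruning")
        return fit
    pvals = coefficient_pvalues(fit, candidate_profiles, y)
    if alpha_level >= 1.0:
        return replace(fit, pvalues=pvals)
    survivors = tuple(k for k in fit.selected if pvals[k] < alpha_level)
    if survivors == fit.selected:
        return replace(fit, pvalues=pvals)
    ws = _Workspace({k: candidate_profiles[k] for k in survivors} if survivors else {}, y)
    refit = ws.as_fit(fit.target, survivors)
    refit.pvalues = {k: pvals[k] for k in survivors}
    return refit


@dataclass
class StageNetwork:
    """Weighted directed interaction network for one stage.

    ``adjacency[(i, k)]`` is the identified activity of interactor k on
    target i; ``beta`` carries the per-protein basal levels.
    """

    proteins: list[str]
    adjacency: dict[Edge, float]
    beta: dict[str, float]
    stage: str = "C"
    fits: dict[str, ProteinModelFit] | None = None

    def __post_init__(self) -> None:
        for (i, k) in self.adjacency:
            if i == k:
                raise ValueError("diagonal entries are not allowed")

    @property
    def n_edges(self) -> int:
        return len(self.adjacency)

    def to_matrix(self, order: list[str] | None = None) -> np.ndarray:
        order = list(self.proteins) if order is None else order
        index = {p: j for j, p in enumerate(order)}
        N = np.zeros((len(order), len(order)))
        for (i, k), a in self.adjacency.items():
            N[index[i], index[k]] = a
        return N

    def undirected_support(self) -> set[tuple[str, str]]:
        return {(i, k) if i <= k else (k, i) for (i, k) in self.adjacency}


def build_stage_network(
    expr: ExpressionMatrix,
    cand: CandidateNetwork,
    alpha_level: float = 0.05,
    keep_fits: bool = False,
) -> StageNetwork:
    """Identify the full stage network, one target protein at a time.

    Every protein in the candidate network is fit by stepwise AIC selection
    over its candidate interactors followed by t-test pruning; a protein with
    no candidates receives an intercept-only fit. Per-target fits are
    independent, so the result does not depend on evaluation order.
    """
    genes = set(expr.gene_ids)
    missing = [p for p in cand.proteins if p not in genes]
    if missing:
        raise ValueError(f"candidate proteins not measured: {missing[:5]}")
    rows = {p: expr.profile(p) for p in cand.proteins}
    extra = {
        k
        for ns in cand.neighbors.values()
        for k in ns
        if k not in rows
    }
    for k in extra:
        rows[k] = expr.profile(k)
    adjacency: dict[Edge, float] = {}
    beta: dict[str, float] = {}
    fits: dict[str, ProteinModelFit] = {}
    for i in cand.proteins:
        profiles = {k: rows[k] for k in sorted(cand.neighbors.get(i, set()))}
        fit = stepwise_select(profiles, rows[i], target=i)
        fit = prune_by_ttest(fit, profiles, rows[i], alpha_level=alpha_level)
        for k, a in fit.alpha.items():
            adjacency[(i, k)] = a
        beta[i] = fit.beta
        if keep_fits:
            fits[i] = fit
    return StageNetwork(
        proteins=list(cand.proteins),
        adjacency=adjacency,
        beta=beta,
        stage=expr.stage,
        fits=fits if keep_fits else None,
    )
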