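"""Correction-parameter learning: Express, ExpressKR, Probability, Binning.

All algorithms estimate one correction value f_i per fend (HiC) or fragment
(5C) over the valid interaction set A (both elements unfiltered, cis
separation within the configured limits; for 5C additionally count > 0
because counts are log-transformed).  Expected values are

    HiC:  E_ij = exp(D(i, j) + theta) * f_i * f_j          (count scale)
    5C:   E_ij = D(i, j) + theta + f_i + f_j               (log-count scale)

where D is the distance-dependence signal (0 when disabled) and theta is a
global intercept that absorbs the dataset scale so the corrections can be
held exactly at their gauge (geometric mean 1 for HiC, arithmetic mean 0
for 5C) without perturbing the model: multiplying all f by s and adding
2*ln(s) to theta leaves every E_ij unchanged.

Algorithms
----------
* ``express_normalize`` — weighted matrix balancing: Jacobi sweeps of
  f_i' = f_i * sqrt(mean_{j in A_i} c_ij / E_ij) (HiC) or the additive
  log-residual analogue (5C).  Row sums are scaled by each row's number of
  valid interactions, which tolerates filtered elements and distance
  cutoffs without skewing corrections.
* ``kr_balance`` — standard matrix balancing via the Knight-Ruiz
  inner-outer Newton iteration on the dense valid submatrix.
* ``probability_normalize_hic`` / ``probability_normalize_5c`` — maximum
  likelihood under Poisson or binomial (HiC) or lognormal (5C) count
  models, by backtracking-line gradient descent (Armijo criterion).
* ``binning_normalize`` — combinatorial model: per-element features are cut
  into equal-occupancy ranges and a symmetric correction grid per feature
  is learned by round-robin BFGS on a Bernoulli observed/unobserved
  likelihood with a distance prior; pseudo-counts regularize each grid cell
  toward 1.

Corrections are learned on cis interactions within the distance limits and
applied unchanged to trans expected values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _sciopt

from ccnorm.distance import (FiveCDistanceFit, HiCDistanceFunction, PROB_EPS,
                             valid_cis_pairs)
from ccnorm.interactions import FilterState, InteractionSet, neutral_filter
from ccnorm.partition import Partition

__all__ = [
    "CorrectionSet", "ExpectedModel", "BinningModel", "OptimizerState",
    "expected_hic", "expected_5c", "express_update_hic", "express_update_5c",
    "express_normalize", "kr_balance", "probability_normalize_hic",
    "probability_normalize_5c", "binning_normalize", "armijo_backtrack",
]

_LR_CAP = 2.0 ** 10


class NormalizationError(RuntimeError):
    pass


@dataclass
class CorrectionSet:
    """Per-element corrections plus algorithm and convergence metadata."""

    f: np.ndarray
    algorithm: str
    assay: str
    iterations: int = 0
    cost: float = np.nan
    converged: bool = True
    theta: float = 0.0
    sigma: float | None = None  # lognormal scale (5C probability)

    def neutral_like(self) -> np.ndarray:
        return (np.ones_like(self.f) if self.assay == "hic"
                else np.zeros_like(self.f))


def neutral_corrections(partition: Partition,
                        algorithm: str = "neutral") -> CorrectionSet:
    n = partition.n_elements
    f = np.ones(n) if partition.assay == "hic" else np.zeros(n)
    return CorrectionSet(f, algorithm, partition.assay)


@dataclass
class ExpectedModel:
    """Distance function + corrections, bound to a partition.

    ``binning`` optionally supplies combinatorial pair-level corrections
    (a :class:`BinningModel`) multiplied into HiC expected values.
    """

    partition: Partition
    corrections: CorrectionSet
    distance_function: HiCDistanceFunction | FiveCDistanceFit | None = None
    binning: "BinningModel | None" = None

    @property
    def assay(self) -> str:
        return self.partition.assay

    def distance_term(self, d) -> np.ndarray:
        """D evaluated at distances d; zero when no distance function."""
        d = np.asarray(d, dtype=float)
        if self.distance_function is None:
            return np.zeros_like(d)
        return np.asarray(self.distance_function.evaluate(d), dtype=float)


@dataclass
class OptimizerState:
    learning_rate: float
    cost: float
    cost_prev: float
    iteration: int


def _mids_distance(model: ExpectedModel, i, j) -> np.ndarray:
    mids = model.partition.element_mids()
    return np.abs(mids[np.asarray(i)] - mids[np.asarray(j)]).astype(float)


def expected_hic(i, j, model: ExpectedModel) -> np.ndarray | float:
    """E_ij = exp(D(i,j) + theta) * f_i * f_j, on count scale."""
    f = model.corrections.f
    d = _mids_distance(model, i, j)
    D = model.distance_term(d)
    out = np.exp(D + model.corrections.theta) * f[np.asarray(i)] * f[np.asarray(j)]
    if model.binning is not None:
        out = out * model.binning.pair_correction(i, j)
    return float(out) if np.isscalar(i) else out

def expected_5c(i, j, model: ExpectedModel) -> np.ndarray | float:
    """E_ij = D(i,j) + theta + f_i + f_j, on log-count scale."""
    f = model.corrections.f
    d = _mids_distance(model, i, j)
    D = model.distance_term(d)
    out = D + model.corrections.theta + f[np.asarray(i)] + f[np.asarray(j)]
    return float(out) if np.isscalar(i) else out


# -- set-A pair preparation ----------------------------------------------

@dataclass
class _Pairs:
    """Dense set-A cis pair arrays prepared once per normalization."""

    i: np.ndarray
    j: np.ndarray
    d: np.ndarray
    c: np.ndarray
    n_elements: int
    valid: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.i)

    def row_counts(self) -> np.ndarray:
        """|A_i|: number of set-A partners per element."""
        out = np.zeros(self.n_elements, dtype=np.int64)
        np.add.at(out, self.i, 1)
        np.add.at(out, self.j, 1)
        return out

    def row_sum(self, values: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_elements)
        np.add.at(out, self.i, values)
        np.add.at(out, self.j, values)
        return out


def _prepare_pairs(ints: InteractionSet, filt: FilterState | None,
                   nonzero_only: bool = False,
                   opposite_orientation_only: bool = False) -> _Pairs:
    partition = ints.partition
    if filt is None:
        filt = neutral_filter(partition)
    intra_region = partition.assay == "fivec"
    i, j, d, c = valid_cis_pairs(ints, partition, filt,
                                 intra_region_only=intra_region)
    if opposite_orientation_only and partition.assay == "fivec":
        orient = partition.orientations()
        keep = orient[i] != orient[j]
        i, j, d, c = i[keep], j[keep], d[keep], c[keep]
    if nonzero_only:
        keep = c > 0
        i, j, d, c = i[keep], j[keep], d[keep], c[keep]
    return _Pairs(i, j, d.astype(float), c.astype(float),
                  partition.n_elements, filt.valid.copy())


# -- Express: weighted matrix balancing ----------------------------------

def _expected_pairs_hic(pairs: _Pairs, f: np.ndarray, theta: float,
                        D: np.ndarray) -> np.ndarray:
    return np.exp(D + theta) * f[pairs.i] * f[pairs.j]


def express_update_hic(f: np.ndarray, pairs: _Pairs, D: np.ndarray,
                       theta: float) -> tuple[np.ndarray, float]:
    """One Jacobi sweep of the weighted-balancing update (HiC).

    Every element is updated from the same incoming f; the result is then
    regauged to unit geometric mean over valid elements, with the scale
    absorbed into theta (model-invariant).
    """
    E = _expected_pairs_hic(pairs, f, theta, D)
    ratio_sum = pairs.row_sum(pairs.c / E)
    n_a = pairs.row_counts()
    f_new = f.copy()
    upd = (n_a > 0) & pairs.valid
    f_new[upd] = f[upd] * np.sqrt(ratio_sum[upd] / n_a[upd])
    log_s = np.log(f_new[pairs.valid & (n_a > 0)]).mean()
    f_new[pairs.valid] /= np.exp(log_s)
    return f_new, theta + 2.0 * log_s


def express_update_5c(f: np.ndarray, pairs: _Pairs, D: np.ndarray,
                      theta: float) -> tuple[np.ndarray, float]:
    """One Jacobi sweep of the additive log-residual update (5C)."""
    E = D + theta + f[pairs.i] + f[pairs.j]
    resid_sum = pairs.row_sum(np.log(pairs.c) - E)
    n_a = pairs.row_counts()
    f_new = f.copy()
    upd = (n_a > 0) & pairs.valid
    f_new[upd] = f[upd] + resid_sum[upd] / (2.0 * n_a[upd])
    shift = f_new[pairs.valid & (n_a > 0)].mean()
    f_new[pairs.valid] -= shift
    return f_new, theta + 2.0 * shift


def express_normalize(ints: InteractionSet, filt: FilterState | None = None,
                      distance_function=None, max_iters: int = 1000,
                      tol: float = 1e-8,
                      remove_distance: bool = True) -> CorrectionSet:
    """Weighted matrix balancing to a fixed point of the sweep update.

    With ``remove_distance`` the fitted distance-dependence signal enters
    the expected values, so corrections capture only fend/fragment biases;
    otherwise D is identically zero and theta alone absorbs the scale.
    """
    assay = ints.partition.assay
    if assay == "fivec":
        pairs = _prepare_pairs(ints, filt, nonzero_only=True,
                               opposite_orientation_only=True)
    else:
        pairs = _prepare_pairs(ints, filt)
    df = distance_function if remove_distance else None
    model = ExpectedModel(ints.partition, neutral_corrections(ints.partition),
                          df)
    D = model.distance_term(pairs.d)
    f = model.corrections.f.copy()
    theta = 0.0
    n_a = pairs.row_counts()
    stranded = pairs.valid & (n_a == 0)
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        if assay == "hic":
            f_new, theta = express_update_hic(f, pairs, D, theta)
        else:
            f_new, theta = express_update_5c(f, pairs, D, theta)
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"express did not converge in {max_iters} sweeps")
    if stranded.any():
        f[stranded] = 1.0 if assay == "hic" else 0.0
    f[~pairs.valid] = 1.0 if assay == "hic" else 0.0
    cost = _express_cost(assay, pairs, f, theta, D)
    return CorrectionSet(f, "express", assay, iterations=it, cost=cost,
                         converged=converged, theta=theta)


def _express_cost(assay, pairs, f, theta, D):
    if assay == "hic":
        E = _expected_pairs_hic(pairs, f, theta, D)
        return float(np.sum((pairs.c - E) ** 2))
    E = D + theta + f[pairs.i] + f[pairs.j]
    return float(np.sum((np.log(pairs.c) - E) ** 2))


# -- Knight-Ruiz standard matrix balancing -------------------------------

def _kr_core(A: np.ndarray, tol: float = 1e-12,
             max_outer: int = 100) -> np.ndarray:
    """Knight-Ruiz balancing of a symmetric non-negative matrix.

    Returns x with diag(x) A diag(x) doubly stochastic (row sums 1).
    Inner Newton steps solve via conjugate gradient; parameters follow the
    published algorithm (delta/Delta safeguards, eta forcing sequence).
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    rt = tol ** 2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    i = 0
    while rout > rt and i < max_outer:
        i += 1
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, rt)
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 200:
                break
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        eta = max(min(g * rat, etamax), 0.5 * tol / np.sqrt(rout) if rout > 0 else 0)
    return x


def kr_balance(ints: InteractionSet, filt: FilterState | None = None,
               distance_function=None, tol: float = 1e-10,
               remove_distance: bool = False) -> CorrectionSet:
    """Standard matrix balancing with the Knight-Ruiz algorithm.

    The dense symmetric count matrix over valid elements (optionally divided
    by exp(D) first) is balanced so every row sum equals 1; corrections are
    stored as f_i = 1 / x_i, regauged to unit geometric mean with theta
    absorbing the scale.
    """
    pairs = _prepare_pairs(ints, filt)
    model = ExpectedModel(ints.partition, neutral_corrections(ints.partition),
                          distance_function if remove_distance else None)
    valid_idx = np.flatnonzero(pairs.valid)
    pos = -np.ones(pairs.n_elements, dtype=np.int64)
    pos[valid_idx] = np.arange(len(valid_idx))
    m = len(valid_idx)
    A = np.zeros((m, m))
    w = pairs.c / np.exp(model.distance_term(pairs.d))
    A[pos[pairs.i], pos[pairs.j]] = w
    A[pos[pairs.j], pos[pairs.i]] = w
    rowsum = A.sum(axis=1)
    dead = np.flatnonzero(rowsum == 0)
    if len(dead):
        raise NormalizationError(
            "matrix has zero-support rows (element indices "
            f"{valid_idx[dead].tolist()}); filter more aggressively")
    x = _kr_core(A, tol=tol)
    check = x * (A @ x)
    converged = bool(np.abs(check - 1.0).max() < 1e-5)
    f = np.ones(pairs.n_elements)
    fx = 1.0 / x
    log_s = np.log(fx).mean()
    fx /= np.exp(log_s)
    f[valid_idx] = fx
    return CorrectionSet(f, "expresskr", ints.partition.assay,
                         iterations=1, converged=converged,
                         theta=2.0 * log_s)


# -- backtracking-line gradient descent ----------------------------------

def armijo_backtrack(cost_fn, f: np.ndarray, gradient: np.ndarray,
                     r0: float = 1.0, shrink: float = 0.5,
                     c_armijo: float = 1e-4, max_halvings: int = 30):
    """One backtracked gradient step satisfying the Armijo decrease test.

    Tries f' = f - r * gradient for r = r0 * shrink**k, accepting the first
    step with  C(f') <= C(f) - c_armijo * r * sum(gradient**2).  Returns
    ``(f_accepted, r_accepted, ok)``; when the budget of halvings is
    exhausted the smallest step is returned with ok = False.  A zero
    gradient returns f unchanged.
    """
    gnorm2 = float(gradient @ gradient)
    if gnorm2 == 0.0:
        return f, r0, True
    c0 = cost_fn(f)
    r = r0
    for _ in range(max_halvings + 1):
        f_try = f - r * gradient
        c_try = cost_fn(f_try)
        if np.isfinite(c_try) and c_try <= c0 - c_armijo * r * gnorm2:
            return f_try, r, True
        r *= shrink
    return f - r * gradient, r, False


def _descend(cost_grad, x0: np.ndarray, max_iters: int, tol: float,
             gtol: float = 1e-9) -> tuple[np.ndarray, OptimizerState, bool]:
    """Minimize with Armijo-backtracked gradient descent.

    The learning rate doubles (capped) after a step accepted at the first
    try and is carried over otherwise.  Converged when the cost decrease
    falls below ``tol`` (relative) or the gradient infinity-norm below
    ``gtol``.
    """
    x = x0.copy()
    r = 1.0
    c_prev = np.inf
    c, grad = cost_grad(x)
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        x_new, r_acc, ok = armijo_backtrack(
            lambda v: cost_grad(v)[0], x, grad, r0=r)
        if not ok:
            break
        if r_acc == r:
            r = min(r * 2.0, _LR_CAP)
        else:
            r = r_acc
        c_prev = c
        x = x_new
        c, grad = cost_grad(x)
        if abs(c_prev - c) < tol * (1.0 + abs(c)):
            converged = True
            break
    return x, OptimizerState(r, c, c_prev, it), converged


# -- Probability algorithms ----------------------------------------------

def probability_normalize_hic(ints: InteractionSet,
                              filt: FilterState | None = None,
                              distance_function: HiCDistanceFunction | None = None,
                              dist: str = "poisson",
                              max_iters: int = 2000,
                              tol: float = 1e-14, gtol: float = 1e-12) -> CorrectionSet:
    """Maximum-likelihood multiplicative corrections for HiC.

    ``dist="poisson"`` models counts c_ij ~ Poisson(E_ij) with the
    counts-variant distance signal as prior; ``dist="binomial"`` models the
    observed/unobserved indicator ~ Bernoulli(p_ij) with
    p_ij = clamp(f_i f_j p_D(i,j)) and the binary-variant distance signal.
    Corrections are optimized in log space (f > 0 guaranteed) jointly with
    the global intercept theta; gradient descent uses Armijo backtracking.
    """
    if dist not in ("poisson", "binomial"):
        raise ValueError(f"unknown distribution {dist!r}")
    pairs = _prepare_pairs(ints, filt)
    if pairs.n_pairs == 0:
        raise NormalizationError("empty valid interaction set")
    n = pairs.n_elements
    upd = np.flatnonzero(pairs.valid & (pairs.row_counts() > 0))
    pos = -np.ones(n, dtype=np.int64)
    pos[upd] = np.arange(len(upd))
    pi, pj = pos[pairs.i], pos[pairs.j]
    scale = 1.0 / pairs.n_pairs  # cost on per-pair scale

    if dist == "poisson":
        D = np.zeros(pairs.n_pairs)
        if distance_function is not None:
            D = np.asarray(distance_function.evaluate(pairs.d, "counts"))
        c = pairs.c
        c_tot = c.sum()

        # theta is profiled out in closed form (e^theta = sum c / sum E0),
        # which keeps the descent well conditioned and makes the cost
        # invariant under recentering of g.
        def _theta_of(g):
            E0 = np.exp(D + g[pi] + g[pj])
            return float(np.log(c_tot / E0.sum())), E0

        def cost_grad(x):
            g = x
            theta, E0 = _theta_of(g)
            E = np.exp(theta) * E0
            cost = scale * float(np.sum(E - c * (D + theta + g[pi] + g[pj])))
            diff = E - c
            grad = np.zeros(len(x))
            np.add.at(grad, pi, diff)
            np.add.at(grad, pj, diff)
            # Jacobi preconditioning: divide by the diagonal curvature
            # sum_j E_ij so every coordinate steps on a comparable scale
            hdiag = np.zeros(len(x))
            np.add.at(hdiag, pi, E)
            np.add.at(hdiag, pj, E)
            return cost, scale * grad / np.maximum(scale * hdiag, 1e-12)
    else:
        pD = np.full(pairs.n_pairs, np.clip((pairs.c > 0).mean(),
                                            PROB_EPS, 1 - PROB_EPS))
        if distance_function is not None:
            pD = np.asarray(distance_function.evaluate(pairs.d, "binary"))
        o = (pairs.c > 0).astype(float)
        log_pD = np.log(pD)

        def cost_grad(x):
            g, theta = x[:-1], x[-1]
            logp = log_pD + theta + g[pi] + g[pj]
            p = np.exp(logp)
            clamped = (p <= PROB_EPS) | (p >= 1 - PROB_EPS)
            p = np.clip(p, PROB_EPS, 1 - PROB_EPS)
            cost = -scale * float(np.sum(o * np.log(p)
                                         + (1 - o) * np.log1p(-p)))
            dpair = np.where(clamped, 0.0, (1 - o) * p / (1 - p) - o)
            grad = np.zeros(len(x))
            np.add.at(grad, pi, dpair)
            np.add.at(grad, pj, dpair)
            grad[-1] = dpair.sum()
            return cost, scale * grad

    if dist == "poisson":
        x0 = np.zeros(len(upd))
        x, state, converged = _descend(cost_grad, x0, max_iters, tol, gtol)
        g = x
        theta, _ = _theta_of(g)
    else:
        x0 = np.zeros(len(upd) + 1)
        x, state, converged = _descend(cost_grad, x0, max_iters, tol, gtol)
        g, theta = x[:-1], x[-1]
    center = g.mean()
    g = g - center
    theta += 2.0 * center
    f = np.ones(n)
    f[upd] = np.exp(g)
    return CorrectionSet(f, f"probability-{dist}", "hic",
                         iterations=state.iteration, cost=state.cost,
                         converged=converged, theta=theta)


def probability_normalize_5c(ints: InteractionSet,
                             filt: FilterState | None = None,
                             distance_fit: FiveCDistanceFit | None = None,
                             max_iters: int = 2000,
                             tol: float = 1e-14, gtol: float = 1e-12) -> CorrectionSet:
    """Maximum-likelihood lognormal corrections for 5C.

    ln(c_ij) ~ Normal(E_ij, sigma^2) over valid non-zero pairs, sigma^2
    re-estimated from the residuals; maximizing the likelihood in f and
    theta is a least-squares problem solved by Armijo gradient descent.
    """
    pairs = _prepare_pairs(ints, filt, nonzero_only=True,
                           opposite_orientation_only=True)
    if pairs.n_pairs < 2:
        raise NormalizationError("need >= 2 valid non-zero pairs")
    n = pairs.n_elements
    upd = np.flatnonzero(pairs.valid & (pairs.row_counts() > 0))
    pos = -np.ones(n, dtype=np.int64)
    pos[upd] = np.arange(len(upd))
    pi, pj = pos[pairs.i], pos[pairs.j]
    D = np.zeros(pairs.n_pairs)
    if distance_fit is not None:
        D = np.asarray(distance_fit.evaluate(pairs.d))
    lnc = np.log(pairs.c)
    scale = 1.0 / pairs.n_pairs

    # theta profiled in closed form: the mean residual at the current f
    def _theta_of(f):
        return float(np.mean(lnc - (D + f[pi] + f[pj])))

    n_a = np.zeros(len(upd))
    np.add.at(n_a, pi, 1.0)
    np.add.at(n_a, pj, 1.0)

    def cost_grad(x):
        theta = _theta_of(x)
        resid = lnc - (D + theta + x[pi] + x[pj])
        cost = scale * float(resid @ resid)
        grad = np.zeros(len(x))
        np.add.at(grad, pi, -2.0 * resid)
        np.add.at(grad, pj, -2.0 * resid)
        # precondition by the (constant) diagonal curvature 2|A_i|
        return cost, scale * grad / (2.0 * scale * np.maximum(n_a, 1.0))

    x0 = np.zeros(len(upd))
    x, state, converged = _descend(cost_grad, x0, max_iters, tol, gtol)
    fv = x
    theta = _theta_of(fv)
    center = fv.mean()
    fv = fv - center
    theta += 2.0 * center
    f = np.zeros(n)
    f[upd] = fv
    resid = lnc - (D + theta + fv[pos[pairs.i]] + fv[pos[pairs.j]])
    sigma = float(np.sqrt(np.mean(resid ** 2)))
    return CorrectionSet(f, "probability-lognormal", "fivec",
                         iterations=state.iteration, cost=state.cost,
                         converged=converged, theta=theta, sigma=sigma)


# -- Binning: combinatorial feature model --------------------------------

@dataclass
class BinningModel:
    """Per-feature range edges and symmetric correction grids.

    ``grids[name]`` is an (n_ranges, n_ranges) symmetric positive array;
    ``assignments[name]`` maps each element to its range.  The pair
    probability is clamp(prior * prod_f grid_f[r_f(i), r_f(j)]).
    """

    features: list[str]
    edges: dict[str, np.ndarray]
    grids: dict[str, np.ndarray]
    assignments: dict[str, np.ndarray]
    pseudo_count: float
    log_likelihood: float = np.nan
    rounds_run: int = 0

    def pair_correction(self, i, j) -> np.ndarray | float:
        out = 1.0
        for name in self.features:
            r = self.assignments[name]
            out = out * self.grids[name][r[np.asarray(i)], r[np.asarray(j)]]
        return out


def _quantile_ranges(values: np.ndarray, mask: np.ndarray,
                     n_ranges: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-occupancy cuts; returns (edges, per-element assignment)."""
    qs = np.quantile(values[mask], np.linspace(0, 1, n_ranges + 1)[1:-1])
    edges = np.unique(qs)
    assign = np.searchsorted(edges, values, side="right")
    if len(np.unique(assign[mask])) < min(n_ranges, 2) and n_ranges > 1:
        warnings.warn("degenerate feature ranges re-derived from ranks")
        order = values[mask].argsort(kind="stable")
        ranks = np.empty(mask.sum(), dtype=np.int64)
        ranks[order] = np.arange(mask.sum())
        assign = np.zeros(len(values), dtype=np.int64)
        assign[mask] = ranks * n_ranges // mask.sum()
        edges = np.array([])
    return edges, assign.astype(np.int64)


def binning_normalize(ints: InteractionSet, features: dict[str, np.ndarray],
                      n_ranges: int | dict[str, int] = 3,
                      pseudo_count: float = 0.0, rounds: int = 20,
                      tol: float = 1e-6, filt: FilterState | None = None,
                      distance_function: HiCDistanceFunction | None = None
                      ) -> BinningModel:
    """Learn combinatorial feature-bin corrections by round-robin BFGS.

    Each feature's observed values are cut into equal-occupancy ranges; a
    symmetric grid of corrections over range pairs is learned per feature
    by maximizing the Bernoulli likelihood of the observed/unobserved
    indicator, with the binary-variant distance signal (or the overall
    observed fraction) as prior, holding the other features' grids fixed.
    ``pseudo_count`` adds the given number of reads to both the observed
    and expected tallies of every range combination, pulling grid values
    toward 1.  Rounds stop when the likelihood gain drops below ``tol``.
    """
    pairs = _prepare_pairs(ints, filt)
    if pairs.n_pairs == 0:
        raise NormalizationError("empty valid interaction set")
    names = list(features)
    if isinstance(n_ranges, int):
        n_ranges = {name: n_ranges for name in names}
    edges, assigns, grids = {}, {}, {}
    for name in names:
        vals = np.asarray(features[name], dtype=float)
        if len(vals) != pairs.n_elements:
            raise ValueError(f"feature {name!r} length mismatch")
        edges[name], assigns[name] = _quantile_ranges(
            vals, pairs.valid, n_ranges[name])
        k = int(assigns[name].max()) + 1
        grids[name] = np.ones((max(k, n_ranges[name]), max(k, n_ranges[name])))
    o = (pairs.c > 0).astype(float)
    prior = np.full(pairs.n_pairs,
                    np.clip(o.mean(), PROB_EPS, 1 - PROB_EPS))
    if distance_function is not None:
        prior = np.asarray(distance_function.evaluate(pairs.d, "binary"))

    def pair_grid_product(skip=None):
        out = np.ones(pairs.n_pairs)
        for name in names:
            if name == skip:
                continue
            r = assigns[name]
            out *= grids[name][r[pairs.i], r[pairs.j]]
        return out

    def loglik():
        p = np.clip(prior * pair_grid_product(), PROB_EPS, 1 - PROB_EPS)
        ll = float(np.sum(o * np.log(p) + (1 - o) * np.log1p(-p)))
        for name in names:
            G = grids[name]
            iu = np.triu_indices(G.shape[0])
            ll += pseudo_count * float(
                np.sum(np.log(G[iu]) - G[iu] + 1.0))
        return ll

    ll_prev = loglik()
    r_done = 0
    for r_done in range(1, rounds + 1):
        for name in names:
            grids[name] = _fit_grid(pairs, o, prior, assigns[name],
                                    grids[name], pair_grid_product(name),
                                    pseudo_count)
        ll = loglik()
        if ll - ll_prev < tol * (1.0 + abs(ll_prev)):
            ll_prev = ll
            break
        ll_prev = ll
    return BinningModel(names, edges, grids, assigns, pseudo_count,
                        log_likelihood=ll_prev, rounds_run=r_done)


def _fit_grid(pairs: _Pairs, o: np.ndarray, prior: np.ndarray,
              assign: np.ndarray, grid: np.ndarray, other: np.ndarray,
              pseudo_count: float) -> np.ndarray:
    """BFGS fit of one feature's symmetric grid (others held fixed)."""
    k = grid.shape[0]
    iu = np.triu_indices(k)
    combo = np.full((k, k), -1, dtype=np.int64)
    combo[iu] = np.arange(len(iu[0]))
    combo = np.maximum(combo, combo.T)
    pair_combo = combo[assign[pairs.i], assign[pairs.j]]
    base = prior * other

    def cost_grad(logg):
        gvals = np.exp(logg)
        p = base * gvals[pair_combo]
        clamped = (p <= PROB_EPS) | (p >= 1 - PROB_EPS)
        p = np.clip(p, PROB_EPS, 1 - PROB_EPS)
        cost = -np.sum(o * np.log(p) + (1 - o) * np.log1p(-p))
        cost -= pseudo_count * np.sum(logg - gvals + 1.0)
        dpair = np.where(clamped, 0.0, (1 - o) * p / (1 - p) - o)
        grad = np.bincount(pair_combo, weights=dpair, minlength=len(iu[0]))
        grad -= pseudo_count * (1.0 - gvals)
        return cost, grad

    res = _sciopt.minimize(cost_grad, np.log(grid[iu]), jac=True,
                           method="BFGS",
                           options={"gtol": 1e-8, "maxiter": 500})
    new = np.ones_like(grid)
    new[iu] = np.exp(res.x)
    new.T[iu] = np.exp(res.x)  # symmetric by construction
    return new
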