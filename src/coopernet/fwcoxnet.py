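"""Feature-weighted elastic net for cause-specific Cox models (fwcoxnet).

The penalty of an ordinary Cox elastic net is multiplied per feature by

    w_j(theta) = sum_l exp(z_l * theta) / (p * exp(z_j * theta)),

where ``z`` is a vector of nonnegative prior relevance scores and ``theta``
a scalar learned from the data.  ``theta = 0`` gives w_j = 1 (plain elastic
net); positive theta shifts penalty mass away from high-score features.  The
weights satisfy the harmonic-mean identity ``sum_j 1/w_j = p``, so prior
information redistributes but never removes penalization.

Fitting alternates a weighted coordinate-descent Cox solve (beta-step) with
a one-dimensional convex minimization of the penalty in theta (theta-step)
along a decreasing lambda path; lambda is then chosen by the cross-validated
partial log-likelihood (Verweij-Van Houwelingen), the ``lambda.min`` rule.

Objective scaling: internally the data term is NLL/n so that lambda is
comparable across cross-validation folds of different sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ._kernels import (
    minimize_theta_golden,
    minimize_theta_sparse,
    solve_penalized_cox,
    theta_objective,
    theta_objective_sparse,
)
from .cox_core import CauseView, cox_gradient

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureInfo",
    "PenaltyConfig",
    "WeightVector",
    "FwcoxnetFit",
    "weight_vector",
    "lambda_path",
    "solve_beta",
    "update_theta",
    "fit_fwcoxnet",
    "cv_partial_loglik",
    "make_cv_folds",
]


@dataclass
class FeatureInfo:
    """Prior relevance scores, one nonnegative value per feature (G = 1)."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.z)):
            raise ValueError("relevance scores must be finite")
        if np.any(self.z < 0):
            raise ValueError("relevance scores must be nonnegative")


@dataclass
class PenaltyConfig:
    """Controls for a single fwcoxnet fit.

    alpha mixes l1 and l2 (1 = lasso).  ``t_init`` and ``thresh`` are the
    theta-loop learning rate and convergence tolerance; ``thresh`` also stops
    the beta/theta alternation.  ``lambda_path`` may be an explicit strictly
    decreasing array, otherwise a log-spaced path of ``n_lambda`` values is
    built from lambda_max (``lambda_min_ratio`` defaults to 0.01 when n < p,
    else 1e-4).
    """

    alpha: float = 1.0
    lambda_path: np.ndarray | None = None
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    t_init: float = 100.0
    thresh: float = 1e-7
    nfolds: int = 10
    stratify_by_status: bool = False
    standardize: bool = True
    theta_max: float = 50.0
    max_outer: int = 25
    dfmax: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.nfolds < 2:
            raise ValueError("nfolds must be at least 2")
        if self.t_init <= 0 or self.thresh <= 0:
            raise ValueError("t_init and thresh must be positive")
        if self.lambda_path is not None:
            lp = np.asarray(self.lambda_path, dtype=np.float64)
            if lp.ndim != 1 or np.any(lp <= 0) or np.any(np.diff(lp) >= 0):
                raise ValueError("lambda_path must be strictly decreasing and positive")
            self.lambda_path = lp


@dataclass
class WeightVector:
    """Per-feature penalty factors w_j(theta) for one scalar theta."""

    w: np.ndarray
    theta: float

    @property
    def harmonic_identity_gap(self) -> float:
        """|sum_j 1/w_j - p|, zero up to round-off by construction."""
        return abs(float(np.sum(1.0 / self.w)) - self.w.shape[0])


@dataclass
class FwcoxnetFit:
    """Result of one cross-validated cause-specific fwcoxnet fit."""

    beta: np.ndarray
    theta: float
    lambda_selected: float
    cv_loglik: np.ndarray
    objective_trace: np.ndarray
    lambdas: np.ndarray
    feature_names: list[str] | None = None
    n_events: int = 0
    null_fit: bool = False
    warning: str | None = None

    def nonzero(self) -> dict[str, float]:
        """Sparse map of the nonzero coefficients."""
        names = self.feature_names or [f"x{j + 1}" for j in range(self.beta.shape[0])]
        return {names[j]: float(self.beta[j]) for j in np.flatnonzero(self.beta)}


def weight_vector(z: FeatureInfo | np.ndarray, theta: float) -> WeightVector:
    """Penalty factors w_j(theta); larger z_j * theta means a smaller factor.

    Computed in log space so extreme scores cannot overflow.
    """
    zv = z.z if isinstance(z, FeatureInfo) else np.asarray(z, dtype=np.float64).ravel()
    if not np.all(np.isfinite(zv)):
        raise ValueError("relevance scores must be finite")
    p = zv.shape[0]
    s = zv * theta
    m = s.max()
    lse = m + np.log(np.sum(np.exp(s - m)))
    # cap the exponent: beyond ~700 the factor is an effective +inf penalty
    w = np.exp(np.minimum(lse - np.log(p) - s, 700.0))
    return WeightVector(w=w, theta=float(theta))


def lambda_path(view: CauseView, X: np.ndarray, alpha: float,
                w: WeightVector | np.ndarray | None = None,
                n_lambda: int = 100,
                lambda_min_ratio: float | None = None) -> np.ndarray:
    """Decreasing log-spaced lambda grid starting at the all-zero threshold.

    lambda_max = max_j |g_j| / (alpha w_j) with g the gradient of NLL/n at
    beta = 0; every coefficient is zero for lambda >= lambda_max.  For
    alpha = 0 the threshold is undefined and the conventional alpha = 0.001
    surrogate is used (logged).
    """
    n, p = X.shape
    if view.n_events == 0:
        raise ValueError("cannot build a lambda path without events")
    wv = np.ones(p) if w is None else (w.w if isinstance(w, WeightVector) else np.asarray(w))
    a = alpha
    if a <= 0.0:
        logger.info("alpha=0: computing lambda_max with the alpha=0.001 surrogate")
        a = 0.001
    g0 = cox_gradient(np.zeros(p), view, X) / n
    lam_max = float(np.max(np.abs(g0) / (a * wv)))
    if lam_max <= 0:
        raise ValueError("degenerate data: zero gradient at beta = 0")
    if lambda_min_ratio is None:
        lambda_min_ratio = 0.01 if n < p else 1e-4
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


class _FitContext:
    """Time-sorted (optionally standardized) arrays for one cause-specific fit."""

    def __init__(self, view: CauseView, X: np.ndarray, standardize: bool):
        idx, d_s, gs, gd = view.risk_order()
        Xs = X[idx]
        self.n, self.p = Xs.shape
        if standardize:
            self.mean = Xs.mean(axis=0)
            self.scale = Xs.std(axis=0)
            self.scale[self.scale == 0.0] = 1.0
            Xs = (Xs - self.mean) / self.scale
        else:
            self.mean = np.zeros(self.p)
            self.scale = np.ones(self.p)
        self.Xs = np.asfortranarray(Xs)
        self.delta_s = d_s
        self.group_start = gs
        self.group_delta = gd
        self.view_sorted = CauseView(time=view.time[idx], delta=view.delta[idx], cause=view.cause)


def _solve_at(ctx: _FitContext, pen_l1: np.ndarray, pen_l2: np.ndarray,
              beta: np.ndarray, ws_mask: np.ndarray, full_kkt: bool = True,
              cd_tol: float = 1e-9, irls_tol: float = 1e-9) -> tuple[float, np.ndarray, int]:
    nll, grad, n_new = solve_penalized_cox(
        ctx.Xs, ctx.delta_s, ctx.group_start, ctx.group_delta,
        pen_l1, pen_l2, beta, ws_mask,
        cd_tol, irls_tol, 25, 200, 1e-7, full_kkt,
    )
    beta[np.abs(beta) < 1e-13] = 0.0  # round-off dust at the KKT boundary
    return nll, grad, n_new


def solve_beta(view: CauseView, X: np.ndarray, alpha: float, lam: float,
               w: WeightVector | np.ndarray | None = None,
               beta_init: np.ndarray | None = None) -> np.ndarray:
    """Minimize NLL/n + lam * sum_j w_j (alpha |b_j| + (1-alpha)/2 b_j^2).

    Solved by IRLS around cyclic coordinate descent with per-feature penalty
    factors and soft-threshold updates, warm-started from ``beta_init``.  No
    internal standardization is applied here; :func:`fit_fwcoxnet` manages
    scaling for full fits.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    p = X.shape[1]
    wv = np.ones(p) if w is None else (w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=np.float64))
    ctx = _FitContext(view, np.asarray(X, dtype=np.float64), standardize=False)
    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=np.float64).copy()
    ws_mask = np.ones(p, dtype=np.bool_)  # no screening for one-off solves
    _solve_at(ctx, lam * alpha * wv, lam * (1.0 - alpha) * wv, beta, ws_mask,
              cd_tol=1e-12, irls_tol=1e-12)
    return beta


def _theta_penalty(z: np.ndarray, q: np.ndarray, theta: float) -> float:
    return float(theta_objective(z, q, float(theta)))


def update_theta(view: CauseView, X: np.ndarray, beta: np.ndarray, z: np.ndarray,
                 alpha: float, lam: float, theta_init: float = 0.0,
                 t_init: float = 100.0, thresh: float = 1e-7,
                 theta_max: float = 50.0) -> float:
    """Minimize the penalty term of the fwcoxnet objective over scalar theta.

    The data term does not depend on theta, so the objective reduces to
    ``lam * sum_j w_j(theta) q_j`` with ``q_j = alpha |b_j| + (1-alpha)/2
    b_j^2`` — a positive sum of exponentials, convex in theta.  Gradient
    descent with backtracking (step ``t_init``, stopping when the relative
    decrease drops below ``thresh``) is followed by a bounded scalar polish;
    the best of the visited points is returned, so the objective never
    increases relative to ``theta_init``.
    """
    z = np.asarray(z, dtype=np.float64).ravel()
    beta = np.asarray(beta, dtype=np.float64)
    q = alpha * np.abs(beta) + 0.5 * (1.0 - alpha) * beta**2
    if not q.any() or np.ptp(z) == 0.0:
        return float(theta_init)

    def g(th: float) -> float:
        return _theta_penalty(z, q, float(np.clip(th, -theta_max, theta_max)))

    def gprime(th: float) -> float:
        s = z * th
        m = s.max()
        e = np.exp(s - m)
        zbar = float((z * e).sum() / e.sum())
        wv = weight_vector(z, th).w
        return float(np.sum(q * wv * (zbar - z)))

    th = float(np.clip(theta_init, -theta_max, theta_max))
    f = g(th)
    if not np.isfinite(f):
        logger.warning("non-finite theta objective at init; resetting theta to 0")
        th, f = 0.0, g(0.0)
    best_th, best_f = th, f
    for _ in range(200):
        gr = gprime(th)
        if gr == 0.0:
            break
        t = t_init
        cand, fc = th, f
        while t > 1e-14:
            c = float(np.clip(th - t * gr, -theta_max, theta_max))
            fcand = g(c)
            if np.isfinite(fcand) and fcand < f:
                cand, fc = c, fcand
                break
            t *= 0.5
        if fc >= f:
            break
        decrease = f - fc
        th, f = cand, fc
        if f < best_f:
            best_th, best_f = th, f
        if decrease < thresh * max(1.0, abs(f)):
            break
    res = minimize_scalar(g, bounds=(-theta_max, theta_max), method="bounded",
                          options={"xatol": 1e-8})
    if np.isfinite(res.fun) and res.fun < best_f:
        best_th, best_f = float(res.x), float(res.fun)
    if g(float(theta_init)) < best_f:
        best_th = float(theta_init)
    return best_th


class _ThetaSolver:
    """Per-path helper minimizing the convex theta penalty for fixed scores.

    Scores are compressed once (distinct positive entries vs the zero
    block), so each theta solve costs O(#positive scores) per evaluation.
    """

    def __init__(self, z_std: np.ndarray, theta_max: float):
        self.nz_idx = np.flatnonzero(z_std)
        self.z_nz = np.ascontiguousarray(z_std[self.nz_idx])
        self.n_zero = z_std.shape[0] - self.nz_idx.shape[0]
        self.theta_max = theta_max

    def objective(self, q: np.ndarray, theta: float) -> float:
        q_nz = np.ascontiguousarray(q[self.nz_idx])
        return float(theta_objective_sparse(
            self.z_nz, q_nz, self.n_zero, float(q.sum() - q_nz.sum()), float(theta)))

    def step(self, q: np.ndarray, theta: float) -> float:
        """Global minimizer over the clipped range; never increases the penalty."""
        q_nz = np.ascontiguousarray(q[self.nz_idx])
        q0 = float(q.sum() - q_nz.sum())
        th_new, f_new = minimize_theta_sparse(
            self.z_nz, q_nz, self.n_zero, q0, -self.theta_max, self.theta_max, 1e-7)
        f_cur = theta_objective_sparse(self.z_nz, q_nz, self.n_zero, q0, theta)
        return float(th_new) if np.isfinite(f_new) and f_new < f_cur else theta


def _fit_path(ctx: _FitContext, z_std: np.ndarray | None, lambdas: np.ndarray,
              cfg: PenaltyConfig, cd_tol: float = 1e-8,
              irls_tol: float = 1e-7,
              ) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], int]:
    """Pathwise beta/theta alternation on (pre-standardized) sorted data.

    Returns coefficients on the standardized scale, the theta per lambda,
    the per-lambda objective traces (one entry per outer alternation) and
    the number of path points actually fit: the path stops once the active
    set exceeds ``dfmax`` (default: the number of events, past which a Cox
    model is saturated and cross-validation cannot prefer it).
    """
    n, p = ctx.n, ctx.p
    L = lambdas.shape[0]
    alpha = cfg.alpha
    betas = np.zeros((L, p))
    thetas = np.zeros(L)
    traces: list[np.ndarray] = []
    beta = np.zeros(p)
    theta = 0.0
    grad_prev: np.ndarray | None = None
    a_screen = max(alpha, 1e-3)
    z_support = None if z_std is None else (z_std > 0)
    tsolver = None if z_std is None else _ThetaSolver(z_std, cfg.theta_max)
    dfmax = cfg.dfmax if cfg.dfmax is not None else int(ctx.group_delta.sum())
    n_valid = L

    for l, lam in enumerate(lambdas):
        # theta restarts from neutral weights at every path point: a warm
        # theta at the clip boundary would permanently exclude one side of
        # the score spectrum from all later path points
        theta = 0.0
        wv = np.ones(p)
        # fresh working set: current support + sequential strong rule
        ws_mask = beta != 0.0
        if grad_prev is not None:
            ws_mask |= np.abs(grad_prev) >= a_screen * wv * (2.0 * lam - lambdas[l - 1])
        if z_support is not None:
            ws_mask |= z_support  # weight drops concentrate on scored features
        trace: list[float] = []
        if z_std is None:
            pen_l1 = lam * alpha * wv
            nll, grad_prev, _ = _solve_at(ctx, pen_l1, lam * (1.0 - alpha) * wv,
                                          beta, ws_mask, cd_tol=cd_tol,
                                          irls_tol=irls_tol)
            q = alpha * np.abs(beta) + 0.5 * (1.0 - alpha) * beta**2
            trace.append(nll / n + lam * float(wv @ q))
        else:
            # alternate beta (working set only) and theta, then validate KKT
            pobj_prev = np.inf
            pobj = np.inf
            for _outer in range(cfg.max_outer):
                nll, _, _ = _solve_at(ctx, lam * alpha * wv, lam * (1.0 - alpha) * wv,
                                      beta, ws_mask, full_kkt=False,
                                      cd_tol=cd_tol, irls_tol=irls_tol)
                q = alpha * np.abs(beta) + 0.5 * (1.0 - alpha) * beta**2
                if q.any():
                    theta = tsolver.step(q, theta)
                    wv = weight_vector(z_std, theta).w
                pobj = nll / n + lam * float(wv @ q)
                trace.append(pobj)
                if pobj_prev - pobj < cfg.thresh * max(1.0, abs(pobj)) or not q.any():
                    break
                pobj_prev = pobj
            for _round in range(4):
                nll, grad_prev, n_new = _solve_at(ctx, lam * alpha * wv,
                                                  lam * (1.0 - alpha) * wv,
                                                  beta, ws_mask, full_kkt=True,
                                                  cd_tol=cd_tol, irls_tol=irls_tol)
                q = alpha * np.abs(beta) + 0.5 * (1.0 - alpha) * beta**2
                pobj = nll / n + lam * float(wv @ q)
                trace.append(pobj)
                if n_new == 0:
                    break
                if q.any():
                    theta = tsolver.step(q, theta)
                    wv = weight_vector(z_std, theta).w
        betas[l] = beta
        thetas[l] = theta
        traces.append(np.asarray(trace))
        if int(np.count_nonzero(beta)) > dfmax:
            n_valid = l + 1
            break
    return betas, thetas, traces, n_valid


def make_cv_folds(delta: np.ndarray, nfolds: int, stratify: bool,
                  seed: int) -> list[np.ndarray]:
    """Test-index partition for CV; optionally stratified on the event flag.

    Every training set must contain at least one event: stratified splits are
    re-drawn (fresh sub-seed) on violation, unstratified splits raise.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    delta = np.asarray(delta)
    n = delta.shape[0]
    ss = np.random.SeedSequence(seed)
    for attempt in range(20):
        state = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        if stratify:
            splitter = StratifiedKFold(n_splits=nfolds, shuffle=True, random_state=state)
            splits = [test for _, test in splitter.split(np.zeros(n), delta)]
        else:
            splitter = KFold(n_splits=nfolds, shuffle=True, random_state=state)
            splits = [test for _, test in splitter.split(np.zeros(n))]
        ok = all(delta.sum() - delta[test].sum() >= 1 for test in splits)
        if ok:
            return splits
        if not stratify:
            raise ValueError("a CV fold's training split contains no events; "
                             "use stratified folds or fewer folds")
    raise ValueError("could not build event-covering stratified folds")


def _batch_breslow_nll(E_s: np.ndarray, d_s: np.ndarray, group_start: np.ndarray,
                       group_delta: np.ndarray) -> np.ndarray:
    """Breslow NLL for many linear predictors at once (columns of E_s)."""
    if group_delta.sum() == 0:
        return np.zeros(E_s.shape[1])
    m = E_s.max(axis=0)
    e = np.exp(E_s - m)
    suffix = np.cumsum(e[::-1], axis=0)[::-1]
    S = suffix[group_start[:-1]]
    return -(d_s @ E_s) + group_delta @ (np.log(S) + m)


def cv_partial_loglik(view: CauseView, X: np.ndarray,
                      beta_per_fold: list[np.ndarray],
                      folds: list[np.ndarray]) -> np.ndarray:
    """Verweij-Van Houwelingen cross-validated partial log-likelihood per lambda.

    Each fold contributes ``NLL(all data, beta_{-f}) - NLL(training data,
    beta_{-f})``; the negated sum over folds is returned, so larger is
    better.  Lambdas with non-finite contributions are set to -inf.
    """
    n = X.shape[0]
    covered = np.sort(np.concatenate(folds))
    if covered.shape[0] != n or not np.array_equal(covered, np.arange(n)):
        raise ValueError("folds must partition the observations")
    idx, d_s, gs, gd = view.risk_order()
    Xs = X[idx]
    L = beta_per_fold[0].shape[0]
    cv = np.zeros(L)
    for test, B in zip(folds, beta_per_fold):
        cols = np.flatnonzero(np.any(B != 0.0, axis=0))  # only active features matter
        Bc = B[:, cols]
        E_full = Xs[:, cols] @ Bc.T
        nll_full = _batch_breslow_nll(E_full, d_s, gs, gd)
        train = np.setdiff1d(np.arange(n), test)
        sub = CauseView(time=view.time[train], delta=view.delta[train], cause=view.cause)
        idx_t, d_t, gs_t, gd_t = sub.risk_order()
        E_train = X[train][idx_t][:, cols] @ Bc.T
        nll_train = _batch_breslow_nll(E_train, d_t, gs_t, gd_t)
        cv -= nll_full - nll_train
    bad = ~np.isfinite(cv)
    if bad.any():
        logger.warning("excluding %d lambda values with non-finite CV contributions", bad.sum())
        cv[bad] = -np.inf
    return cv


def fit_fwcoxnet(view: CauseView, X: np.ndarray,
                 z: FeatureInfo | np.ndarray | None = None,
                 config: PenaltyConfig | None = None,
                 seed: int = 0,
                 feature_names: list[str] | None = None) -> FwcoxnetFit:
    """Cross-validated fwcoxnet fit for one cause.

    ``z = None`` (or a constant vector) freezes theta at 0, which is exactly
    a plain Cox elastic net.  Scores are rescaled to unit maximum magnitude
    before entering the weight function — only relative magnitudes matter.
    Coefficients are returned on the input covariate scale at lambda.min.
    """
    cfg = config or PenaltyConfig()
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if view.n_events == 0:
        warnings.warn(f"no events for cause {view.cause}: returning the null fit")
        return FwcoxnetFit(beta=np.zeros(p), theta=0.0, lambda_selected=np.nan,
                           cv_loglik=np.array([]), objective_trace=np.array([]),
                           lambdas=np.array([]), feature_names=feature_names,
                           n_events=0, null_fit=True, warning="no events")
    if view.n_events < cfg.nfolds:
        raise ValueError(
            f"cause {view.cause} has {view.n_events} events, fewer than nfolds={cfg.nfolds}")

    z_std: np.ndarray | None
    if z is None:
        z_std = None
    else:
        zv = z.z if isinstance(z, FeatureInfo) else np.asarray(z, dtype=np.float64).ravel()
        if zv.shape[0] != p:
            raise ValueError("z length must equal the number of covariates")
        zmax = np.max(np.abs(zv))
        z_std = None if zmax == 0.0 or np.ptp(zv) == 0.0 else zv / zmax

    ctx = _FitContext(view, X, cfg.standardize)
    if cfg.lambda_path is not None:
        lambdas = cfg.lambda_path
    else:
        lambdas = lambda_path(ctx.view_sorted, ctx.Xs, cfg.alpha,
                              n_lambda=cfg.n_lambda,
                              lambda_min_ratio=cfg.lambda_min_ratio)

    betas_std, thetas, traces, n_valid = _fit_path(ctx, z_std, lambdas, cfg)

    folds = make_cv_folds(view.delta, cfg.nfolds, cfg.stratify_by_status, seed)
    beta_per_fold = []
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        sub_view = CauseView(time=view.time[train], delta=view.delta[train], cause=view.cause)
        sub_ctx = _FitContext(sub_view, X[train], cfg.standardize)
        b_std, _, _, nv = _fit_path(sub_ctx, z_std, lambdas, cfg)
        n_valid = min(n_valid, nv)
        beta_per_fold.append(b_std / sub_ctx.scale)  # back to the input scale
    # lambda.min is chosen among path points every fit completed
    beta_per_fold = [b[:n_valid] for b in beta_per_fold]
    cv_ll = cv_partial_loglik(view, X, beta_per_fold, folds)

    sel = int(np.argmax(cv_ll))
    # tight re-polish at lambda.min (the path runs at pathwise tolerance)
    lam = float(lambdas[sel])
    beta_std = betas_std[sel].copy()
    theta = float(thetas[sel])
    tsolver = None if z_std is None else _ThetaSolver(z_std, cfg.theta_max)
    trace_polish: list[float] = []
    pobj_prev = np.inf
    for _outer in range(cfg.max_outer):
        wv = np.ones(p) if z_std is None else weight_vector(z_std, theta).w
        ws_mask = np.ones(p, dtype=np.bool_)
        nll, _, _ = _solve_at(ctx, lam * cfg.alpha * wv, lam * (1.0 - cfg.alpha) * wv,
                              beta_std, ws_mask, cd_tol=1e-11, irls_tol=1e-10)
        q = cfg.alpha * np.abs(beta_std) + 0.5 * (1.0 - cfg.alpha) * beta_std**2
        if z_std is not None and q.any():
            theta = tsolver.step(q, theta)
            wv = weight_vector(z_std, theta).w
        pobj = nll / ctx.n + lam * float(wv @ q)
        trace_polish.append(pobj)
        if z_std is None or not q.any() or pobj_prev - pobj < cfg.thresh * max(1.0, abs(pobj)):
            break
        pobj_prev = pobj
    beta = beta_std / ctx.scale
    return FwcoxnetFit(
        beta=beta,
        theta=theta,
        lambda_selected=lam,
        cv_loglik=cv_ll,
        objective_trace=np.asarray(trace_polish),
        lambdas=lambdas,
        feature_names=feature_names,
        n_events=view.n_events,
    )
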