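"""Cox partial-likelihood machinery for cause-specific competing-risks models.

A competing-risks dataset carries an observed time, a status code
(0 = censored, 1 or 2 = event of that cause) and a covariate matrix.
Cause-specific modelling treats events of the competing cause as censored,
which reduces each cause to an ordinary right-censored Cox problem; this
module provides the negative log partial likelihood (Breslow convention for
ties), its gradient, and the diagonal IRLS quadratic approximation consumed
by the penalized solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurvivalDataset",
    "CauseView",
    "CoxQuadratic",
    "cox_nll",
    "cox_gradient",
    "cox_quadratic",
]


@dataclass
class SurvivalDataset:
    """Right-censored competing-risks data: (time, status, X).

    Parameters
    ----------
    time : array of shape (n,)
        Strictly positive observation times.
    status : array of shape (n,)
        Integer codes: 0 = censored, 1 = event of cause 1, 2 = event of
        cause 2.
    X : array of shape (n, p)
        Covariate matrix without missing values.
    feature_names : list of str, optional
        Column labels; defaults to ``x1 .. xp``.
    """

    time: np.ndarray
    status: np.ndarray
    X: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.status = np.asarray(self.status)
        self.X = np.ascontiguousarray(np.asarray(self.X, dtype=np.float64))
        if self.time.ndim != 1 or self.status.shape != self.time.shape:
            raise ValueError("time and status must be 1-d arrays of equal length")
        if self.X.ndim != 2 or self.X.shape[0] != self.time.shape[0]:
            raise ValueError("X must be an (n, p) matrix aligned with time")
        if self.time.shape[0] < 2:
            raise ValueError("need at least two observations")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("all times must be finite and strictly positive")
        status_int = np.asarray(self.status)
        if not np.all(np.isin(status_int, (0, 1, 2))):
            bad = np.flatnonzero(~np.isin(status_int, (0, 1, 2)))
            raise ValueError(f"status codes must be in {{0,1,2}}; bad rows: {bad[:10].tolist()}")
        self.status = status_int.astype(np.int64)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("covariate matrix contains non-finite values")
        if self.feature_names is None:
            self.feature_names = [f"x{j + 1}" for j in range(self.X.shape[1])]
        elif len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal the number of columns of X")

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def cause_view(self, cause: int) -> "CauseView":
        """Binary event view for one cause; the competing event is censored."""
        if cause not in (1, 2):
            raise ValueError(f"cause must be 1 or 2, got {cause!r}")
        return CauseView(time=self.time, delta=(self.status == cause).astype(np.float64), cause=cause)


@dataclass
class CauseView:
    """One cause-specific view: times with a binary event indicator delta_k."""

    time: np.ndarray
    delta: np.ndarray
    cause: int = 1
    _order: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.delta = np.asarray(self.delta, dtype=np.float64)
        if self.time.shape != self.delta.shape or self.time.ndim != 1:
            raise ValueError("time and delta must be 1-d arrays of equal length")
        if not np.all(np.isin(self.delta, (0.0, 1.0))):
            raise ValueError("delta must be binary")

    @property
    def n_events(self) -> int:
        return int(self.delta.sum())

    def risk_order(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Ascending-time ordering and tie-group boundaries.

        Returns ``(sort_idx, delta_sorted, group_start, group_delta)`` where
        ``group_start`` has a trailing sentinel equal to n, so tie group g
        spans ``sort_idx[group_start[g]:group_start[g+1]]``.
        """
        if self._order is None:
            idx = np.argsort(self.time, kind="stable")
            t_s = self.time[idx]
            d_s = self.delta[idx]
            n = t_s.shape[0]
            new_group = np.empty(n, dtype=bool)
            new_group[0] = True
            np.greater(t_s[1:], t_s[:-1], out=new_group[1:])
            starts = np.flatnonzero(new_group)
            group_start = np.append(starts, n).astype(np.int64)
            group_delta = np.add.reduceat(d_s, starts)
            self._order = (idx, d_s, group_start, group_delta)
        return self._order


@dataclass
class CoxQuadratic:
    """IRLS linearization of the Cox NLL around a linear predictor.

    One penalized weighted-least-squares step on ``(working_response,
    working_weight)`` equals one (diagonal-Hessian) Newton-type step on the
    negative log partial likelihood.
    """

    working_response: np.ndarray
    working_weight: np.ndarray
    linear_predictor: np.ndarray

    @property
    def degenerate(self) -> bool:
        """True when every working weight vanishes (no usable events)."""
        return bool(np.all(self.working_weight == 0.0))


def _breslow_numpy(eta_s: np.ndarray, delta_s: np.ndarray, group_start: np.ndarray,
                   group_delta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """NLL, d NLL/d eta and diagonal Hessian in sorted (ascending-time) order."""
    n = eta_s.shape[0]
    if group_delta.sum() == 0:
        return 0.0, np.zeros(n), np.zeros(n)
    m = float(eta_s.max())
    e = np.exp(eta_s - m)
    starts = group_start[:-1]
    # suffix risk sums: risk set at group g = all rows with time >= t_g
    suffix = np.cumsum(e[::-1])[::-1]
    S = suffix[starts]
    nll = -float(delta_s @ eta_s) + float(group_delta @ (np.log(S) + m))
    a = np.cumsum(group_delta / S)          # sum of d_g / S_g over groups <= current
    b = np.cumsum(group_delta / S**2)
    group_sizes = np.diff(group_start)
    a_i = np.repeat(a, group_sizes)
    b_i = np.repeat(b, group_sizes)
    grad = -delta_s + e * a_i               # the stabilizing shift m cancels
    hess = e * a_i - e**2 * b_i
    np.maximum(hess, 0.0, out=hess)         # guard tiny negative round-off
    return nll, grad, hess


def _validate_inputs(beta: np.ndarray, view: CauseView, X: np.ndarray) -> np.ndarray:
    beta = np.asarray(beta, dtype=np.float64)
    if beta.shape != (X.shape[1],):
        raise ValueError("beta length must equal the number of covariates")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains non-finite values")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariate matrix contains non-finite values")
    if X.shape[0] != view.time.shape[0]:
        raise ValueError("X rows must align with the view's observations")
    if X.shape[0] < 1:
        raise ValueError("need at least one observation")
    return beta


def cox_nll(beta: np.ndarray, view: CauseView, X: np.ndarray) -> float:
    """Negative log Cox partial likelihood (Breslow convention for ties).

    Returns 0 when the view contains no events.  The value is the raw sum
    over events, so at ``beta = 0`` it equals the sum of log risk-set sizes.
    """
    beta = _validate_inputs(beta, view, X)
    idx, d_s, gs, gd = view.risk_order()
    eta_s = X[idx] @ beta
    nll, _, _ = _breslow_numpy(eta_s, d_s, gs, gd)
    return float(nll)


def cox_gradient(beta: np.ndarray, view: CauseView, X: np.ndarray) -> np.ndarray:
    """Exact gradient of :func:`cox_nll` with respect to beta."""
    beta = _validate_inputs(beta, view, X)
    idx, d_s, gs, gd = view.risk_order()
    Xs = X[idx]
    eta_s = Xs @ beta
    _, g_eta, _ = _breslow_numpy(eta_s, d_s, gs, gd)
    return Xs.T @ g_eta


def cox_quadratic(beta: np.ndarray, view: CauseView, X: np.ndarray) -> CoxQuadratic:
    """Diagonal-Hessian IRLS approximation of the Cox NLL at beta.

    Working weights are the diagonal of the Breslow Hessian; the working
    response is the Newton target ``eta - grad/hess`` wherever the weight is
    positive.  Rows with (numerically) zero weight are flagged by weight 0
    and contribute nothing to the weighted least-squares step.
    """
    beta = _validate_inputs(beta, view, X)
    idx, d_s, gs, gd = view.risk_order()
    Xs = X[idx]
    eta_s = Xs @ beta
    _, g_eta, h_eta = _breslow_numpy(eta_s, d_s, gs, gd)
    n = eta_s.shape[0]
    z_s = eta_s.copy()
    pos = h_eta > 1e-12
    z_s[pos] -= g_eta[pos] / h_eta[pos]
    h_eta = np.where(pos, h_eta, 0.0)
    # scatter back to the original observation order
    inv = np.empty(n, dtype=np.int64)
    inv[idx] = np.arange(n)
    return CoxQuadratic(
        working_response=z_s[inv],
        working_weight=h_eta[inv],
        linear_predictor=eta_s[inv],
    )
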