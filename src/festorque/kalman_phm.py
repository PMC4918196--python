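"""Forgetting-factor Kalman estimation of a polynomial Hammerstein model.

The model maps the per-loop eEMG MAV ``u(k)`` to torque ``y(k)``:

    y(k) = sum_i a_i y(k-i) + sum_{i,j} d_ij u^j(k-i) + w(k)

with ``i = 1..l`` output lags, ``i = 1..m`` input lags and powers
``j = 1..n``.  The static-nonlinearity and linear-block coefficients enter
only through their products, so the estimator identifies the coupled
``d_ij`` directly (the factorization is not identifiable).

Two recursive formulations are provided:

* ``mode="parameters"`` — pure parameter estimation (RLS with forgetting):
  the state is the parameter vector, the regressor is built from *measured*
  outputs.  With forgetting factor 1 and a diffuse prior this reproduces
  batch least squares, which the tests exploit as an oracle.
* ``mode="joint"`` — EKF-style joint state/parameter estimation: the state
  augments the last ``l`` (estimated) outputs with the parameters, the
  output block is propagated through the model and the observation selects
  its first component.

Both run in constant time per loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from time import perf_counter

import numpy as np
from numpy.typing import ArrayLike, NDArray

DEFAULT_LAMBDA = 0.95
DEFAULT_P0 = 1.0e3
DIVERGENCE_BOUND = 1.0e8


@dataclass(frozen=True)
class PHMParameters:
    """Identified polynomial-Hammerstein coefficients."""

    l: int
    m: int
    n: int
    a: NDArray[np.float64]  # output-lag coefficients, length l
    d: NDArray[np.float64]  # coupled input coefficients, shape (m, n)

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float).reshape(self.m, self.n))
        if min(self.l, self.m, self.n) < 1:
            raise ValueError("model orders must be >= 1")
        if self.a.shape != (self.l,):
            raise ValueError("a must have length l")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.d))):
            raise ValueError("parameters must be finite")

    @property
    def n_params(self) -> int:
        return self.l + self.m * self.n

    def theta(self) -> NDArray[np.float64]:
        return np.concatenate([self.a, self.d.ravel()])

    @classmethod
    def from_theta(cls, theta: ArrayLike, l: int, m: int, n: int) -> "PHMParameters":
        theta = np.asarray(theta, dtype=float)
        return cls(l=l, m=m, n=n, a=theta[:l], d=theta[l:].reshape(m, n))


@dataclass
class KalmanState:
    """Augmented state vector, covariance and forgetting factor."""

    x: NDArray[np.float64]
    P: NDArray[np.float64]
    lam: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not (0.9 <= self.lam <= 1.0):
            raise ValueError("forgetting factor must lie in [0.9, 1]")
        if self.P.shape != (self.x.size, self.x.size):
            raise ValueError("P must be square and match the state dimension")


@dataclass(frozen=True)
class PrioriEstimate:
    """Output of the a-priori phase, consumed by the a-posteriori update."""

    x_hat: NDArray[np.float64]
    P_hat: NDArray[np.float64]
    y_hat: float
    H: NDArray[np.float64]  # observation row (1, dim)


def poly_basis(u: float, n: int) -> NDArray[np.float64]:
    """Monomial basis ``[u, u^2, ..., u^n]`` of the static nonlinearity."""
    if n < 1:
        raise ValueError("polynomial degree must be >= 1")
    return np.asarray(u, dtype=float) ** np.arange(1, n + 1)


def phm_regressor(
    y_hist: ArrayLike, u_hist: ArrayLike, l: int, m: int, n: int
) -> NDArray[np.float64]:
    """Linear-in-parameters regressor row.

    ``y_hist``/``u_hist`` hold the most recent values first:
    ``y_hist[0] = y(k-1)``, ``u_hist[0] = u(k-1)``.
    """
    y_hist = np.asarray(y_hist, dtype=float)
    u_hist = np.asarray(u_hist, dtype=float)
    phi_u = np.concatenate([poly_basis(u_hist[i - 1], n) for i in range(1, m + 1)])
    return np.concatenate([y_hist[:l], phi_u])


def phm_predict_one(params: PHMParameters, y_hist: ArrayLike, u_hist: ArrayLike) -> float:
    """One-step model output from the most-recent-first histories."""
    phi = phm_regressor(y_hist, u_hist, params.l, params.m, params.n)
    return float(phi @ params.theta())


def _split_joint(x: NDArray[np.float64], l: int) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    return x[:l], x[l:]


def kf_priori(
    state: KalmanState,
    u_hist: ArrayLike,
    y_hist: ArrayLike,
    orders: tuple[int, int, int],
    mode: str = "joint",
) -> PrioriEstimate:
    """A-priori phase: propagate the state and inflate the covariance by 1/lambda.

    ``u_hist``/``y_hist`` are most-recent-first (``u_hist[0] = u(k-1)``);
    in joint mode the output lags come from the state itself and ``y_hist``
    is ignored.
    """
    l, m, n = orders
    if not np.all(np.isfinite(state.x)):
        raise FloatingPointError("estimator diverged")
    u_hist = np.asarray(u_hist, dtype=float)
    dim = state.x.size

    if mode == "parameters":
        phi = phm_regressor(y_hist, u_hist, l, m, n)
        x_hat = state.x.copy()
        P_hat = state.P / state.lam
        return PrioriEstimate(x_hat, P_hat, float(phi @ x_hat), phi.reshape(1, -1))

    if mode != "joint":
        raise ValueError("mode must be 'joint' or 'parameters'")

    y_state, theta = _split_joint(state.x, l)
    params = PHMParameters.from_theta(theta, l, m, n)
    phi = phm_regressor(y_state, u_hist, l, m, n)
    y_new = float(phi @ theta)

    x_hat = state.x.copy()
    x_hat[0] = y_new
    if l > 1:
        x_hat[1:l] = y_state[:-1]

    # Jacobian of the propagation at the current estimate
    A = np.eye(dim)
    A[0, :l] = params.a
    A[0, l:] = phi  # d y_new / d theta
    for i in range(1, l):
        A[i, :] = 0.0
        A[i, i - 1] = 1.0
    P_hat = A @ state.P @ A.T / state.lam

    H = np.zeros((1, dim))
    H[0, 0] = 1.0
    return PrioriEstimate(x_hat, P_hat, y_new, H)


def kf_posteriori(state: KalmanState, priori: PrioriEstimate, y_meas: float) -> KalmanState:
    """A-posteriori phase: innovation-weighted correction of state and covariance.

    ``S = H P_hat H' + lambda I``, ``K = P_hat H' S^-1``,
    ``x <- x_hat + K (y - y_hat)``, ``P <- (I - K H) P_hat``.
    """
    H = priori.H
    S = H @ priori.P_hat @ H.T + state.lam * np.eye(H.shape[0])
    if abs(np.linalg.det(S)) < np.finfo(float).tiny:
        raise np.linalg.LinAlgError("singular innovation covariance")
    K = priori.P_hat @ H.T @ np.linalg.inv(S)
    x_new = priori.x_hat + (K * (y_meas - priori.y_hat)).ravel()
    P_new = (np.eye(state.x.size) - K @ H) @ priori.P_hat
    P_new = 0.5 * (P_new + P_new.T)  # guard symmetry against round-off
    return KalmanState(x=x_new, P=P_new, lam=state.lam)


@dataclass(frozen=True)
class IdentificationResult:
    params: PHMParameters
    y_pred: NDArray[np.float64]  # one-step-ahead predictions per loop
    state: KalmanState
    theta_trace: NDArray[np.float64]  # parameter trajectory, (n_loops, n_params)
    per_loop_time_s: NDArray[np.float64] = None  # wall time of each recursive update


def kf_identify(
    u: ArrayLike,
    y: ArrayLike,
    orders: tuple[int, int, int] = (2, 2, 2),
    lam: float = DEFAULT_LAMBDA,
    mode: str = "joint",
    p0: float = DEFAULT_P0,
    theta0: ArrayLike | None = None,
) -> IdentificationResult:
    """Run the recursive estimator over an identification record.

    Parameters are initialized at zero (or ``theta0``), the output block of
    the joint state at the first measured output, and the covariance at the
    diffuse ``p0 * I``.  Histories before the record start are zero-padded.

    Raises
    ------
    FloatingPointError
        If the state norm exceeds the divergence bound ("identification
        failed").
    """
    l, m, n = orders
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    if u.shape != y.shape or u.ndim != 1:
        raise ValueError("u and y must be 1-D arrays of equal length")
    n_par = l + m * n
    if u.size <= n_par:
        raise ValueError("identification failed: series shorter than parameter count")

    theta_init = np.zeros(n_par) if theta0 is None else np.asarray(theta0, dtype=float)
    if mode == "parameters":
        x0 = theta_init.copy()
    else:
        x0 = np.concatenate([np.full(l, y[0]), theta_init])
    state = KalmanState(x=x0, P=p0 * np.eye(x0.size), lam=lam)

    y_pred = np.empty(u.size)
    theta_trace = np.empty((u.size, n_par))
    loop_times = np.empty(u.size)
    for k in range(u.size):
        tic = perf_counter()
        u_hist = np.array([u[k - i] if k - i >= 0 else 0.0 for i in range(1, m + 1)])
        y_hist = np.array([y[k - i] if k - i >= 0 else 0.0 for i in range(1, l + 1)])
        pri = kf_priori(state, u_hist, y_hist, orders, mode=mode)
        y_pred[k] = pri.y_hat
        state = kf_posteriori(state, pri, float(y[k]))
        if not np.all(np.isfinite(state.x)) or np.linalg.norm(state.x) > DIVERGENCE_BOUND:
            raise FloatingPointError(f"identification failed: estimator diverged at loop {k}")
        theta_trace[k] = state.x if mode == "parameters" else state.x[l:]
        loop_times[k] = perf_counter() - tic

    theta_final = state.x if mode == "parameters" else state.x[l:]
    return IdentificationResult(
        params=PHMParameters.from_theta(theta_final, l, m, n),
        y_pred=y_pred,
        state=state,
        theta_trace=theta_trace,
        per_loop_time_s=loop_times,
    )


def kf_free_run_predict(
    u: ArrayLike,
    params: PHMParameters,
    y_init: ArrayLike | None = None,
    u_init: ArrayLike | None = None,
) -> NDArray[np.float64]:
    """Iterate the identified model with its own outputs fed back.

    ``y_init`` / ``u_init`` seed the lag histories with the last values of
    the identification phase, ordered oldest to newest; missing history is
    zero.  Measured torque is never read: the prediction at loop ``k``
    depends only on ``u`` up to ``k-1`` and on earlier predictions.
    """
    u = np.asarray(u, dtype=float)
    l, m = params.l, params.m
    y_hist = np.zeros(l)  # most recent first
    if y_init is not None:
        y_init = np.asarray(y_init, dtype=float)
        take = min(l, y_init.size)
        y_hist[:take] = y_init[::-1][:take]
    u_hist = np.zeros(m)
    if u_init is not None:
        u_init = np.asarray(u_init, dtype=float)
        take = min(m, u_init.size)
        u_hist[:take] = u_init[::-1][:take]

    out = np.empty(u.size)
    for k in range(u.size):
        y_new = phm_predict_one(params, y_hist, u_hist)
        out[k] = y_new
        y_hist = np.concatenate([[y_new], y_hist[:-1]])
        u_hist = np.concatenate([[u[k]], u_hist[:-1]])
    return out
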