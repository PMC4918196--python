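"""NARX torque model: one-shot pseudoinverse identification, free-run prediction.

The model augments an ARX-with-polynomial-input structure with two bilinear
input-output cross terms:

    tau(k) = sum_r v_r tau(k-r) + sum_{i,j} w_ij u^j(k-i)
             + a u(k-m) tau(k-1) + b u(k-1) tau(k-l)

with output lags ``r = 1..l``, input lags ``i = 1..m`` and powers
``j = 1..n``.  Identification stacks one regression row per loop into a
design matrix and solves it once, at the end of the identification phase,
by SVD pseudoinverse (minimum-norm least squares); from then on the
coefficients are frozen and the model runs free, feeding its own
predictions back into the lagged and cross terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray


@dataclass(frozen=True)
class NARXParameters:
    """Identified NARX coefficients, frozen after loop ``k_id``."""

    l: int
    m: int
    n: int
    v: NDArray[np.float64]  # output-lag coefficients, length l
    w: NDArray[np.float64]  # input-power coefficients, shape (m, n)
    a: float  # coefficient of u(k-m) * tau(k-1)
    b: float  # coefficient of u(k-1) * tau(k-l)
    k_id: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float).reshape(self.m, self.n))
        if min(self.l, self.m, self.n) < 1:
            raise ValueError("model orders must be >= 1")
        if self.v.shape != (self.l,):
            raise ValueError("v must have length l")
        finite = np.all(np.isfinite(self.v)) and np.all(np.isfinite(self.w))
        if not (finite and np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("parameters must be finite")

    @property
    def n_params(self) -> int:
        return self.l + self.m * self.n + 2

    def coeffs(self) -> NDArray[np.float64]:
        return np.concatenate([self.v, self.w.ravel(), [self.a, self.b]])

    @classmethod
    def from_coeffs(
        cls, coeffs: ArrayLike, l: int, m: int, n: int, k_id: int
    ) -> "NARXParameters":
        c = np.asarray(coeffs, dtype=float)
        return cls(
            l=l, m=m, n=n,
            v=c[:l],
            w=c[l : l + m * n].reshape(m, n),
            a=float(c[-2]),
            b=float(c[-1]),
            k_id=k_id,
        )


@dataclass(frozen=True)
class DesignMatrix:
    """Stacked regression rows ``[Y, X_1..X_m, C_1, C_2]`` and their targets."""

    D: NDArray[np.float64]
    target: NDArray[np.float64]
    orders: tuple[int, int, int]

    def __post_init__(self) -> None:
        l, m, n = self.orders
        if self.D.shape != (self.target.size, l + m * n + 2):
            raise ValueError("alignment error: design shape inconsistent with orders")


def _at(x: NDArray[np.float64], i: int) -> float:
    """Series value with zero pre-history (index < 0 contributes 0)."""
    return float(x[i]) if i >= 0 else 0.0


def narx_row(
    u: NDArray[np.float64],
    tau: NDArray[np.float64],
    t: int,
    orders: tuple[int, int, int],
) -> NDArray[np.float64]:
    """Regression row predicting ``tau(t)``; indices before the start are zero."""
    l, m, n = orders
    row = np.empty(l + m * n + 2)
    for r in range(1, l + 1):
        row[r - 1] = _at(tau, t - r)
    pos = l
    for i in range(1, m + 1):
        ui = _at(u, t - i)
        for j in range(1, n + 1):
            row[pos] = ui**j
            pos += 1
    row[pos] = _at(u, t - m) * _at(tau, t - 1)
    row[pos + 1] = _at(u, t - 1) * _at(tau, t - l)
    return row


def build_design_matrix(
    u: ArrayLike, tau: ArrayLike, orders: tuple[int, int, int] = (2, 2, 2)
) -> DesignMatrix:
    """One row per loop ``t = 0..k-1`` regressing ``tau(t)`` on its lagged terms.

    The first rows carry the leading-zero padding of the pre-history: every
    lagged index before the series start contributes zero (the row for
    ``t = 0`` is entirely zero).
    """
    u = np.asarray(u, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if u.shape != tau.shape or u.ndim != 1:
        raise ValueError("alignment error: u and tau must be 1-D of equal length")
    if u.size < 1:
        raise ValueError("alignment error: empty series")
    D = np.vstack([narx_row(u, tau, t, orders) for t in range(u.size)])
    return DesignMatrix(D=D, target=tau.copy(), orders=orders)


def identify_narx(design: DesignMatrix, rcond: float | None = None) -> NARXParameters:
    """Minimum-norm least-squares coefficients via SVD pseudoinverse.

    Singular values below ``max(D.shape) * eps * sigma_max`` are truncated
    (numpy's default), which keeps the solve stable under the collinearity
    of polynomial regressors.  The residual is orthogonal to the retained
    column space by construction.
    """
    if design.D.size == 0 or design.target.size == 0:
        raise ValueError("no identification data")
    coeffs, *_ = np.linalg.lstsq(design.D, design.target, rcond=rcond)
    l, m, n = design.orders
    return NARXParameters.from_coeffs(coeffs, l, m, n, k_id=int(design.target.size - 1))


def narx_predict_one(
    params: NARXParameters, tau_hist: NDArray[np.float64], u_hist: NDArray[np.float64]
) -> float:
    """One model step from most-recent-first histories
    (``tau_hist[0] = tau(k-1)``, ``u_hist[0] = u(k-1)``)."""
    l, m, n = params.l, params.m, params.n
    out = float(params.v @ tau_hist[:l])
    for i in range(1, m + 1):
        ui = u_hist[i - 1]
        out += float(params.w[i - 1] @ ui ** np.arange(1, n + 1))
    out += params.a * u_hist[m - 1] * tau_hist[0]
    out += params.b * u_hist[0] * tau_hist[l - 1]
    return out


def narx_free_run_predict(
    u: ArrayLike,
    params: NARXParameters,
    tau_init: ArrayLike | None = None,
    u_init: ArrayLike | None = None,
) -> NDArray[np.float64]:
    """Iterate the frozen model over ``u`` feeding predictions back.

    ``tau_init`` seeds the ``l`` output lags and ``u_init`` the ``m`` input
    lags with the last values of the identification phase (oldest to
    newest); missing history is zero.  With all-zero coefficients the
    output is identically zero.

    Raises
    ------
    FloatingPointError
        If the recursion produces a non-finite value ("free-run diverged"),
        reported with the loop index.
    """
    u = np.asarray(u, dtype=float)
    l, m = params.l, params.m
    tau_hist = np.zeros(l)  # most recent first
    if tau_init is not None:
        tau_init = np.asarray(tau_init, dtype=float)
        take = min(l, tau_init.size)
        tau_hist[:take] = tau_init[::-1][:take]
    u_hist = np.zeros(m)
    if u_init is not None:
        u_init = np.asarray(u_init, dtype=float)
        take = min(m, u_init.size)
        u_hist[:take] = u_init[::-1][:take]

    out = np.empty(u.size)
    for k in range(u.size):
        val = narx_predict_one(params, tau_hist, u_hist)
        if not np.isfinite(val):
            raise FloatingPointError(f"free-run diverged at loop {k}")
        out[k] = val
        tau_hist = np.concatenate([[val], tau_hist[:-1]])
        u_hist = np.concatenate([[u[k]], u_hist[:-1]])
    return out


def narx_simulate(
    u: ArrayLike, params: NARXParameters, noise_sd: float = 0.0, seed: int = 0
) -> NDArray[np.float64]:
    """Generate a torque series from known coefficients (test oracle).

    Identical recursion to the free run from zero history, optionally with
    additive Gaussian noise on the generated output.
    """
    clean = narx_free_run_predict(u, params)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        return clean + rng.normal(0.0, noise_sd, clean.size)
    return clean
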