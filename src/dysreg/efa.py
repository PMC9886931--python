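"""Maximum-likelihood exploratory factor analysis with Oblimin rotation.

Extraction profiles the ML discrepancy over the uniquenesses: for fixed
uniqueness matrix Psi the optimal loadings come from the eigen-structure
of Psi^{-1/2} S Psi^{-1/2}, leaving a smooth objective

    F(Psi) = sum_{i>m} (gamma_i - log gamma_i - 1)

over the trailing eigenvalues gamma_i, minimized by L-BFGS-B on log
uniquenesses with an analytic gradient.  Rotation uses the oblique
gradient-projection algorithm on the oblimin family (gamma = 0, direct
quartimin, by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["EfaSolution", "ml_efa", "efa_df", "oblimin_rotate", "parallel_analysis"]

_MIN_UNIQUENESS = 0.005  # Heywood guard


class EfaConvergenceError(RuntimeError):
    pass


@dataclass
class EfaSolution:
    """An m-factor ML solution on a standardized correlation matrix."""

    m: int
    loadings: np.ndarray  # p x m (unrotated) or pattern (after rotation)
    uniqueness: np.ndarray  # p
    phi: np.ndarray  # m x m factor correlations (identity when unrotated)
    T: float  # ML test statistic (chi-square scale)
    df: int
    F_min: float
    n: int
    rotation: str = "none"
    gamma: float = 0.0
    heywood: bool = False
    variance_explained: np.ndarray | None = None  # proportional, per factor
    variable_names: list | None = None

    @property
    def communality(self) -> np.ndarray:
        return 1.0 - self.uniqueness

    def cumulative_variance(self) -> np.ndarray:
        if self.variance_explained is None:
            raise ValueError("variance_explained not computed")
        return np.cumsum(self.variance_explained)

    def pattern_table(self, suppress_below: float = 0.1) -> pd.DataFrame:
        """Printable loading table; small loadings blanked for display only."""
        names = self.variable_names or [f"v{i+1}" for i in range(len(self.uniqueness))]
        df = pd.DataFrame(
            self.loadings, index=names, columns=[f"F{k+1}" for k in range(self.m)]
        )
        return df.where(df.abs() >= suppress_below)


def efa_df(p: int, m: int) -> int:
    """Degrees of freedom of the m-factor model on p variables.

    [(p - m)^2 - (p + m)] / 2; zero means just-identified, negative means
    the model is over-parameterized and is rejected.
    """
    if not p > m >= 0:
        raise ValueError(f"need p > m >= 0, got p={p}, m={m}")
    df2 = (p - m) ** 2 - (p + m)
    if df2 % 2:
        raise ValueError(f"inconsistent (p={p}, m={m}): odd df numerator")
    df = df2 // 2
    if df < 0:
        raise ValueError(f"over-parameterized model: df = {df} < 0 for p={p}, m={m}")
    return df


def _objective(logpsi: np.ndarray, S: np.ndarray, m: int) -> tuple[float, np.ndarray]:
    psi = np.exp(logpsi)
    d = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(d, d)
    gam, V = np.linalg.eigh(Sstar)
    gam, V = gam[::-1], V[:, ::-1]  # descending
    tail = gam[m:]
    tail = np.maximum(tail, 1e-12)
    F = float(np.sum(tail - np.log(tail) - 1.0))
    # dF/dpsi_j = -(1/psi_j) * sum_{i>m} (gamma_i - 1) * V_ji^2 ; chain to log psi
    W = V[:, m:] ** 2
    grad_log = -(W @ (gam[m:] - 1.0))
    return F, grad_log


def ml_efa(
    S: np.ndarray | pd.DataFrame,
    n: int,
    m: int,
    n_restarts: int = 10,
    tol: float = 1e-6,
    seed: int = 0,
) -> EfaSolution:
    """Unrotated maximum-likelihood factor extraction from a correlation matrix.

    Heywood cases are bounded at uniqueness >= 0.005 and flagged.  The test
    statistic is T = (n - 1) * F_min on efa_df(p, m) degrees of freedom.
    """
    names = list(S.columns) if isinstance(S, pd.DataFrame) else None
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be a symmetric correlation matrix")
    if np.linalg.eigvalsh(S).min() < -1e-8:
        raise ValueError("S must be positive semi-definite")
    df = efa_df(p, m)

    if m == 0:
        F = float(-np.log(max(np.linalg.det(S), 1e-300)))
        return EfaSolution(
            m=0, loadings=np.zeros((p, 0)), uniqueness=np.ones(p),
            phi=np.zeros((0, 0)), T=(n - 1) * F, df=df, F_min=F, n=n,
            variable_names=names,
        )

    # start at 1 - squared multiple correlation
    Sinv = np.linalg.pinv(S)
    smc = 1.0 - 1.0 / np.maximum(np.diag(Sinv), 1.0)
    start = np.clip(1.0 - smc, 0.05, 1.0)
    rng = np.random.default_rng(seed)
    bounds = [(np.log(_MIN_UNIQUENESS), np.log(1.0))] * p

    best = None
    for trial in range(n_restarts):
        x0 = np.log(start) if trial == 0 else np.log(
            np.clip(start * np.exp(rng.normal(0, 0.3, p)), _MIN_UNIQUENESS, 1.0)
        )
        res = optimize.minimize(
            _objective, x0, args=(S, m), jac=True, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 1000, "ftol": tol * 1e-3, "gtol": tol},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if best.success and trial >= 0 and best.fun < tol and df == 0:
            break
    if best is None or not np.isfinite(best.fun):
        raise EfaConvergenceError("ML EFA failed to converge after restarts")

    psi = np.exp(best.x)
    d = 1.0 / np.sqrt(psi)
    gam, V = np.linalg.eigh(S * np.outer(d, d))
    gam, V = gam[::-1], V[:, ::-1]
    lam = np.sqrt(psi)[:, None] * V[:, :m] * np.sqrt(np.maximum(gam[:m] - 1.0, 0.0))
    # sign convention: positive column sums
    signs = np.where(lam.sum(axis=0) >= 0, 1.0, -1.0)
    lam = lam * signs
    F_min = float(best.fun)
    heywood = bool(np.any(psi <= _MIN_UNIQUENESS * (1 + 1e-6)))
    ve = (lam**2).sum(axis=0) / p
    return EfaSolution(
        m=m, loadings=lam, uniqueness=psi, phi=np.eye(m),
        T=float((n - 1) * F_min), df=df, F_min=F_min, n=n,
        heywood=heywood, variance_explained=ve, variable_names=names,
    )


# ----------------------------------------------------------------------
# Oblique rotation: gradient projection on the oblimin criterion
# ----------------------------------------------------------------------

def _oblimin_criterion(L: np.ndarray, gamma: float) -> tuple[float, np.ndarray]:
    """Oblimin criterion Q and its gradient dQ/dL (gamma=0: quartimin)."""
    p, m = L.shape
    L2 = L**2
    N = np.ones((m, m)) - np.eye(m)
    C = np.eye(p) - (gamma / p) * np.ones((p, p))
    X = C @ L2 @ N
    Q = float(np.sum(L2 * X) / 4.0)
    Gq = L * X
    return Q, Gq


def _gpa_oblique(
    A: np.ndarray, gamma: float, T0: np.ndarray, max_iter: int = 2000, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Oblique gradient-projection rotation (Jennrich-style).

    A is the unrotated loading matrix; returns (pattern, phi, Q, converged)
    with pattern = A (T')^{-1} and phi = T'T.
    """
    T = T0.copy()
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    Q, Gq = _oblimin_criterion(L, gamma)
    G = -((L.T @ Gq @ Ti).T)
    converged = False
    for _ in range(max_iter):
        Gp = G - T * (T * G).sum(axis=0, keepdims=True)
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            converged = True
            break
        al = 2.0 * al
        for _ in range(60):
            X = T - al * Gp
            X = X / np.sqrt((X**2).sum(axis=0, keepdims=True))
            Ti_new = np.linalg.inv(X)
            L_new = A @ Ti_new.T
            Q_new, Gq_new = _oblimin_criterion(L_new, gamma)
            if Q_new < Q - 0.5 * s**2 * al:
                break
            al = al / 2.0
        T, Ti, L, Q, Gq = X, Ti_new, L_new, Q_new, Gq_new
        G = -((L.T @ Gq @ Ti).T)
    phi = T.T @ T
    return L, phi, Q, converged


def oblimin_rotate(
    solution: EfaSolution,
    gamma: float = 0.0,
    n_restarts: int = 10,
    seed: int = 0,
) -> EfaSolution:
    """Oblique oblimin rotation of an unrotated ML solution.

    gamma = 0 gives direct quartimin.  Communalities (hence T and df) are
    rotation-invariant; factors are reordered by descending explained
    variance and sign-aligned so each column of the pattern sums >= 0.
    Explained variance uses squared structure loadings (pattern @ phi)
    summed per factor and divided by p.
    """
    A = solution.loadings
    p, m = A.shape
    if m == 1:
        ve = ((A @ np.eye(1)) ** 2).sum(axis=0) / p
        out = EfaSolution(
            m=1, loadings=A.copy(), uniqueness=solution.uniqueness.copy(),
            phi=np.eye(1), T=solution.T, df=solution.df, F_min=solution.F_min,
            n=solution.n, rotation="oblimin", gamma=gamma,
            heywood=solution.heywood, variance_explained=ve,
            variable_names=solution.variable_names,
        )
        return out
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(n_restarts):
        if trial == 0:
            T0 = np.eye(m)
        else:
            M = rng.normal(size=(m, m))
            Qm, _ = np.linalg.qr(M)
            T0 = Qm
            T0 = T0 / np.sqrt((T0**2).sum(axis=0, keepdims=True))
        L, phi, Q, conv = _gpa_oblique(A, gamma, T0)
        if conv and (best is None or Q < best[2] - 1e-12):
            best = (L, phi, Q)
    if best is None:
        raise EfaConvergenceError("oblimin rotation failed to converge after restarts")
    L, phi, _ = best

    structure = L @ phi
    ve = (structure**2).sum(axis=0) / p
    order = np.argsort(ve)[::-1]
    L, phi, ve = L[:, order], phi[np.ix_(order, order)], ve[order]
    signs = np.where(L.sum(axis=0) >= 0, 1.0, -1.0)
    L = L * signs
    phi = phi * np.outer(signs, signs)

    return EfaSolution(
        m=m, loadings=L, uniqueness=solution.uniqueness.copy(), phi=phi,
        T=solution.T, df=solution.df, F_min=solution.F_min, n=solution.n,
        rotation="oblimin", gamma=gamma, heywood=solution.heywood,
        variance_explained=ve, variable_names=solution.variable_names,
    )


def _pa_eigs(R: np.ndarray, kind: str) -> np.ndarray:
    if kind == "pca":
        return np.linalg.eigvalsh(R)[::-1]
    # factor variant: reduced correlation matrix with squared multiple
    # correlations on the diagonal (the convention of the standard
    # psychometrics tooling when retaining common factors)
    Rinv = np.linalg.pinv(R)
    smc = 1.0 - 1.0 / np.maximum(np.diag(Rinv), 1.0)
    Rr = R.copy()
    np.fill_diagonal(Rr, smc)
    return np.linalg.eigvalsh(Rr)[::-1]


def parallel_analysis(
    data: pd.DataFrame | np.ndarray,
    n_reps: int = 200,
    quantile: float = 0.95,
    seed: int = 0,
    kind: str = "fa",
) -> int:
    """Horn's parallel analysis for the number of factors to retain.

    Observed eigenvalues are compared against the chosen quantile of
    eigenvalues from standard-normal data of the same shape; the suggested
    count is the number of leading eigenvalues exceeding their threshold
    before the first failure.  ``kind="fa"`` (default) uses common-factor
    eigenvalues of the reduced correlation matrix, which stays sensitive to
    well-determined factors even when a strong general dimension dominates
    the raw spectrum; ``kind="pca"`` uses raw correlation eigenvalues.
    """
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    if kind not in ("fa", "pca"):
        raise ValueError(f"kind must be 'fa' or 'pca', got {kind!r}")
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    obs = _pa_eigs(np.corrcoef(X, rowvar=False), kind)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_reps, p))
    for r in range(n_reps):
        Z = rng.standard_normal((n, p))
        sims[r] = _pa_eigs(np.corrcoef(Z, rowvar=False), kind)
    # "higher" keeps the threshold conservative at finite n_reps (plain
    # interpolation underestimates the upper tail of the eigenvalue null)
    thresh = np.quantile(sims, quantile, axis=0, method="higher")
    m = 0
    for k in range(p):
        if obs[k] > thresh[k]:
            m += 1
        else:
            break
    return m
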