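"""Confirmatory factor analysis by maximum likelihood, from scratch.

The measurement model for p indicators and K latent regulatory domains is

    x = nu + Lambda eta + eps,   eta ~ N(alpha, Phi),  eps ~ N(0, Theta),

implying Sigma = Lambda Phi Lambda' + Theta and mu = nu + Lambda alpha.
Identification fixes every factor variance to 1 and every factor mean to 0
in unconstrained groups; in the measurement-invariance ladder, constraining
loadings across groups frees the second group's factor variances, and
constraining intercepts frees its factor means.

Estimation minimizes the Wishart ML discrepancy

    F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p  [+ (xbar-mu)' Sigma^-1 (xbar-mu)]

summed over groups with weights (n_g - 1); the test statistic is the
weighted discrepancy at the optimum, T = sum_g (n_g - 1) F_g.  A
quasi-Newton optimizer (L-BFGS-B) with the analytic gradient does the
minimization; standard errors come from the inverse expected information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SemModelSpec",
    "SemParameters",
    "SemFit",
    "default_cfa_spec",
    "second_order_spec",
    "bifactor_spec",
    "model_df",
    "count_free_parameters",
    "fit_cfa",
    "saturated_fit",
    "fit_indices",
    "information_criteria",
    "factor_scores",
]

CONSTRAINT_KINDS = ("loadings", "intercepts", "residuals")


class SemConvergenceError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# Model specification
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SemModelSpec:
    """Which indicator loads on which factor, plus structural options.

    ``loadings`` lists (indicator, factor) pairs — primary loadings and
    cross-loadings alike.  ``structure_kind`` selects among correlated
    first-order factors (default), a second-order general factor explaining
    the factor correlations, or a bifactor model with an orthogonal general
    factor alongside orthogonal specifics.
    """

    factors: tuple[str, ...]
    loadings: tuple[tuple[str, str], ...]
    mean_structure: bool = False
    structure_kind: str = "correlated-factors"

    def __post_init__(self):
        if len(self.factors) < 1:
            raise ValueError("need at least one factor")
        if self.structure_kind not in ("correlated-factors", "second-order", "bifactor"):
            raise ValueError(f"unknown structure_kind: {self.structure_kind!r}")
        known = set(self.factors) | ({"general"} if self.structure_kind == "bifactor" else set())
        for ind, fac in self.loadings:
            if fac not in known:
                raise ValueError(f"loading {ind!r} -> {fac!r}: unknown factor")
        for ind in self.indicators:
            if not any(i == ind for i, _ in self.loadings):
                raise ValueError(f"indicator {ind!r} has no loading")

    @property
    def indicators(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ind, _ in self.loadings:
            seen.setdefault(ind, None)
        return tuple(seen)

    @property
    def all_factors(self) -> tuple[str, ...]:
        if self.structure_kind == "bifactor":
            return self.factors + ("general",)
        return self.factors

    def with_means(self, flag: bool = True) -> "SemModelSpec":
        return SemModelSpec(self.factors, self.loadings, flag, self.structure_kind)

    @classmethod
    def from_config(cls, config: Mapping | str) -> "SemModelSpec":
        """Build a spec from a declarative config (dict or YAML path).

        Expected keys: ``factors`` mapping factor -> indicator list,
        optional ``cross_loadings`` as [indicator, factor] pairs, optional
        ``kind`` and ``mean_structure``.
        """
        if not isinstance(config, Mapping):
            import yaml

            with open(config) as fh:
                config = yaml.safe_load(fh) or {}
        factor_map = config["factors"]
        loadings = [
            (str(ind), str(fac)) for fac, inds in factor_map.items() for ind in inds
        ]
        for ind, fac in config.get("cross_loadings", []):
            loadings.append((str(ind), str(fac)))
        return cls(
            factors=tuple(factor_map),
            loadings=tuple(loadings),
            mean_structure=bool(config.get("mean_structure", False)),
            structure_kind=str(config.get("kind", "correlated-factors")),
        )


# Primary indicator sets of the six regulatory domains, plus the two
# cross-loadings of the simplified 16-indicator model (18 loadings total).
_DEFAULT_STRUCTURE: dict[str, tuple[str, ...]] = {
    "metabolism": ("BUN", "Cr", "K", "P", "UA"),
    "circulation": ("SBP", "DBP"),
    "liver": ("AST", "ALT"),
    "salt": ("Na", "Cl"),
    "inflammation": ("WBC", "Plat", "Hb"),
    "protein": ("TP", "Alb"),
}
_DEFAULT_CROSS: tuple[tuple[str, str], ...] = (("Alb", "metabolism"), ("Hb", "metabolism"))


def default_cfa_spec(mean_structure: bool = False) -> SemModelSpec:
    """The 6-factor, 16-indicator, 18-loading measurement model.

    Correlated factors for metabolism {BUN, Cr, K, P, UA}, circulation
    {SBP, DBP}, liver {AST, ALT}, salt {Na, Cl}, inflammation
    {WBC, Plat, Hb} and protein {TP, Alb}, with Alb and Hb cross-loading on
    metabolism.  Single-group df = 87; two-group configural df (with mean
    structure) = 174.
    """
    loadings = [
        (ind, fac) for fac, inds in _DEFAULT_STRUCTURE.items() for ind in inds
    ] + list(_DEFAULT_CROSS)
    return SemModelSpec(
        factors=tuple(_DEFAULT_STRUCTURE),
        loadings=tuple(loadings),
        mean_structure=mean_structure,
    )


def second_order_spec(base: SemModelSpec | None = None) -> SemModelSpec:
    """Second-order variant: a general dysregulation factor replaces Phi."""
    base = base or default_cfa_spec()
    return SemModelSpec(base.factors, base.loadings, base.mean_structure, "second-order")


def bifactor_spec(base: SemModelSpec | None = None) -> SemModelSpec:
    """Bifactor variant: an orthogonal general factor loads on every indicator."""
    base = base or default_cfa_spec()
    extra = tuple((ind, "general") for ind in base.indicators)
    return SemModelSpec(base.factors, base.loadings + extra, base.mean_structure, "bifactor")


# ----------------------------------------------------------------------
# Parameters
# ----------------------------------------------------------------------

@dataclass
class SemParameters:
    """One group's parameter matrices (Lambda, Phi, Theta, nu, alpha)."""

    lam: pd.DataFrame  # indicator x factor
    phi: pd.DataFrame  # factor covariance (correlation in reference groups)
    theta: pd.Series  # residual variances
    nu: pd.Series  # intercepts (zeros when no mean structure)
    alpha: pd.Series  # factor means

    def implied_sigma(self) -> pd.DataFrame:
        lam = self.lam.to_numpy()
        sig = lam @ self.phi.to_numpy() @ lam.T + np.diag(self.theta.to_numpy())
        return pd.DataFrame(sig, index=self.lam.index, columns=self.lam.index)

    def implied_mu(self) -> pd.Series:
        return self.nu + pd.Series(
            self.lam.to_numpy() @ self.alpha.to_numpy(), index=self.lam.index
        )


@dataclass
class SemFit:
    """A converged (or diagnosed) CFA fit."""

    spec: SemModelSpec
    params: list[SemParameters]  # one per group
    param_names: list[str]
    x: np.ndarray  # free-parameter vector at the optimum
    se: pd.Series | None
    T: float
    df: int
    fit: dict  # CFI, TLI, RMSEA, SRMR, AIC, BIC, chisq/df
    loglik: float
    n_free: int
    converged: bool
    grad_norm: float
    n_per_group: list[int]
    group_labels: list[str]
    S: list[pd.DataFrame]
    xbar: list[pd.Series] | None
    scaling_factor: float | None = None
    T_scaled: float | None = None

    @property
    def n_groups(self) -> int:
        return len(self.params)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for name, val in zip(self.param_names, self.x):
            se = float(self.se[name]) if self.se is not None else np.nan
            rows.append((name, val, se))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])


# ----------------------------------------------------------------------
# Free-parameter layout
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class _Param:
    kind: str  # lam | rho | lsd | lth | nu | alpha | g2
    item: tuple  # identifying indices (names)
    group: int | None  # None = shared across groups

    @property
    def name(self) -> str:
        tag = ".".join(str(i) for i in self.item)
        g = "" if self.group is None else f"@g{self.group + 1}"
        return f"{self.kind}[{tag}]{g}"


class _Layout:
    """Maps the free-parameter vector onto per-group model matrices."""

    def __init__(
        self,
        spec: SemModelSpec,
        n_groups: int,
        constraints: frozenset[str] = frozenset(),
        exempt: Mapping[str, Sequence] | None = None,
    ):
        bad = set(constraints) - set(CONSTRAINT_KINDS)
        if bad:
            raise ValueError(f"unknown constraint kinds: {sorted(bad)}")
        if n_groups > 1 and spec.structure_kind != "correlated-factors":
            raise ValueError("multi-group fitting supports correlated-factors only")
        self.spec = spec
        self.n_groups = n_groups
        self.constraints = constraints
        self.exempt = {k: set(v) for k, v in (exempt or {}).items()}
        self.indicators = list(spec.indicators)
        self.factors = list(spec.all_factors)
        self.p = len(self.indicators)
        self.K = len(self.factors)
        self.params: list[_Param] = []
        self._build()
        self.index = {p: i for i, p in enumerate(self.params)}
        self._build_index_arrays()

    def _shared(self, kind: str, item) -> bool:
        if self.n_groups == 1:
            return False
        if kind not in self.constraints:
            return False
        return item not in self.exempt.get(kind, set())

    def _build(self):
        spec, G = self.spec, self.n_groups
        add = self.params.append
        for ind, fac in spec.loadings:
            if self._shared("loadings", (ind, fac)) or self._shared("loadings", ind):
                add(_Param("lam", (ind, fac), None))
            else:
                for g in range(G):
                    add(_Param("lam", (ind, fac), g))
        if spec.structure_kind == "correlated-factors":
            for g in range(G):
                for a in range(self.K):
                    for b in range(a + 1, self.K):
                        add(_Param("rho", (self.factors[a], self.factors[b]), g))
            if "loadings" in self.constraints:
                for g in range(1, G):
                    for f in spec.factors:
                        add(_Param("lsd", (f,), g))
        elif spec.structure_kind == "second-order":
            for g in range(G):
                for f in spec.factors:
                    add(_Param("g2", (f,), g))
        # bifactor: Phi fixed to the identity; nothing to add
        for ind in self.indicators:
            if self._shared("residuals", ind):
                add(_Param("lth", (ind,), None))
            else:
                for g in range(G):
                    add(_Param("lth", (ind,), g))
        if spec.mean_structure:
            for ind in self.indicators:
                if self._shared("intercepts", ind):
                    add(_Param("nu", (ind,), None))
                else:
                    for g in range(G):
                        add(_Param("nu", (ind,), g))
            if "intercepts" in self.constraints:
                for g in range(1, G):
                    for f in spec.factors:
                        add(_Param("alpha", (f,), g))

    @property
    def n_free(self) -> int:
        return len(self.params)

    def bounds(self) -> list[tuple]:
        out = []
        for p in self.params:
            if p.kind == "rho":
                out.append((-0.99, 0.99))
            elif p.kind == "g2":
                out.append((-0.995, 0.995))
            elif p.kind == "lth":
                out.append((np.log(1e-8), np.log(1e8)))
            elif p.kind == "lsd":
                out.append((np.log(1e-3), np.log(1e3)))
            else:
                out.append((None, None))
        return out

    def _build_index_arrays(self):
        """Per-group numpy index arrays so unpack/gradient avoid Python loops."""
        fpos = {f: k for k, f in enumerate(self.factors)}
        ipos = {i: j for j, i in enumerate(self.indicators)}
        self._ix = []
        for g in range(self.n_groups):
            d = {k: [] for k in ("lam", "rho", "lsd", "g2", "lth", "nu", "alpha")}
            for idx, pm in enumerate(self.params):
                if pm.group is not None and pm.group != g:
                    continue
                if pm.kind == "lam":
                    d["lam"].append((idx, ipos[pm.item[0]], fpos[pm.item[1]]))
                elif pm.kind == "rho":
                    d["rho"].append((idx, fpos[pm.item[0]], fpos[pm.item[1]]))
                elif pm.kind == "lsd":
                    d["lsd"].append((idx, fpos[pm.item[0]]))
                elif pm.kind == "g2":
                    d["g2"].append((idx, fpos[pm.item[0]]))
                elif pm.kind == "lth":
                    d["lth"].append((idx, ipos[pm.item[0]]))
                elif pm.kind == "nu":
                    d["nu"].append((idx, ipos[pm.item[0]]))
                elif pm.kind == "alpha":
                    d["alpha"].append((idx, fpos[pm.item[0]]))
            arity = {"lam": 3, "rho": 3, "lsd": 2, "g2": 2, "lth": 2, "nu": 2, "alpha": 2}
            arr = {}
            for k, rows in d.items():
                if rows:
                    arr[k] = tuple(np.array(col, dtype=int) for col in zip(*rows))
                else:
                    arr[k] = tuple(np.array([], dtype=int) for _ in range(arity[k]))
            self._ix.append(arr)

    # -- vector -> matrices ------------------------------------------------
    def _unpack_np(self, x: np.ndarray) -> list[dict]:
        groups = []
        for g in range(self.n_groups):
            ix = self._ix[g]
            lam = np.zeros((self.p, self.K))
            if ix["lam"][0].size:
                pi, r, c = ix["lam"]
                lam[r, c] = x[pi]
            R = np.eye(self.K)
            if ix["rho"][0].size:
                pi, a, b = ix["rho"]
                R[a, b] = x[pi]
                R[b, a] = x[pi]
            dvec = np.ones(self.K)
            if ix["lsd"][0].size:
                pi, k = ix["lsd"]
                dvec[k] = np.exp(x[pi])
            gam = np.zeros(self.K)
            if ix["g2"][0].size:
                pi, k = ix["g2"]
                gam[k] = x[pi]
            theta = np.zeros(self.p)
            pi, j = ix["lth"]
            theta[j] = np.exp(x[pi])
            nu = np.zeros(self.p)
            if ix["nu"][0].size:
                pi, j = ix["nu"]
                nu[j] = x[pi]
            alpha = np.zeros(self.K)
            if ix["alpha"][0].size:
                pi, k = ix["alpha"]
                alpha[k] = x[pi]
            if self.spec.structure_kind == "second-order":
                phi = np.outer(gam, gam) + np.diag(1.0 - gam**2)
            elif self.spec.structure_kind == "bifactor":
                phi = np.eye(self.K)
            else:
                phi = np.outer(dvec, dvec) * R
            groups.append(
                {"lam": lam, "phi": phi, "theta": theta, "nu": nu, "alpha": alpha,
                 "dvec": dvec, "gam": gam}
            )
        return groups

    def unpack(self, x: np.ndarray) -> list[SemParameters]:
        inds, facs = self.indicators, self.factors
        out = []
        for m in self._unpack_np(x):
            out.append(
                SemParameters(
                    lam=pd.DataFrame(m["lam"], index=inds, columns=facs),
                    phi=pd.DataFrame(m["phi"], index=facs, columns=facs),
                    theta=pd.Series(m["theta"], index=inds),
                    nu=pd.Series(m["nu"], index=inds),
                    alpha=pd.Series(m["alpha"], index=facs),
                )
            )
        return out


def count_free_parameters(
    spec: SemModelSpec,
    n_groups: int = 1,
    constraints: Iterable[str] = (),
    exempt: Mapping[str, Sequence] | None = None,
) -> int:
    return _Layout(spec, n_groups, frozenset(constraints), exempt).n_free


def model_df(
    spec: SemModelSpec,
    n_groups: int = 1,
    mean_structure: bool | None = None,
    constraints: Iterable[str] = (),
    exempt: Mapping[str, Sequence] | None = None,
) -> int:
    """Degrees of freedom: sample moments minus free parameters.

    Moments per group are p(p+1)/2 covariances plus p means when the mean
    structure is modeled.  The identification rule (unit factor variances,
    zero factor means in unconstrained groups; metric frees group-2 factor
    variances, scalar frees group-2 factor means) is baked into the
    parameter count.
    """
    if mean_structure is not None:
        spec = spec.with_means(mean_structure)
    p = len(spec.indicators)
    moments = n_groups * (p * (p + 1) // 2 + (p if spec.mean_structure else 0))
    df = moments - count_free_parameters(spec, n_groups, constraints, exempt)
    if df < 0:
        raise ValueError(f"over-parameterized model: df = {df} < 0")
    return df


# ----------------------------------------------------------------------
# Objective and gradient
# ----------------------------------------------------------------------

def _objective(
    x: np.ndarray,
    layout: _Layout,
    S: list[np.ndarray],
    logdetS: list[float],
    xbar: list[np.ndarray] | None,
    weights: np.ndarray,
):
    spec = layout.spec
    p = layout.p
    f_total = 0.0
    grad = np.zeros_like(x)
    groups = layout._unpack_np(x)
    for g, prm in enumerate(groups):
        lam, phi, theta = prm["lam"], prm["phi"], prm["theta"]
        ix = layout._ix[g]
        w = weights[g]
        eigmin_phi = np.linalg.eigvalsh(phi).min()
        if eigmin_phi < 1e-8 or np.any(theta <= 0):
            # barrier: push the factor covariance back toward PD territory
            f_total += w * (1e6 + 1e8 * max(0.0, 1e-8 - eigmin_phi))
            _, vecs = np.linalg.eigh(phi)
            v = vecs[:, 0]
            dv = np.sqrt(np.maximum(np.diag(phi), 1e-12))
            if ix["rho"][0].size:
                pi, a, b = ix["rho"]
                grad[pi] += w * (-1e8) * (2.0 * v[a] * v[b] * dv[a] * dv[b])
            continue
        sigma = lam @ phi @ lam.T + np.diag(theta)
        try:
            c = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            f_total += w * 1e10
            continue
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        sinv = np.linalg.inv(sigma)
        Fg = logdet - logdetS[g] + float(np.sum(sinv * S[g])) - p
        d = None
        if xbar is not None:
            mu = prm["nu"] + lam @ prm["alpha"]
            d = xbar[g] - mu
            Fg += float(d @ sinv @ d)
        f_total += w * Fg

        # gradient pieces
        if d is None:
            G = sinv @ (sigma - S[g]) @ sinv
            gmu = None
        else:
            G = sinv @ (sigma - S[g] - np.outer(d, d)) @ sinv
            gmu = -2.0 * (sinv @ d)
        GLP = G @ lam @ phi  # p x K
        M = lam.T @ G @ lam  # K x K
        dv = np.sqrt(np.maximum(np.diag(phi), 1e-12))
        alpha = prm["alpha"]
        pi, r, cix = ix["lam"]
        if pi.size:
            val = 2.0 * GLP[r, cix]
            if gmu is not None:
                val = val + gmu[r] * alpha[cix]
            grad[pi] += w * val
        if ix["rho"][0].size:
            pi, a, b = ix["rho"]
            grad[pi] += w * 2.0 * dv[a] * dv[b] * M[a, b]
        if ix["lsd"][0].size:
            pi, k = ix["lsd"]
            grad[pi] += w * 2.0 * np.diag(M @ phi)[k]
        pi, j = ix["lth"]
        grad[pi] += w * np.diag(G)[j] * theta[j]
        if gmu is not None and ix["nu"][0].size:
            pi, j = ix["nu"]
            grad[pi] += w * gmu[j]
        if gmu is not None and ix["alpha"][0].size:
            pi, k = ix["alpha"]
            grad[pi] += w * (gmu @ lam)[k]
        if spec.structure_kind == "second-order" and ix["g2"][0].size:
            # dPhi/dgamma_k = e_k g' + g e_k' - 2 g_k E_k
            gam = prm["gam"]
            Mg = M @ gam
            pi, k = ix["g2"]
            grad[pi] += w * (2.0 * Mg[k] - 2.0 * gam[k] * np.diag(M)[k])
    return f_total, grad


# ----------------------------------------------------------------------
# Moments and fitting
# ----------------------------------------------------------------------

def _moments_from_data(
    data: pd.DataFrame, indicators: Sequence[str], group: pd.Series | None
):
    if group is None:
        groups = [("all", data)]
    else:
        groups = [(str(lab), data.loc[group == lab]) for lab in pd.unique(group)]
    S, xbar, ns, labels, raw = [], [], [], [], []
    for lab, sub in groups:
        X = sub[list(indicators)].dropna()
        if len(X) < len(indicators) + 1:
            raise ValueError(f"group {lab!r} has too few complete rows ({len(X)})")
        S.append(X.cov())  # ddof=1, Wishart convention
        xbar.append(X.mean())
        ns.append(len(X))
        labels.append(lab)
        raw.append(X)
    return S, xbar, ns, labels, raw


def _start_vector(layout: _Layout, S: list[pd.DataFrame], xbar) -> np.ndarray:
    """Start values: primary loadings at half the marginal SD, residuals at
    half the variance, factor correlations at zero."""
    x0 = np.zeros(layout.n_free)
    sd = [np.sqrt(np.diag(s.to_numpy())) for s in S]
    ipos = {i: j for j, i in enumerate(layout.indicators)}
    for idx, pm in enumerate(layout.params):
        g = pm.group if pm.group is not None else 0
        if pm.kind == "lam":
            x0[idx] = 0.5 * sd[g][ipos[pm.item[0]]]
        elif pm.kind == "lth":
            x0[idx] = np.log(0.5 * sd[g][ipos[pm.item[0]]] ** 2)
        elif pm.kind == "nu":
            x0[idx] = float(xbar[g][pm.item[0]]) if xbar is not None else 0.0
        elif pm.kind == "g2":
            x0[idx] = 0.5
        # rho, lsd, alpha start at 0
    return x0


def fit_cfa(
    data: pd.DataFrame | None = None,
    spec: SemModelSpec | None = None,
    *,
    group: pd.Series | str | None = None,
    S=None,
    xbar=None,
    n: int | Sequence[int] | None = None,
    constraints: Iterable[str] = (),
    exempt: Mapping[str, Sequence] | None = None,
    robust: bool = False,
    x0: np.ndarray | None = None,
    compute_se: bool = True,
    gtol: float = 1e-8,
    max_restarts: int = 5,
    seed: int = 0,
) -> SemFit:
    """Fit a CFA model to raw data or to sample moments.

    Parameters
    ----------
    data : complete-case indicator table (one row per patient); or pass
        moments via ``S`` (covariance DataFrame or list per group),
        ``xbar`` (means, needed for a mean structure) and ``n``.
    group : grouping series (or column name in ``data``) for multi-group
        fits; exactly the levels found define the groups, first level =
        reference group.
    constraints : subset of {"loadings", "intercepts", "residuals"} for
        cross-group equality; ``exempt`` releases named parameters from a
        constraint (partial invariance).
    robust : additionally compute a mean-scaled (Satorra-Bentler style)
        test statistic from fourth moments; requires raw data, one group.
    """
    if spec is None:
        raise ValueError("a SemModelSpec is required")
    raw = None
    if data is not None:
        if isinstance(group, str):
            group = data[group]
        S_list, xbar_list, ns, labels, raw = _moments_from_data(data, spec.indicators, group)
    else:
        if S is None or n is None:
            raise ValueError("moment input requires S and n")
        S_list = S if isinstance(S, (list, tuple)) else [S]
        S_list = [
            s if isinstance(s, pd.DataFrame)
            else pd.DataFrame(np.asarray(s, float), index=spec.indicators, columns=spec.indicators)
            for s in S_list
        ]
        S_list = [s.loc[list(spec.indicators), list(spec.indicators)] for s in S_list]
        ns = list(n) if isinstance(n, (list, tuple)) else [int(n)]
        labels = [f"g{i + 1}" for i in range(len(S_list))]
        if xbar is not None:
            xbar_list = xbar if isinstance(xbar, (list, tuple)) else [xbar]
            xbar_list = [pd.Series(np.asarray(m, float), index=spec.indicators) for m in xbar_list]
        else:
            xbar_list = None
        if spec.mean_structure and xbar_list is None:
            raise ValueError("mean structure requires xbar")
    if not spec.mean_structure:
        xbar_list = None

    layout = _Layout(spec, len(S_list), frozenset(constraints), exempt)
    Snp = [s.to_numpy() for s in S_list]
    for s, lab in zip(Snp, labels):
        if np.linalg.eigvalsh(s).min() <= 0:
            raise ValueError(f"sample covariance for group {lab!r} is not PD")
    logdetS = [float(np.linalg.slogdet(s)[1]) for s in Snp]
    xb_np = [m.to_numpy() for m in xbar_list] if xbar_list is not None else None
    weights = np.array([max(ni - 1, 1) for ni in ns], dtype=float)

    args = (layout, Snp, logdetS, xb_np, weights)
    start = x0 if x0 is not None else _start_vector(layout, S_list, xbar_list)
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max_restarts):
        xs = start if trial == 0 else start * np.exp(rng.normal(0, 0.2, start.shape)) + rng.normal(0, 0.01, start.shape)
        res = optimize.minimize(
            _objective, xs, args=args, jac=True, method="L-BFGS-B",
            bounds=layout.bounds(),
            options={"maxiter": 5000, "maxfun": 50000, "ftol": 1e-14, "gtol": gtol},
        )
        # gradient of the per-observation discrepancy F (weights divided out)
        gnorm = float(np.max(np.abs(_objective(res.x, *args)[1]))) / float(weights.sum())
        if best is None or res.fun < best[0].fun - 1e-10:
            best = (res, gnorm)
        if best[1] < 1e-6:
            break
    res, gnorm = best
    res.x = _align_signs(layout, res.x)
    if not np.isfinite(res.fun) or res.fun >= 1e6:
        raise SemConvergenceError(
            f"CFA failed to converge (f={res.fun:.3g}, grad norm={gnorm:.3g})"
        )
    converged = gnorm < 1e-4

    params = layout.unpack(res.x)
    T = float(res.fun)
    df = model_df(spec, len(S_list), None, constraints, exempt)

    # baseline (independence) model: diagonal Sigma, free means
    corrs = [s / np.outer(np.sqrt(np.diag(s)), np.sqrt(np.diag(s))) for s in Snp]
    T_b = float(sum(w * -np.linalg.slogdet(c)[1] for w, c in zip(weights, corrs)))
    p = layout.p
    df_b = len(S_list) * (p * (p - 1) // 2)

    sigma_hat = [pr.implied_sigma() for pr in params]
    N = int(sum(ns))
    if df > 0 and df_b > 0:
        fitdict = fit_indices(T, df, T_b, df_b, N, S_list, sigma_hat, n_per_group=ns)
    else:  # just-identified model: incremental indices are undefined
        fitdict = {"chisq": T, "df": df, "CFI": np.nan, "TLI": np.nan,
                   "RMSEA": 0.0 if T <= max(df, 0) else np.nan, "SRMR": np.nan,
                   "baseline_chisq": T_b, "baseline_df": df_b}

    ll = _loglik(params, Snp, xb_np, ns, p)
    aic, bic = information_criteria(ll, layout.n_free, N)
    fitdict["AIC"] = aic
    fitdict["BIC"] = bic

    se = None
    if compute_se:
        se = _expected_information_se(layout, res.x, params, ns)

    scaling = T_sc = None
    if robust:
        if raw is None or len(raw) != 1:
            raise ValueError("robust scaling requires raw data and a single group")
        scaling = _sb_scaling(layout, res.x, params[0], raw[0], df)
        T_sc = T / scaling if scaling and scaling > 0 else np.nan

    return SemFit(
        spec=spec, params=params, param_names=[pm.name for pm in layout.params],
        x=res.x.copy(), se=se, T=T, df=df, fit=fitdict, loglik=ll,
        n_free=layout.n_free, converged=converged, grad_norm=gnorm,
        n_per_group=list(ns), group_labels=labels, S=S_list,
        xbar=xbar_list, scaling_factor=scaling, T_scaled=T_sc,
    )


def _align_signs(layout: _Layout, x: np.ndarray) -> np.ndarray:
    """Resolve factor sign indeterminacy: each factor's loadings sum >= 0.

    Sigma and mu are invariant under jointly flipping a factor's loadings,
    its correlations, and its mean, so this only standardizes reporting.
    """
    if layout.spec.structure_kind == "second-order":
        return x
    x = x.copy()
    sign = {}
    for fac in layout.factors:
        total = sum(
            x[i]
            for i, pm in enumerate(layout.params)
            if pm.kind == "lam" and pm.item[1] == fac and pm.group in (None, 0)
        )
        sign[fac] = -1.0 if total < 0 else 1.0
    for i, pm in enumerate(layout.params):
        if pm.kind == "lam":
            x[i] *= sign[pm.item[1]]
        elif pm.kind == "rho":
            x[i] *= sign[pm.item[0]] * sign[pm.item[1]]
        elif pm.kind == "alpha":
            x[i] *= sign[pm.item[0]]
    return x


def _loglik(params, Snp, xb_np, ns, p) -> float:
    ll = 0.0
    for g, prm in enumerate(params):
        sigma = prm.implied_sigma().to_numpy()
        sinv = np.linalg.inv(sigma)
        logdet = float(np.linalg.slogdet(sigma)[1])
        n = ns[g]
        Smle = Snp[g] * (n - 1) / n
        quad = float(np.sum(sinv * Smle))
        if xb_np is not None:
            d = xb_np[g] - prm.implied_mu().to_numpy()
            quad += float(d @ sinv @ d)
        ll += -0.5 * n * (p * np.log(2 * np.pi) + logdet + quad)
    return float(ll)


def saturated_fit(S: pd.DataFrame, n: int, xbar: pd.Series | None = None) -> dict:
    """The saturated model: Sigma-hat = S, T = 0, df = 0 by construction."""
    return {"sigma": S.copy(), "mu": None if xbar is None else xbar.copy(), "T": 0.0, "df": 0, "n": n}


# ----------------------------------------------------------------------
# Fit indices and information criteria
# ----------------------------------------------------------------------

def fit_indices(
    T: float,
    df: int,
    T_baseline: float,
    df_baseline: int,
    n: int,
    S: Sequence[pd.DataFrame] | pd.DataFrame | None = None,
    sigma_hat: Sequence[pd.DataFrame] | pd.DataFrame | None = None,
    n_per_group: Sequence[int] | None = None,
) -> dict:
    """CFI, TLI, RMSEA (and SRMR when moments are supplied).

    CFI   = 1 - max(T - df, 0) / max(T_b - df_b, T - df, 0)
    TLI   = [(T_b/df_b) - (T/df)] / [(T_b/df_b) - 1]
    RMSEA = sqrt(max(T - df, 0) / (df * (n - 1)))
    SRMR  = root mean square of the standardized residuals of S versus
            Sigma-hat, diagonal included (n-weighted across groups).
    """
    if df <= 0 or df_baseline <= 0:
        raise ValueError("df and df_baseline must be positive")
    num = max(T - df, 0.0)
    den = max(T_baseline - df_baseline, T - df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    rb = T_baseline / df_baseline
    if abs(rb - 1.0) < 1e-12:
        tli = float("nan")  # undefined: baseline fits as well as its df
    else:
        tli = (rb - T / df) / (rb - 1.0)
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))
    out = {
        "chisq": T,
        "df": df,
        "chisq_df": T / df,
        "CFI": float(np.clip(cfi, 0.0, 1.0)),
        "TLI": float(tli),
        "RMSEA": rmsea,
        "baseline_chisq": T_baseline,
        "baseline_df": df_baseline,
    }
    if S is not None and sigma_hat is not None:
        S_list = S if isinstance(S, (list, tuple)) else [S]
        H_list = sigma_hat if isinstance(sigma_hat, (list, tuple)) else [sigma_hat]
        ns = list(n_per_group) if n_per_group is not None else [n] * len(S_list)
        total, wsum = 0.0, 0.0
        for s, h, ni in zip(S_list, H_list, ns):
            s, h = s.to_numpy(), h.to_numpy()
            d = np.sqrt(np.diag(s))
            resid = (s - h) / np.outer(d, d)
            iu = np.triu_indices_from(resid)
            total += ni * float(np.mean(resid[iu] ** 2))
            wsum += ni
        out["SRMR"] = float(np.sqrt(total / wsum))
    return out


def information_criteria(loglik: float, n_free_params: int, n: int) -> tuple[float, float]:
    """AIC = -2 loglik + 2k; BIC = -2 loglik + k ln(n)."""
    aic = -2.0 * loglik + 2.0 * n_free_params
    bic = -2.0 * loglik + n_free_params * np.log(n)
    return float(aic), float(bic)


# ----------------------------------------------------------------------
# Standard errors, factor scores, robust scaling
# ----------------------------------------------------------------------

def _implied_moment_vector(layout: _Layout, x: np.ndarray) -> list[np.ndarray]:
    out = []
    for prm in layout._unpack_np(x):
        sig = prm["lam"] @ prm["phi"] @ prm["lam"].T + np.diag(prm["theta"])
        vec = [sig.ravel()]
        if layout.spec.mean_structure:
            vec.append(prm["nu"] + prm["lam"] @ prm["alpha"])
        out.append(np.concatenate(vec))
    return out


def _expected_information_se(
    layout: _Layout, x: np.ndarray, params: list[SemParameters], ns: Sequence[int]
) -> pd.Series:
    """SEs from the inverse expected (normal-theory) information.

    Uses vec(Sigma) with weight (n-1)/2 (Sigma^-1 x Sigma^-1) plus the mean
    block n * Sigma^-1; Jacobians by central finite differences.
    """
    q = layout.n_free
    h = 1e-6
    base = _implied_moment_vector(layout, x)
    J = [np.zeros((len(b), q)) for b in base]
    for i in range(q):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        mp = _implied_moment_vector(layout, xp)
        mm = _implied_moment_vector(layout, xm)
        for g in range(layout.n_groups):
            J[g][:, i] = (mp[g] - mm[g]) / (2 * h)
    p = layout.p
    info = np.zeros((q, q))
    for g, prm in enumerate(params):
        sigma = prm.implied_sigma().to_numpy()
        sinv = np.linalg.inv(sigma)
        W = np.kron(sinv, sinv) * (ns[g] - 1) / 2.0
        Js = J[g][: p * p]
        info += Js.T @ W @ Js
        if layout.spec.mean_structure:
            Jm = J[g][p * p :]
            info += ns[g] * (Jm.T @ sinv @ Jm)
    try:
        cov = np.linalg.pinv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(q, np.nan)
    return pd.Series(se, index=[pm.name for pm in layout.params])


def factor_scores(
    fit: SemFit, data: pd.DataFrame, group: pd.Series | str | None = None
) -> pd.DataFrame:
    """Regression-method factor scores eta-hat = alpha + Phi Lambda' Sigma^-1 (x - mu).

    Without a mean structure, mu is taken as the per-group sample mean and
    alpha as zero.  Returns one row per patient, one column per factor.
    """
    inds = list(fit.spec.indicators)
    if isinstance(group, str):
        group = data[group]
    X = data[inds]
    if X.isna().any().any():
        raise ValueError("factor scores require complete data")
    out = pd.DataFrame(
        np.nan, index=data.index, columns=list(fit.spec.all_factors), dtype=float
    )
    for g, lab in enumerate(fit.group_labels):
        rows = data.index if group is None else data.index[group == lab]
        if len(rows) == 0:
            continue
        prm = fit.params[g]
        sigma = prm.implied_sigma().to_numpy()
        if np.linalg.cond(sigma) > 1e12:
            raise np.linalg.LinAlgError("implied covariance is singular")
        sinv = np.linalg.inv(sigma)
        lam = prm.lam.to_numpy()
        phi = prm.phi.to_numpy()
        if fit.spec.mean_structure:
            mu = prm.implied_mu().to_numpy()
            alpha = prm.alpha.to_numpy()
        else:
            mu = X.loc[rows].mean().to_numpy()
            alpha = np.zeros(phi.shape[0])
        dev = X.loc[rows].to_numpy() - mu
        out.loc[rows] = alpha + dev @ (sinv @ lam @ phi)
    return out


def _duplication(p: int) -> np.ndarray:
    """Duplication matrix: vec(A) = D vech(A) for symmetric A."""
    rows = p * p
    cols = p * (p + 1) // 2
    D = np.zeros((rows, cols))
    k = 0
    for j in range(p):
        for i in range(j, p):
            D[i * p + j, k] = 1.0
            D[j * p + i, k] = 1.0
            k += 1
    return D


def _sb_scaling(
    layout: _Layout, x: np.ndarray, prm: SemParameters, X: pd.DataFrame, df: int
) -> float:
    """Mean-scaling correction factor c with T_scaled = T / c.

    Gamma is the sample asymptotic covariance of vech(S) from fourth
    moments; U projects out the model tangent space under the
    normal-theory weight; c = tr(U Gamma) / df.
    """
    p = layout.p
    Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    n = Xc.shape[0]
    iu = [(i, j) for j in range(p) for i in range(j, p)]
    W = np.array([[xc[i] * xc[j] for (i, j) in iu] for xc in Xc])
    Gamma = np.cov(W, rowvar=False, ddof=1)
    sigma = prm.implied_sigma().to_numpy()
    sinv = np.linalg.inv(sigma)
    D = _duplication(p)
    V = 0.5 * D.T @ np.kron(sinv, sinv) @ D
    # Jacobian of vech(Sigma) wrt free params
    h = 1e-6
    q = layout.n_free
    idx = [i * p + j for (i, j) in iu]
    Delta = np.zeros((len(iu), q))
    for i in range(q):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        sp = _implied_moment_vector(layout, xp)[0][: p * p][idx]
        sm = _implied_moment_vector(layout, xm)[0][: p * p][idx]
        Delta[:, i] = (sp - sm) / (2 * h)
    VD = V @ Delta
    U = V - VD @ np.linalg.pinv(Delta.T @ VD) @ VD.T
    return float(np.trace(U @ Gamma) / df)
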