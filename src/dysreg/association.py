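"""Mixed-method pairwise correlation matrices over variabilities and covariates.

Method selection follows distributional tags: pairs involving a binary
variable use the point-biserial coefficient (a product-moment correlation
on 0/1 coding), pairs of two normal continuous variables use Pearson, and
any pair involving a non-normal continuous variable uses Spearman.
P-values come from the t approximation t = r*sqrt((n-2)/(1-r^2)) on n-2
degrees of freedom and are deliberately not adjusted for multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableTag",
    "CorrelationMatrix",
    "choose_method",
    "correlation_matrix",
    "pair_partition",
    "count_significant",
    "point_biserial_welch",
]


@dataclass(frozen=True)
class VariableTag:
    """Distributional tag used for correlation-method selection."""

    kind: str  # "continuous" | "binary"
    normal: bool = True

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"kind must be 'continuous' or 'binary', got {self.kind!r}")


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise correlations with per-pair method, p, and n."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    method: pd.DataFrame

    def pair(self, a: str, b: str) -> dict:
        return {
            "r": float(self.r.loc[a, b]),
            "p": float(self.p.loc[a, b]),
            "n": int(self.n.loc[a, b]),
            "method": str(self.method.loc[a, b]),
        }

    def to_long(self) -> pd.DataFrame:
        rows = [
            (a, b, self.method.loc[a, b], self.r.loc[a, b], self.p.loc[a, b], self.n.loc[a, b])
            for a, b in combinations(self.variables, 2)
        ]
        return pd.DataFrame(rows, columns=["var_a", "var_b", "method", "r", "p", "n"])


def choose_method(tag_a: VariableTag, tag_b: VariableTag) -> str:
    """Select the correlation method for one variable pair from its tags."""
    if tag_a is None or tag_b is None:
        raise ValueError("both variables must carry a distributional tag")
    if tag_a.kind == "binary" or tag_b.kind == "binary":
        return "point-biserial"
    if tag_a.normal and tag_b.normal:
        return "pearson"
    return "spearman"


def _t_approx_p(r: float, n: int) -> float:
    """Two-sided p from t = r*sqrt((n-2)/(1-r^2)) on n-2 df."""
    if n < 3:
        return float("nan")
    r2 = min(r * r, 1.0)
    if r2 >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r2))
    return float(2.0 * stats.t.sf(t, df=n - 2))


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |r| significant at ``alpha`` under the t approximation."""
    tcrit = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(np.sqrt(tcrit**2 / (tcrit**2 + n - 2)))


def correlation_matrix(
    table: pd.DataFrame, tags: Mapping[str, VariableTag]
) -> CorrelationMatrix:
    """Pairwise mixed-method correlation matrix over the columns of ``table``.

    Each pair is computed on its complete observations (pairwise deletion);
    at least 3 complete observations are required per pair.  Zero-variance
    columns are rejected by name.
    """
    cols = list(table.columns)
    for c in cols:
        if c not in tags:
            raise ValueError(f"variable {c!r} has no distributional tag")
        x = table[c].dropna().to_numpy(dtype=float)
        if x.size and np.ptp(x) == 0:
            raise ValueError(f"zero-variance column: {c!r}")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    nmat = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    meth = pd.DataFrame("", index=cols, columns=cols, dtype=object)
    for c in cols:
        nmat.loc[c, c] = int(table[c].notna().sum())
        meth.loc[c, c] = "identity"
    for a, b in combinations(cols, 2):
        sub = table[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"pair ({a!r}, {b!r}) has {n} < 3 complete observations")
        method = choose_method(tags[a], tags[b])
        xa, xb = sub[a].to_numpy(dtype=float), sub[b].to_numpy(dtype=float)
        if method == "spearman":
            rv = stats.spearmanr(xa, xb).statistic
        else:  # pearson and point-biserial are both product-moment
            rv = stats.pearsonr(xa, xb).statistic
        rv = float(np.clip(rv, -1.0, 1.0))
        pv = _t_approx_p(rv, n)
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
        nmat.loc[a, b] = nmat.loc[b, a] = n
        meth.loc[a, b] = meth.loc[b, a] = method
    return CorrelationMatrix(variables=cols, r=r, p=p, n=nmat, method=meth)


def pair_partition(
    variables: Sequence[str] | CorrelationMatrix, hemodynamic_set: Iterable[str]
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Split unordered variable pairs by hemodynamic membership.

    Returns (blood_only_pairs, mixed_pairs) where a pair is "mixed" when at
    least one member is hemodynamic.  With 22 variabilities of which 3 are
    hemodynamic this yields the 171 / 60 split of the 231 possible pairs.
    """
    if isinstance(variables, CorrelationMatrix):
        variables = variables.variables
    hemo = set(hemodynamic_set)
    unknown = hemo - set(variables)
    if unknown:
        raise ValueError(f"hemodynamic set contains unknown variables: {sorted(unknown)}")
    blood_only, mixed = [], []
    for a, b in combinations(variables, 2):
        (mixed if (a in hemo or b in hemo) else blood_only).append((a, b))
    return blood_only, mixed


def count_significant(
    matrix: CorrelationMatrix,
    subset: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> tuple[int, int, int]:
    """Census of unordered pairs within ``subset``: (n_pairs, n_significant, n_negative).

    Significance uses the unadjusted two-sided p at level ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    vars_ = list(subset) if subset is not None else matrix.variables
    unknown = set(vars_) - set(matrix.variables)
    if unknown:
        raise ValueError(f"subset contains unknown variables: {sorted(unknown)}")
    n_pairs = n_sig = n_neg = 0
    for a, b in combinations(vars_, 2):
        n_pairs += 1
        if matrix.p.loc[a, b] < alpha:
            n_sig += 1
        if matrix.r.loc[a, b] < 0:
            n_neg += 1
    return n_pairs, n_sig, n_neg


def point_biserial_welch(x: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Point-biserial r between a continuous variable and a 0/1 group, Welch-t p.

    The coefficient is the product-moment correlation on the 0/1 coding; the
    p-value comes from the Welch two-sample t-test, the convention used for
    factor-score vs dichotomous-covariate contrasts.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(group)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"group must be dichotomous, found {len(levels)} levels")
    b = (g == levels[1]).astype(float)
    r = float(stats.pearsonr(x, b).statistic)
    p = float(stats.ttest_ind(x[b == 1], x[b == 0], equal_var=False).pvalue)
    return r, p
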