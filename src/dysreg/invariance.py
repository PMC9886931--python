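"""Multi-group measurement-invariance ladder and factor-mean comparison.

Four nested two-group CFA models are fitted with progressively stringent
equality constraints:

  configural — same pattern, all parameters free per group;
  metric     — loadings equal (group-2 factor variances freed);
  scalar     — + intercepts equal (group-2 factor means freed);
  strict     — + residual variances equal.

Adjacent levels are compared by changes in alternative fit indices; a step
fails when dCFI < -0.01, dTLI < -0.01, or dRMSEA > 0.015.  The chi-square
difference test is reported alongside but never drives the decision (it is
oversensitive at these sample sizes).  Factor means of the second group,
with the reference group fixed at zero, are contrasted by Wald z tests at
the deepest achieved level of at least scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from dysreg.sem import SemFit, SemModelSpec, _Layout, fit_cfa

__all__ = [
    "LEVELS",
    "InvarianceThresholds",
    "InvarianceReport",
    "fit_invariance_ladder",
    "evaluate_invariance",
    "compare_factor_means",
]

LEVELS = ("configural", "metric", "scalar", "strict")

_CONSTRAINTS = {
    "configural": frozenset(),
    "metric": frozenset({"loadings"}),
    "scalar": frozenset({"loadings", "intercepts"}),
    "strict": frozenset({"loadings", "intercepts", "residuals"}),
}


@dataclass(frozen=True)
class InvarianceThresholds:
    """Non-invariance is declared when any delta crosses its threshold."""

    dCFI: float = -0.01
    dTLI: float = -0.01
    dRMSEA: float = 0.015


@dataclass
class InvarianceReport:
    fits: dict[str, SemFit]
    deltas: pd.DataFrame  # indexed by "metric-configural" etc.
    achieved_level: str
    thresholds: InvarianceThresholds
    group_labels: list[str]
    failed_level: str | None = None  # level that failed to converge, if any

    def grid(self) -> pd.DataFrame:
        """Table-shaped summary: one row per fitted level."""
        rows = []
        for level in LEVELS:
            if level not in self.fits:
                continue
            f = self.fits[level]
            rows.append(
                {
                    "level": level,
                    "chisq": f.T,
                    "df": f.df,
                    "chisq_df": f.T / f.df,
                    "CFI": f.fit["CFI"],
                    "TLI": f.fit["TLI"],
                    "RMSEA": f.fit["RMSEA"],
                    "AIC": f.fit["AIC"],
                    "BIC": f.fit["BIC"],
                }
            )
        return pd.DataFrame(rows).set_index("level")


def fit_invariance_ladder(
    data: pd.DataFrame,
    spec: SemModelSpec,
    group: pd.Series | str,
    thresholds: InvarianceThresholds | None = None,
    exempt: dict | None = None,
    min_group_n: int = 50,
    seed: int = 0,
) -> InvarianceReport:
    """Fit the configural-to-strict ladder on a two-group dataset.

    ``exempt`` releases named parameters from a constraint set (partial
    invariance), e.g. {"residuals": ["Hb", "WBC"]}.  Each level warm-starts
    from the previous solution.  A level that fails to converge truncates
    the ladder; the report carries the failure flag.
    """
    thresholds = thresholds or InvarianceThresholds()
    if isinstance(group, str):
        group = data[group]
    levels_found = pd.unique(group)
    if len(levels_found) != 2:
        raise ValueError(f"invariance ladder requires exactly 2 groups, got {len(levels_found)}")
    for lab in levels_found:
        n_g = int((group == lab).sum())
        if n_g < min_group_n:
            raise ValueError(f"group {lab!r} too small for multi-group CFA: n={n_g}")
    spec = spec.with_means(True)

    fits: dict[str, SemFit] = {}
    failed = None
    prev: SemFit | None = None
    for level in LEVELS:
        exempt_lv = exempt if level != "configural" else None
        x0 = None
        if prev is not None:
            layout = _Layout(spec, 2, _CONSTRAINTS[level], exempt_lv)
            x0 = _warm_start(prev, layout)
        try:
            fit = fit_cfa(
                data,
                spec,
                group=group,
                constraints=_CONSTRAINTS[level],
                exempt=exempt_lv,
                compute_se=(level in ("scalar", "strict")),
                x0=x0,
                seed=seed,
            )
        except Exception:
            failed = level
            break
        fits[level] = fit
        prev = fit

    deltas = _delta_table(fits)
    achieved = evaluate_invariance(deltas, thresholds, fitted=list(fits))
    labels = fits[next(iter(fits))].group_labels if fits else []
    return InvarianceReport(
        fits=fits,
        deltas=deltas,
        achieved_level=achieved,
        thresholds=thresholds,
        group_labels=labels,
        failed_level=failed,
    )


def _warm_start(prev: SemFit, layout: _Layout) -> np.ndarray:
    """Map the previous level's solution onto the next level's parameters.

    A newly shared parameter starts at the mean of its per-group values;
    newly freed group-2 factor variances start at 1 (log SD 0) and factor
    means at 0.
    """
    prev_vals = dict(zip(prev.param_names, prev.x))
    x0 = np.zeros(layout.n_free)
    for i, pm in enumerate(layout.params):
        if pm.name in prev_vals:
            x0[i] = prev_vals[pm.name]
            continue
        tag = ".".join(str(t) for t in pm.item)
        if pm.group is None:
            per_group = [
                v for n, v in prev_vals.items() if n.startswith(f"{pm.kind}[{tag}]@")
            ]
            if per_group:
                x0[i] = float(np.mean(per_group))
        else:
            shared = f"{pm.kind}[{tag}]"
            if shared in prev_vals:
                x0[i] = prev_vals[shared]
            # else: lsd -> 0 (unit variance), alpha -> 0
    return x0


def _delta_table(fits: dict[str, SemFit]) -> pd.DataFrame:
    rows = []
    fitted = [lv for lv in LEVELS if lv in fits]
    for prev, cur in zip(fitted, fitted[1:]):
        a, b = fits[prev], fits[cur]
        dchi = b.T - a.T
        ddf = b.df - a.df
        rows.append(
            {
                "step": f"{cur}-{prev}",
                "dchisq": dchi,
                "ddf": ddf,
                "dp": float(stats.chi2.sf(max(dchi, 0.0), ddf)) if ddf > 0 else np.nan,
                "dCFI": b.fit["CFI"] - a.fit["CFI"],
                "dTLI": b.fit["TLI"] - a.fit["TLI"],
                "dRMSEA": b.fit["RMSEA"] - a.fit["RMSEA"],
                "dAIC": b.fit["AIC"] - a.fit["AIC"],
                "dBIC": b.fit["BIC"] - a.fit["BIC"],
            }
        )
    return pd.DataFrame(rows).set_index("step") if rows else pd.DataFrame(
        columns=["dchisq", "ddf", "dp", "dCFI", "dTLI", "dRMSEA", "dAIC", "dBIC"]
    )


def evaluate_invariance(
    deltas: pd.DataFrame,
    thresholds: InvarianceThresholds | None = None,
    fitted: list[str] | None = None,
) -> str:
    """Walk the ladder and return the deepest level whose step passes.

    A step passes when dCFI >= -0.01, dTLI >= -0.01 and dRMSEA <= 0.015
    (defaults).  The chi-square difference p-value present in the table is
    reported but plays no role here.
    """
    thresholds = thresholds or InvarianceThresholds()
    fitted = fitted or list(LEVELS)
    achieved = fitted[0] if fitted else "none"
    for prev, cur in zip(fitted, fitted[1:]):
        row = deltas.loc[f"{cur}-{prev}"]
        ok = (
            row["dCFI"] >= thresholds.dCFI
            and row["dTLI"] >= thresholds.dTLI
            and row["dRMSEA"] <= thresholds.dRMSEA
        )
        if not ok:
            break
        achieved = cur
    return achieved


def compare_factor_means(
    report: InvarianceReport, level: str = "strict", scale: str = "latent"
) -> pd.DataFrame:
    """Per-factor mean contrast of group 2 against the zero-fixed reference.

    Requires the requested level (scalar or strict) to have been achieved;
    returns estimate, SE, Wald z and two-sided p per factor.  With
    ``scale="marker"`` the estimate and SE are rescaled by the factor's
    first (marker) loading, i.e. expressed in that indicator's LCV units —
    the scale on which marker-identified software reports these contrasts
    (z and p are scale invariant).
    """
    if scale not in ("latent", "marker"):
        raise ValueError("scale must be 'latent' or 'marker'")
    if level not in ("scalar", "strict"):
        raise ValueError("factor means are identified from the scalar level upward")
    order = {lv: i for i, lv in enumerate(LEVELS)}
    if order[report.achieved_level] < order[level]:
        raise ValueError(
            f"requested level {level!r} was not achieved "
            f"(achieved: {report.achieved_level!r}); compare at that level instead"
        )
    fit = report.fits[level]
    rows = []
    for fac in fit.spec.factors:
        pname = f"alpha[{fac}]@g2"
        try:
            i = fit.param_names.index(pname)
        except ValueError as e:
            raise KeyError(f"factor mean parameter {pname!r} not in fit") from e
        est = float(fit.x[i])
        se = float(fit.se[pname]) if fit.se is not None else np.nan
        if est == 0.0:
            z, p = 0.0, 1.0
        elif se > 0:
            z = est / se
            p = float(2.0 * stats.norm.sf(abs(z)))
        else:
            z, p = np.nan, np.nan
        if scale == "marker":
            marker = next(ind for ind, f in fit.spec.loadings if f == fac)
            lam_m = float(fit.params[0].lam.loc[marker, fac])
            est, se = est * lam_m, se * abs(lam_m)
        rows.append({"factor": fac, "estimate": est, "se": se, "z": z, "p": p})
    return pd.DataFrame(rows).set_index("factor")
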