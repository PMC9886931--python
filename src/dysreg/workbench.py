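"""Pipeline orchestration: simulate -> variability -> correlate -> network
-> EFA -> CFA -> invariance -> report, with a thin command-line front end.

Every stage reads and writes the documented CSV/JSON contracts, so stages
are independently scriptable; a manifest records seeds, the configuration
hash, and package versions, and a rerun with the same configuration is
reproducible.
"""

from __future__ import annotations

import argparse
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import dysreg
from dysreg import association, efa, invariance, network, sem, synthetic_cohort, variability

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "table3_report", "lcv_wide_table", "main"]


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    records: str | None = None  # CSV paths; None -> simulate
    metadata: str | None = None
    n_patients: int = 334
    year: int = 2020
    alpha: float = 0.05
    seed: int = 1
    layout_seed: int = 42
    n_factors: int = 6
    group_column: str | None = "group"  # None disables invariance
    d_cfi: float = -0.01
    d_tli: float = -0.01
    d_rmsea: float = 0.015
    robust: bool = False
    spearman_override: list[str] = field(default_factory=list)  # force Spearman

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def lcv_wide_table(records: pd.DataFrame) -> pd.DataFrame:
    """Yearly LCVs as a patient x biomarker table (the analysis unit)."""
    summ = variability.aggregate(records, window="year")
    return summ.pivot(index="patient_id", columns="biomarker", values="LCV")


def _variable_tags(table: pd.DataFrame, alpha: float, force_spearman=()) -> dict:
    tags = {}
    for col in table.columns:
        x = table[col].dropna()
        _, _, rejected = variability.ks_normality(x, alpha=alpha)
        normal = not rejected and col not in force_spearman
        tags[col] = association.VariableTag(kind="continuous", normal=normal)
    return tags


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the report bundle as a dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # -- stage 1: data ----------------------------------------------------
    if config.records is not None:
        records = pd.read_csv(config.records)
        metadata = pd.read_csv(config.metadata, index_col=0) if config.metadata else None
        cohort = None
        logger.info("stage simulate: skipped, loaded %d records", len(records))
    else:
        spec = synthetic_cohort.default_spec(n_patients=config.n_patients)
        cohort = synthetic_cohort.generate_cohort(spec, seed=config.seed)
        cohort.write(out / "cohort")
        records, metadata = cohort.records, cohort.metadata
        logger.info(
            "stage simulate: %d patients, %d records", config.n_patients, len(records)
        )

    if metadata is not None and {"n_sessions", "n_blood_tests", "vintage_years"} <= set(
        metadata.columns
    ):
        included = variability.eligibility_filter(metadata)
        n_before = len(metadata)
        metadata = metadata.loc[included]
        records = records[records["patient_id"].isin(included)]
        logger.info("stage eligibility: %d -> %d patients", n_before, len(metadata))

    # -- stage 2: variability ---------------------------------------------
    lcv_year = variability.aggregate(records, window="year")
    lcv_year.to_csv(out / "lcv_table.csv", index=False)
    wide = lcv_year.pivot(index="patient_id", columns="biomarker", values="LCV")
    wide = wide.dropna()
    bundle["n_patients"] = len(wide)
    logger.info("stage variability: %d complete patients x %d LCVs", *wide.shape)

    # -- stage 3: correlations --------------------------------------------
    tags = _variable_tags(wide, config.alpha, config.spearman_override)
    corr = association.correlation_matrix(wide, tags)
    corr.r.to_csv(out / "corr_matrix.csv")
    corr.to_long().to_csv(out / "corr_long.csv", index=False)
    hemo = [b for b in synthetic_cohort.HEMODYNAMIC if b in wide.columns]
    blood_pairs, mixed_pairs = association.pair_partition(corr, hemo)
    n_pairs, n_sig, n_neg = association.count_significant(corr, alpha=config.alpha)
    census = {
        "n_pairs": n_pairs,
        "n_significant": n_sig,
        "n_negative": n_neg,
        "blood_only_pairs": len(blood_pairs),
        "mixed_pairs": len(mixed_pairs),
    }
    (out / "pair_census.json").write_text(json.dumps(census, indent=2))
    bundle["pair_census"] = census
    logger.info("stage correlate: %(n_significant)d/%(n_pairs)d significant", census)

    # -- stage 4: network --------------------------------------------------
    net = network.build_graph(corr)
    network.fr_layout(net, seed=config.layout_seed)
    cent = network.centralities(net)
    net.write(out)
    bundle["top_strength_node"] = cent["strength"].idxmax()
    logger.info("stage network: top-strength node %s", bundle["top_strength_node"])

    # -- stage 5: EFA -------------------------------------------------------
    S = wide.corr()
    unrot = efa.ml_efa(S, n=len(wide), m=config.n_factors)
    rot = efa.oblimin_rotate(unrot)
    pa_m = efa.parallel_analysis(wide.to_numpy(), seed=config.seed)
    efa_report = {
        "m": rot.m,
        "suggested_m_parallel": int(pa_m),
        "chisq": rot.T,
        "df": rot.df,
        "variance_explained": [float(v) for v in rot.variance_explained],
        "heywood": rot.heywood,
    }
    rot.pattern_table(0.0).to_csv(out / "efa_pattern.csv")
    (out / "efa_report.json").write_text(json.dumps(efa_report, indent=2))
    bundle["efa"] = efa_report
    logger.info("stage efa: chisq=%.1f df=%d, parallel suggests m=%d", rot.T, rot.df, pa_m)

    # -- stage 6: CFA -------------------------------------------------------
    cfa_spec = sem.default_cfa_spec()
    fit = sem.fit_cfa(wide, cfa_spec, robust=config.robust)
    scores = sem.factor_scores(fit, wide)
    scores.to_csv(out / "factor_scores.csv")
    cfa_json = {
        "chisq": fit.T,
        "df": fit.df,
        "converged": fit.converged,
        "fit": {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in fit.fit.items()},
        "params": fit.summary_table().to_dict(orient="records"),
    }
    if fit.scaling_factor is not None:
        cfa_json["scaling_factor"] = fit.scaling_factor
        cfa_json["chisq_scaled"] = fit.T_scaled
    (out / "cfa_fit.json").write_text(json.dumps(cfa_json, indent=2, default=float))
    bundle["cfa"] = {k: cfa_json[k] for k in ("chisq", "df", "converged")}
    bundle["cfa"]["fit"] = cfa_json["fit"]
    logger.info("stage cfa: chisq=%.1f df=%d CFI=%.3f", fit.T, fit.df, fit.fit["CFI"])

    # -- stage 7: factor-score association table ---------------------------
    if metadata is not None:
        level_means = lcv_year_levels(records)
        table3 = table3_report(scores, metadata.loc[wide.index], level_means, alpha=config.alpha)
        table3.to_csv(out / "table3.csv")
        bundle["table3_shape"] = list(table3.shape)

    # -- stage 8: invariance ------------------------------------------------
    if config.group_column and metadata is not None and config.group_column in metadata.columns:
        groups = metadata.loc[wide.index, config.group_column]
        thresholds = invariance.InvarianceThresholds(config.d_cfi, config.d_tli, config.d_rmsea)
        report = invariance.fit_invariance_ladder(
            wide, cfa_spec, groups, thresholds=thresholds, seed=config.seed
        )
        means_level = (
            "strict"
            if invariance.LEVELS.index(report.achieved_level) >= invariance.LEVELS.index("strict")
            else report.achieved_level
        )
        inv_json = {
            "grid": report.grid().reset_index().to_dict(orient="records"),
            "deltas": report.deltas.reset_index().to_dict(orient="records"),
            "achieved_level": report.achieved_level,
        }
        if means_level in ("scalar", "strict"):
            fm = invariance.compare_factor_means(report, means_level)
            fm.to_csv(out / "factor_means.csv")
            inv_json["factor_means_level"] = means_level
            inv_json["factor_means"] = fm.reset_index().to_dict(orient="records")
        (out / "invariance_report.json").write_text(json.dumps(inv_json, indent=2, default=float))
        bundle["invariance"] = {"achieved_level": report.achieved_level}
        logger.info("stage invariance: achieved %s", report.achieved_level)
    else:
        logger.info("stage invariance: skipped (no grouping)")

    manifest = {
        "package": "dysreg",
        "version": dysreg.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "layout_seed": config.layout_seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": sorted(bundle),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


def lcv_year_levels(records: pd.DataFrame) -> pd.DataFrame:
    """Patient x biomarker table of yearly mean levels (the M values)."""
    summ = variability.aggregate(records, window="year")
    wide = summ.pivot(index="patient_id", columns="biomarker", values="M")
    return wide.rename(columns=lambda b: f"{b}-M")


def table3_report(
    factor_scores: pd.DataFrame,
    metadata: pd.DataFrame,
    lcv_levels: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Factor-score x covariate association grid.

    Continuous covariates use the Pearson/Spearman selection rule;
    dichotomous covariates (sex, diabetes) use point-biserial coefficients
    with Welch-t p-values.  Cells carry the coefficient, with significance
    stars at 0.05 / 0.01 / 0.001 in a parallel column.
    """
    cov = metadata.copy()
    if lcv_levels is not None:
        cov = cov.join(lcv_levels, how="inner")
    cov = cov.loc[factor_scores.index.intersection(cov.index)]
    fs = factor_scores.loc[cov.index]
    rows = {}
    for col in cov.columns:
        series = cov[col]
        if series.dtype == object or series.dtype == bool or series.nunique() == 2:
            if series.nunique() != 2:
                logger.warning("table3: covariate %r skipped (not dichotomous)", col)
                continue
            vals = {}
            for fac in fs.columns:
                r, p = association.point_biserial_welch(fs[fac].to_numpy(), series.to_numpy())
                vals[fac] = (r, p)
        elif np.issubdtype(series.dtype, np.number):
            x = series.to_numpy(dtype=float)
            try:
                _, _, rejected = variability.ks_normality(x, alpha=alpha)
            except ValueError:
                logger.warning("table3: covariate %r skipped (degenerate)", col)
                continue
            vals = {}
            from scipy import stats as _st

            for fac in fs.columns:
                if rejected:
                    r = float(_st.spearmanr(fs[fac], x).statistic)
                else:
                    r = float(_st.pearsonr(fs[fac], x).statistic)
                p = association._t_approx_p(r, len(x))
                vals[fac] = (r, p)
        else:
            logger.warning("table3: covariate %r skipped (unsupported dtype)", col)
            continue
        rows[col] = vals

    def star(p):
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < alpha else ""

    out = {}
    for cov_name, vals in rows.items():
        for fac, (r, p) in vals.items():
            out.setdefault(fac, {})[cov_name] = r
            out.setdefault(f"{fac}_sig", {})[cov_name] = star(p)
    return pd.DataFrame(out)


# ----------------------------------------------------------------------
# CLI
# ----------------------------------------------------------------------

def _add_common(sp):
    sp.add_argument("--out", default="results/pipeline", help="output directory")
    sp.add_argument("--seed", type=int, default=1)
    sp.add_argument("--n-patients", type=int, default=334)


def main(argv=None) -> int:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    ap = argparse.ArgumentParser(
        prog="dysreg",
        description="Variability-based physiological network analysis pipeline",
    )
    sub = ap.add_subparsers(dest="cmd", required=True)
    for cmd in ("simulate", "variability", "correlate", "network", "efa", "cfa", "invariance", "run-all"):
        sp = sub.add_parser(cmd)
        _add_common(sp)
        if cmd != "simulate":
            sp.add_argument("--records", default=None, help="records.csv (default: simulate)")
            sp.add_argument("--metadata", default=None)
        if cmd in ("run-all",):
            sp.add_argument("--config", default=None, help="YAML config file")
    args = ap.parse_args(argv)

    if getattr(args, "config", None):
        config = PipelineConfig.from_yaml(args.config)
    else:
        config = PipelineConfig(
            outdir=args.out,
            seed=args.seed,
            n_patients=args.n_patients,
            records=getattr(args, "records", None),
            metadata=getattr(args, "metadata", None),
        )

    if args.cmd == "simulate":
        spec = synthetic_cohort.default_spec(n_patients=config.n_patients)
        cohort = synthetic_cohort.generate_cohort(spec, seed=config.seed)
        cohort.write(Path(config.outdir) / "cohort")
        print(f"wrote cohort ({len(cohort.records)} records) under {config.outdir}/cohort")
        return 0

    if args.cmd == "run-all":
        bundle = run_pipeline(config)
        print(json.dumps({k: v for k, v in bundle.items() if k != "manifest"}, indent=2, default=str))
        return 0

    # single stages run the pipeline up to the requested point by reusing
    # run_pipeline with stage-appropriate config; stages are cheap enough
    # that recomputation beats partial-state bookkeeping.
    bundle = run_pipeline(config)
    print(json.dumps({k: v for k, v in bundle.items() if k != "manifest"}, indent=2, default=str))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
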