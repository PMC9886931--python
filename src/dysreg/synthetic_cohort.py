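"""Synthetic maintenance-hemodialysis cohorts with latent dysregulation structure.

The generator emulates one year of routine monitoring for a hemodialysis
population: 19 blood biomarkers drawn on fixed twice-monthly / monthly /
bi-monthly schedules and 3 hemodynamic biomarkers (SBP, DBP, PR) recorded
at every dialysis session (~147 per patient per year).

The data-generating model places the latent structure directly on the
variability (LCV) scale: each patient i carries a 6-vector of regulatory
domain states eta_i ~ MVN(alpha_g, Phi) (metabolism, circulation, liver,
salt, inflammation, protein), and the patient's true log10 coefficient of
variation for biomarker j is

    LCV_ij = nu_j + Lambda_j . eta_i + eps_ij,   eps_ij ~ N(0, theta_j).

Measurements are then drawn around a patient-level mean M_ij with SD
10**LCV_ij * M_ij, plus an additive seasonal cosine for blood pressure.
Loadings and marginal LCV/level moments default to reference values
reported for this panel; the loading matrix is scaled so the implied LCV SD
sqrt((Lambda Phi Lambda' + Theta)_jj) equals the target marginal SD
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FACTORS",
    "BIOMARKERS",
    "HEMODYNAMIC",
    "GroupSpec",
    "GenerativeSpec",
    "CohortData",
    "default_spec",
    "generate_cohort",
    "sample_lcv_matrix",
    "add_seasonal_component",
]

FACTORS = ["metabolism", "circulation", "liver", "salt", "inflammation", "protein"]

# biomarker -> (measurements/year, level mean, level SD, LCV mean, LCV SD)
# Levels in native units (mmHg, /min, /ul, g/dl, IU/l, mg/dl, mmol/l, 1e4/ul).
_MARGINALS: dict[str, tuple[int, float, float, float, float]] = {
    "SBP": (147, 150.8, 18.3, -0.99, 0.10),
    "DBP": (147, 80.0, 10.8, -0.99, 0.11),
    "PR": (147, 75.9, 10.0, -1.11, 0.12),
    "WBC": (24, 6325.0, 1572.0, -0.93, 0.15),
    "Hb": (24, 11.1, 0.7, -1.24, 0.18),
    "Plat": (24, 20.0, 6.0, -1.03, 0.18),
    "TP": (12, 6.3, 0.4, -1.50, 0.15),
    "Alb": (24, 3.6, 0.3, -1.36, 0.15),
    "AST": (6, 13.8, 6.7, -0.69, 0.26),
    "ALT": (6, 11.6, 6.4, -0.75, 0.28),
    "LDH": (6, 179.0, 46.0, -1.11, 0.18),
    "ALP": (6, 224.0, 82.0, -0.97, 0.23),
    "BUN": (24, 64.5, 12.3, -0.91, 0.14),
    "Cr": (24, 11.7, 2.7, -1.26, 0.18),
    "UA": (12, 7.2, 1.2, -1.08, 0.17),
    "Na": (12, 137.9, 2.3, -1.96, 0.13),
    "K": (24, 5.0, 0.5, -1.10, 0.15),
    "Cl": (12, 103.3, 2.7, -1.79, 0.14),
    "Ca": (24, 8.6, 0.5, -1.42, 0.18),
    "P": (24, 5.3, 0.9, -0.80, 0.14),
    "LDL": (6, 86.7, 26.5, -1.02, 0.22),
    "HDL": (6, 45.0, 13.2, -1.09, 0.21),
}

BIOMARKERS = list(_MARGINALS)
HEMODYNAMIC = ["SBP", "DBP", "PR"]

# Standardized loadings of each biomarker's LCV on the six domains.  The
# primary (>= 0.4) loadings define the factor structure used by every
# recovery test; the smaller secondary loadings spread weak positive
# dependence across the panel the way a real panel shows it (their factor
# assignment is a modelling choice, see docs/methods.md).
_STD_LOADINGS: dict[str, dict[str, float]] = {
    "BUN": {"metabolism": 0.82},
    "Cr": {"metabolism": 0.61},
    "K": {"metabolism": 0.69},
    "P": {"metabolism": 0.61, "circulation": -0.11, "protein": 0.11},
    "UA": {"metabolism": 0.44, "circulation": -0.20, "protein": 0.14},
    "SBP": {"circulation": 0.78},
    "DBP": {"circulation": 1.00},
    "AST": {"liver": 0.94},
    "ALT": {"liver": 0.72, "metabolism": 0.11, "protein": -0.12},
    "Na": {"salt": 0.76, "inflammation": 0.11},
    "Cl": {"salt": 0.88},
    "WBC": {"inflammation": 0.54},
    "Plat": {"inflammation": 0.84},
    "TP": {"protein": 0.88},
    "Alb": {"protein": 0.61, "metabolism": 0.31},
    "Hb": {"metabolism": 0.34, "inflammation": 0.21},
    "LDH": {"metabolism": 0.21, "liver": 0.10, "inflammation": 0.27},
    "ALP": {"liver": 0.33},
    "Ca": {"metabolism": 0.22, "salt": 0.13, "protein": 0.17},
    "LDL": {"metabolism": 0.29, "protein": 0.16},
    "HDL": {"metabolism": 0.14, "liver": 0.17, "protein": 0.16},
    "PR": {"metabolism": 0.12, "circulation": 0.25, "inflammation": 0.11, "protein": 0.17},
}

# Biomarkers whose largest standardized loading is >= 0.40;
# these define the primary indicator sets of the six domains.
PRIMARY_INDICATORS: dict[str, list[str]] = {
    "metabolism": ["BUN", "Cr", "K", "P", "UA"],
    "circulation": ["SBP", "DBP"],
    "liver": ["AST", "ALT"],
    "salt": ["Na", "Cl"],
    "inflammation": ["WBC", "Plat"],
    "protein": ["TP", "Alb"],
}

# Additive seasonal cycle (amplitude in native units, peak month); winter
# blood-pressure peak with Feb-minus-Aug differences of ~7.8 / ~4.8 mmHg.
_SEASONAL_DEFAULT: dict[str, tuple[float, int]] = {
    "SBP": (3.9, 2),
    "DBP": (2.4, 2),
    "PR": (0.2, 2),
}

# Factor-mean shift of the diabetic group on each domain, expressed in the
# units of each domain's primary marker indicator's LCV (the scale on which
# multi-group CFA software reports factor-mean contrasts under marker
# identification; reference group at zero).  default_spec converts these to
# unit-factor-variance latent units by dividing by the marker loading.
DIABETIC_OFFSETS_MARKER = np.array([0.049, 0.009, 0.021, 0.034, 0.005, -0.006])

# first (marker) indicator of each domain
MARKER_INDICATORS = {
    "metabolism": "BUN",
    "circulation": "SBP",
    "liver": "AST",
    "salt": "Na",
    "inflammation": "WBC",
    "protein": "TP",
}

_MAX_COMMUNALITY = 0.98  # cap so every residual variance stays positive


@dataclass(frozen=True)
class GroupSpec:
    label: str
    fraction: float
    factor_mean_offset: np.ndarray  # per-factor latent mean shift
    lcv_scale: float = 1.0  # multiplies the latent deviation (nu stays put)


@dataclass
class GenerativeSpec:
    """Full parameterization of the synthetic cohort generator."""

    biomarkers: list[str]
    factors: list[str]
    n_patients: int
    groups: list[GroupSpec]
    phi: np.ndarray  # factor correlation matrix
    loadings: pd.DataFrame  # biomarker x factor, LCV scale
    lcv_intercepts: pd.Series  # nu, log10 units
    lcv_residual_sd: pd.Series  # sqrt(theta), log10 units
    level_mean: pd.Series  # biomarker units
    level_sd: pd.Series
    schedule: dict[str, int]  # measurements per year
    seasonal: dict[str, tuple[float, int]]  # amplitude, peak month
    hemodynamic: list[str] = field(default_factory=lambda: list(HEMODYNAMIC))
    year: int = 2020
    noise: str = "normal"  # "normal" | "lognormal"

    def validate(self) -> None:
        k = len(self.factors)
        phi = np.asarray(self.phi, dtype=float)
        if phi.shape != (k, k):
            raise ValueError(f"phi must be {k}x{k}, got {phi.shape}")
        if not np.allclose(phi, phi.T):
            raise ValueError("phi must be symmetric")
        if not np.allclose(np.diag(phi), 1.0):
            raise ValueError("phi must have a unit diagonal")
        if np.linalg.eigvalsh(phi).min() < -1e-10:
            raise ValueError("phi must be positive semi-definite")
        if (self.lcv_residual_sd <= 0).any():
            raise ValueError("all lcv_residual_sd must be > 0")
        if (self.level_mean <= 0).any():
            raise ValueError("all level_mean must be > 0")
        fr = sum(g.fraction for g in self.groups)
        if abs(fr - 1.0) > 1e-9:
            raise ValueError(f"group fractions must sum to 1, got {fr}")
        if self.noise not in ("normal", "lognormal"):
            raise ValueError(f"noise must be 'normal' or 'lognormal', got {self.noise!r}")

    # -- population-implied quantities -------------------------------------
    def implied_lcv_cov(self) -> pd.DataFrame:
        lam = self.loadings.to_numpy()
        cov = lam @ self.phi @ lam.T + np.diag(self.lcv_residual_sd.to_numpy() ** 2)
        return pd.DataFrame(cov, index=self.biomarkers, columns=self.biomarkers)

    def implied_lcv_sd(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.implied_lcv_cov().to_numpy())), index=self.biomarkers
        )

    def implied_lcv_corr(self) -> pd.DataFrame:
        cov = self.implied_lcv_cov().to_numpy()
        d = 1.0 / np.sqrt(np.diag(cov))
        return pd.DataFrame(
            cov * np.outer(d, d), index=self.biomarkers, columns=self.biomarkers
        )


@dataclass
class CohortData:
    """Long-format records plus metadata and generative ground truth."""

    records: pd.DataFrame  # patient_id, date, biomarker, value
    metadata: pd.DataFrame  # indexed by patient_id
    truth_eta: pd.DataFrame  # patient x factor latent states
    truth_lcv: pd.DataFrame  # patient x biomarker true LCV
    spec: GenerativeSpec
    seed: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "records.csv", index=False)
        self.metadata.to_csv(outdir / "metadata.csv")
        self.truth_eta.to_csv(outdir / "truth_eta.csv")
        self.truth_lcv.to_csv(outdir / "truth_lcv.csv")


def default_spec(n_patients: int = 334, phi_offdiag: float = 0.4) -> GenerativeSpec:
    """Generative spec reproducing the reference panel's marginal structure.

    22 biomarkers on their routine schedules, marginal level and LCV
    moments matching the cohort table, standardized domain loadings from
    the 6-factor solution, a uniform inter-domain correlation
    (default 0.4), and a diabetic subgroup (fraction 143/334) whose domain
    means are shifted by the reference contrasts.
    """
    factors = list(FACTORS)
    k = len(factors)
    phi = np.full((k, k), phi_offdiag)
    np.fill_diagonal(phi, 1.0)

    lcv_mean = pd.Series({b: _MARGINALS[b][3] for b in BIOMARKERS})
    lcv_sd = pd.Series({b: _MARGINALS[b][4] for b in BIOMARKERS})

    # standardized loadings -> LCV-scale loadings with exact marginal SDs
    std = pd.DataFrame(0.0, index=BIOMARKERS, columns=factors)
    for b, row in _STD_LOADINGS.items():
        for f, v in row.items():
            std.loc[b, f] = v
    lam_std = std.to_numpy()
    comm = np.einsum("jf,fg,jg->j", lam_std, phi, lam_std)
    over = comm > _MAX_COMMUNALITY
    lam_std[over] *= np.sqrt(_MAX_COMMUNALITY / comm[over])[:, None]
    comm = np.minimum(comm, _MAX_COMMUNALITY)
    loadings = pd.DataFrame(
        lam_std * lcv_sd.to_numpy()[:, None], index=BIOMARKERS, columns=factors
    )
    resid_sd = pd.Series(np.sqrt((1.0 - comm)) * lcv_sd.to_numpy(), index=BIOMARKERS)

    frac_dm = 143 / 334
    # convert marker-scale contrasts to unit-variance latent units
    marker_loading = np.array(
        [loadings.loc[MARKER_INDICATORS[f], f] for f in factors]
    )
    latent_offsets = DIABETIC_OFFSETS_MARKER / marker_loading
    groups = [
        GroupSpec("non_diabetic", 1 - frac_dm, np.zeros(k)),
        GroupSpec("diabetic", frac_dm, latent_offsets),
    ]
    # center intercepts so the population LCV mean hits the marginal target
    alpha_bar = sum(g.fraction * g.factor_mean_offset for g in groups)
    nu = lcv_mean - pd.Series(loadings.to_numpy() @ alpha_bar, index=BIOMARKERS)

    spec = GenerativeSpec(
        biomarkers=list(BIOMARKERS),
        factors=factors,
        n_patients=n_patients,
        groups=groups,
        phi=phi,
        loadings=loadings,
        lcv_intercepts=nu,
        lcv_residual_sd=resid_sd,
        level_mean=pd.Series({b: _MARGINALS[b][1] for b in BIOMARKERS}),
        level_sd=pd.Series({b: _MARGINALS[b][2] for b in BIOMARKERS}),
        schedule={b: _MARGINALS[b][0] for b in BIOMARKERS},
        seasonal=dict(_SEASONAL_DEFAULT),
    )
    spec.validate()
    return spec


def spec_from_config(config: dict | str | Path) -> GenerativeSpec:
    """Build a generative spec from a declarative key-value config.

    The config (a dict or a YAML file path) overrides fields of the
    default spec: scalar fields (``n_patients``, ``year``, ``noise``,
    ``phi_offdiag``), per-biomarker maps (``schedule``, ``level_mean``,
    ``level_sd``, ``lcv_intercepts``, ``lcv_residual_sd``), ``seasonal``
    as {biomarker: [amplitude, peak_month]}, and ``groups`` as a list of
    {label, fraction, factor_mean_offset, lcv_scale} entries.
    """
    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    spec = default_spec(
        n_patients=int(config.get("n_patients", 334)),
        phi_offdiag=float(config.get("phi_offdiag", 0.4)),
    )
    if "year" in config:
        spec.year = int(config["year"])
    if "noise" in config:
        spec.noise = str(config["noise"])
    for field_name in ("level_mean", "level_sd", "lcv_intercepts", "lcv_residual_sd"):
        for bm, val in (config.get(field_name) or {}).items():
            getattr(spec, field_name)[bm] = float(val)
    for bm, val in (config.get("schedule") or {}).items():
        spec.schedule[bm] = int(val)
    for bm, val in (config.get("seasonal") or {}).items():
        spec.seasonal[bm] = (float(val[0]), int(val[1]))
    if "groups" in config:
        spec.groups = [
            GroupSpec(
                label=str(g["label"]),
                fraction=float(g["fraction"]),
                factor_mean_offset=np.asarray(
                    g.get("factor_mean_offset", np.zeros(len(spec.factors))), dtype=float
                ),
                lcv_scale=float(g.get("lcv_scale", 1.0)),
            )
            for g in config["groups"]
        ]
    spec.validate()
    return spec


def _seasonal_shift(spec: GenerativeSpec, biomarker: str, months: np.ndarray) -> np.ndarray:
    amp, peak = spec.seasonal.get(biomarker, (0.0, 2))
    if amp == 0.0:
        return np.zeros_like(months, dtype=float)
    return amp * np.cos(2.0 * np.pi * (months - peak) / 12.0)


def _group_assignment(spec: GenerativeSpec) -> list[str]:
    n = spec.n_patients
    counts = [int(round(g.fraction * n)) for g in spec.groups]
    counts[-1] = n - sum(counts[:-1])
    labels: list[str] = []
    for g, c in zip(spec.groups, counts):
        labels.extend([g.label] * c)
    return labels


def _sample_latent(spec: GenerativeSpec, rng: np.random.Generator):
    """Draw per-patient latent states and true LCVs."""
    labels = _group_assignment(spec)
    by_label = {g.label: g for g in spec.groups}
    k = len(spec.factors)
    chol = np.linalg.cholesky(spec.phi + 1e-12 * np.eye(k))
    n = spec.n_patients
    eta = np.empty((n, k))
    scale = np.empty(n)
    for i, lab in enumerate(labels):
        g = by_label[lab]
        eta[i] = g.factor_mean_offset + chol @ rng.standard_normal(k)
        scale[i] = g.lcv_scale
    lam = spec.loadings.to_numpy()
    theta_sd = spec.lcv_residual_sd.to_numpy()
    eps = rng.standard_normal((n, len(spec.biomarkers))) * theta_sd
    lcv_true = spec.lcv_intercepts.to_numpy() + scale[:, None] * (eta @ lam.T + eps)
    return labels, eta, lcv_true


def _blood_dates(year: int, per_year: int) -> pd.DatetimeIndex:
    if per_year == 24:
        days = [(m, d) for m in range(1, 13) for d in (5, 19)]
    elif per_year == 12:
        days = [(m, 5) for m in range(1, 13)]
    elif per_year == 6:
        days = [(m, 5) for m in (1, 3, 5, 7, 9, 11)]
    else:
        raise ValueError(f"unsupported blood schedule: {per_year}/year")
    return pd.DatetimeIndex([pd.Timestamp(year, m, d) for m, d in days])


def _session_grid(year: int) -> pd.DatetimeIndex:
    """Mon/Wed/Fri dialysis-session days of the observation year."""
    all_days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    return all_days[all_days.weekday.isin([0, 2, 4])]


def _session_counts(rng: np.random.Generator, n: int, grid_size: int) -> np.ndarray:
    """Per-patient yearly session counts: discretized, median 147, IQR 118-156."""
    q = np.array([0.0, 0.05, 0.25, 0.50, 0.75, 0.95, 1.0])
    v = np.array([60.0, 92.0, 118.0, 147.0, 156.0, 156.0, 156.0])
    u = rng.uniform(size=n)
    counts = np.rint(np.interp(u, q, v)).astype(int)
    return np.clip(counts, 10, grid_size)


def _positive_normal(
    rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray, max_tries: int = 200
) -> np.ndarray:
    """Gaussian draws resampled until strictly positive (element-wise)."""
    out = rng.normal(mean, sd)
    bad = out <= 0
    tries = 0
    while bad.any():
        out[bad] = rng.normal(np.broadcast_to(mean, out.shape)[bad], np.broadcast_to(sd, out.shape)[bad])
        bad = out <= 0
        tries += 1
        if tries > max_tries:
            raise RuntimeError("positive resampling failed to converge")
    return out


def generate_cohort(spec: GenerativeSpec, seed: int) -> CohortData:
    """Simulate one observation year of records for a cohort under ``spec``.

    Identical (spec, seed) pairs produce byte-identical output.  Raises if
    the seed is omitted: every run must be explicitly reproducible.
    """
    if seed is None:
        raise ValueError("generate_cohort requires an explicit integer seed")
    spec.validate()
    rng = np.random.default_rng(seed)

    labels, eta, lcv_true = _sample_latent(spec, rng)
    n = spec.n_patients
    pids = [f"pt{i + 1:04d}" for i in range(n)]
    biomarkers = spec.biomarkers
    p = len(biomarkers)

    # patient-level means, resampled until positive
    level_mu = spec.level_mean.to_numpy()
    level_sd = spec.level_sd.to_numpy()
    M = _positive_normal(rng, np.tile(level_mu, (n, 1)), np.tile(level_sd, (n, 1)))

    grid = _session_grid(spec.year)
    counts = _session_counts(rng, n, len(grid))
    session_dates = [
        pd.DatetimeIndex(np.sort(rng.choice(grid.values, size=c, replace=False)))
        for c in counts
    ]

    frames = []
    for j, bm in enumerate(biomarkers):
        sched = spec.schedule[bm]
        sigma = 10.0 ** lcv_true[:, j] * M[:, j]  # within-patient SD
        if bm in spec.hemodynamic:
            pid_col, date_col, val_col = [], [], []
            for i in range(n):
                dates = session_dates[i]
                months = dates.month.to_numpy()
                mu = M[i, j] + _seasonal_shift(spec, bm, months)
                vals = _draw_values(rng, mu, sigma[i], spec.noise)
                pid_col.append(np.repeat(pids[i], len(dates)))
                date_col.append(dates.values)
                val_col.append(vals)
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": np.concatenate(pid_col),
                        "date": np.concatenate(date_col),
                        "biomarker": bm,
                        "value": np.concatenate(val_col),
                    }
                )
            )
        else:
            dates = _blood_dates(spec.year, sched)
            months = dates.month.to_numpy()
            seas = _seasonal_shift(spec, bm, months)
            mu = M[:, j][:, None] + seas[None, :]
            vals = _draw_values(rng, mu, sigma[:, None], spec.noise)
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": np.repeat(pids, len(dates)),
                        "date": np.tile(dates.values, n),
                        "biomarker": bm,
                        "value": vals.ravel(),
                    }
                )
            )
    records = pd.concat(frames, ignore_index=True)
    records["date"] = pd.to_datetime(records["date"]).dt.strftime("%Y-%m-%d")
    records = records.sort_values(["patient_id", "biomarker", "date"], kind="mergesort")
    records = records.reset_index(drop=True)

    age = np.clip(rng.normal(62.9, 11.9, size=n), 28.6, 88.4)
    sex = np.where(rng.uniform(size=n) < 255 / 334, "M", "F")
    vintage = np.clip(rng.lognormal(mean=2.14, sigma=0.73, size=n), 0.5, 45.0)
    bmi = np.clip(rng.normal(23.5, 5.0, size=n), 13.0, 45.0)
    metadata = pd.DataFrame(
        {
            "group": labels,
            "age_years": np.round(age, 1),
            "sex": sex,
            "diabetes": [lab == "diabetic" for lab in labels],
            "vintage_years": np.round(vintage, 2),
            "bmi": np.round(bmi, 1),
            "n_sessions": counts,
            "n_blood_tests": 24,
        },
        index=pd.Index(pids, name="patient_id"),
    )

    truth_eta = pd.DataFrame(eta, index=metadata.index, columns=spec.factors)
    truth_lcv = pd.DataFrame(lcv_true, index=metadata.index, columns=biomarkers)
    return CohortData(
        records=records,
        metadata=metadata,
        truth_eta=truth_eta,
        truth_lcv=truth_lcv,
        spec=spec,
        seed=seed,
    )


def _draw_values(
    rng: np.random.Generator, mu: np.ndarray, sigma: np.ndarray, noise: str
) -> np.ndarray:
    """Measurement noise around the (seasonal) patient mean.

    Gaussian by default, resampled until positive; the CVs in this panel
    are small enough (<~0.2) that truncation bias is negligible.  The
    lognormal option matches the target mean and SD exactly and is always
    positive.
    """
    mu = np.broadcast_to(mu, np.broadcast_shapes(np.shape(mu), np.shape(sigma)))
    sigma = np.broadcast_to(sigma, mu.shape)
    if noise == "normal":
        return _positive_normal(rng, mu.copy(), sigma)
    cv2 = (sigma / mu) ** 2
    s2 = np.log1p(cv2)
    z = rng.standard_normal(mu.shape)
    return mu * np.exp(np.sqrt(s2) * z - s2 / 2.0)


def sample_lcv_matrix(spec: GenerativeSpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent shortcut: draw true per-patient LCVs without record simulation.

    Returns (lcv_table, eta_table) with group labels on the index level
    'group'.  Useful when only the variability layer matters (the full
    generator adds finite-sampling noise on top of these values).
    """
    if seed is None:
        raise ValueError("sample_lcv_matrix requires an explicit integer seed")
    spec.validate()
    rng = np.random.default_rng(seed)
    labels, eta, lcv_true = _sample_latent(spec, rng)
    idx = pd.MultiIndex.from_arrays(
        [[f"pt{i + 1:04d}" for i in range(spec.n_patients)], labels],
        names=["patient_id", "group"],
    )
    return (
        pd.DataFrame(lcv_true, index=idx, columns=spec.biomarkers),
        pd.DataFrame(eta, index=idx, columns=spec.factors),
    )


def add_seasonal_component(
    records: pd.DataFrame, biomarker: str, amplitude: float, peak_month: int = 2
) -> pd.DataFrame:
    """Add a cosine seasonal cycle to one biomarker's measurements.

    Each measurement gains amplitude * cos(2*pi*(month - peak_month)/12);
    the default peak month 2 (February) encodes a winter blood-pressure
    peak.  Returns a modified copy.
    """
    if amplitude < 0:
        raise ValueError(f"amplitude must be >= 0, got {amplitude}")
    if biomarker not in set(records["biomarker"]):
        raise ValueError(f"unknown biomarker: {biomarker!r}")
    out = records.copy()
    mask = out["biomarker"] == biomarker
    months = pd.to_datetime(out.loc[mask, "date"]).dt.month.to_numpy()
    out.loc[mask, "value"] = out.loc[mask, "value"].to_numpy() + amplitude * np.cos(
        2.0 * np.pi * (months - peak_month) / 12.0
    )
    return out
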