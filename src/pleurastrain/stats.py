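"""Study statistics: dose-response mixed models, reliability, feasibility.

The modeling layer follows the Model/Results idiom: build a
:class:`DoseResponseModel` from a long-format study table, call ``fit()``
and read estimates off the returned :class:`DoseResponseResults` (slopes on
the standardized scale with Wald 95% CIs, variance components, marginal and
conditional R², ``summary()``).  Reliability is analysed the same way with
:class:`ReliabilityModel` → :class:`ReliabilityResults` (ICC(2,1) with
analytic and BCa-bootstrap CIs, Bland–Altman agreement).

Analysis conventions: continuous dependent and independent variables are
centered and reduced before modeling so slopes are comparable across the six
parameters; triplicate cineloops are averaged per cell; the reliability
re-acquisitions at 10 mL/kg are excluded from the dose-response models; the
tidal-volume effect is screened at the Bonferroni level 0.05/6; mixed models
use REML with random intercepts per patient and per anatomical location
nested within patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

N_PARAMETERS = 6
BONFERRONI_ALPHA = 0.05 / N_PARAMETERS    # displayed as 0.008
ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))


# ---------------------------------------------------------------------------
# table preparation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Standardization:
    """Centering/reduction metadata allowing back-transformation."""

    mean: float
    sd: float

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(
    table: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, dict[str, Standardization]]:
    """Center and reduce the named continuous columns (population SD).

    Returns the transformed table plus per-variable scaling metadata; a
    zero-variance column is rejected by name.
    """
    out = table.copy()
    scales: dict[str, Standardization] = {}
    for var in variables:
        x = out[var].to_numpy(dtype=float)
        sd = float(np.std(x))
        if sd == 0:
            raise ValueError(f"variable {var!r} has zero variance; cannot standardize")
        scales[var] = Standardization(mean=float(np.mean(x)), sd=sd)
        out[var] = scales[var].transform(x)
    return out, scales


def average_triplicates(
    table: pd.DataFrame,
    value_columns: list[str] | None = None,
    *,
    drop_reliability: bool = True,
) -> pd.DataFrame:
    """Average replicate cineloops within each patient × location × TV × session.

    Reliability-session rows (the repeated 10 mL/kg acquisitions) are dropped
    from the modeling table when ``drop_reliability`` is set; missing
    replicates are simply averaged over those present.
    """
    if value_columns is None:
        value_columns = [c for c in ("response",) if c in table.columns]
    t = table
    if drop_reliability and "session" in t.columns:
        t = t[t["session"] == "primary"]
    keys = [c for c in ("patient_id", "location", "side", "dependence",
                        "tidal_volume_ml_kg", "observer", "session") if c in t.columns]
    agg = {c: "mean" for c in value_columns}
    if "quality_flag" in t.columns:
        # a cell is high quality only if every replicate is
        agg["quality_flag"] = lambda s: "high" if (s == "high").all() else "standard"
    return t.groupby(keys, as_index=False, sort=True).agg(agg)


def sensitivity_subset(table: pd.DataFrame, *, tracking_ok: pd.Series | None = None) -> pd.DataFrame:
    """Better-imaging-quality subset: high quality flag and perfect tracking."""
    mask = table["quality_flag"] == "high"
    if tracking_ok is not None:
        mask &= tracking_ok.reindex(table.index, fill_value=False)
    subset = table[mask]
    if subset.empty:
        import warnings

        warnings.warn("sensitivity subset is empty; fits skipped", stacklevel=2)
    return subset


# ---------------------------------------------------------------------------
# dose-response mixed model
# ---------------------------------------------------------------------------

class DoseResponseModel:
    """Nested linear mixed model of one elastography parameter vs tidal volume.

    Fixed effects: standardized tidal volume, side (left vs right),
    gravity dependence (dependent vs non-dependent) and the tidal-volume ×
    dependence interaction.  Random intercepts: patient, and location nested
    within patient.  The response is centered and reduced (unless
    ``standardize_response=False``), so the reported slope is in SD units per
    SD of tidal volume.

    Parameters
    ----------
    table
        Long-format study table; replicates should already be averaged
        (see :func:`average_triplicates`).
    parameter
        Name of the response column.
    """

    def __init__(self, table: pd.DataFrame, parameter: str = "response",
                 *, standardize_response: bool = True):
        required = {"patient_id", "location", "side", "dependence",
                    "tidal_volume_ml_kg", parameter}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"study table lacks columns: {sorted(missing)}")
        if table["tidal_volume_ml_kg"].nunique() < 2:
            raise ValueError("need at least two tidal-volume levels")

        data = table.copy()
        data = data.rename(columns={parameter: "y"}) if parameter != "y" else data
        to_scale = ["tidal_volume_ml_kg"] + (["y"] if standardize_response else [])
        data, self.scaling = standardize(data, to_scale)
        data["tv_std"] = data["tidal_volume_ml_kg"]
        data["dependence"] = pd.Categorical(
            data["dependence"], categories=["nondependent", "dependent"])
        data["side"] = pd.Categorical(data["side"], categories=["right", "left"])
        self.data = data
        self.parameter = parameter

    @classmethod
    def from_study_table(cls, raw_table: pd.DataFrame, parameter: str = "response",
                         **kwargs) -> "DoseResponseModel":
        """Build from a raw (replicate-level) table: averages triplicates and
        drops the reliability sessions first."""
        return cls(average_triplicates(raw_table, [parameter]), parameter, **kwargs)

    def fit(self, reml: bool = True) -> "DoseResponseResults":
        model = smf.mixedlm(
            "y ~ tv_std + C(side) + C(dependence) + tv_std:C(dependence)",
            data=self.data,
            groups=self.data["patient_id"],
            re_formula="1",
            vc_formula={"location": "0 + C(location)"},
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=reml, method=["lbfgs", "powell"])
        return DoseResponseResults(self, fit)


@dataclass
class DoseResponseResults:
    """Estimates from a fitted dose-response mixed model."""

    model: DoseResponseModel
    _fit: object

    def __post_init__(self) -> None:
        fit = self._fit
        params = fit.params
        cov = fit.cov_params()
        names = list(fit.model.exog_names)
        self._tv = "tv_std"
        self._ix = "tv_std:C(dependence)[T.dependent]"

        self.slope_nondependent = float(params[self._tv])
        self.interaction = float(params[self._ix])
        # dependent-zone slope = TV coefficient + interaction
        contrast = pd.Series(0.0, index=params.index)
        contrast[self._tv] = 1.0
        contrast[self._ix] = 1.0
        c = contrast.loc[cov.index].to_numpy()
        var_dep = float(c @ cov.to_numpy() @ c)
        self.slope_dependent = self.slope_nondependent + self.interaction
        self.se_nondependent = float(fit.bse[self._tv])
        self.se_dependent = float(np.sqrt(var_dep))

        z = sps.norm.ppf(0.975)
        self.ci_nondependent = (self.slope_nondependent - z * self.se_nondependent,
                                self.slope_nondependent + z * self.se_nondependent)
        self.ci_dependent = (self.slope_dependent - z * self.se_dependent,
                             self.slope_dependent + z * self.se_dependent)
        self.p_value_tv = float(fit.pvalues[self._tv])

        self.left_effect = float(params.get("C(side)[T.left]", np.nan))
        self.dependent_effect = float(params.get("C(dependence)[T.dependent]", np.nan))

        # variance components, response-scale
        self.var_patient = float(np.asarray(fit.cov_re)[0, 0])
        self.var_location = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
        self.var_residual = float(fit.scale)
        self.converged = bool(getattr(fit, "converged", True))

        # back-transform to the raw response scale (slopes per standardized TV)
        sd_y = self.model.scaling["y"].sd if "y" in self.model.scaling else 1.0
        self.response_sd = sd_y
        self.slope_nondependent_raw = self.slope_nondependent * sd_y
        self.slope_dependent_raw = self.slope_dependent * sd_y
        self.ci_nondependent_raw = tuple(v * sd_y for v in self.ci_nondependent)
        self.ci_dependent_raw = tuple(v * sd_y for v in self.ci_dependent)

        self.r2_marginal, self.r2_conditional = r2_nakagawa(self)

    @property
    def fixed_effects(self) -> pd.Series:
        return self._fit.params[self._fit.model.exog_names]

    def fixed_effect_predictions(self) -> np.ndarray:
        fit = self._fit
        return np.asarray(fit.model.exog @ fit.fe_params)

    def significant(self, alpha: float = BONFERRONI_ALPHA) -> bool:
        return self.p_value_tv < alpha

    def summary(self) -> pd.DataFrame:
        """One-row report mirroring a dose-response results table."""
        return pd.DataFrame([{
            "parameter": self.model.parameter,
            "slope_nondependent": self.slope_nondependent,
            "ci_nondependent_low": self.ci_nondependent[0],
            "ci_nondependent_high": self.ci_nondependent[1],
            "slope_dependent": self.slope_dependent,
            "ci_dependent_low": self.ci_dependent[0],
            "ci_dependent_high": self.ci_dependent[1],
            "p_value_tv": self.p_value_tv,
            "left_effect": self.left_effect,
            "dependent_effect": self.dependent_effect,
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "var_patient": self.var_patient,
            "var_location": self.var_location,
            "var_residual": self.var_residual,
            "converged": self.converged,
        }])


def fit_dose_response(table: pd.DataFrame, parameter: str = "response",
                      **kwargs) -> DoseResponseResults:
    """Convenience wrapper: build a :class:`DoseResponseModel` and fit it."""
    return DoseResponseModel(table, parameter, **kwargs).fit()


def r2_nakagawa(results: DoseResponseResults) -> tuple[float, float]:
    """Marginal and conditional R² for a mixed model.

    marginal = var(fixed-effect predictions) / total, conditional adds the
    random-intercept variances to the numerator; total = fixed + patient +
    location + residual variances.
    """
    var_fixed = float(np.var(results.fixed_effect_predictions()))
    var_random = results.var_patient + results.var_location
    total = var_fixed + var_random + results.var_residual
    if total == 0:
        return 1.0, 1.0
    return var_fixed / total, (var_fixed + var_random) / total


def screen_parameters(
    fits: dict[str, DoseResponseResults],
    alpha: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """Bonferroni screen and slope ordering across the six parameters.

    Flags each parameter's tidal-volume effect at ``alpha`` (0.05/6 by
    default), orders significant parameters by decreasing absolute slope and
    reports whether each parameter's 95% CI overlaps the top one's (the
    criterion for declaring no single winner).
    """
    rows = []
    for name, res in fits.items():
        rows.append({
            "parameter": name,
            "slope": res.slope_nondependent,
            "abs_slope": abs(res.slope_nondependent),
            "ci_low": res.ci_nondependent[0],
            "ci_high": res.ci_nondependent[1],
            "p_value": res.p_value_tv,
            "significant": res.p_value_tv < alpha,
        })
    report = pd.DataFrame(rows).sort_values(
        ["significant", "abs_slope"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)

    sig = report[report["significant"]]
    if len(sig):
        top = sig.iloc[0]
        report["ci_overlaps_top"] = ~((report["ci_high"] < top["ci_low"])
                                      | (report["ci_low"] > top["ci_high"]))
    else:
        report["ci_overlaps_top"] = False
    report.attrs["alpha"] = alpha
    return report


# ---------------------------------------------------------------------------
# reliability: ICC(2,1), bootstrap BCa, Bland–Altman
# ---------------------------------------------------------------------------

def icc_2_1(matrix: np.ndarray, ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``matrix`` is subjects × raters, complete (no NaN).  Point estimate from
    the two-way ANOVA mean squares,

        ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + k·(MS_C − MS_E)/n),

    with the F-based confidence interval of the two-way random-effects
    absolute-agreement formulation.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("ICC needs a 2-D matrix with >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("ICC matrix must be complete (no missing cells)")
    n, k = m.shape

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 0.0

    # McGraw & Wong F-based CI for ICC(A,1)
    alpha = 1.0 - ci_level
    if mse <= 0:
        return float(icc), (float(icc), float(icc))
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return float(icc), (float(icc), float(icc))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    fl = sps.f.ppf(1 - alpha / 2, n - 1, v)
    fu = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - fl * mse) / (fl * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (fu * msr - mse) / (k * msc + (k * n - k - n) * mse + n * fu * msr)
    return float(icc), (float(lower), float(upper))


def icc_band(icc: float) -> str:
    """Qualitative reliability band with breakpoints 0.5 / 0.75 / 0.9."""
    for cut, label in ICC_BANDS:
        if icc < cut:
            return label
    return "excellent"


def bootstrap_bca(
    statistic,
    data: np.ndarray,
    n_boot: int = 10_000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI, resampling rows.

    ``data`` rows are the resampling units (subjects, preserving any
    within-subject structure held in the columns); ``statistic`` maps an
    (m, ...) array to a scalar.  Bias correction z0 comes from the bootstrap
    CDF at the point estimate; acceleration a from jackknife skewness.
    Deterministic given the seed.  A degenerate bootstrap distribution
    collapses to the point estimate.
    """
    data = np.asarray(data)
    n = data.shape[0]
    rng = np.random.default_rng(seed)
    theta_hat = float(statistic(data))

    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boot[b] = statistic(data[idx])

    if np.all(boot == boot[0]):
        return theta_hat, theta_hat

    prop = np.mean(boot < theta_hat) + 0.5 * np.mean(boot == theta_hat)
    prop = min(max(prop, 1.0 / (2 * n_boot)), 1 - 1.0 / (2 * n_boot))
    z0 = sps.norm.ppf(prop)

    jack = np.array([statistic(np.delete(data, i, axis=0)) for i in range(n)])
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den != 0 else 0.0

    alpha = 1.0 - ci_level
    lo, hi = [], []
    for q in (alpha / 2, 1 - alpha / 2):
        z = sps.norm.ppf(q)
        adj = sps.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
        (lo if q < 0.5 else hi).append(adj)
    lower = float(np.quantile(boot, np.clip(lo[0], 0, 1)))
    upper = float(np.quantile(boot, np.clip(hi[0], 0, 1)))
    return lower, upper


def bland_altman(pairs: np.ndarray) -> dict[str, float]:
    """Mean bias and 95% limits of agreement for paired measurements."""
    p = np.asarray(pairs, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    if p.shape[0] < 3:
        raise ValueError("Bland–Altman needs at least 3 pairs")
    diff = p[:, 0] - p[:, 1]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd,
            "sd_diff": sd}


class ReliabilityModel:
    """Reliability of one parameter from the repeated 10 mL/kg acquisitions.

    Sessions are operationalized as: *intraobserver* — the three primary
    replicates at 10 mL/kg as "raters"; *interobserver* — observer-1 vs
    observer-2 session means; *test-retest* — observer-1 first-session vs
    repeat-session means.  Subjects are patient × location sites.
    """

    def __init__(self, table: pd.DataFrame, parameter: str = "response"):
        self.table = table
        self.parameter = parameter

    def _matrix(self, kind: str) -> np.ndarray:
        t = self.table
        p = self.parameter
        at_tv = t[t["tidal_volume_ml_kg"] == 10.0]
        site = ["patient_id", "location"]
        if kind == "intraobserver":
            sub = at_tv[at_tv["session"] == "primary"]
            wide = sub.pivot_table(index=site, columns="replicate", values=p)
        elif kind == "interobserver":
            means = at_tv[at_tv["session"].isin(["primary", "interobserver"])]
            wide = means.pivot_table(index=site, columns="session", values=p,
                                     aggfunc="mean")[["primary", "interobserver"]]
        elif kind == "test-retest":
            means = at_tv[at_tv["session"].isin(["primary", "test-retest"])]
            wide = means.pivot_table(index=site, columns="session", values=p,
                                     aggfunc="mean")[["primary", "test-retest"]]
        else:
            raise ValueError(f"unknown reliability kind {kind!r}")
        return wide.dropna().to_numpy()

    def fit(self, kinds: tuple[str, ...] = ("intraobserver", "interobserver", "test-retest"),
            n_boot: int = 10_000, seed: int = 0) -> "ReliabilityResults":
        rows = {}
        for kind in kinds:
            m = self._matrix(kind)
            icc, ci = icc_2_1(m)
            bca = bootstrap_bca(lambda d: icc_2_1(d)[0], m, n_boot=n_boot, seed=seed)
            entry = {
                "icc": icc, "ci_low": ci[0], "ci_high": ci[1],
                "bca_low": bca[0], "bca_high": bca[1],
                "band": icc_band(icc), "n_subjects": m.shape[0], "n_raters": m.shape[1],
            }
            if kind in ("interobserver", "test-retest"):
                entry["bland_altman"] = bland_altman(m[:, :2])
            rows[kind] = entry
        return ReliabilityResults(parameter=self.parameter, sessions=rows)


@dataclass
class ReliabilityResults:
    parameter: str
    sessions: dict[str, dict]

    def summary(self) -> pd.DataFrame:
        rows = []
        for kind, e in self.sessions.items():
            row = {"parameter": self.parameter, "session": kind,
                   "icc": e["icc"], "ci_low": e["ci_low"], "ci_high": e["ci_high"],
                   "bca_low": e["bca_low"], "bca_high": e["bca_high"],
                   "band": e["band"], "n_subjects": e["n_subjects"]}
            ba = e.get("bland_altman")
            if ba:
                row.update({"ba_bias": ba["bias"], "ba_loa_low": ba["loa_low"],
                            "ba_loa_high": ba["loa_high"]})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feasibility accounting and design arithmetic
# ---------------------------------------------------------------------------

@dataclass
class FeasibilityLedger:
    """Sequential exclusion accounting from planned to computed cineloops."""

    planned: int
    stages: list[tuple[str, int]]
    remaining: list[int] = field(default_factory=list)

    @property
    def computed(self) -> int:
        return self.remaining[-1] if self.remaining else self.planned

    @property
    def feasibility_pct(self) -> float:
        return round(100.0 * self.computed / self.planned, 1)

    def stage_pct(self, names: list[str] | None = None) -> float:
        """Percentage of planned cineloops excluded by the named stages."""
        total = sum(c for n, c in self.stages if names is None or n in names)
        return round(100.0 * total / self.planned, 1)

    def summary(self) -> pd.DataFrame:
        rows = [{"stage": "planned", "excluded": 0, "remaining": self.planned,
                 "pct_of_planned": 100.0}]
        for (name, count), rem in zip(self.stages, self.remaining):
            rows.append({"stage": name, "excluded": count, "remaining": rem,
                         "pct_of_planned": round(100.0 * rem / self.planned, 1)})
        return pd.DataFrame(rows)


def feasibility_ledger(planned: int, exclusions: list[tuple[str, int]]) -> FeasibilityLedger:
    """Subtract ordered exclusion stages from the planned cineloop count.

    Rejects accounting that drives the remainder negative.
    """
    if planned <= 0:
        raise ValueError("planned count must be positive")
    remaining = []
    current = planned
    for name, count in exclusions:
        if count < 0:
            raise ValueError(f"negative exclusion count at stage {name!r}")
        current -= count
        if current < 0:
            raise ValueError(f"exclusions exceed planned count at stage {name!r}")
        remaining.append(current)
    return FeasibilityLedger(planned=planned, stages=list(exclusions), remaining=remaining)


def proportion_ci_halfwidth(p: float, n: int, level: float = 0.95) -> float:
    """Normal-approximation margin of error for a proportion, in percentage
    points: z · sqrt(p(1−p)/n).  Degenerate proportions return 0."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be at least 1")
    if p in (0.0, 1.0):
        return 0.0
    z = sps.norm.ppf(0.5 + level / 2)
    return float(100.0 * z * np.sqrt(p * (1 - p) / n))
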