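"""Cohort biomarker statistics: Z-scores, normalization, ANOVA and regression.

This module reproduces the analysis battery applied to the biomarker
table: per-group summaries with one-way ANOVA and post-hoc Fisher LSD
tests (plus a chi-square test for the sex ratio), Pearson regressions of
each biomarker against the ALPS index, and the normalized-slope comparison
that puts ALPS, atrophy and cognition on a common 0-100 disease-severity
scale against amyloid burden:

    nDTI-ALPS = (ALPS_MAX - ALPS) / (ALPS_MAX - 1) * 100
    nMMSE     = (30 - MMSE) / 30 * 100
    nVSRAD    = (VSRAD - VSRAD_MIN) / VSRAD_MAX * 100

with MAX/MIN taken over all subjects.  The nVSRAD denominator is
``VSRAD_MAX`` as printed in the source formulation (so nVSRAD reaches 100
at the maximum only when VSRAD_MIN = 0); pass
``vsrad_range_denominator=True`` for the conventional range form.

The high-level entry point is statsmodels-style::

    results = CohortModel(table).fit()
    print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "GroupComparison",
    "NormalizationConstants",
    "vsrad_z",
    "normalize_biomarkers",
    "group_compare",
    "group_compare_categorical",
    "pearson_regression",
    "normalized_slope_analysis",
    "CohortModel",
    "CohortResults",
]


def vsrad_z(individual_gm: float, control_mean: float, control_sd: float) -> float:
    """Atrophy Z-score: (control mean - individual value) / control SD.

    Positive Z means less gray matter than the control average.
    """
    if control_sd <= 0:
        raise ValueError("control SD must be positive")
    return (control_mean - individual_gm) / control_sd


# ---------------------------------------------------------------------------
# Pearson regression

@dataclass(frozen=True)
class RegressionResult:
    """OLS line fit with the Pearson correlation and its two-sided p-value.

    ``p`` comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of
    freedom.  Carries what is needed to draw pointwise confidence bands
    for the mean response.
    """

    slope: float
    intercept: float
    r: float
    p: float
    n: int
    mean_x: float
    ssx: float              # sum of squared deviations of x
    mse_resid: float        # residual mean square, df = n - 2

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x, alpha: float = 0.05):
        """Pointwise (1-alpha) band for the mean response at ``x``."""
        x = np.asarray(x, dtype=float)
        se = np.sqrt(self.mse_resid * (1.0 / self.n + (x - self.mean_x) ** 2 / self.ssx))
        t = sps.t.ppf(1.0 - alpha / 2.0, self.n - 2)
        yhat = self.predict(x)
        return yhat - t * se, yhat + t * se


def pearson_regression(x, y) -> RegressionResult:
    """Least-squares line y on x with Pearson r and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression inputs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    lr = sps.linregress(x, y)
    resid = y - (lr.intercept + lr.slope * x)
    ssx = float(((x - x.mean()) ** 2).sum())
    mse = float((resid**2).sum() / (n - 2))
    return RegressionResult(
        slope=float(lr.slope), intercept=float(lr.intercept),
        r=float(lr.rvalue), p=float(lr.pvalue), n=n,
        mean_x=float(x.mean()), ssx=ssx, mse_resid=mse,
    )


# ---------------------------------------------------------------------------
# Group comparison

@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA across groups with Fisher LSD post-hoc p-values.

    Fisher's LSD performs unadjusted pairwise t-tests using the pooled
    ANOVA mean-square error — no multiplicity correction, by definition.
    """

    column: str
    groups: tuple[str, ...]
    ns: dict[str, int]
    means: dict[str, float]
    sds: dict[str, float]
    f: float
    p: float
    lsd_p: dict[tuple[str, str], float]

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def group_compare(table: pd.DataFrame, column: str,
                  group_col: str = "group") -> GroupComparison:
    """One-way ANOVA on ``column`` across the groups in ``group_col``."""
    clean = table[[group_col, column]].dropna()
    names = tuple(dict.fromkeys(clean[group_col]))
    samples = [clean.loc[clean[group_col] == g, column].to_numpy(float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs n >= 2")

    grand = np.concatenate(samples)
    ss_between = sum(len(s) * (s.mean() - grand.mean()) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(names) - 1
    df_w = grand.size - len(names)
    if ss_within == 0:
        # identical values within groups: equal means -> no effect (p = 1)
        if ss_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))

    mse = ss_within / df_w if df_w > 0 else np.nan
    lsd: dict[tuple[str, str], float] = {}
    for (ga, sa), (gb, sb) in combinations(zip(names, samples), 2):
        if mse == 0:
            lsd[(ga, gb)] = 1.0 if sa.mean() == sb.mean() else 0.0
            continue
        se = np.sqrt(mse * (1.0 / len(sa) + 1.0 / len(sb)))
        t = (sa.mean() - sb.mean()) / se
        lsd[(ga, gb)] = float(2.0 * sps.t.sf(abs(t), df_w))

    return GroupComparison(
        column=column, groups=names,
        ns={g: len(s) for g, s in zip(names, samples)},
        means={g: float(s.mean()) for g, s in zip(names, samples)},
        sds={g: float(s.std(ddof=1)) for g, s in zip(names, samples)},
        f=float(f_stat), p=float(p), lsd_p=lsd,
    )


def group_compare_categorical(table: pd.DataFrame, column: str,
                              group_col: str = "group") -> dict[str, float]:
    """Chi-square contingency test of a categorical column (e.g. sex ratio)."""
    contingency = pd.crosstab(table[group_col], table[column])
    chi2, p, dof, _ = sps.chi2_contingency(contingency)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}


# ---------------------------------------------------------------------------
# Normalization onto the common 0-100 severity scale

@dataclass(frozen=True)
class NormalizationConstants:
    """Cohort-level constants entering the normalization equations."""

    alps_max: float
    vsrad_min: float
    vsrad_max: float


def normalize_biomarkers(table: pd.DataFrame, alps_col: str = "alps_b1000",
                         vsrad_range_denominator: bool = False,
                         ) -> tuple[pd.DataFrame, NormalizationConstants]:
    """Add nDTI_ALPS / nMMSE / nVSRAD columns on the 0-100 severity scale.

    Constants (ALPS_MAX, VSRAD_MIN, VSRAD_MAX) are computed over *all*
    subjects of the table.  Higher normalized values always mean more
    severe disease: lower ALPS, lower MMSE, higher VSRAD.
    """
    alps_max = float(table[alps_col].max())
    if alps_max <= 1.0:
        raise ValueError(
            f"ALPS_MAX = {alps_max:.3f} <= 1: nDTI-ALPS normalization undefined"
        )
    vsrad_min = float(table["vsrad_z"].min())
    vsrad_max = float(table["vsrad_z"].max())
    if vsrad_max == 0:
        raise ValueError("VSRAD_MAX = 0: nVSRAD normalization undefined")
    out = table.copy()
    out["nDTI_ALPS"] = (alps_max - table[alps_col]) / (alps_max - 1.0) * 100.0
    out["nMMSE"] = (30.0 - table["mmse"]) / 30.0 * 100.0
    denom = (vsrad_max - vsrad_min) if vsrad_range_denominator else vsrad_max
    if denom == 0:
        raise ValueError("degenerate VSRAD range")
    out["nVSRAD"] = (table["vsrad_z"] - vsrad_min) / denom * 100.0
    return out, NormalizationConstants(alps_max, vsrad_min, vsrad_max)


def normalized_slope_analysis(table: pd.DataFrame, alps_col: str = "alps_b1000",
                              vsrad_range_denominator: bool = False,
                              ) -> tuple[dict[str, RegressionResult], NormalizationConstants]:
    """Regress each normalized biomarker on centiloid for slope comparison.

    Returns ``{"nDTI_ALPS": ..., "nVSRAD": ..., "nMMSE": ...}`` plus the
    constants used.  Because normalization is affine, each |r| equals the
    raw biomarker's |r| against centiloid; the slopes become directly
    comparable across biomarkers.
    """
    norm, consts = normalize_biomarkers(table, alps_col, vsrad_range_denominator)
    out = {col: pearson_regression(norm["centiloid"], norm[col])
           for col in ("nDTI_ALPS", "nVSRAD", "nMMSE")}
    return out, consts


# ---------------------------------------------------------------------------
# High-level model object

_TABLE1_ROWS = ("age", "mmse", "vsrad_z", "centiloid", "alps_b1000", "alps_b2000")
_TABLE2_PREDICTORS = ("mmse", "centiloid", "vsrad_z")


@dataclass
class CohortResults:
    """Fitted cohort analyses; produced by :meth:`CohortModel.fit`."""

    model: "CohortModel"
    group_summary: pd.DataFrame
    sex_test: dict[str, float] | None
    regressions: pd.DataFrame
    regression_fits: dict[tuple[str, str], RegressionResult]
    normalized: pd.DataFrame | None
    normalized_fits: dict[str, RegressionResult] | None
    constants: NormalizationConstants | None

    def summary(self) -> str:
        lines = ["Cohort biomarker analysis", "=" * 60,
                 "", "Group comparison (mean ± SD, one-way ANOVA p):",
                 self.group_summary.to_string()]
        if self.sex_test is not None:
            lines.append(
                f"sex ratio: chi2 = {self.sex_test['chi2']:.3f}, "
                f"p = {self.sex_test['p']:.3f}")
        lines += ["", "Pearson regressions (response / predictor):",
                  self.regressions.to_string()]
        if self.normalized is not None:
            lines += ["", "Normalized slopes vs centiloid "
                      f"(ALPS_MAX = {self.constants.alps_max:.3f}, "
                      f"VSRAD_MIN = {self.constants.vsrad_min:.3f}, "
                      f"VSRAD_MAX = {self.constants.vsrad_max:.3f}):",
                      self.normalized.to_string()]
        return "\n".join(lines)


class CohortModel:
    """Statistical model of a two-group biomarker cohort table.

    Parameters
    ----------
    table : DataFrame
        One row per subject with columns ``group``, ``mmse``, ``vsrad_z``,
        ``centiloid`` and one or more ``alps_b*`` columns.
    vsrad_range_denominator : bool
        Use (VSRAD_MAX - VSRAD_MIN) instead of VSRAD_MAX in nVSRAD.
    """

    def __init__(self, table: pd.DataFrame, *, alps_col: str = "alps_b1000",
                 vsrad_range_denominator: bool = False):
        required = {"group", alps_col}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"cohort table lacks columns {sorted(missing)}")
        self.table = table.reset_index(drop=True)
        self.alps_col = alps_col
        self.vsrad_range_denominator = vsrad_range_denominator

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "CohortModel":
        return cls(pd.read_csv(path, sep="\t"), **kwargs)

    def fit(self) -> CohortResults:
        """Run the group comparisons, regressions and normalized analysis."""
        t = self.table
        rows = []
        for col in _TABLE1_ROWS:
            if col not in t.columns:
                continue
            gc = group_compare(t, col)
            row = {"variable": col, "F": gc.f, "p": gc.p}
            for g in gc.groups:
                row[f"{g}_mean"] = gc.means[g]
                row[f"{g}_sd"] = gc.sds[g]
            for pair, p in gc.lsd_p.items():
                row[f"lsd_p_{pair[0]}_vs_{pair[1]}"] = p
            rows.append(row)
        group_summary = pd.DataFrame(rows).set_index("variable")

        sex_test = (group_compare_categorical(t, "sex")
                    if "sex" in t.columns else None)

        # ALPS-vs-biomarker regressions in the orientation each is reported:
        # ALPS is the response for MMSE and centiloid, the predictor for the
        # atrophy score.
        reg_fits: dict[tuple[str, str], RegressionResult] = {}
        reg_rows = []
        alps_cols = [c for c in t.columns if c.startswith("alps_b")]
        for alps_col in alps_cols:
            for pred in _TABLE2_PREDICTORS:
                if pred not in t.columns:
                    continue
                if pred == "vsrad_z":
                    res = pearson_regression(t[alps_col], t[pred])
                    response, regressor = pred, alps_col
                else:
                    res = pearson_regression(t[pred], t[alps_col])
                    response, regressor = alps_col, pred
                reg_fits[(alps_col, pred)] = res
                reg_rows.append({
                    "response": response, "predictor": regressor,
                    "slope": res.slope, "intercept": res.intercept,
                    "r": res.r, "p": res.p, "n": res.n,
                })
        regressions = pd.DataFrame(reg_rows)

        normalized = norm_fits = consts = None
        if {"mmse", "vsrad_z", "centiloid"} <= set(t.columns):
            norm_fits, consts = normalized_slope_analysis(
                t, self.alps_col, self.vsrad_range_denominator)
            normalized = pd.DataFrame([
                {"biomarker": k, "slope": v.slope, "intercept": v.intercept,
                 "r": v.r, "p": v.p}
                for k, v in norm_fits.items()
            ]).set_index("biomarker")

        return CohortResults(
            model=self, group_summary=group_summary, sex_test=sex_test,
            regressions=regressions, regression_fits=reg_fits,
            normalized=normalized, normalized_fits=norm_fits, constants=consts,
        )
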