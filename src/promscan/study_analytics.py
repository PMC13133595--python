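"""Study-level uptake analytics.

Aggregates outcome-level detections to a per-study flag and runs the
descriptive and inferential analyses: yearly trends with a
Cochran-Armitage-style score test, bivariate chi-squares, stratified
multivariate logistic regression with Wald CIs on the odds-ratio scale,
and a regression-based missing-completely-at-random check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

MISSING = "missing"


class AnalyticsError(ValueError):
    pass


class SeparationError(AnalyticsError):
    """Perfect separation / non-identifiable predictor in the regression."""


@dataclass(frozen=True)
class ORResult:
    stratum: str
    predictor: str
    level: str
    reference_level: str
    odds_ratio: float
    ci95: tuple[float, float]
    wald_p: float | None  # None on the reference row

    @property
    def is_reference(self) -> bool:
        return self.level == self.reference_level


def aggregate_study_flags(
    detections: Mapping[tuple[str, int], bool] | Sequence[tuple[tuple[str, int], bool]],
) -> dict[str, bool]:
    """Study flag = OR over its outcomes' detection flags."""
    pairs = detections.items() if isinstance(detections, Mapping) else detections
    flags: dict[str, bool] = {}
    seen = False
    for (study_id, _idx), flag in pairs:
        seen = True
        flags[study_id] = flags.get(study_id, False) or bool(flag)
    if not seen:
        return {}
    return flags


def build_table(
    studies,
    study_flags: Mapping[str, bool],
    site_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One row per study: flag, start year and design covariates."""
    site_labels = site_labels or {}
    rows = []
    for s in studies:
        if s.study_id not in study_flags:
            raise AnalyticsError(f"study {s.study_id} has no detection flag "
                                 "(zero outcomes should be filtered upstream)")
        rows.append(
            {
                "study_id": s.study_id,
                "uses_prompem": int(study_flags[s.study_id]),
                "year": s.start_date.year if s.start_date else None,
                "study_type": s.study_type.value,
                "phase": s.phase.value,
                "allocation": s.allocation.value,
                "intervention_model": s.intervention_model.value,
                "primary_purpose": s.primary_purpose.value,
                "observational_model": s.observational_model.value,
                "time_perspective": s.time_perspective.value,
                "site_label": site_labels.get(s.study_id, MISSING),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trends

def yearly_trend(table: pd.DataFrame) -> dict:
    """Per-year prevalence plus a score test for linear trend in year.

    Returns ``{"series": DataFrame(year, n, proportion), "statistic", "p_value"}``;
    the test entries are None when fewer than two years are present.
    """
    if table.empty:
        return {"series": pd.DataFrame(columns=["year", "n", "proportion"]),
                "statistic": None, "p_value": None}
    grouped = (
        table.dropna(subset=["year"])
        .groupby("year")["uses_prompem"]
        .agg(n="count", positives="sum")
        .reset_index()
    )
    grouped["proportion"] = grouped["positives"] / grouped["n"]
    series = grouped[["year", "n", "proportion"]]
    if len(grouped) < 2:
        return {"series": series, "statistic": None, "p_value": None}

    # Cochran-Armitage score test with the year as a linear score
    s = grouped["year"].to_numpy(dtype=float)
    nj = grouped["n"].to_numpy(dtype=float)
    rj = grouped["positives"].to_numpy(dtype=float)
    n_total, r_total = nj.sum(), rj.sum()
    pbar = r_total / n_total
    if pbar in (0.0, 1.0):
        return {"series": series, "statistic": None, "p_value": None}
    t = float(np.sum(rj * s) - pbar * np.sum(nj * s))
    var = pbar * (1 - pbar) * (np.sum(nj * s**2) - np.sum(nj * s) ** 2 / n_total)
    z = t / np.sqrt(var)
    return {
        "series": series,
        "statistic": float(z),
        "p_value": float(2 * stats.norm.sf(abs(z))),
    }


# ---------------------------------------------------------------------------
# bivariate tests

def bivariate_chisq(table: pd.DataFrame, covariate: str) -> dict[str, float]:
    """Pearson chi-square of covariate x flag, excluding the missing level."""
    sub = table[table[covariate] != MISSING]
    levels = sub[covariate].nunique()
    if levels < 2:
        raise AnalyticsError(
            f"covariate {covariate!r} has {levels} non-missing level(s); need >= 2"
        )
    contingency = pd.crosstab(sub[covariate], sub["uses_prompem"])
    stat, p, _, expected = stats.chi2_contingency(contingency, correction=False)
    if (expected == 0).any():
        raise AnalyticsError("zero expected count in the contingency table")
    return {"statistic": float(stat), "p_value": float(p)}


# ---------------------------------------------------------------------------
# logistic regression

def fit_use_model(
    table: pd.DataFrame,
    stratum: str,
    predictors: Sequence[str],
    reference_levels: Mapping[str, str] | None = None,
) -> tuple[list[ORResult], dict]:
    """Multivariate logistic regression of the study flag on predictors.

    Complete-case within the stratum: rows missing any predictor are
    dropped (count reported in the info dict).  Returns exponentiated
    coefficients with 95% Wald CIs and Wald p-values, plus an OR=1 row per
    reference level.
    """
    reference_levels = dict(reference_levels or {})
    sub = table[table["study_type"] == stratum].copy()
    if sub.empty:
        raise AnalyticsError(f"empty stratum: {stratum!r}")
    mask = np.ones(len(sub), dtype=bool)
    for p in predictors:
        mask &= (sub[p] != MISSING) & sub[p].notna()
    n_dropped = int((~mask).sum())
    sub = sub[mask]
    if sub.empty:
        raise AnalyticsError("no complete-case rows left after dropping missing values")

    design_cols = []
    col_meta: list[tuple[str, str, str]] = []  # (column, predictor, level)
    for p in predictors:
        levels = sorted(sub[p].unique())
        if len(levels) < 2:
            raise SeparationError(
                f"predictor {p!r} is constant within stratum {stratum!r}"
            )
        ref = reference_levels.setdefault(p, levels[0])
        if ref not in levels:
            raise AnalyticsError(f"reference level {ref!r} absent for predictor {p!r}")
        for lvl in levels:
            if lvl == ref:
                continue
            design_cols.append((sub[p] == lvl).astype(float).rename(f"{p}[{lvl}]"))
            col_meta.append((f"{p}[{lvl}]", p, lvl))
    x = pd.concat(design_cols, axis=1)
    x = sm.add_constant(x)
    y = sub["uses_prompem"].astype(float)
    if y.nunique() < 2:
        raise SeparationError("outcome flag is constant within the stratum")

    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected explicitly below; silence the advisory
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # includes perfect-separation failures
        culprits = [
            p for p in predictors
            if (sub.groupby(p)["uses_prompem"].nunique() == 1).any()
        ]
        named = ", ".join(repr(p) for p in culprits) or "unknown predictor"
        raise SeparationError(
            f"logistic fit failed (suspected separation in {named}): {exc}"
        ) from exc
    params = fit.params
    if not np.all(np.isfinite(fit.bse)) or np.abs(params.drop("const")).max() > 15:
        worst = params.drop("const").abs().idxmax()
        pred = next(p for c, p, _ in col_meta if c == worst)
        raise SeparationError(f"separation suspected for predictor {pred!r}")

    conf = fit.conf_int()
    results: list[ORResult] = []
    for p in predictors:
        ref = reference_levels[p]
        results.append(
            ORResult(stratum, p, ref, ref, 1.0, (1.0, 1.0), None)
        )
        for col, pred, lvl in col_meta:
            if pred != p:
                continue
            results.append(
                ORResult(
                    stratum=stratum,
                    predictor=p,
                    level=lvl,
                    reference_level=ref,
                    odds_ratio=float(np.exp(params[col])),
                    ci95=(float(np.exp(conf.loc[col, 0])), float(np.exp(conf.loc[col, 1]))),
                    wald_p=float(fit.pvalues[col]),
                )
            )
    info = {"n_used": int(len(sub)), "n_dropped_missing": n_dropped,
            "converged": bool(fit.mle_retvals.get("converged", True)),
            "coefficients": {c: float(params[c]) for c in params.index}}
    return results, info


# ---------------------------------------------------------------------------
# missingness

def missingness_check(
    table: pd.DataFrame,
    variable: str,
    covariates: Sequence[str] = ("year",),
) -> dict:
    """Regression-based MCAR-style check.

    Logistic regression of the variable's missingness indicator on fully
    observed covariates; the verdict is "consistent with MCAR" iff the
    joint Wald p-value for the covariate slopes is >= .05.
    """
    indicator = ((table[variable] == MISSING) | table[variable].isna()).astype(float)
    if indicator.sum() == 0:
        return {"test_p": None, "verdict": "nothing to test"}
    if indicator.mean() == 1.0:
        return {"test_p": None, "verdict": "nothing to test"}

    cols = []
    for c in covariates:
        col = table[c]
        if np.issubdtype(col.dtype, np.number):
            cols.append(col.astype(float).rename(c))
        else:
            levels = sorted(col.unique())
            for lvl in levels[1:]:
                cols.append((col == lvl).astype(float).rename(f"{c}[{lvl}]"))
    x = sm.add_constant(pd.concat(cols, axis=1))
    with np.errstate(all="ignore"):
        fit = sm.Logit(indicator, x).fit(disp=0, maxiter=200)
    slope_names = [c for c in x.columns if c != "const"]
    constraint = np.zeros((len(slope_names), len(x.columns)))
    for i, name in enumerate(slope_names):
        constraint[i, list(x.columns).index(name)] = 1.0
    wald = fit.wald_test(constraint, scalar=True)
    p = float(wald.pvalue)
    verdict = "consistent with MCAR" if p >= 0.05 else "not consistent with MCAR"
    return {"test_p": p, "verdict": verdict}


def format_p(p: float | None) -> str:
    """Display convention: '<.001' below threshold, two decimals otherwise."""
    if p is None:
        return "NA"
    if p < 0.001:
        return "<.001"
    return f"{p:.2f}".lstrip("0") or ".00"
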