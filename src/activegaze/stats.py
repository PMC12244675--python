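"""Statistical reporting layer.

A thin wrapper over standard estimators with this study design's exact
modelling choices baked in:

* random-intercept linear mixed models (subject as random effect) fitted
  by REML, fixed-effect p-values from the normal approximation to the
  Wald statistic;
* skewed trial metrics (response time, counts, distance) are
  log-transformed before fitting;
* the intra-class correlation (ICC) of the subject factor is
  var(random intercept) / (var(random intercept) + var(residual));
* two-way ANOVA (visibility x set size, target-present trials only) with
  partial eta squared and Tukey HSD post-hocs;
* accuracy, being binary per trial, goes through a repeated-measures
  two-way ANOVA on per-subject cell means instead of regression;
* orientation effects use deviation (sum-to-zero) coding, so each
  category's coefficient is its deviation from the grand mean and the
  reference category's deviation is minus their sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.formula.api import mixedlm, ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._util import sd_outlier_mask

__all__ = [
    "LmmResult",
    "AnovaResult",
    "LEARNING_DEPENDENTS",
    "fit_lmm",
    "fit_learning_models",
    "fit_condition_models",
    "fit_orientation_models",
    "elevation_regression",
    "simulate_learning_data",
]

#: trial-metric columns analysed for learning effects, with their transforms
LEARNING_DEPENDENTS = {
    "response_time": "log",
    "n_fixations": "log",
    "n_lookat_fixations": "log1p",
    "distance": "log",
}


@dataclass
class LmmResult:
    """One random-intercept mixed-model fit."""

    dependent: str
    intercept: float
    slopes: dict[str, tuple[float, float]]      # term -> (estimate, p)
    icc: float
    transform: str = "none"
    subset: str = "all"
    converged: bool = True
    n_obs: int = 0
    intercept_p: float = float("nan")
    stderrs: dict[str, float] = field(default_factory=dict)

    def slope(self, term: str) -> float:
        return self.slopes[term][0]

    def p(self, term: str) -> float:
        return self.slopes[term][1]

    def conf_int(self, term: str, level: float = 0.95) -> tuple[float, float]:
        """Wald (normal-approximation) confidence interval for a term."""
        est = self.slopes[term][0]
        se = self.stderrs[term]
        z = sps.norm.ppf(0.5 + level / 2.0)
        return est - z * se, est + z * se


@dataclass
class AnovaResult:
    """Factorial ANOVA effects plus Tukey HSD pairwise contrasts."""

    dependent: str
    effects: dict[str, tuple[float, float, float, float, float]]
    # term -> (F, df1, df2, p, partial_eta_sq)
    posthoc: list[dict] = field(default_factory=list)


def _apply_transform(y: pd.Series, transform: str) -> pd.Series:
    if transform == "log":
        if (y <= 0).any():
            raise ValueError("log transform requires positive values")
        return np.log(y)
    if transform == "log1p":
        return np.log1p(y)
    if transform == "none":
        return y
    raise ValueError(f"unknown transform {transform!r}")


def fit_lmm(
    data: pd.DataFrame,
    dependent: str,
    fixed: str,
    group: str = "subject",
    transform: str = "none",
    subset: str = "all",
) -> LmmResult:
    """Fit ``transform(dependent) ~ fixed`` with a subject random intercept.

    Singular or non-converging fits are returned flagged, not raised.
    """
    df = data.copy()
    df["_y"] = _apply_transform(df[dependent].astype(float), transform)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = mixedlm(f"_y ~ {fixed}", df, groups=df[group])
        try:
            res = model.fit(reml=True)
            converged = bool(res.converged)
        except (np.linalg.LinAlgError, ValueError):
            return LmmResult(
                dependent=dependent, intercept=float("nan"), slopes={},
                icc=float("nan"), transform=transform, subset=subset,
                converged=False, n_obs=len(df),
            )
    params = res.params
    pvalues = res.pvalues
    var_re = float(np.asarray(res.cov_re)[0, 0])
    icc = var_re / (var_re + float(res.scale)) if var_re + res.scale > 0 else float("nan")
    slopes = {
        name: (float(params[name]), float(pvalues[name]))
        for name in params.index
        if name not in ("Intercept", "Group Var")
    }
    stderrs = {
        name: float(res.bse[name])
        for name in params.index
        if name != "Group Var"
    }
    return LmmResult(
        dependent=dependent,
        intercept=float(params.get("Intercept", np.nan)),
        slopes=slopes,
        icc=float(icc),
        transform=transform,
        subset=subset,
        converged=converged,
        n_obs=len(df),
        intercept_p=float(pvalues.get("Intercept", np.nan)),
        stderrs=stderrs,
    )


# ---------------------------------------------------------------------------
# learning (trial-number) models

def _subsets(metrics: pd.DataFrame) -> dict[str, pd.DataFrame]:
    present = metrics[metrics["target_present"] == True]  # noqa: E712
    absent = metrics[metrics["target_present"] == False]  # noqa: E712
    out = {"present": present, "absent": absent}
    if "visible_from_start" in metrics.columns:
        out["present_visible"] = present[present["visible_from_start"] == True]  # noqa: E712
        out["present_not_visible"] = present[present["visible_from_start"] == False]  # noqa: E712
    return out


def fit_learning_models(
    metrics: pd.DataFrame,
    dependents: dict[str, str] = LEARNING_DEPENDENTS,
    subsets: tuple[str, ...] = ("present", "absent", "present_visible", "present_not_visible"),
) -> list[LmmResult]:
    """Trial-number slopes per efficiency metric and trial subset.

    A negative slope on the (log) metric means the searcher got faster /
    leaner with experience.
    """
    if metrics["subject"].nunique() < 2 or metrics.groupby("subject")["trial"].count().min() < 2:
        raise ValueError("need >= 2 subjects with >= 2 trials each")
    pools = _subsets(metrics)
    results = []
    for name in subsets:
        pool = pools.get(name)
        if pool is None or pool.empty:
            continue
        for dv, transform in dependents.items():
            results.append(
                fit_lmm(pool, dv, "trial", transform=transform, subset=name)
            )
    return results


# ---------------------------------------------------------------------------
# condition models

def fit_condition_models(
    metrics: pd.DataFrame,
    dependents: tuple[str, ...] = ("response_time", "n_fixations", "distance", "revisits"),
) -> tuple[list[LmmResult], list[AnovaResult], AnovaResult]:
    """Presence/set-size mixed models, the visibility x set-size ANOVA and
    the repeated-measures accuracy ANOVA.

    Returns (mixed-model results, per-metric two-way ANOVAs on
    target-present trials, accuracy rm-ANOVA).
    """
    for col in ("target_present", "set_size"):
        if metrics[col].isna().any():
            raise ValueError(f"column {col} contains missing cells")
    lmms = []
    for dv in dependents:
        transform = LEARNING_DEPENDENTS.get(dv, "log1p")
        lmms.append(
            fit_lmm(metrics, dv, "C(target_present) + set_size", transform=transform,
                    subset="all")
        )

    present = metrics[metrics["target_present"] == True].copy()  # noqa: E712
    anovas = [
        _two_way_anova(present, dv, "visible_from_start", "set_size")
        for dv in dependents
    ]

    acc = (
        metrics.assign(correct=metrics["correct"].astype(float))
        .groupby(["subject", "target_present", "set_size"], as_index=False)["correct"]
        .mean()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rm = pg.rm_anova(
            data=acc, dv="correct", within=["target_present", "set_size"],
            subject="subject", detailed=True,
        )
    effects = {}
    for _, row in rm.iterrows():
        term = str(row["Source"])
        if term.lower() in ("residual", "error"):
            continue
        p_unc = row["p_unc"] if "p_unc" in row else row["p-unc"]
        eta = row.get("ng2", row.get("np2", np.nan))
        effects[term] = (
            float(row["F"]), float(row["ddof1"]), float(row["ddof2"]),
            float(p_unc), float(eta),
        )
    accuracy = AnovaResult(dependent="correct", effects=effects)
    return lmms, anovas, accuracy


def _two_way_anova(data: pd.DataFrame, dv: str, factor_a: str, factor_b: str) -> AnovaResult:
    df = data[[dv, factor_a, factor_b]].dropna().copy()
    df.columns = ["y", "A", "B"]
    if df.groupby(["A", "B"]).size().min() < 2:
        raise ValueError("every factor cell needs >= 2 observations")
    model = ols("y ~ C(A) * C(B)", df).fit()
    table = anova_lm(model, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    df_resid = float(table.loc["Residual", "df"])
    names = {"C(A)": factor_a, "C(B)": factor_b, "C(A):C(B)": f"{factor_a}:{factor_b}"}
    effects = {}
    for raw, pretty in names.items():
        ss = float(table.loc[raw, "sum_sq"])
        effects[pretty] = (
            float(table.loc[raw, "F"]),
            float(table.loc[raw, "df"]),
            df_resid,
            float(table.loc[raw, "PR(>F)"]),
            ss / (ss + ss_resid),
        )
    cell = df["A"].astype(str) + "/" + df["B"].astype(str)
    tukey = pairwise_tukeyhsd(df["y"].to_numpy(), cell.to_numpy())
    posthoc = [
        {
            "group1": str(r[0]), "group2": str(r[1]),
            "meandiff": float(r[2]), "p_adj": float(r[3]),
            "reject": bool(r[6]),
        }
        for r in tukey.summary().data[1:]
    ]
    return AnovaResult(dependent=dv, effects=effects, posthoc=posthoc)


# ---------------------------------------------------------------------------
# orientation-conditioned head-pose models

def fit_orientation_models(
    target_fixations: pd.DataFrame,
    dependents: tuple[str, ...] = ("roll", "pitch", "rel_elevation"),
    outlier_k: float = 3.0,
) -> list[LmmResult]:
    """Deviation-coded orientation effects on head pose at target fixations.

    Expects one row per target fixation with columns ``subject``,
    ``orientation`` and the dependents.  Angles are cleaned per subject
    with the k-SD rule before fitting.  Each returned slope maps an
    orientation category to its deviation from the grand mean; the
    reference category (absorbed by the intercept) is reported as
    ``<category> (reference)`` with deviation equal to minus the sum of
    the others.
    """
    cats = sorted(target_fixations["orientation"].dropna().unique())
    if len(cats) < 2:
        raise ValueError("need >= 2 orientation categories")
    results = []
    for dv in dependents:
        df = target_fixations[["subject", "orientation", dv]].dropna().copy()
        keep = np.ones(len(df), dtype=bool)
        for _, idx in df.groupby("subject").groups.items():
            vals = df.loc[idx, dv].to_numpy(dtype=float)
            keep[df.index.get_indexer(idx)] = sd_outlier_mask(vals, outlier_k)
        df = df[keep]
        res = fit_lmm(df, dv, "C(orientation, Sum)", transform="none", subset="target_fixations")
        # rename patsy's S.<level> terms and add the reference category
        renamed = {}
        total = 0.0
        for term, (est, p) in res.slopes.items():
            if "C(orientation, Sum)" in term:
                level = term.split("S.")[-1].rstrip("]")
                renamed[level] = (est, p)
                total += est
            else:
                renamed[term] = (est, p)
        ref = [c for c in cats if c not in renamed]
        if len(ref) == 1:
            renamed[f"{ref[0]} (reference)"] = (-total, float("nan"))
        res.slopes = renamed
        results.append(res)
    return results


def elevation_regression(
    target_fixations: pd.DataFrame,
    y: str = "rel_elevation",
    x: str = "surface_elevation",
) -> tuple[float, float, float, float]:
    """OLS of head elevation on target surface elevation.

    Returns (slope, intercept, Pearson r, two-sided p).  Tests whether
    searchers bring their head toward the height of the shelf the target
    sits on (crouching for table-height targets).
    """
    df = target_fixations[[x, y]].dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 points")
    if df[x].nunique() < 2:
        raise ValueError("zero variance in x")
    res = sps.linregress(df[x].to_numpy(dtype=float), df[y].to_numpy(dtype=float))
    return (
        float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# simulation helper (calibration / power checks)

def simulate_learning_data(
    n_subjects: int,
    n_trials: int,
    intercept: float,
    slope: float,
    subject_sd: float,
    resid_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw from the random-intercept model itself (already on the model
    scale): y_ij = intercept + slope * trial_j + b_i + e_ij."""
    rng = np.random.default_rng([seed])
    b = rng.normal(0.0, subject_sd, n_subjects)
    rows = []
    for s in range(n_subjects):
        e = rng.normal(0.0, resid_sd, n_trials)
        for j in range(n_trials):
            rows.append(
                {"subject": s + 1, "trial": j + 1,
                 "y": intercept + slope * (j + 1) + b[s] + e[j]}
            )
    return pd.DataFrame(rows)
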