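"""Prognostic screening, modular risk signatures and survival metrics.

The screen applies three sequential filters to every module lncRNA:

1. median-split of tumour expression, two-group log-rank test (p < a1);
2. multivariable Cox proportional-hazards fit of the high/low indicator
   adjusted for age and ordinal stage (p < a2);
3. stage dependency (Kruskal-Wallis across stages I-IV, p < a3) AND
   tumour-vs-normal differential expression (Wilcoxon rank-sum, p < a4).

A module's risk score sums coefficient-weighted member expression, the
coefficient being each surviving lncRNA's continuous-expression Cox
coefficient adjusted for age and stage.  Signatures are evaluated by
median-split Kaplan-Meier + log-rank (OS and PFS), an adjusted Cox hazard
ratio, and cumulative/dynamic time-dependent AUC with inverse probability
of censoring weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from scipy import stats

from .errors import (
    DegenerateSplitError,
    FitError,
    InputError,
    InsufficientDataError,
)
from .io import ClinicalTable, ExpressionMatrix
from .network import Module

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenThresholds:
    """Significance levels of the three-step screen (all 0.05 by default)."""

    logrank: float = 0.05
    cox: float = 0.05
    stage: float = 0.05
    de: float = 0.05


@dataclass
class ScreenResult:
    """Per-lncRNA screening outcome (one row of the screening table)."""

    lnc_id: str
    module_id: str
    logrank_p: float
    cox_beta: float
    cox_hr: float
    cox_ci: tuple[float, float]
    cox_p: float
    kw_p: float
    de_p: float
    passed: bool
    direction: str | None  # 'favourable' iff HR(high vs low) < 1


@dataclass
class SignatureResult:
    """Modular (or pooled) coefficient-weighted risk signature."""

    signature_id: str
    weights: dict[str, float]
    scores: pd.Series
    group: pd.Series
    hr: float
    ci: tuple[float, float]
    cox_p: float
    km_logrank_p: dict[str, float] = field(default_factory=dict)  # 'os', 'pfs'
    auc_at: dict[float, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary operations


def median_split(values: pd.Series) -> pd.Series:
    """'high' for values strictly above the median, 'low' otherwise.

    With an odd sample count the median-valued sample goes to 'low'.
    """
    if len(values) < 4:
        raise InsufficientDataError("median split needs >= 4 samples")
    med = values.median()
    groups = pd.Series(
        np.where(values > med, "high", "low"), index=values.index, name="group"
    )
    if groups.nunique() < 2:
        raise DegenerateSplitError("all values equal; median split degenerate")
    return groups


def logrank(groups: pd.Series, times: pd.Series, events: pd.Series) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic and two-sided p-value."""
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise InputError(f"log-rank needs exactly 2 groups, got {labels}")
    a = groups == labels[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    covariates: pd.DataFrame, times: pd.Series, events: pd.Series
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) via the partial likelihood.

    Returns one row per covariate with beta, hr, ci_low, ci_high, p
    (Wald 95% interval).
    """
    for col in covariates.columns:
        if covariates[col].nunique() < 2:
            raise FitError(f"constant covariate {col!r}")
    df = covariates.copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:  # pragma: no cover - diagnostic path
        raise FitError(f"Cox fit failed to converge: {exc}") from exc
    s = cph.summary
    return pd.DataFrame(
        {
            "beta": s["coef"],
            "hr": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )


def km_curve(times: pd.Series, events: pd.Series) -> pd.Series:
    """Product-limit survival estimate as a right-continuous step series."""
    if len(times) == 0:
        raise InsufficientDataError("Kaplan-Meier needs >= 1 subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    sf.index.name = "time"
    sf.name = "survival"
    return sf


def _step_lookup(step: pd.Series, t: float, left: bool = False) -> float:
    """Value of a right-continuous step series at t (or its left limit)."""
    idx = step.index.to_numpy(dtype=float)
    vals = step.to_numpy(dtype=float)
    side = "left" if left else "right"
    pos = np.searchsorted(idx, t, side=side) - 1
    return 1.0 if pos < 0 else float(vals[pos])


def time_auc(
    scores: pd.Series,
    times: pd.Series,
    events: pd.Series,
    eval_times,
    higher_score_is_riskier: bool = True,
) -> dict[float, float]:
    """Cumulative-case / dynamic-control AUC(t) with IPCW.

    Cases at t are subjects with an observed event at or before t, controls
    those still under observation after t.  Censoring weights come from the
    Kaplan-Meier estimate of the censoring distribution G: cases weigh
    1/G(T-), controls 1/G(t).  Ties in score count 1/2.  Times where no
    case or no control exists (or a weight is undefined) yield NaN.
    """
    s = scores.to_numpy(dtype=float)
    if not higher_score_is_riskier:
        s = -s
    t_arr = times.to_numpy(dtype=float)
    e_arr = events.to_numpy(dtype=int)
    censor_sf = km_curve(times, 1 - events)  # survival of the censoring time

    out: dict[float, float] = {}
    for t in eval_times:
        cases = (t_arr <= t) & (e_arr == 1)
        controls = t_arr > t
        if not cases.any() or not controls.any():
            out[float(t)] = float("nan")
            continue
        g_cases = np.array([_step_lookup(censor_sf, ti, left=True) for ti in t_arr[cases]])
        g_t = _step_lookup(censor_sf, t)
        if g_t <= 0 or (g_cases <= 0).any():
            out[float(t)] = float("nan")
            continue
        w = 1.0 / g_cases
        v = np.full(controls.sum(), 1.0 / g_t)
        diff = s[cases][:, None] - s[controls][None, :]
        conc = (diff > 0) + 0.5 * (diff == 0)
        wmat = w[:, None] * v[None, :]
        out[float(t)] = float((conc * wmat).sum() / wmat.sum())
    return out


# ---------------------------------------------------------------------------
# screening


def _aligned(
    expr: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    common = [s for s in clinical.sample_ids if s in set(expr.sample_ids)]
    if not common:
        raise InputError("no overlap between expression and clinical samples")
    return expr.values[common], clinical.data.loc[common]


def screen_lncrnas(
    tumour: ExpressionMatrix,
    normal: ExpressionMatrix,
    clinical: ClinicalTable,
    modules: list[Module],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[ScreenResult]:
    """Run the three-step prognostic screen over every module lncRNA.

    Steps run sequentially: the Cox fit is only attempted for lncRNAs that
    pass the log-rank filter (later p-values are NaN when an earlier step
    fails).  Stage dependency and differential expression are computed for
    every lncRNA since they are cheap and diagnostic.
    """
    for col in ("os_time", "os_event", "age", "stage"):
        if col not in clinical.data.columns:
            raise InputError(f"clinical table missing field {col!r}")
    expr_t, clin = _aligned(tumour, clinical)
    results: list[ScreenResult] = []
    nan = float("nan")
    for mod in modules:
        for lnc in sorted(mod.members):
            if lnc not in expr_t.index:
                raise InputError(f"module lncRNA {lnc} absent from expression matrix")
            x = expr_t.loc[lnc]

            # stage dependency (KW across stages present) and tumour-vs-normal DE
            stage_groups = [
                x[clin["stage"] == s].to_numpy()
                for s in (1, 2, 3, 4)
                if (clin["stage"] == s).sum() >= 2
            ]
            if len(stage_groups) >= 2:
                kw_p = float(stats.kruskal(*stage_groups).pvalue)
            else:
                kw_p = nan
            if lnc in normal.values.index and normal.values.shape[1] > 0:
                de_p = float(
                    stats.mannwhitneyu(
                        x.to_numpy(),
                        normal.values.loc[lnc].to_numpy(),
                        alternative="two-sided",
                    ).pvalue
                )
            else:
                de_p = nan

            try:
                groups = median_split(x)
            except DegenerateSplitError:
                logger.warning("lncRNA %s has constant expression; screen fails", lnc)
                results.append(
                    ScreenResult(lnc, mod.module_id, nan, nan, nan, (nan, nan), nan,
                                 kw_p, de_p, False, None)
                )
                continue
            _, lr_p = logrank(groups, clin["os_time"], clin["os_event"])

            beta = hr = cox_p = nan
            ci = (nan, nan)
            direction = None
            if lr_p < thresholds.logrank:
                cov = pd.DataFrame(
                    {
                        "high": (groups == "high").astype(float),
                        "age": clin["age"],
                        "stage": clin["stage"],
                    }
                ).dropna()
                try:
                    fit = cox_fit(
                        cov, clin.loc[cov.index, "os_time"], clin.loc[cov.index, "os_event"]
                    )
                    beta = float(fit.loc["high", "beta"])
                    hr = float(fit.loc["high", "hr"])
                    ci = (float(fit.loc["high", "ci_low"]), float(fit.loc["high", "ci_high"]))
                    cox_p = float(fit.loc["high", "p"])
                    direction = "favourable" if hr < 1 else "unfavourable"
                except FitError as exc:
                    logger.warning("Cox fit failed for %s: %s", lnc, exc)

            passed = bool(
                lr_p < thresholds.logrank
                and cox_p < thresholds.cox
                and kw_p < thresholds.stage
                and de_p < thresholds.de
            )
            results.append(
                ScreenResult(lnc, mod.module_id, float(lr_p), beta, hr, ci, cox_p,
                             kw_p, de_p, passed, direction)
            )
    return results


def write_screen_table(results: list[ScreenResult], path) -> None:
    rows = [
        {
            "lnc_id": r.lnc_id,
            "module_id": r.module_id,
            "logrank_p": r.logrank_p,
            "cox_beta": r.cox_beta,
            "cox_hr": r.cox_hr,
            "cox_ci_low": r.cox_ci[0],
            "cox_ci_high": r.cox_ci[1],
            "cox_p": r.cox_p,
            "kw_p": r.kw_p,
            "de_p": r.de_p,
            "passed": r.passed,
            "direction": r.direction or "",
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signatures


def signature_weights(
    tumour: ExpressionMatrix, clinical: ClinicalTable, lnc_ids
) -> dict[str, float]:
    """Continuous-expression Cox coefficients (age- and stage-adjusted).

    One fit per lncRNA: hazard ~ expression + age + stage; the expression
    coefficient is the signature weight beta_i.
    """
    expr_t, clin = _aligned(tumour, clinical)
    weights: dict[str, float] = {}
    for lnc in lnc_ids:
        cov = pd.DataFrame(
            {"expr": expr_t.loc[lnc], "age": clin["age"], "stage": clin["stage"]}
        ).dropna()
        fit = cox_fit(cov, clin.loc[cov.index, "os_time"], clin.loc[cov.index, "os_event"])
        weights[lnc] = float(fit.loc["expr", "beta"])
    return weights


def evaluate_signature(
    signature_id: str,
    weights: dict[str, float],
    tumour: ExpressionMatrix,
    clinical: ClinicalTable,
    eval_times=(),
) -> SignatureResult:
    """Score, median-split, KM/log-rank (OS + PFS), adjusted Cox and time-AUC."""
    if not weights:
        raise InsufficientDataError("signature has no lncRNAs")
    expr_t, clin = _aligned(tumour, clinical)
    beta = pd.Series(weights)
    scores = beta @ expr_t.loc[beta.index]
    scores.name = "score"
    groups = median_split(scores)

    km_p: dict[str, float] = {}
    _, km_p["os"] = logrank(groups, clin["os_time"], clin["os_event"])
    if "pfs_time" in clin.columns and clin["pfs_event"].sum() > 0:
        _, km_p["pfs"] = logrank(groups, clin["pfs_time"], clin["pfs_event"])

    cov = pd.DataFrame(
        {
            "high": (groups == "high").astype(float),
            "age": clin["age"],
            "stage": clin["stage"],
        }
    ).dropna()
    fit = cox_fit(cov, clin.loc[cov.index, "os_time"], clin.loc[cov.index, "os_event"])
    auc = (
        time_auc(scores, clin["os_time"], clin["os_event"], eval_times)
        if len(eval_times)
        else {}
    )
    return SignatureResult(
        signature_id=signature_id,
        weights=dict(weights),
        scores=scores,
        group=groups,
        hr=float(fit.loc["high", "hr"]),
        ci=(float(fit.loc["high", "ci_low"]), float(fit.loc["high", "ci_high"])),
        cox_p=float(fit.loc["high", "p"]),
        km_logrank_p=km_p,
        auc_at=auc,
    )


def module_signature(
    tumour: ExpressionMatrix,
    clinical: ClinicalTable,
    module: Module,
    screen_results: list[ScreenResult],
    eval_times=(),
) -> SignatureResult | None:
    """Signature of one module from its screen-passing lncRNAs (None if none)."""
    passed = [
        r.lnc_id
        for r in screen_results
        if r.module_id == module.module_id and r.passed
    ]
    if not passed:
        logger.warning("module %s has no screen-passing lncRNAs; dropped", module.module_id)
        return None
    weights = signature_weights(tumour, clinical, passed)
    return evaluate_signature(module.module_id, weights, tumour, clinical, eval_times)


def pooled_signature(
    tumour: ExpressionMatrix,
    clinical: ClinicalTable,
    module_results: list[SignatureResult],
    eval_times=(),
    signature_id: str = "pooled",
) -> SignatureResult:
    """Union of the module signatures, evaluated like a single module."""
    if not module_results:
        raise InsufficientDataError("pooled signature needs >= 1 module result")
    weights: dict[str, float] = {}
    for res in module_results:
        weights.update(res.weights)
    return evaluate_signature(signature_id, weights, tumour, clinical, eval_times)


def write_signature_table(result: SignatureResult, path) -> None:
    pd.DataFrame({"score": result.scores, "group": result.group}).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def signature_summary(result: SignatureResult) -> dict:
    return {
        "signature_id": result.signature_id,
        "n_lncrnas": len(result.weights),
        "weights": {k: result.weights[k] for k in sorted(result.weights)},
        "hr": result.hr,
        "ci": list(result.ci),
        "cox_p": result.cox_p,
        "km_logrank_p": result.km_logrank_p,
        "auc_at": {str(k): v for k, v in sorted(result.auc_at.items())},
    }
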