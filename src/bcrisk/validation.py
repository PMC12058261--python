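"""Calibration and discrimination statistics for predicted absolute risks.

Implements the standard validation battery for an absolute-risk model
evaluated on a prospective cohort:

* expected/observed (E/O) case ratio with the Poisson normal-approximation
  95% CI, ``(E/O) * exp(+-1.96 / sqrt(O))``;
* calibration slope: the coefficient of ``logit(predicted risk)`` in a
  maximum-likelihood logistic regression of observed status (Wald CI);
* decile calibration: equal-count groups by predicted risk with exact
  binomial CIs for the observed proportion;
* AUC by the Mann-Whitney estimator (ties count 1/2) with the DeLong
  placement-value covariance CI;
* Harrell's C over comparable pairs under right censoring, with a
  leave-one-subject-out jackknife CI on the concordance U-statistic.

``E`` is the sum of individual predicted risks over each woman's own
(possibly censored) prediction window, so the expected count is directly
comparable with the observed count under independent censoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats, special

import statsmodels.api as sm

from .errors import DataError, NumericalError, UndefinedStatisticError

__all__ = [
    "EOResult",
    "eo_interval",
    "expected_observed",
    "calibration_slope",
    "decile_calibration",
    "auc",
    "harrell_c",
    "validation_report",
    "round_display",
]


def round_display(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used in report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EOResult:
    expected: float
    observed: int
    ratio: float
    ci_low: float
    ci_high: float


def eo_interval(ratio: float, observed: int) -> tuple[float, float]:
    """Poisson normal-approximation 95% CI for an E/O ratio.

    ``(ratio * exp(-1.96/sqrt(O)), ratio * exp(+1.96/sqrt(O)))`` — the
    log-scale symmetric interval for a ratio whose denominator is a Poisson
    count ``O``.  Accepts a pre-computed ratio so printed worked examples can
    be reproduced exactly.
    """
    if observed < 1:
        raise UndefinedStatisticError(
            "E/O interval undefined for O = 0; report the expected count alone"
        )
    half = 1.96 / np.sqrt(observed)
    return float(ratio * np.exp(-half)), float(ratio * np.exp(half))


def expected_observed(predicted_risk, outcome) -> EOResult:
    """Expected and observed case counts with the Poisson-CI E/O ratio."""
    p = np.asarray(predicted_risk, float)
    y = np.asarray(outcome, float)
    if p.shape != y.shape:
        raise DataError("predicted_risk and outcome must be equal length")
    expected = float(p.sum())
    observed = int(round(y.sum()))
    if observed < 1:
        raise UndefinedStatisticError(
            f"no observed cases (E = {expected:.2f}); E/O undefined — report E alone"
        )
    ratio = expected / observed
    lo, hi = eo_interval(ratio, observed)
    return EOResult(expected, observed, ratio, lo, hi)


def calibration_slope(predicted_risk, outcome) -> tuple[float, float, float]:
    """Calibration slope: logistic regression of outcome on logit(predicted risk).

    Returns ``(slope, wald_ci_low, wald_ci_high)``.  Slope 1 means the risk
    spread is correct; < 1 means predictions are too extreme.
    """
    p = np.asarray(predicted_risk, float)
    y = np.asarray(outcome, float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise DataError("calibration slope requires predicted risks strictly in (0, 1)")
    if y.sum() < 1 or (1 - y).sum() < 1:
        raise UndefinedStatisticError("calibration slope needs at least one case and one non-case")
    x = sm.add_constant(special.logit(p))
    try:
        fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError subclasses
        raise NumericalError(f"calibration slope did not converge: {exc}") from exc
    if not fit.mle_retvals.get("converged", True) or np.abs(fit.params[1]) > 1e3:
        raise NumericalError("calibration slope did not converge (possible separation)")
    slope = float(fit.params[1])
    lo, hi = fit.conf_int()[1]
    return slope, float(lo), float(hi)


def decile_calibration(predicted_risk, outcome, n_groups: int = 10) -> pd.DataFrame:
    """Equal-count risk groups: mean predicted risk vs observed proportion.

    Women are ranked by predicted risk (stable ties), split into ``n_groups``
    equal-count groups with any remainder spread over the lowest groups, and
    each group gets an exact (Clopper-Pearson) binomial 95% CI for the
    observed proportion.
    """
    p = np.asarray(predicted_risk, float)
    y = np.asarray(outcome, float)
    n = p.size
    if n < n_groups:
        raise DataError(f"need at least {n_groups} observations for {n_groups} groups")
    order = np.argsort(p, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = [base + 1 if g < rem else base for g in range(n_groups)]
    rows = []
    start = 0
    for g, size in enumerate(sizes):
        idx = order[start : start + size]
        start += size
        k = int(round(y[idx].sum()))
        ci = stats.binomtest(k, size).proportion_ci(confidence_level=0.95, method="exact")
        rows.append(
            {
                "decile": g + 1,
                "n": size,
                "mean_pred": float(p[idx].mean()),
                "obs": k / size,
                "ci_low": float(ci.low),
                "ci_high": float(ci.high),
            }
        )
    return pd.DataFrame(rows)


def auc(predicted_risk, outcome) -> tuple[float, float, float]:
    """Mann-Whitney AUC (ties 1/2) with the DeLong placement-value 95% CI."""
    p = np.asarray(predicted_risk, float)
    y = np.asarray(outcome, float).astype(bool)
    m = int(y.sum())
    n = int((~y).sum())
    if m == 0 or n == 0:
        raise UndefinedStatisticError("AUC undefined: need at least one case and one non-case")
    r_all = stats.rankdata(p, method="average")
    r_cases = stats.rankdata(p[y], method="average")
    r_controls = stats.rankdata(p[~y], method="average")
    value = (r_all[y].sum() - m * (m + 1) / 2.0) / (m * n)
    # placement values (DeLong): per-case and per-control concordance shares
    v_case = (r_all[y] - r_cases) / n
    v_control = 1.0 - (r_all[~y] - r_controls) / m
    var = (np.var(v_case, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v_control, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.96 * np.sqrt(var)
    return float(value), float(max(0.0, value - half)), float(min(1.0, value + half))


def harrell_c(predicted_risk, time, event) -> tuple[float, float, float]:
    """Harrell's concordance for right-censored follow-up.

    A pair is comparable when the earlier exit is an event (an event tied in
    time with a censoring is treated as earlier; two events at the same time
    are not comparable).  A comparable pair is concordant when the subject
    with the earlier event has the higher predicted risk; prediction ties
    count 1/2.  The 95% CI is a leave-one-subject-out jackknife on the
    concordance U-statistic.
    """
    p = np.asarray(predicted_risk, float)
    t = np.asarray(time, float)
    e = np.asarray(event, float).astype(bool)
    n = p.size
    a = np.zeros(n)  # per-subject concordance score sums
    b = np.zeros(n)  # per-subject comparable-pair counts
    total_score = 0.0
    total_pairs = 0.0
    for i in np.flatnonzero(e):
        at_risk = (t > t[i]) | ((t == t[i]) & ~e)
        cnt = int(at_risk.sum())
        if cnt == 0:
            continue
        greater = p[i] > p[at_risk]
        tied = p[i] == p[at_risk]
        scores = greater + 0.5 * tied
        s = float(scores.sum())
        a[i] += s
        b[i] += cnt
        a[at_risk] += scores
        b[at_risk] += 1.0
        total_score += s
        total_pairs += cnt
    if total_pairs == 0:
        raise UndefinedStatisticError("Harrell C undefined: no comparable pairs")
    c = total_score / total_pairs
    denom = total_pairs - b
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = np.where(denom > 0, (total_score - a) / denom, c)
    var_jack = (n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)
    half = 1.96 * np.sqrt(var_jack)
    return float(c), float(max(0.0, c - half)), float(min(1.0, c + half))


def _stat_row(pairs: pd.DataFrame) -> dict:
    out: dict = {"n": len(pairs), "O": np.nan, "E": np.nan}
    for key in (
        "eo", "eo_lo", "eo_hi", "slope", "slope_lo", "slope_hi",
        "auc", "auc_lo", "auc_hi", "cindex", "cindex_lo", "cindex_hi",
    ):
        out[key] = np.nan
    if len(pairs) == 0:
        return out
    p = pairs["abs_risk"].to_numpy(float)
    y = pairs["event"].to_numpy(float)
    out["E"] = float(p.sum())
    out["O"] = int(round(y.sum()))
    try:
        eo = expected_observed(p, y)
        out.update(eo=eo.ratio, eo_lo=eo.ci_low, eo_hi=eo.ci_high)
    except UndefinedStatisticError:
        pass
    try:
        s, lo, hi = calibration_slope(p, y)
        out.update(slope=s, slope_lo=lo, slope_hi=hi)
    except (UndefinedStatisticError, NumericalError, DataError):
        pass
    try:
        a, lo, hi = auc(p, y)
        out.update(auc=a, auc_lo=lo, auc_hi=hi)
    except UndefinedStatisticError:
        pass
    if {"entry_age", "exit_age"} <= set(pairs.columns):
        try:
            fu = pairs["exit_age"].to_numpy(float) - pairs["entry_age"].to_numpy(float)
            c, lo, hi = harrell_c(p, fu, y)
            out.update(cindex=c, cindex_lo=lo, cindex_hi=hi)
        except UndefinedStatisticError:
            pass
    return out


def validation_report(pairs_by_variant: dict, strata: dict | None = None) -> pd.DataFrame:
    """Tidy calibration/discrimination report: one row per (variant, stratum).

    ``pairs_by_variant`` maps variant name to a frame with columns
    ``abs_risk``, ``event`` and (for the concordance index) ``entry_age`` and
    ``exit_age``.  ``strata`` maps stratum name to a boolean mask aligned with
    the frames; the overall stratum ``"all"`` is always included first.
    Empty strata produce rows with NA statistics, never silent drops.
    """
    rows = []
    for variant, pairs in pairs_by_variant.items():
        masks: dict = {"all": np.ones(len(pairs), dtype=bool)}
        for name, mask in (strata or {}).items():
            masks[name] = np.asarray(mask, dtype=bool)
        for name, mask in masks.items():
            if mask.shape[0] != len(pairs):
                raise DataError(f"stratum {name!r} mask length mismatch for variant {variant!r}")
            row = {"variant": variant, "stratum": name}
            row.update(_stat_row(pairs.loc[mask]))
            rows.append(row)
    return pd.DataFrame(rows)
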