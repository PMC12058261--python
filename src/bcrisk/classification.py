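"""Risk-category classification and case-capture tabulation.

Predicted 10-year risks are classified into three ordered categories
(near-population / moderate / high) under either

* **relative** thresholds on the ratio of the individual 10-year absolute
  risk to the population absolute risk over the same age window (the
  age-dependent scheme; guideline cut-points 1.6 and 3.1 are the hazard
  multipliers equivalent to lifetime risks of 17% and 30%), or
* **absolute** thresholds on the 10-year risk itself (age-independent
  schemes, e.g. 3%/8%, or the 5.8%/11% cut-points matching the relative
  thresholds for a woman at the cohort's median age of 58).

Boundary semantics are half-open upwards: the moderate category is
``cut_low <= value < cut_high`` and values exactly at a threshold go to the
higher category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .incidence import IncidenceTable

__all__ = [
    "CATEGORIES",
    "ThresholdScheme",
    "NICE_TEN_YEAR",
    "ALT_TEN_YEAR",
    "RELATIVE_RR",
    "to_relative_risk",
    "classify",
    "classification_table",
    "top_fraction_capture",
    "scheme_from_lifetime",
]

CATEGORIES = ("near-population", "moderate", "high")


@dataclass(frozen=True)
class ThresholdScheme:
    """Three ordered risk categories split at ``cut_low`` and ``cut_high``."""

    kind: str  # "relative" or "absolute"
    cut_low: float
    cut_high: float
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("relative", "absolute"):
            raise ConfigError(f"scheme kind must be 'relative' or 'absolute', got {self.kind!r}")
        if not (0.0 < self.cut_low < self.cut_high):
            raise ConfigError("thresholds must satisfy 0 < cut_low < cut_high")


#: Guideline 10-year absolute-risk categories: <3%, 3-8%, >=8%.
NICE_TEN_YEAR = ThresholdScheme("absolute", 0.03, 0.08, "nice10")
#: Alternative 10-year categories matching the relative cut-points at age 58.
ALT_TEN_YEAR = ThresholdScheme("absolute", 0.058, 0.11, "alt10")
#: Relative-risk categories equivalent to lifetime risks of 17% and 30%.
RELATIVE_RR = ThresholdScheme("relative", 1.6, 3.1, "rr")


def to_relative_risk(abs_risk, window_start, window_end, table: IncidenceTable):
    """Ratio of predicted absolute risk to the population risk over the same window."""
    pop = table.cumulative_risk(np.asarray(window_start, float), np.asarray(window_end, float), 1.0)
    pop = np.asarray(pop, float)
    if np.any(pop <= 0.0):
        raise DataError("population risk is zero over a prediction window; RR undefined")
    out = np.asarray(abs_risk, float) / pop
    return float(out) if out.ndim == 0 else out


def classify(value, scheme: ThresholdScheme):
    """Assign each value to a category: low ``< cut_low``, moderate
    ``[cut_low, cut_high)``, high ``>= cut_high``."""
    v = np.asarray(value, float)
    if np.any(v < 0) or not np.isfinite(v).all():
        raise DataError("classification requires finite non-negative values")
    idx = (v >= scheme.cut_low).astype(int) + (v >= scheme.cut_high).astype(int)
    if v.ndim == 0:
        return CATEGORIES[int(idx)]
    return np.asarray(CATEGORIES, dtype=object)[idx]


def classification_table(
    values, outcome, scheme: ThresholdScheme, strata: dict | None = None
) -> pd.DataFrame:
    """Percent of the population and of incident cases per category and stratum.

    Returns a tidy frame ``stratum, category, n, n_cases, pct_population,
    pct_cases``; within each stratum the two percentage columns sum to 100.
    Empty strata yield NA rows.
    """
    v = np.asarray(values, float)
    y = np.asarray(outcome, float).astype(bool)
    cats = classify(v, scheme)
    masks: dict = {"all": np.ones(v.size, dtype=bool)}
    for name, mask in (strata or {}).items():
        masks[name] = np.asarray(mask, dtype=bool)
    rows = []
    for name, mask in masks.items():
        n_tot = int(mask.sum())
        n_cases_tot = int((mask & y).sum())
        for cat in CATEGORIES:
            in_cat = mask & (cats == cat)
            rows.append(
                {
                    "stratum": name,
                    "category": cat,
                    "n": int(in_cat.sum()),
                    "n_cases": int((in_cat & y).sum()),
                    "pct_population": 100.0 * in_cat.sum() / n_tot if n_tot else np.nan,
                    "pct_cases": 100.0 * (in_cat & y).sum() / n_cases_tot
                    if n_cases_tot
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def top_fraction_capture(predicted_risk, outcome, fractions=(0.1, 0.3, 0.5)) -> dict:
    """Share of incident cases among the top fraction of predicted risks.

    Ranks descending with stable ties, takes ``ceil(fraction * n)`` women and
    reports the percentage of all cases falling inside, per fraction.
    """
    p = np.asarray(predicted_risk, float)
    y = np.asarray(outcome, float).astype(bool)
    n = p.size
    n_cases = int(y.sum())
    order = np.argsort(-p, kind="stable")
    out = {}
    for frac in fractions:
        if not (0.0 < frac <= 1.0):
            raise DataError(f"fractions must be in (0, 1]; got {frac!r}")
        k = int(np.ceil(frac * n))
        captured = int(y[order[:k]].sum())
        out[float(frac)] = 100.0 * captured / n_cases if n_cases else np.nan
    return out


def scheme_from_lifetime(
    lifetime_cuts: tuple = (0.17, 0.30),
    table: IncidenceTable | None = None,
    from_age: float = 20.0,
    to_age: float = 80.0,
    label: str = "rr-from-lifetime",
) -> ThresholdScheme:
    """Relative-risk scheme equivalent to lifetime-risk category cut-points.

    Each lifetime cut ``c`` maps to the hazard multiplier ``r`` with
    ``1 - exp(-r * H_life) = c``.  On a table mimicking national incidence
    the 17%/30% cuts land near the conventional 1.6/3.1 multipliers.
    """
    if table is None:
        from .defaults import synthetic_incidence_table

        table = synthetic_incidence_table()
    c1, c2 = lifetime_cuts
    if not (0.0 < c1 < c2 < 1.0):
        raise ConfigError("lifetime cuts must satisfy 0 < c1 < c2 < 1")
    return ThresholdScheme(
        "relative",
        table.rr_threshold_from_lifetime(c1, from_age, to_age),
        table.rr_threshold_from_lifetime(c2, from_age, to_age),
        label,
    )
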