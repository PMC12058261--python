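"""Default model parameterization and cohort-structure defaults.

The effect sizes below are package defaults declared for the surrogate
multiplicative model — plausible, literature-order values chosen so the
discrimination ordering PRS > family history ~ questionnaire factors holds —
not estimates from any specific dataset.  Category frequencies follow the
structure of a large UK volunteer cohort of women aged 40-70: carrier
frequencies of order 0.05-0.5% per gene, standardized PRS ~ N(0,1), roughly
12% with any first-degree family history, and ~3% 10-year cumulative
breast-cancer incidence.
"""

from __future__ import annotations

import numpy as np

from .incidence import IncidenceTable, packaged_incidence_table
from .model import Factor, RelativeRiskModel

__all__ = [
    "default_model",
    "default_entry_age_weights",
    "default_missingness",
    "synthetic_incidence_table",
]


def _factor(name, cats, rr, freq):
    freq = np.asarray(freq, float)
    return Factor(name, cats, np.log(np.asarray(rr, float)), freq / freq.sum())


def default_model() -> RelativeRiskModel:
    """The package's default relative-risk model.

    Per-SD PRS hazard ratio 1.61 (AUC from the PRS alone ~0.63 under a
    liability-normal population); moderate-to-high per-gene PV hazard ratios;
    modest questionnaire effects; family-history hazard ratios 1.8 (one
    affected first-degree relative) and 2.9 (two or more).
    """
    factors = {
        "menarche": _factor(
            "menarche",
            ("<=10", "11", "12", "13", "14", "15", ">=16"),
            (1.15, 1.10, 1.05, 1.00, 0.96, 0.92, 0.88),
            (0.046, 0.155, 0.189, 0.245, 0.198, 0.110, 0.052),
        ),
        "parity": _factor(
            "parity",
            ("0", "1", "2", "3+"),
            (1.15, 1.05, 0.95, 0.90),
            (0.188, 0.133, 0.445, 0.235),
        ),
        "first_birth": _factor(
            "first_birth",
            ("<=19", "20-24", "25-29", ">=30"),
            (0.90, 0.95, 1.00, 1.10),
            (0.097, 0.346, 0.379, 0.179),
        ),
        "menopause": _factor(
            "menopause",
            ("<=39", "40-44", "45-49", "50-54", "55-70"),
            (0.80, 0.85, 0.92, 1.00, 1.15),
            (0.040, 0.089, 0.235, 0.484, 0.152),
        ),
        "oc_use": _factor(
            "oc_use",
            ("current", "former", "never"),
            (1.20, 1.00, 0.95),
            (0.040, 0.786, 0.174),
        ),
        "mht_use": _factor(
            "mht_use",
            ("current_c", "current_e", "former", "never"),
            (1.60, 1.30, 1.05, 1.00),
            (0.211, 0.002, 0.254, 0.533),
        ),
        "bmi": _factor(
            "bmi",
            ("<18.5", "18.5-25", "25-30", "30+"),
            (0.90, 1.00, 1.05, 1.10),
            (0.008, 0.398, 0.366, 0.228),
        ),
        "height": _factor(
            "height",
            ("<153", "153-160", "160-166", "166-173", "173+"),
            (0.90, 0.95, 1.00, 1.05, 1.10),
            (0.050, 0.258, 0.376, 0.258, 0.058),
        ),
        "alcohol": _factor(
            "alcohol",
            ("0-5", "5-15", "15-25", "25-35", "35-45", "45+"),
            (1.00, 1.03, 1.07, 1.10, 1.13, 1.16),
            (0.307, 0.401, 0.180, 0.068, 0.025, 0.019),
        ),
        "family_history": _factor(
            "family_history",
            ("0", "1", "2"),
            (1.00, 1.80, 2.90),
            (0.880, 0.105, 0.015),
        ),
    }
    return RelativeRiskModel(
        beta_prs=float(np.log(1.61)),
        pv_log_rr={
            "brca1": float(np.log(5.0)),
            "brca2": float(np.log(4.0)),
            "palb2": float(np.log(3.5)),
            "atm": float(np.log(2.0)),
            "chek2": float(np.log(2.3)),
            "rad51c": float(np.log(1.8)),
            "rad51d": float(np.log(1.8)),
            "bard1": float(np.log(1.8)),
        },
        pv_freq={
            "brca1": 0.00044,
            "brca2": 0.00195,
            "palb2": 0.00134,
            "atm": 0.00214,
            "chek2": 0.00442,
            "rad51c": 0.00028,
            "rad51d": 0.00041,
            "bard1": 0.00052,
        },
        factors=factors,
    )


def default_entry_age_weights() -> dict:
    """Weights over 5-year entry-age bands 40-69 (cohort age structure)."""
    return {
        (40.0, 45.0): 0.076,
        (45.0, 50.0): 0.130,
        (50.0, 55.0): 0.157,
        (55.0, 60.0): 0.181,
        (60.0, 65.0): 0.242,
        (65.0, 70.0): 0.213,
    }


def default_missingness() -> dict:
    """Per-factor independent missingness probabilities.

    Patterned on questionnaire completeness in a large volunteer cohort:
    menopause age and hormone-therapy use are missing for a large share of
    women (mostly premenopausal), alcohol and age at first birth are
    moderately incomplete, anthropometry is nearly complete.  Genetic data
    (PRS, PV) are complete by eligibility.
    """
    return {
        "prs": 0.0,
        "menarche": 0.027,
        "parity": 0.001,
        "first_birth": 0.13,
        "menopause": 0.44,
        "oc_use": 0.002,
        "mht_use": 0.45,
        "bmi": 0.003,
        "height": 0.002,
        "alcohol": 0.20,
        "family_history": 0.0,
    }


def synthetic_incidence_table() -> IncidenceTable:
    """Alias for the packaged illustrative incidence table."""
    return packaged_incidence_table()
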