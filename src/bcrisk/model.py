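"""Multiplicative multifactorial relative-hazard model and absolute-risk prediction.

The model combines, on the hazard scale, the contributions of

* a standardized polygenic risk score (PRS): ``exp(beta_prs * z)``,
* rare pathogenic variants (PV) in breast-cancer susceptibility genes
  (a woman carrying several is assigned the highest-risk gene only),
* categorical questionnaire risk factors (menarche, parity, age at first
  live birth, menopause, oral contraceptive use, menopausal hormone therapy,
  BMI, height, alcohol), and
* a first-degree family-history count (0 / 1 / 2+),

each declared with per-category log relative hazards and population category
frequencies.  Every factor is internally normalized so its frequency-weighted
mean relative risk is exactly 1; for the PRS the normalizer is
``E[exp(beta * Z)] = exp(beta^2 / 2)`` for standard-normal ``Z``.  A missing
value therefore contributes exactly the population-average effect, i.e. a
factor of 1 — the standard missing-data convention for population-calibrated
multifactorial risk models — and a fully missing profile has combined
relative risk exactly 1 (the age-only null model).

Absolute risks are obtained by scaling the population hazard from an
:class:`~bcrisk.incidence.IncidenceTable`: a woman recruited at age ``a`` is
predicted over the window ``[a + 1, min(a + 11, 80))`` (the first year is
excluded to remove prevalent cancers); for women censored unaffected before
the window end the window is truncated at the censoring age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, PredictionWindowError
from .incidence import IncidenceTable

__all__ = [
    "PRS_RAW_MEAN",
    "PRS_RAW_SD",
    "GENES",
    "QUESTIONNAIRE_FACTORS",
    "MISSING",
    "Factor",
    "RelativeRiskModel",
    "RiskFactorProfile",
    "PredictedRisk",
    "standardize_prs",
    "combined_rr",
    "combined_rr_frame",
    "calibrate_baseline",
    "predict_window_risk",
    "predict_cohort",
    "expand_variant",
]

#: Published standardization constants for the 313-SNP polygenic score
#: (raw-score population mean and standard deviation).
PRS_RAW_MEAN = -0.424
PRS_RAW_SD = 0.603

#: Susceptibility genes with rare protein-truncating pathogenic variants.
GENES = ("brca1", "brca2", "palb2", "atm", "chek2", "rad51c", "rad51d", "bard1")

QUESTIONNAIRE_FACTORS = (
    "menarche",
    "parity",
    "first_birth",
    "menopause",
    "oc_use",
    "mht_use",
    "bmi",
    "height",
    "alcohol",
)

#: Marker for a missing categorical value in in-memory profiles.
MISSING = None


def standardize_prs(raw_score):
    """Standardize a raw polygenic score: ``(raw - mean) / sd``.

    Uses the published population constants mean = -0.424, sd = 0.603, so the
    standardized score is approximately standard normal in the population.
    """
    raw = np.asarray(raw_score, dtype=float)
    if not np.isfinite(raw).all():
        raise DataError("raw polygenic score must be finite")
    out = (raw - PRS_RAW_MEAN) / PRS_RAW_SD
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Factor:
    """One categorical risk factor: categories, log relative hazards, frequencies."""

    name: str
    categories: tuple
    log_rr: np.ndarray
    freq: np.ndarray

    def __post_init__(self):
        log_rr = np.asarray(self.log_rr, dtype=float)
        freq = np.asarray(self.freq, dtype=float)
        object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        object.__setattr__(self, "log_rr", log_rr)
        object.__setattr__(self, "freq", freq)
        k = len(self.categories)
        if len(set(self.categories)) != k:
            raise ConfigError(f"factor {self.name!r}: duplicate categories")
        if log_rr.shape != (k,) or freq.shape != (k,):
            raise ConfigError(f"factor {self.name!r}: categories/log_rr/freq length mismatch")
        if not np.isfinite(log_rr).all():
            raise ConfigError(f"factor {self.name!r}: non-finite log relative risks")
        if np.any(freq < 0) or abs(freq.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"factor {self.name!r}: frequencies must be >= 0 and sum to 1 "
                f"(sum={freq.sum()!r})"
            )

    @property
    def mean_rr(self) -> float:
        """Frequency-weighted mean relative risk before normalization."""
        return float(self.freq @ np.exp(self.log_rr))

    def normalized_rr(self) -> np.ndarray:
        """Per-category relative risks scaled so the population mean is exactly 1."""
        return np.exp(self.log_rr) / self.mean_rr

    def index_of(self, category: str) -> int:
        try:
            return self.categories.index(str(category))
        except ValueError:
            raise DataError(
                f"unknown category {category!r} for factor {self.name!r}; "
                f"declared: {self.categories}"
            ) from None


@dataclass(frozen=True)
class RelativeRiskModel:
    """Declared multiplicative relative-hazard model.

    Parameters
    ----------
    beta_prs : float
        Log relative hazard per standard deviation of the standardized PRS.
    pv_log_rr, pv_freq : dict
        Per-gene log relative hazard and carrier frequency for pathogenic
        variants; non-carriers have log RR 0.
    factors : dict[str, Factor]
        Questionnaire factors plus the ``family_history`` count factor.
    age_knots : dict, optional
        Optional per-factor age attenuation: ``{name: [(age, scale), ...]}``.
        The factor's log relative hazard is multiplied by the scale linearly
        interpolated at the evaluation age (constant beyond the end knots).
        ``'prs'`` is accepted as a name.  Default: no age dependence.
    """

    beta_prs: float
    pv_log_rr: dict
    pv_freq: dict
    factors: dict
    age_knots: dict | None = None

    def __post_init__(self):
        if not np.isfinite(self.beta_prs):
            raise ConfigError("beta_prs must be finite")
        for g in self.pv_log_rr:
            if g not in GENES:
                raise ConfigError(f"unknown gene {g!r}; known genes: {GENES}")
        for g, f in self.pv_freq.items():
            if g not in self.pv_log_rr:
                raise ConfigError(f"pv_freq for gene {g!r} without a matching pv_log_rr")
            if not (0.0 <= f < 1.0):
                raise ConfigError(f"carrier frequency for {g!r} must be in [0, 1)")
        if sum(self.pv_freq.values()) >= 1.0:
            raise ConfigError("total carrier frequency must be < 1")
        for name, fac in self.factors.items():
            if fac.name != name:
                raise ConfigError(f"factor key {name!r} does not match Factor.name {fac.name!r}")

    # ------------------------------------------------------------- components
    @property
    def prs_normalizer(self) -> float:
        """``E[exp(beta * Z)]`` for standard-normal Z."""
        return float(np.exp(self.beta_prs**2 / 2.0))

    def pv_mean_rr(self) -> float:
        """Population mean PV relative risk (non-carriers contribute RR 1)."""
        total = 1.0 - sum(self.pv_freq.values())
        for g, f in self.pv_freq.items():
            total += f * np.exp(self.pv_log_rr[g])
        return float(total)

    def _age_scale(self, name: str, age) -> float:
        if not self.age_knots or name not in self.age_knots:
            return 1.0 if np.ndim(age) == 0 else np.ones(np.shape(age))
        knots = sorted(self.age_knots[name])
        xs = [k[0] for k in knots]
        ys = [k[1] for k in knots]
        return np.interp(age, xs, ys)

    # -------------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "beta_prs": float(self.beta_prs),
            "pv_log_rr": {g: float(v) for g, v in self.pv_log_rr.items()},
            "pv_freq": {g: float(v) for g, v in self.pv_freq.items()},
            "factors": {
                name: {
                    "categories": list(f.categories),
                    "log_rr": [float(x) for x in f.log_rr],
                    "freq": [float(x) for x in f.freq],
                }
                for name, f in self.factors.items()
            },
            "age_knots": self.age_knots,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RelativeRiskModel":
        try:
            factors = {
                name: Factor(name, spec["categories"], spec["log_rr"], spec["freq"])
                for name, spec in d.get("factors", {}).items()
            }
            return cls(
                beta_prs=float(d["beta_prs"]),
                pv_log_rr={g: float(v) for g, v in d.get("pv_log_rr", {}).items()},
                pv_freq={g: float(v) for g, v in d.get("pv_freq", {}).items()},
                factors=factors,
                age_knots=d.get("age_knots"),
            )
        except KeyError as exc:
            raise ConfigError(f"model config missing key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RelativeRiskModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class RiskFactorProfile:
    """One woman's predictors, with ``None`` as the explicit missing marker.

    ``pv`` maps gene name to 0/1 carrier flags (``None`` = PV status unknown);
    ``questionnaire`` maps factor name to category label; ``family_history``
    is the count of affected first-degree relatives coded 0, 1 or 2 (= 2+).
    """

    prs: float | None = None
    pv: dict | None = None
    questionnaire: dict = field(default_factory=dict)
    family_history: int | None = None

    def carrier_gene(self, model: RelativeRiskModel) -> str | None:
        """The highest-risk flagged gene, or None when carrier-free/unknown."""
        if self.pv is None:
            return None
        flagged = [g for g, v in self.pv.items() if v]
        for g in flagged:
            if g not in GENES:
                raise DataError(f"unknown gene {g!r} in profile")
        if not flagged:
            return None
        return max(flagged, key=lambda g: model.pv_log_rr.get(g, 0.0))


@dataclass(frozen=True)
class PredictedRisk:
    """Absolute and relative risk over an individual prediction window."""

    absolute_risk: float
    window_start: float
    window_end: float
    relative_risk: float          # hazard-scale multiplier vs the population
    population_risk: float        # population absolute risk over the same window
    factors_used: frozenset

    @property
    def risk_ratio(self) -> float:
        """Absolute-risk ratio vs the population window risk (classification scale)."""
        return self.absolute_risk / self.population_risk


ALL_FACTOR_KEYS = frozenset(("prs", "pv", "family_history") + QUESTIONNAIRE_FACTORS)

_VARIANT_GROUPS = {
    "NULL": frozenset(),
    "AGE": frozenset(),
    "FH": frozenset({"family_history"}),
    "QRF": frozenset(QUESTIONNAIRE_FACTORS),
    "PRS": frozenset({"prs"}),
    "PV": frozenset({"pv"}),
}


def expand_variant(spec) -> frozenset:
    """Expand a variant spec into enabled factor keys.

    Accepts an iterable of factor keys, or a string of ``+``-joined group
    aliases (``NULL``, ``FH``, ``QRF``, ``PRS``, ``PV``), e.g.
    ``"FH+QRF+PRS+PV"`` for the full model.
    """
    if isinstance(spec, str):
        keys: set = set()
        for part in spec.replace(" ", "").split("+"):
            alias = part.upper()
            if alias in _VARIANT_GROUPS:
                keys |= _VARIANT_GROUPS[alias]
            elif part in ALL_FACTOR_KEYS:
                keys.add(part)
            else:
                raise ConfigError(f"unknown model-variant component {part!r}")
        return frozenset(keys)
    keys = set(spec)
    unknown = keys - ALL_FACTOR_KEYS
    if unknown:
        raise ConfigError(f"unknown factor keys: {sorted(unknown)}")
    return frozenset(keys)


def _enabled_keys(model: RelativeRiskModel, factors_enabled) -> frozenset:
    """Default (None) enables every factor the model declares, plus PRS and PV."""
    if factors_enabled is None:
        return frozenset({"prs", "pv"} | set(model.factors))
    return expand_variant(factors_enabled)


def combined_rr(
    profile: RiskFactorProfile,
    model: RelativeRiskModel,
    factors_enabled=None,
    age: float | None = None,
    normalize: bool = True,
) -> float:
    """Combined multiplicative relative risk for one woman.

    Missing values contribute the factor's population-average effect, which is
    exactly 1 under the default internal normalization.  ``age`` feeds the
    optional age-attenuation knots (evaluated at the window midpoint by the
    cohort-level API); it is ignored for models without knots.
    """
    enabled = _enabled_keys(model, factors_enabled)
    rr = 1.0
    if "prs" in enabled and profile.prs is not None:
        if not np.isfinite(profile.prs):
            raise DataError("standardized PRS must be finite or None")
        beta = model.beta_prs * model._age_scale("prs", age if age is not None else 0.0)
        rr *= np.exp(beta * profile.prs)
        if normalize:
            rr /= float(np.exp(beta**2 / 2.0))
    if "pv" in enabled and profile.pv is not None:
        gene = profile.carrier_gene(model)
        pv_rr = np.exp(model.pv_log_rr[gene]) if gene is not None else 1.0
        rr *= pv_rr
        if normalize:
            rr /= model.pv_mean_rr()
    for name in enabled & (set(QUESTIONNAIRE_FACTORS) | {"family_history"}):
        fac = model.factors.get(name)
        if fac is None:
            raise ConfigError(f"model declares no factor {name!r}")
        value = (
            profile.family_history
            if name == "family_history"
            else profile.questionnaire.get(name)
        )
        if value is MISSING:
            continue
        scale = model._age_scale(name, age if age is not None else 0.0)
        idx = fac.index_of(value)
        rrs = np.exp(fac.log_rr * scale)
        rr *= rrs[idx] / (fac.freq @ rrs if normalize else 1.0)
    return float(rr)


def _frame_value(df: pd.DataFrame, col: str) -> pd.Series:
    if col not in df.columns:
        raise DataError(f"cohort frame missing column {col!r}")
    return df[col]


def combined_rr_frame(
    df: pd.DataFrame,
    model: RelativeRiskModel,
    factors_enabled=None,
    age=None,
    normalize: bool = True,
) -> np.ndarray:
    """Vectorized :func:`combined_rr` over a cohort frame.

    Expects columns ``prs`` (float, NaN = missing), one 0/1 column per gene,
    one string column per questionnaire factor ('' or NaN = missing) and
    ``fh_count`` (float with NaN = missing).
    """
    enabled = _enabled_keys(model, factors_enabled)
    n = len(df)
    rr = np.ones(n)
    if age is None:
        age = np.zeros(n)
    age = np.broadcast_to(np.asarray(age, dtype=float), (n,))

    if "prs" in enabled:
        z = _frame_value(df, "prs").to_numpy(float)
        beta = model.beta_prs * np.asarray(model._age_scale("prs", age), dtype=float)
        contrib = np.exp(beta * np.nan_to_num(z))
        if normalize:
            contrib = contrib / np.exp(beta**2 / 2.0)
        rr *= np.where(np.isnan(z), 1.0, contrib)
    if "pv" in enabled:
        # highest-risk flagged gene per woman; all-zero rows are non-carriers
        gene_rrs = np.ones(n)
        for g in GENES:
            if g in df.columns and g in model.pv_log_rr:
                flag = df[g].to_numpy(float)
                gene_rrs = np.where(
                    (flag == 1.0) & (np.exp(model.pv_log_rr[g]) > gene_rrs),
                    np.exp(model.pv_log_rr[g]),
                    gene_rrs,
                )
        if normalize:
            gene_rrs = gene_rrs / model.pv_mean_rr()
        rr *= gene_rrs
    for name in sorted(enabled & (set(QUESTIONNAIRE_FACTORS) | {"family_history"})):
        fac = model.factors.get(name)
        if fac is None:
            raise ConfigError(f"model declares no factor {name!r}")
        col = "fh_count" if name == "family_history" else name
        raw = _frame_value(df, col)
        if name == "family_history":
            vals = raw.to_numpy(float)
            with np.errstate(invalid="ignore"):
                as_int = np.nan_to_num(vals).astype(int).astype(str)
            labels = pd.Series(np.where(np.isnan(vals), "", as_int), index=df.index)
        else:
            labels = raw.fillna("").astype(str)
        scale = np.asarray(model._age_scale(name, age), dtype=float)
        cat_idx = np.full(n, -1, dtype=int)
        for i, c in enumerate(fac.categories):
            cat_idx[(labels == c).to_numpy()] = i
        unknown = (cat_idx < 0) & (labels != "").to_numpy()
        if unknown.any():
            bad = labels.to_numpy()[unknown][0]
            raise DataError(
                f"unknown category {bad!r} for factor {name!r}; declared: {fac.categories}"
            )
        log_rr = np.where(cat_idx >= 0, fac.log_rr[np.clip(cat_idx, 0, None)], 0.0)
        contrib = np.exp(log_rr * scale)
        if normalize:
            # normalizer depends on age only through the knots
            norm = np.exp(fac.log_rr[None, :] * scale[:, None]) @ fac.freq
            contrib = contrib / norm
        rr *= np.where(cat_idx >= 0, contrib, 1.0)
    return rr


def population_mean_rr(
    model: RelativeRiskModel, factors_enabled=None, normalize: bool = True
) -> float:
    """Analytic population mean of the combined relative risk.

    Factors are independent in the population model, so the mean is the
    product of per-factor means; 1 exactly for normalized models.
    """
    enabled = _enabled_keys(model, factors_enabled)
    if normalize:
        return 1.0
    mean = 1.0
    if "prs" in enabled:
        mean *= model.prs_normalizer
    if "pv" in enabled:
        mean *= model.pv_mean_rr()
    for name in enabled & (set(QUESTIONNAIRE_FACTORS) | {"family_history"}):
        mean *= model.factors[name].mean_rr
    return float(mean)


def calibrate_baseline(
    model: RelativeRiskModel,
    table: IncidenceTable,
    factors_enabled=None,
    normalize: bool = True,
):
    """Population-consistent baseline hazard: ``b(age) = hazard_pop(age) / E[RR]``.

    With the default internal normalization ``E[RR] = 1`` and the baseline is
    the population hazard itself.  For an un-normalized model the analytic
    mean over the declared frequencies (and ``exp(beta^2/2)`` for the PRS)
    rescales the baseline so that the model-average incidence matches the
    population incidence.
    """
    mean_rr = population_mean_rr(model, factors_enabled, normalize=normalize)
    if mean_rr <= 0.0:
        raise ConfigError("degenerate model: population mean relative risk is zero")

    def baseline(age):
        return table.hazard_at(age) / mean_rr

    baseline.mean_rr = mean_rr  # type: ignore[attr-defined]
    return baseline


def _windows(entry_age, exit_age, event, horizon, cap):
    """Per-woman prediction windows: ``[entry+1, entry+1+horizon)`` capped at ``cap``.

    Women censored unaffected before the window end have the window truncated
    at the censoring age; incident cases keep the full window.
    """
    ws = entry_age + 1.0
    we = np.minimum(entry_age + 1.0 + horizon, cap)
    if exit_age is not None:
        exit_age = np.asarray(exit_age, dtype=float)
        event = np.asarray(event, dtype=float) if event is not None else np.zeros_like(exit_age)
        we = np.where(event > 0, we, np.minimum(we, exit_age))
    if np.any(we <= ws):
        bad = np.atleast_1d(entry_age)[np.atleast_1d(we <= ws)][0]
        raise PredictionWindowError(
            f"empty prediction window for entry age {bad!r}: follow-up must exceed 1 year"
        )
    return ws, we


def predict_window_risk(
    profile: RiskFactorProfile,
    entry_age: float,
    censor_age: float | None,
    model: RelativeRiskModel,
    table: IncidenceTable,
    factors_enabled=None,
    horizon: float = 10.0,
    cap: float = 80.0,
) -> PredictedRisk:
    """10-year absolute risk for one woman, window ``[entry+1, min(entry+11, 80))``.

    ``censor_age`` (if given) truncates the window, mirroring prediction to
    the censoring age for unaffected women with short follow-up.
    """
    ws, we = _windows(
        np.asarray(float(entry_age)),
        None if censor_age is None else np.asarray(float(censor_age)),
        None,
        horizon,
        cap,
    )
    ws, we = float(ws), float(we)
    rr = combined_rr(profile, model, factors_enabled, age=0.5 * (ws + we))
    abs_risk = table.cumulative_risk(ws, we, rr)
    pop_risk = table.cumulative_risk(ws, we, 1.0)
    return PredictedRisk(
        absolute_risk=float(abs_risk),
        window_start=ws,
        window_end=we,
        relative_risk=float(rr),
        population_risk=float(pop_risk),
        factors_used=_enabled_keys(model, factors_enabled),
    )


def predict_cohort(
    cohort: pd.DataFrame,
    model: RelativeRiskModel,
    table: IncidenceTable,
    factors_enabled=None,
    horizon: float = 10.0,
    cap: float = 80.0,
) -> pd.DataFrame:
    """Per-woman predicted risks for a cohort frame.

    Returns a frame ``id, window_start, window_end, abs_risk, rel_risk,
    pop_risk, risk_ratio`` aligned with the cohort rows.  ``rel_risk`` is the
    hazard-scale multiplier; ``risk_ratio`` is the absolute-risk ratio vs the
    population window risk (the scale used for relative-risk classification).
    """
    if len(cohort) == 0:
        raise DataError("empty cohort")
    entry = cohort["entry_age"].to_numpy(float)
    exit_age = cohort["exit_age"].to_numpy(float) if "exit_age" in cohort.columns else None
    event = cohort["event"].to_numpy(float) if "event" in cohort.columns else None
    ws, we = _windows(entry, exit_age, event, horizon, cap)
    rr = combined_rr_frame(cohort, model, factors_enabled, age=0.5 * (ws + we))
    abs_risk = table.cumulative_risk(ws, we, rr)
    pop_risk = table.cumulative_risk(ws, we, 1.0)
    return pd.DataFrame(
        {
            "id": cohort["id"].to_numpy() if "id" in cohort.columns else np.arange(len(cohort)),
            "window_start": ws,
            "window_end": we,
            "abs_risk": abs_risk,
            "rel_risk": rr,
            "pop_risk": pop_risk,
            "risk_ratio": abs_risk / pop_risk,
        }
    )
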