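"""Synthetic prospective-cohort generator.

Generates cohorts with the statistical structure the validation analysis
assumes: entry ages 40-70 with a configurable 5-year-band age structure,
standardized PRS ~ N(0, 1), rare per-gene pathogenic-variant carriers,
categorical questionnaire factors and a first-degree family-history count
drawn from declared frequencies, independent per-factor missingness, and
outcomes simulated from the piecewise-constant individual hazard

    h_i(age) = baseline(age) * RR_i * multiplier(age)

by exact inverse-transform sampling.  ``multiplier(age)`` is an optional
age-group hazard excess applied at the woman's *current* age (e.g. 1.5819
below age 50), which lets a cohort systematically exceed the population
incidence in one age group — the scenario behind calibration-drift analyses.

Follow-up mimics a prospective design: each woman is followed from entry to
the first of breast cancer, a censoring event (loss, death, other cancer,
mastectomy — collapsed into one exponential process with labelled draws),
the administrative linkage end, the end of the 10-year prediction window
(entry + 11 years, the first year being burn-in), or age 80.  Events in the
first year after entry mark the woman ineligible, mirroring the exclusion of
prevalent cancers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .incidence import IncidenceTable
from .model import (
    GENES,
    QUESTIONNAIRE_FACTORS,
    RelativeRiskModel,
    calibrate_baseline,
    combined_rr_frame,
)
from . import defaults as _defaults

__all__ = [
    "CohortConfig",
    "sample_profiles",
    "simulate_events",
    "apply_eligibility",
    "simulate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = (
    ["id", "entry_age", "prs"]
    + list(GENES)
    + list(QUESTIONNAIRE_FACTORS)
    + ["fh_count", "prior_cancer", "mastectomy_history", "event", "exit_age", "censor_cause"]
)

_CAUSE_SHARES = {"loss": 0.30, "death": 0.35, "other-cancer": 0.25, "mastectomy": 0.10}


@dataclass
class CohortConfig:
    """Generator configuration; defaults are the package's study conditions."""

    n_women: int = 10_000
    seed: int = 0
    entry_age_weights: dict = field(default_factory=_defaults.default_entry_age_weights)
    missingness: dict = field(default_factory=_defaults.default_missingness)
    #: age-group hazard multipliers as (age_lo, age_hi, multiplier) triples,
    #: applied at the woman's current age; default none (multiplier 1).
    age_multipliers: list = field(default_factory=list)
    #: annual rate of the single competing censoring process collapsing loss,
    #: death, other cancer and mastectomy (causes drawn from censor_cause_shares)
    loss_rate: float = 0.0015
    #: optional age-dependent mortality extension: Gompertz hazard
    #: mu(age) = death_rate_40 * exp(death_log_slope * (age - 40)); off by
    #: default (the constant-rate process already carries deaths)
    death_rate_40: float = 0.0
    death_log_slope: float = 0.088
    #: administrative linkage end, in years after entry: a fixed cap (float)
    #: or a (lo, hi) uniform range emulating a staggered recruitment window
    #: against a fixed linkage date
    admin_followup: object = (10.5, 14.5)
    horizon: float = 10.0
    burn_in: float = 1.0
    age_cap: float = 80.0
    censor_cause_shares: dict = field(default_factory=lambda: dict(_CAUSE_SHARES))
    prior_cancer_prob: float = 0.0
    mastectomy_prob: float = 0.0

    def __post_init__(self):
        if self.n_women < 1:
            raise ConfigError("n_women must be >= 1")
        for p in (self.prior_cancer_prob, self.mastectomy_prob, *self.missingness.values()):
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability out of [0, 1]: {p!r}")
        w = np.array(list(self.entry_age_weights.values()), float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ConfigError("entry age weights must be non-negative with positive sum")
        for lo, hi, m in self.age_multipliers:
            if m < 0:
                raise ConfigError("age-group hazard multipliers must be >= 0")
            if hi <= lo:
                raise ConfigError("age-multiplier bands must satisfy lo < hi")
        admin = self.admin_followup
        if not isinstance(admin, (int, float)):
            admin = tuple(float(x) for x in admin)
            if len(admin) != 2 or not (0 < admin[0] <= admin[1]):
                raise ConfigError("admin_followup range must be (lo, hi) with 0 < lo <= hi")
            self.admin_followup = admin
        elif admin <= 0:
            raise ConfigError("admin_followup must be positive")
        if self.loss_rate < 0 or self.death_rate_40 < 0 or self.horizon <= 0:
            raise ConfigError("censoring rates >= 0 and a positive horizon are required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["entry_age_weights"] = {f"{lo:g}-{hi:g}": w for (lo, hi), w in self.entry_age_weights.items()}
        d["age_multipliers"] = [list(t) for t in self.age_multipliers]
        if isinstance(self.admin_followup, tuple):
            d["admin_followup"] = list(self.admin_followup)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if "entry_age_weights" in d and d["entry_age_weights"] is not None:
            weights = {}
            for key, w in d["entry_age_weights"].items():
                if isinstance(key, str):
                    lo, hi = key.split("-")
                    weights[(float(lo), float(hi))] = float(w)
                else:
                    weights[tuple(map(float, key))] = float(w)
            d["entry_age_weights"] = weights
        if "age_multipliers" in d and d["age_multipliers"] is not None:
            d["age_multipliers"] = [tuple(map(float, t)) for t in d["age_multipliers"]]
        if isinstance(d.get("admin_followup"), (list, tuple)):
            d["admin_followup"] = tuple(map(float, d["admin_followup"]))
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown cohort-config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _age_multiplier_fn(age_multipliers):
    bands = [(float(lo), float(hi), float(m)) for lo, hi, m in age_multipliers]

    def mult(age):
        age = np.asarray(age, float)
        out = np.ones_like(age)
        for lo, hi, m in bands:
            out = np.where((age >= lo) & (age < hi), m, out)
        return out

    return mult


def sample_profiles(
    config: CohortConfig,
    model: RelativeRiskModel | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw entry ages and complete (latent) risk-factor profiles.

    Returns one row per woman with the *true* factor values; missingness is
    applied later so that outcomes can depend on the latent values.
    """
    model = model if model is not None else _defaults.default_model()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_women

    bands = list(config.entry_age_weights.keys())
    w = np.array([config.entry_age_weights[b] for b in bands], float)
    band_idx = rng.choice(len(bands), size=n, p=w / w.sum())
    lows = np.array([b[0] for b in bands])
    highs = np.array([b[1] for b in bands])
    entry_age = lows[band_idx] + rng.random(n) * (highs[band_idx] - lows[band_idx])

    df = pd.DataFrame({"id": np.arange(n), "entry_age": entry_age})
    df["prs"] = rng.standard_normal(n)
    for g in GENES:
        freq = model.pv_freq.get(g, 0.0)
        df[g] = (rng.random(n) < freq).astype(int)
    for name in QUESTIONNAIRE_FACTORS:
        fac = model.factors[name]
        idx = rng.choice(len(fac.categories), size=n, p=fac.freq / fac.freq.sum())
        df[name] = pd.Series(np.asarray(fac.categories, dtype=object)[idx])
    fh = model.factors["family_history"]
    df["fh_count"] = rng.choice(
        np.array([int(c) for c in fh.categories]), size=n, p=fh.freq / fh.freq.sum()
    ).astype(float)
    df["prior_cancer"] = (rng.random(n) < config.prior_cancer_prob).astype(int)
    df["mastectomy_history"] = (rng.random(n) < config.mastectomy_prob).astype(int)
    return df


def simulate_events(
    profiles: pd.DataFrame,
    truth_model: RelativeRiskModel,
    table: IncidenceTable,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    normalize: bool = True,
) -> pd.DataFrame:
    """Simulate outcomes by inverse-transform sampling from individual hazards.

    The per-woman hazard is ``baseline(age) * RR_i * multiplier(age)`` with
    the baseline calibrated so the model-average incidence matches the
    population table.  Integration is exact on the union of table band edges
    and multiplier band edges.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = len(profiles)
    entry = profiles["entry_age"].to_numpy(float)
    window_end = entry + config.burn_in + config.horizon
    rr = combined_rr_frame(
        profiles, truth_model, age=entry + config.burn_in + config.horizon / 2.0,
        normalize=normalize,
    )
    baseline = calibrate_baseline(truth_model, table, normalize=normalize)
    mult = _age_multiplier_fn(config.age_multipliers)

    # exact integration grid: table edges plus multiplier breakpoints
    edges = set(np.append(table.age_start, table.age_end[-1]).tolist())
    for lo, hi, _ in config.age_multipliers:
        for e in (lo, hi):
            if table.age_min < e < table.age_max:
                edges.add(float(e))
    grid = np.array(sorted(edges))
    mid = 0.5 * (grid[:-1] + grid[1:])
    seg_hazard = baseline(mid) * mult(mid)           # population-scale segment hazards
    cum = np.concatenate([[0.0], np.cumsum(seg_hazard * np.diff(grid))])

    def cum_at(age):
        k = np.clip(np.searchsorted(grid, age, side="right") - 1, 0, len(mid) - 1)
        return cum[k] + (age - grid[k]) * seg_hazard[k]

    u = rng.random(n)
    target = cum_at(entry) - np.log(u) / rr
    k = np.clip(np.searchsorted(cum, target, side="right") - 1, 0, len(mid) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_event = grid[k] + (target - cum[k]) / seg_hazard[k]
    t_event = np.where(target >= cum[-1], np.inf, t_event)

    if config.loss_rate > 0:
        t_censor = entry + rng.exponential(1.0 / config.loss_rate, size=n)
    else:
        t_censor = np.full(n, np.inf)
    # all-cause mortality: Gompertz hazard with analytic inverse transform
    mu0, b = config.death_rate_40, config.death_log_slope
    if mu0 > 0:
        e_death = rng.exponential(size=n)
        if b > 0:
            t_death = 40.0 + np.log(np.exp(b * (entry - 40.0)) + b * e_death / mu0) / b
        else:
            t_death = entry + e_death / mu0
    else:
        t_death = np.full(n, np.inf)
    if isinstance(config.admin_followup, tuple):
        lo, hi = config.admin_followup
        t_admin = entry + lo + (hi - lo) * rng.random(n)
    else:
        t_admin = entry + float(config.admin_followup)

    exit_age = np.minimum.reduce(
        [t_event, t_censor, t_death, t_admin, window_end, np.full(n, config.age_cap)]
    )
    event = (t_event <= exit_age) & np.isfinite(t_event)

    cause = np.full(n, "", dtype=object)
    cause_labels = list(config.censor_cause_shares)
    shares = np.array([config.censor_cause_shares[c] for c in cause_labels], float)
    drawn = rng.choice(len(cause_labels), size=n, p=shares / shares.sum())
    censored = ~event
    cause[censored & (exit_age == t_censor)] = np.asarray(cause_labels, dtype=object)[
        drawn[censored & (exit_age == t_censor)]
    ]
    cause[censored & (exit_age == t_death)] = "death"
    cause[censored & (exit_age == window_end)] = "window-end"
    cause[censored & (exit_age == config.age_cap)] = "age-80"
    cause[censored & (exit_age == t_admin) & (cause == "")] = "linkage-end"

    out = profiles.copy()
    out["event"] = event.astype(int)
    out["exit_age"] = exit_age
    out["censor_cause"] = cause
    return out


def _apply_missingness(df: pd.DataFrame, missingness: dict, rng: np.random.Generator) -> pd.DataFrame:
    out = df.copy()
    for name, p in missingness.items():
        if p <= 0:
            continue
        mask = rng.random(len(out)) < p
        if name == "prs":
            out.loc[mask, "prs"] = np.nan
        elif name == "family_history":
            out.loc[mask, "fh_count"] = np.nan
        elif name in QUESTIONNAIRE_FACTORS:
            out.loc[mask, name] = ""
        else:
            raise ConfigError(f"missingness declared for unknown factor {name!r}")
    # age at first live birth is structurally missing for nulliparous women
    if "parity" in out.columns and "first_birth" in out.columns:
        out.loc[out["parity"] == "0", "first_birth"] = ""
    return out


DEFAULT_ELIGIBILITY = ("entry_age", "prior_cancer", "mastectomy", "prevalent_event", "short_followup")


def apply_eligibility(
    records: pd.DataFrame,
    rules=DEFAULT_ELIGIBILITY,
    entry_range=(40.0, 70.0),
    min_followup: float = 1.0,
):
    """Apply prospective-design eligibility rules in order.

    Rules: entry age within ``[40, 70)``; no prior cancer; no prophylactic
    mastectomy history; no event within the first year after entry (prevalent
    cancer proxy); follow-up longer than 1 year.  Each woman is tallied under
    the first rule she fails.  Returns ``(eligible_frame, tally_dict)``.
    """
    df = records
    tally: dict = {}
    for rule in rules:
        if rule == "entry_age":
            bad = (df["entry_age"] < entry_range[0]) | (df["entry_age"] >= entry_range[1])
        elif rule == "prior_cancer":
            bad = df["prior_cancer"] == 1 if "prior_cancer" in df.columns else pd.Series(False, index=df.index)
        elif rule == "mastectomy":
            bad = (
                df["mastectomy_history"] == 1
                if "mastectomy_history" in df.columns
                else pd.Series(False, index=df.index)
            )
        elif rule == "prevalent_event":
            bad = (df["event"] == 1) & (df["exit_age"] <= df["entry_age"] + min_followup)
        elif rule == "short_followup":
            bad = (df["exit_age"] - df["entry_age"]) <= min_followup
        else:
            raise ConfigError(f"unknown eligibility rule {rule!r}")
        tally[rule] = int(bad.sum())
        df = df[~bad]
    return df.reset_index(drop=True), tally


def simulate_cohort(
    config: CohortConfig,
    truth_model: RelativeRiskModel | None = None,
    table: IncidenceTable | None = None,
    apply_rules: bool = True,
):
    """Full generator: profiles -> events -> missingness -> eligibility.

    Uses independent child random streams per stage (profiles, events,
    censoring causes, missingness) spawned from the master seed, so stages
    are individually reproducible.  Returns ``(cohort_frame, exclusion_tally)``.
    """
    truth_model = truth_model if truth_model is not None else _defaults.default_model()
    table = table if table is not None else _defaults.synthetic_incidence_table()
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(3)]
    profiles = sample_profiles(config, truth_model, streams[0])
    records = simulate_events(profiles, truth_model, table, config, streams[1])
    records = _apply_missingness(records, config.missingness, streams[2])
    if apply_rules:
        records, tally = apply_eligibility(records)
    else:
        tally = {}
    return records[COHORT_COLUMNS], tally


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort frame with a stable column order and float format."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.10g")


def read_cohort_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            dtype={name: str for name in QUESTIONNAIRE_FACTORS},
            float_precision="round_trip",
        )
    except FileNotFoundError as exc:
        raise DataError(f"cohort file not found: {path}") from exc
    for name in QUESTIONNAIRE_FACTORS:
        if name in df.columns:
            df[name] = df[name].fillna("")
    return df
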