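"""Config-driven orchestration: simulate -> predict -> validate -> classify.

Pure plumbing over the library modules: a :class:`RunConfig` names the model
variants (factor subsets), strata and threshold schemes; :func:`run_pipeline`
executes the stages deterministically for a master seed, writes every product
as CSV into one run directory, and records a manifest (config hash, seed,
library versions, per-stage row counts and wall times).  No statistic is
computed here.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    ALT_TEN_YEAR,
    NICE_TEN_YEAR,
    RELATIVE_RR,
    classification_table,
)
from .cohort import CohortConfig, read_cohort_csv, simulate_cohort, write_cohort_csv
from .defaults import default_model, synthetic_incidence_table
from .errors import ConfigError, DataError
from .incidence import IncidenceTable, load_incidence_csv
from .model import RelativeRiskModel, predict_cohort
from .validation import decile_calibration, validation_report

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_VARIANTS", "default_strata"]

DEFAULT_VARIANTS = (
    "AGE",
    "FH",
    "QRF",
    "PRS",
    "FH+QRF",
    "FH+PRS",
    "QRF+PRS",
    "FH+QRF+PRS",
    "FH+QRF+PRS+PV",
)

_SCHEMES = {"rr": RELATIVE_RR, "nice10": NICE_TEN_YEAR, "alt10": ALT_TEN_YEAR}


def default_strata(cohort: pd.DataFrame) -> dict:
    """Age-at-entry split at 50 plus pathogenic-variant carrier status."""
    entry = cohort["entry_age"].to_numpy(float)
    from .model import GENES

    carrier = np.zeros(len(cohort), dtype=bool)
    for g in GENES:
        if g in cohort.columns:
            carrier |= cohort[g].to_numpy(float) == 1.0
    return {"under50": entry < 50.0, "50plus": entry >= 50.0, "pv_carrier": carrier}


@dataclass
class RunConfig:
    """One pipeline run: cohort conditions, model variants, schemes."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    variants: tuple = DEFAULT_VARIANTS
    schemes: tuple = ("rr", "nice10", "alt10")
    incidence_path: str | None = None
    model_path: str | None = None
    cohort_path: str | None = None  # reuse an existing cohort instead of simulating

    def __post_init__(self):
        if len(set(self.variants)) != len(tuple(self.variants)):
            raise ConfigError("variant names must be unique")
        unknown = set(self.schemes) - set(_SCHEMES)
        if unknown:
            raise ConfigError(f"unknown threshold schemes: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cohort = CohortConfig.from_dict(d.pop("cohort", {}) or {})
        return cls(
            cohort=cohort,
            variants=tuple(d.pop("variants", DEFAULT_VARIANTS)),
            schemes=tuple(d.pop("schemes", ("rr", "nice10", "alt10"))),
            incidence_path=d.pop("incidence_path", None),
            model_path=d.pop("model_path", None),
            cohort_path=d.pop("cohort_path", None),
        )

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "variants": list(self.variants),
            "schemes": list(self.schemes),
            "incidence_path": self.incidence_path,
            "model_path": self.model_path,
            "cohort_path": self.cohort_path,
        }


def _load_inputs(config: RunConfig) -> tuple[RelativeRiskModel, IncidenceTable]:
    model = (
        RelativeRiskModel.from_yaml(config.model_path)
        if config.model_path
        else default_model()
    )
    table = (
        load_incidence_csv(config.incidence_path)
        if config.incidence_path
        else synthetic_incidence_table()
    )
    return model, table


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None) -> dict:
    """Execute all stages into ``out_dir``; returns the manifest dict.

    ``seed`` overrides the cohort config seed.  Identical config + seed give
    byte-identical outputs.  A failure in any stage propagates with the
    package's error types so the CLI can map it to an exit code.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        config.cohort.seed = int(seed)
    model, table = _load_inputs(config)
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.cohort.seed,
        "versions": {
            "bcrisk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(rows):
            manifest["stages"][name] = {
                "rows": int(rows),
                "seconds": round(time.perf_counter() - t0, 3),
            }

        return done

    # ---- simulate ----------------------------------------------------------
    mark = stage("simulate")
    if config.cohort_path:
        cohort = read_cohort_csv(config.cohort_path)
        tally = {}
    else:
        cohort, tally = simulate_cohort(config.cohort, model, table)
    if len(cohort) == 0:
        raise DataError("cohort is empty after eligibility filtering")
    write_cohort_csv(cohort, out / "cohort.csv")
    manifest["exclusions"] = tally
    mark(len(cohort))

    # ---- predict -----------------------------------------------------------
    mark = stage("predict")
    predictions = {}
    for variant in config.variants:
        pred = predict_cohort(cohort, model, table, factors_enabled=variant)
        pred.to_csv(out / f"predictions_{_slug(variant)}.csv", index=False)
        predictions[variant] = pred
    mark(sum(len(p) for p in predictions.values()))

    # ---- validate ----------------------------------------------------------
    mark = stage("validate")
    strata = default_strata(cohort)
    pairs_by_variant = {
        v: pd.DataFrame(
            {
                "abs_risk": p["abs_risk"].to_numpy(),
                "event": cohort["event"].to_numpy(float),
                "entry_age": cohort["entry_age"].to_numpy(float),
                "exit_age": cohort["exit_age"].to_numpy(float),
            }
        )
        for v, p in predictions.items()
    }
    report = validation_report(pairs_by_variant, strata)
    report.to_csv(out / "validation_report.csv", index=False)
    for variant, pairs in pairs_by_variant.items():
        dec = decile_calibration(pairs["abs_risk"], pairs["event"])
        dec.to_csv(out / f"deciles_{_slug(variant)}.csv", index=False)
    mark(len(report))

    # ---- classify ----------------------------------------------------------
    mark = stage("classify")
    rows = 0
    for scheme_name in config.schemes:
        scheme = _SCHEMES[scheme_name]
        for variant, pred in predictions.items():
            values = (
                pred["risk_ratio"].to_numpy()
                if scheme.kind == "relative"
                else pred["abs_risk"].to_numpy()
            )
            tab = classification_table(values, cohort["event"], scheme, strata)
            tab.insert(0, "variant", variant)
            tab.insert(0, "scheme", scheme_name)
            tab.to_csv(out / f"classification_{scheme_name}_{_slug(variant)}.csv", index=False)
            rows += len(tab)
    mark(rows)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _slug(variant: str) -> str:
    return variant.replace("+", "_").replace(" ", "").lower()
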