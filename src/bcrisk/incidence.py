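"""Population incidence tables and absolute-risk arithmetic.

An :class:`IncidenceTable` holds age-specific breast-cancer incidence rates
(events per 100,000 woman-years) on contiguous half-open age bands
``[start, end)``, optionally labelled with a calendar period.  Hazards are
piecewise constant within bands, so every cumulative quantity is exact band
arithmetic: the cumulative hazard between two ages is a sum of
``rate x width`` terms, and the absolute risk of a first event in an interval
under a proportional hazard multiplier ``rr`` is ``1 - exp(-rr * hazard)``.

The same arithmetic converts between risk scales:

* 10-year absolute risk at a given age (capped at age 80),
* lifetime risk accumulated over a configurable window (default 20-80), and
* the relative-risk multiplier equivalent to a lifetime-risk threshold,
  ``rr = -ln(1 - threshold) / cumulative_hazard(20, 80)``, which is how
  guideline lifetime categories (17%, 30%) translate into hazard-ratio
  cut-points.

No competing-mortality adjustment is applied: risks are cause-specific
cumulative incidences.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from importlib import resources

import numpy as np
import pandas as pd

from .errors import AgeRangeError, ConfigError, DataError

__all__ = [
    "IncidenceTable",
    "load_incidence_csv",
    "packaged_incidence_table",
]


@dataclass(frozen=True)
class IncidenceTable:
    """Age-specific incidence rates on contiguous half-open age bands.

    Parameters
    ----------
    age_start, age_end : array-like of float
        Band boundaries in years; band ``i`` covers ``[age_start[i], age_end[i])``.
        Bands must be sorted, non-empty and contiguous (no gaps or overlaps).
    rate : array-like of float
        Incidence rate per 100,000 woman-years in each band; finite, >= 0.
    period : str, optional
        Calendar-period label.  Period-specific analyses switch whole tables;
        no interpolation between periods is performed.
    """

    age_start: np.ndarray
    age_end: np.ndarray
    rate: np.ndarray
    period: str | None = None

    def __post_init__(self) -> None:
        start = np.asarray(self.age_start, dtype=float)
        end = np.asarray(self.age_end, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        object.__setattr__(self, "age_start", start)
        object.__setattr__(self, "age_end", end)
        object.__setattr__(self, "rate", rate)
        if start.ndim != 1 or start.shape != end.shape or start.shape != rate.shape:
            raise ConfigError("age_start, age_end and rate must be 1-d arrays of equal length")
        if start.size == 0:
            raise ConfigError("incidence table needs at least one age band")
        if not (np.isfinite(start).all() and np.isfinite(end).all()):
            raise ConfigError("age band boundaries must be finite")
        if np.any(end <= start):
            raise ConfigError("every age band must satisfy start < end")
        if np.any(start[1:] != end[:-1]):
            raise ConfigError("age bands must be contiguous (band i+1 starts where band i ends)")
        if not np.isfinite(rate).all() or np.any(rate < 0):
            raise ConfigError("rates must be finite and non-negative")

    # ------------------------------------------------------------------ basics
    @property
    def age_min(self) -> float:
        return float(self.age_start[0])

    @property
    def age_max(self) -> float:
        return float(self.age_end[-1])

    @cached_property
    def _edges(self) -> np.ndarray:
        return np.append(self.age_start, self.age_end[-1])

    @cached_property
    def _cumhaz_edges(self) -> np.ndarray:
        """Cumulative hazard from ``age_min`` to each band edge."""
        widths = self.age_end - self.age_start
        return np.concatenate([[0.0], np.cumsum(widths * self.rate / 1e5)])

    def _check_in_range(self, age: np.ndarray, *, upper_open: bool) -> None:
        age = np.asarray(age, dtype=float)
        bad_high = age > self.age_max if not upper_open else age >= self.age_max
        bad = (age < self.age_min) | bad_high | ~np.isfinite(age)
        if np.any(bad):
            offending = np.atleast_1d(age)[np.atleast_1d(bad)][0]
            raise AgeRangeError(
                f"age {offending!r} outside incidence table range "
                f"[{self.age_min}, {self.age_max})"
            )

    # -------------------------------------------------------------- operations
    def hazard_at(self, age):
        """Hazard (per woman-year) at ``age``: ``rate/100000`` of the band containing it."""
        age = np.asarray(age, dtype=float)
        self._check_in_range(age, upper_open=True)
        idx = np.searchsorted(self._edges, age, side="right") - 1
        idx = np.clip(idx, 0, self.rate.size - 1)
        out = self.rate[idx] / 1e5
        return float(out) if out.ndim == 0 else out

    def cumulative_hazard(self, start_age, end_age):
        """Exact integral of the piecewise-constant hazard over ``[start_age, end_age)``."""
        start_age = np.asarray(start_age, dtype=float)
        end_age = np.asarray(end_age, dtype=float)
        if np.any(start_age >= end_age):
            raise DataError("cumulative hazard requires start_age < end_age")
        self._check_in_range(start_age, upper_open=True)
        self._check_in_range(end_age, upper_open=False)
        out = self._cumhaz_at(end_age) - self._cumhaz_at(start_age)
        return float(out) if out.ndim == 0 else out

    def _cumhaz_at(self, age: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self._edges, age, side="right") - 1
        idx = np.clip(idx, 0, self.rate.size - 1)
        return self._cumhaz_edges[idx] + (age - self._edges[idx]) * self.rate[idx] / 1e5

    def cumulative_risk(self, start_age, end_age, rr=1.0):
        """Absolute risk of a first event in ``[start_age, end_age)`` under multiplier ``rr``.

        Returns ``1 - exp(-rr * H)`` with ``H`` the cumulative population
        hazard over the interval; always in ``[0, 1)``.
        """
        rr = np.asarray(rr, dtype=float)
        if np.any(rr < 0) or not np.isfinite(rr).all():
            raise DataError("relative risk multiplier must be finite and >= 0")
        out = -np.expm1(-rr * self.cumulative_hazard(start_age, end_age))
        return float(out) if out.ndim == 0 else out

    def population_ten_year_risk(self, age, cap: float = 80.0):
        """Population 10-year absolute risk from ``age``, window capped at ``cap``."""
        age = np.asarray(age, dtype=float)
        end = np.minimum(age + 10.0, cap)
        out = self.cumulative_risk(age, end, 1.0)
        return float(out) if np.ndim(out) == 0 else out

    def lifetime_hazard(self, from_age: float = 20.0, to_age: float = 80.0) -> float:
        return float(self.cumulative_hazard(from_age, to_age))

    def lifetime_risk(self, from_age: float = 20.0, to_age: float = 80.0, rr: float = 1.0) -> float:
        return float(self.cumulative_risk(from_age, to_age, rr))

    def rr_threshold_from_lifetime(
        self, lifetime_threshold: float, from_age: float = 20.0, to_age: float = 80.0
    ) -> float:
        """Hazard multiplier whose lifetime risk over ``[from_age, to_age)`` equals the threshold.

        Solves ``1 - exp(-r * H_life) = threshold`` exactly:
        ``r = -ln(1 - threshold) / H_life``.
        """
        if not (0.0 < lifetime_threshold < 1.0):
            raise DataError(
                f"lifetime threshold must be in (0, 1); got {lifetime_threshold!r}"
            )
        h_life = self.lifetime_hazard(from_age, to_age)
        if h_life <= 0.0:
            raise DataError("table has zero lifetime cumulative hazard; threshold undefined")
        return float(-np.log1p(-lifetime_threshold) / h_life)

    # --------------------------------------------------------------------- I/O
    @classmethod
    def from_bands(cls, bands, period: str | None = None) -> "IncidenceTable":
        """Build from an iterable of ``(age_start, age_end, rate_per_100k)``."""
        arr = np.asarray(list(bands), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ConfigError("bands must be (start, end, rate) triples")
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], period=period)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, period: str | None = None) -> "IncidenceTable":
        required = {"age_start", "age_end", "rate_per_100k"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"incidence table missing columns: {sorted(missing)}")
        df = df.sort_values("age_start", kind="stable")
        if period is None and "period" in df.columns:
            labels = df["period"].dropna().unique()
            if len(labels) > 1:
                raise DataError(
                    "incidence CSV holds several periods; pass `period` to select one"
                )
            period = str(labels[0]) if len(labels) == 1 else None
        elif period is not None and "period" in df.columns:
            df = df[df["period"].astype(str) == str(period)]
            if df.empty:
                raise DataError(f"no incidence rows for period {period!r}")
        return cls(
            df["age_start"].to_numpy(float),
            df["age_end"].to_numpy(float),
            df["rate_per_100k"].to_numpy(float),
            period=period,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "age_start": self.age_start,
                "age_end": self.age_end,
                "rate_per_100k": self.rate,
            }
        )
        if self.period is not None:
            df["period"] = self.period
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_incidence_csv(path, period: str | None = None) -> IncidenceTable:
    """Read an incidence table from CSV (``age_start,age_end,rate_per_100k[,period]``)."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError as exc:
        raise DataError(f"incidence file not found: {path}") from exc
    return IncidenceTable.from_frame(df, period=period)


def packaged_incidence_table() -> IncidenceTable:
    """The illustrative synthetic incidence table shipped with the package.

    A smooth, registry-shaped synthetic curve (not national statistics) with a
    10-year risk of ~3.6% at age 58, so that relative-risk thresholds of 1.6
    and 3.1 translate to 10-year absolute thresholds near 5.8% and 11%.
    """
    with resources.files("bcrisk").joinpath("data/incidence_synthetic.csv").open("rb") as fh:
        return IncidenceTable.from_frame(pd.read_csv(fh), period="synthetic")
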