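"""Record-level cohort handling and quarterly life-table aggregation.

A surveillance cohort arrives as one row per neonatal death (birth and
death date-times at minute resolution, a verbal-autopsy flag, and an
underlying cause code) plus quarterly live-birth tallies.  This module
applies the analyzability filters, assigns deaths to age bands and
calendar quarters, and aggregates them into :class:`QuarterLifeTable`
objects carrying the cumulative cause-specific mortality probabilities
``q[x, c]`` (per live birth) that the log-quadratic model consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidRecordError, PostNeonatalDeath
from .quarters import Quarter, quarter_range

NEONATAL_HOURS = 672  # 28 days

DEFAULT_CAUSES = ("preterm", "asphyxia", "sepsis", "pneumonia", "congenital", "other")
MODELLED_CAUSES = DEFAULT_CAUSES[:-1]


@dataclass(frozen=True)
class CauseSet:
    """Ordered cause codes; ``other`` is a catch-all that is never modelled."""

    codes: tuple[str, ...] = DEFAULT_CAUSES

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("cause codes must be unique")
        if "other" not in self.codes:
            raise ValueError("cause set must include the 'other' catch-all")

    @property
    def modelled(self) -> tuple[str, ...]:
        return tuple(c for c in self.codes if c != "other")

    def index(self, code: str) -> int:
        return self.codes.index(code)

    def canonical(self, code: str) -> str:
        """Map codes outside the set onto the ``other`` catch-all."""
        return code if code in self.codes else "other"

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(self.codes)


@dataclass(frozen=True)
class AgeGroupScheme:
    """Cumulative age-group upper bounds in completed hours.

    The default four groups (24, 48, 168, 672) are the first day, the
    second day, the remainder of the first week, and weeks two to four.
    Bands are half-open ``[lower, upper)`` except the last, which closes
    at 672 h: a death at exactly 672 completed hours is still neonatal.
    """

    bounds: tuple[int, ...] = (24, 48, 168, NEONATAL_HOURS)
    labels: tuple[str, ...] = ("0-23h", "0-47h", "0h-6 days", "0h-4weeks")

    def __post_init__(self) -> None:
        if list(self.bounds) != sorted(set(self.bounds)):
            raise ValueError("bounds must be strictly increasing")
        if self.bounds[-1] != NEONATAL_HOURS:
            raise ValueError(f"last bound must be {NEONATAL_HOURS} hours")
        if len(self.labels) != len(self.bounds):
            raise ValueError("one label per cumulative age group")

    @property
    def n_bands(self) -> int:
        return len(self.bounds)

    @property
    def band_labels(self) -> tuple[str, ...]:
        lowers = (0,) + self.bounds[:-1]
        return tuple(
            f"{lo}-{hi - 1}h" for lo, hi in zip(lowers, self.bounds)
        )


@dataclass(frozen=True)
class DeathRecord:
    """One neonatal death from mortality surveillance.

    ``death_dt`` is absent when the time of death is unknown (age in
    hours cannot be determined); ``cause`` is absent when no verbal
    autopsy was done or the VA yielded no underlying cause.
    """

    record_id: str
    birth_dt: pd.Timestamp
    death_dt: pd.Timestamp | None
    has_va: bool
    cause: str | None

    def __post_init__(self) -> None:
        if self.death_dt is not None and self.death_dt < self.birth_dt:
            raise InvalidRecordError(
                f"record {self.record_id}: death_dt precedes birth_dt"
            )
        if self.cause is not None and not self.has_va:
            raise InvalidRecordError(
                f"record {self.record_id}: cause present without verbal autopsy"
            )


def filter_analyzable(
    records: Iterable[DeathRecord],
) -> tuple[list[DeathRecord], dict[str, int]]:
    """Keep deaths with a known time of death and a verbal autopsy.

    Returns the retained records and an exclusion tally with keys
    ``no_time`` and ``no_va``.  A record missing both is counted once,
    under ``no_time`` (that priority order keeps the tally additive:
    retained + sum(tally) == input count).
    """
    retained: list[DeathRecord] = []
    tally = {"no_time": 0, "no_va": 0}
    for rec in records:
        if rec.death_dt is None:
            tally["no_time"] += 1
        elif not rec.has_va:
            tally["no_va"] += 1
        else:
            retained.append(rec)
    return retained, tally


def age_at_death_hours(birth_dt: pd.Timestamp, death_dt: pd.Timestamp) -> int:
    """Completed hours between birth and death (floor of the difference)."""
    if death_dt < birth_dt:
        raise InvalidRecordError("death_dt precedes birth_dt")
    delta = death_dt - birth_dt
    return int(math.floor(delta.total_seconds() / 3600.0))


def assign_age_band(age_hours: int, scheme: AgeGroupScheme | None = None) -> int:
    """Zero-based age-band index for an age in completed hours.

    Bands are ``[lower, upper)`` except the last, closed at 672 h.
    Ages beyond 672 h raise :class:`PostNeonatalDeath`.
    """
    scheme = scheme or AgeGroupScheme()
    if age_hours < 0:
        raise InvalidRecordError("negative age at death")
    if age_hours > scheme.bounds[-1]:
        raise PostNeonatalDeath(f"age {age_hours}h exceeds the neonatal period")
    for i, upper in enumerate(scheme.bounds):
        if age_hours < upper:
            return i
    return scheme.n_bands - 1  # exactly 672 h: closed last bound


@dataclass(frozen=True)
class QuarterLifeTable:
    """One calendar quarter's births, deaths and cumulative mortality.

    ``deaths`` is indexed ``[age band, cause]``; ``cum_q[x, c]`` is the
    cumulative probability of dying of cause ``c`` by the upper bound of
    cumulative age group ``x``, per live birth; ``nmr`` is the all-cause
    neonatal mortality probability.  Tables built with
    :meth:`from_deaths` satisfy ``cum_q[x,c] = cumsum(deaths)[x,c] /
    live_births`` and ``nmr = sum_c cum_q[last, c]``.  Model-generated
    surfaces may be constructed directly (``deaths=None``) with the nmr
    covariate supplied, since predictions are not bound by those count
    identities.
    """

    quarter: Quarter
    live_births: int
    cum_q: np.ndarray
    nmr: float
    causes: tuple[str, ...]
    age_labels: tuple[str, ...]
    deaths: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_deaths(
        cls,
        quarter: Quarter,
        live_births: int,
        deaths: np.ndarray,
        causes: Sequence[str],
        scheme: AgeGroupScheme | None = None,
    ) -> "QuarterLifeTable":
        scheme = scheme or AgeGroupScheme()
        if live_births <= 0:
            raise ValueError(f"{quarter}: live_births must be positive")
        deaths = np.asarray(deaths, dtype=float)
        if deaths.shape != (scheme.n_bands, len(causes)):
            raise ValueError(
                f"{quarter}: deaths matrix must be (bands={scheme.n_bands}, "
                f"causes={len(causes)}), got {deaths.shape}"
            )
        cum_q = deaths.cumsum(axis=0) / live_births
        nmr = float(cum_q[-1].sum())
        return cls(
            quarter=quarter,
            live_births=live_births,
            cum_q=cum_q,
            nmr=nmr,
            causes=tuple(causes),
            age_labels=scheme.labels,
            deaths=deaths,
        )

    def cause_q(self, cause: str) -> np.ndarray:
        """Cumulative mortality trajectory for one cause."""
        return self.cum_q[:, self.causes.index(cause)]

    def cause_nmr(self, cause: str) -> float:
        """28-day cumulative mortality for one cause (its cause-specific NMR)."""
        return float(self.cause_q(cause)[-1])


def build_quarter_tables(
    records: Iterable[DeathRecord],
    birth_tallies: Mapping[Quarter, int] | pd.DataFrame,
    scheme: AgeGroupScheme | None = None,
    causes: CauseSet | None = None,
    quarters: Sequence[Quarter] | None = None,
) -> tuple[list[QuarterLifeTable], dict[str, int]]:
    """Aggregate filtered deaths into one life table per calendar quarter.

    Deaths are assigned to the quarter containing the death date; the
    denominator is the quarter's live-birth tally.  Quarters with zero
    deaths are still emitted.  ``quarters`` defaults to every quarter
    with a birth tally.  Returns the tables plus an exclusion tally:
    post-neonatal deaths (age > 672 h) and deaths outside the quarter
    range are counted, never silently dropped.  Cause codes outside the
    configured set are pooled into ``other``.
    """
    scheme = scheme or AgeGroupScheme()
    causes = causes or CauseSet()
    if isinstance(birth_tallies, pd.DataFrame):
        birth_tallies = {
            Quarter(int(r.year), int(r.quarter)): int(r.live_births)
            for r in birth_tallies.itertuples()
        }
    if quarters is None:
        quarters = sorted(birth_tallies)
    for q in quarters:
        if q not in birth_tallies:
            raise ValueError(f"no live-birth tally for quarter {q}")
        if birth_tallies[q] <= 0:
            raise ValueError(f"{q}: live_births must be positive")

    counts = {q: np.zeros((scheme.n_bands, len(causes))) for q in quarters}
    tally = {"post_neonatal": 0, "out_of_range": 0}
    for rec in records:
        if rec.death_dt is None:
            raise InvalidRecordError(
                f"record {rec.record_id}: unfiltered record with unknown death time"
            )
        age = age_at_death_hours(rec.birth_dt, rec.death_dt)
        try:
            band = assign_age_band(age, scheme)
        except PostNeonatalDeath:
            tally["post_neonatal"] += 1
            continue
        q = Quarter.of(rec.death_dt)
        if q not in counts:
            tally["out_of_range"] += 1
            continue
        cause = causes.canonical(rec.cause) if rec.cause is not None else "other"
        counts[q][band, causes.index(cause)] += 1

    tables = [
        QuarterLifeTable.from_deaths(
            q, birth_tallies[q], counts[q], tuple(causes), scheme
        )
        for q in quarters
    ]
    return tables, tally


# ---------------------------------------------------------------------------
# CSV dialects
#
# cohort CSV: record_id, birth_datetime (ISO-8601), death_datetime (ISO-8601
# or empty), has_va (0/1), cause (code or empty).
# births CSV: year, quarter, live_births.
# life-table CSV (long): quarter, age_label, cause, deaths, cum_q, with the
# per-quarter live_births and nmr repeated on every row.
# ---------------------------------------------------------------------------


def _parse_dt(value: str, row_id: str, column: str) -> pd.Timestamp:
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"row {row_id}: malformed {column} {value!r}") from exc
    if pd.isna(ts):
        raise ValueError(f"row {row_id}: malformed {column} {value!r}")
    return ts


def read_cohort_csv(path, causes: CauseSet | None = None) -> list[DeathRecord]:
    """Strictly parse a cohort CSV; malformed rows raise with the row named."""
    causes = causes or CauseSet()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["record_id", "birth_datetime", "death_datetime", "has_va", "cause"]
    if list(df.columns) != expected:
        raise ValueError(f"cohort CSV must have columns {expected}, got {list(df.columns)}")
    records: list[DeathRecord] = []
    for row in df.itertuples(index=False):
        rid = row.record_id
        birth = _parse_dt(row.birth_datetime, rid, "birth_datetime")
        death = (
            _parse_dt(row.death_datetime, rid, "death_datetime")
            if row.death_datetime
            else None
        )
        if row.has_va not in ("0", "1"):
            raise ValueError(f"row {rid}: has_va must be 0 or 1, got {row.has_va!r}")
        has_va = row.has_va == "1"
        cause = row.cause or None
        if cause is not None and cause not in causes.codes:
            raise ValueError(f"row {rid}: unknown cause code {cause!r}")
        records.append(DeathRecord(rid, birth, death, has_va, cause))
    return records


def write_cohort_csv(records: Iterable[DeathRecord], path) -> None:
    df = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "birth_datetime": [r.birth_dt.isoformat() for r in records],
            "death_datetime": [
                r.death_dt.isoformat() if r.death_dt is not None else ""
                for r in records
            ],
            "has_va": [int(r.has_va) for r in records],
            "cause": [r.cause or "" for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_births_csv(path) -> dict[Quarter, int]:
    df = pd.read_csv(path)
    expected = ["year", "quarter", "live_births"]
    if list(df.columns) != expected:
        raise ValueError(f"births CSV must have columns {expected}, got {list(df.columns)}")
    return {
        Quarter(int(r.year), int(r.quarter)): int(r.live_births)
        for r in df.itertuples()
    }


def write_births_csv(tallies: Mapping[Quarter, int], path) -> None:
    rows = sorted(tallies.items())
    pd.DataFrame(
        {
            "year": [q.year for q, _ in rows],
            "quarter": [q.q for q, _ in rows],
            "live_births": [n for _, n in rows],
        }
    ).to_csv(path, index=False)


def write_life_tables_csv(tables: Sequence[QuarterLifeTable], path) -> None:
    """Long-format life-table CSV; full float precision for round-tripping."""
    rows = []
    for t in tables:
        deaths = t.deaths if t.deaths is not None else np.full_like(t.cum_q, np.nan)
        for xi, label in enumerate(t.age_labels):
            for ci, cause in enumerate(t.causes):
                rows.append(
                    {
                        "quarter": str(t.quarter),
                        "age_label": label,
                        "cause": cause,
                        "deaths": float(deaths[xi, ci]),
                        "cum_q": repr(float(t.cum_q[xi, ci])),
                        "live_births": t.live_births,
                        "nmr": repr(float(t.nmr)),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_life_tables_csv(path) -> list[QuarterLifeTable]:
    df = pd.read_csv(path)
    tables = []
    for qid, grp in df.groupby("quarter", sort=False):
        quarter = Quarter.parse(str(qid))
        age_labels = tuple(dict.fromkeys(grp["age_label"]))
        causes = tuple(dict.fromkeys(grp["cause"]))
        cum_q = np.empty((len(age_labels), len(causes)))
        deaths = np.empty_like(cum_q)
        for row in grp.itertuples():
            xi = age_labels.index(row.age_label)
            ci = causes.index(row.cause)
            cum_q[xi, ci] = float(row.cum_q)
            deaths[xi, ci] = float(row.deaths)
        tables.append(
            QuarterLifeTable(
                quarter=quarter,
                live_births=int(grp["live_births"].iloc[0]),
                cum_q=cum_q,
                nmr=float(grp["nmr"].iloc[0]),
                causes=causes,
                age_labels=age_labels,
                deaths=None if np.isnan(deaths).any() else deaths,
            )
        )
    return sorted(tables, key=lambda t: t.quarter)
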