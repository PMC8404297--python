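"""From individual-level event records to stratified person-years, national
rates, and expected counts under internal (indirect) standardization.

One disease-specific *study population* contains every person of at least the
minimum age at the study start, alive and resident at that date, without a
prior diagnosis of the disease.  Follow-up runs from the study start to the
first of incident diagnosis, death, emigration, or the administrative end of
study.  Person-years at risk are accumulated per (area, stratum) where a
stratum is a (sex, age group, income group) combination; age is
time-varying, while area and income are calendar-year assignments.  Expected
counts apply national stratum rates to local stratum person-years:

    E[i, j] = sum_k R[j, k] * T[i, j, k]

which makes ``sum_i E[i, j] = sum_i Y[i, j]`` an exact identity when the
rates come from the same data (internal standardization).

Conventions: half-open follow-up intervals [entry, exit); person-years are
days / 365.25; the study population is closed (fixed at the start date —
persons reaching the minimum age later are not enrolled); on ties, an event
on the same day as death counts as an event.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import (
    AGE_BREAKS,
    AGE_GROUPS,
    DISEASES,
    INCOME_GROUPS,
    SEXES,
    SyntheticCohort,
)

__all__ = [
    "StudyWindow",
    "ExposureCube",
    "NationalRates",
    "ExpectedCounts",
    "ObservedCounts",
    "STRATUM_LABELS",
    "build_study_population",
    "person_years_by_stratum",
    "national_rates",
    "expected_counts",
    "crude_rate_table",
    "crude_rate_table_from_margins",
    "cohort_to_mapping_inputs",
]

DAYS_PER_YEAR = 365.25

#: fixed nested stratum order: sexes x age groups x income groups (income fastest)
STRATUM_LABELS = tuple(
    (s, a, i) for s, a, i in product(SEXES, AGE_GROUPS, INCOME_GROUPS)
)
_STRATUM_INDEX = {lab: k for k, lab in enumerate(STRATUM_LABELS)}
N_STRATA = len(STRATUM_LABELS)  # 2 * 4 * 3 = 24


@dataclass(frozen=True)
class StudyWindow:
    """Closed-cohort study window; ``end`` is the last day of follow-up."""

    start: pd.Timestamp = pd.Timestamp("2014-01-01")
    end: pd.Timestamp = pd.Timestamp("2015-12-31")
    min_age: float = 30.0

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.start > self.end:
            raise ValueError("study window start must be <= end")
        if self.min_age < 0:
            raise ValueError("minimum age must be >= 0")

    @property
    def end_exclusive(self) -> pd.Timestamp:
        return self.end + pd.Timedelta(days=1)


@dataclass(frozen=True)
class ExposureCube:
    """Person-years at risk T[area, disease, stratum]."""

    T: np.ndarray
    area_ids: tuple
    diseases: tuple = DISEASES
    stratum_labels: tuple = STRATUM_LABELS

    def __post_init__(self):
        if self.T.shape != (len(self.area_ids), len(self.diseases), N_STRATA):
            raise ValueError(f"exposure cube shape {self.T.shape} inconsistent")
        if np.any(self.T < 0):
            raise ValueError("negative person-years")

    def national_py(self) -> np.ndarray:
        """(disease, stratum) person-year totals."""
        return self.T.sum(axis=0)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.area_ids):
            for j, d in enumerate(self.diseases):
                for k, lab in enumerate(self.stratum_labels):
                    rows.append((a, d, *lab, self.T[i, j, k]))
        return pd.DataFrame(
            rows, columns=["area", "disease", "sex", "age_group", "income", "person_years"]
        )


@dataclass(frozen=True)
class NationalRates:
    """National incidence rates R[disease, stratum] per person-year."""

    R: np.ndarray
    diseases: tuple = DISEASES
    stratum_labels: tuple = STRATUM_LABELS

    def __post_init__(self):
        if np.any(self.R < 0):
            raise ValueError("negative rates")


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected cases E[area, disease] under internal standardization."""

    E: np.ndarray
    area_ids: tuple
    diseases: tuple = DISEASES


@dataclass(frozen=True)
class ObservedCounts:
    """Observed incident cases Y[area, disease]; optionally with the
    per-stratum breakdown ``by_stratum`` (area, disease, stratum)."""

    Y: np.ndarray
    area_ids: tuple
    diseases: tuple = DISEASES
    by_stratum: Optional[np.ndarray] = None

    def __post_init__(self):
        if np.any(self.Y < 0):
            raise ValueError("negative counts")


# ---------------------------------------------------------------------------
# Study populations
# ---------------------------------------------------------------------------

def build_study_population(
    cohort,
    disease: str,
    window: StudyWindow = StudyWindow(),
) -> pd.DataFrame:
    """Per-person follow-up intervals with event indicator for one disease.

    ``cohort`` is a :class:`~comap.synthetic.SyntheticCohort` or a persons
    DataFrame with columns id, birth_date, death_date, emigration_date and
    ``dx_<disease>``.  Exclusions: prior diagnosis (before the window start),
    under the minimum age at the window start (closed cohort), dead or
    emigrated before the window start.

    Returns columns id, entry, exit, event, reason with half-open intervals
    [entry, exit); ``reason`` is one of event, death, emigration,
    admin-censor.  An event on the start date itself counts as incident
    (with zero person-time).
    """
    persons = cohort.persons if isinstance(cohort, SyntheticCohort) else cohort
    col = f"dx_{disease}"
    if col not in persons.columns:
        raise ValueError(f"no diagnosis column {col!r} for disease {disease!r}")
    p = persons.copy()
    for c in ("birth_date", "death_date", "emigration_date", col):
        p[c] = pd.to_datetime(p[c])
    start, end_excl = window.start, window.end_exclusive

    bad = p["death_date"].notna() & (p["death_date"] < p["birth_date"])
    if bad.any():
        raise ValueError(
            f"records with death before birth: ids {p.loc[bad, 'id'].tolist()[:5]}"
        )

    age_at_start = (start - p["birth_date"]).dt.days / DAYS_PER_YEAR
    keep = (
        (age_at_start >= window.min_age)
        & ~(p[col].notna() & (p[col] < start))          # prior diagnosis
        & ~(p["death_date"].notna() & (p["death_date"] < start))
        & ~(p["emigration_date"].notna() & (p["emigration_date"] < start))
    )
    p = p[keep].copy()

    exits = pd.DataFrame(
        {
            "event": p[col].where(p[col] >= start),
            "death": p["death_date"],
            "emigration": p["emigration_date"],
            "admin-censor": end_excl,
        },
        index=p.index,
    )
    exit_date = exits.min(axis=1)
    # tie precedence: event > death > emigration > admin-censor (column order)
    reason = exits.eq(exit_date, axis=0).idxmax(axis=1)
    out = pd.DataFrame(
        {
            "id": p["id"].to_numpy(),
            "entry": start,
            "exit": exit_date.to_numpy(),
            "event": (reason == "event").to_numpy(),
            "reason": reason.to_numpy(),
        }
    )
    if (out["exit"] < out["entry"]).any():
        bad_ids = out.loc[out["exit"] < out["entry"], "id"].tolist()
        raise ValueError(f"exit before entry for ids {bad_ids[:5]}")
    # zero-length non-event rows (e.g. death on the start date) carry no
    # person-time and no case; drop them
    out = out[(out["exit"] > out["entry"]) | out["event"]].reset_index(drop=True)
    return out


def _age_group_of(days_of_age: float) -> int:
    age = days_of_age / DAYS_PER_YEAR
    if age >= 80:
        return 3
    if age >= 70:
        return 2
    if age >= 60:
        return 1
    return 0


def _split_person(entry, exit_, birth) -> list:
    """Split one follow-up interval at 1 January and age-group birthdays.

    Returns (frag_start, frag_end, year, age_group_index) tuples.
    The age-group boundary is the first day on which (date - birth) in
    days / 365.25 reaches the group's lower bound.
    """
    bounds = set()
    for y in range(entry.year + 1, exit_.year + 1):
        ts = pd.Timestamp(year=y, month=1, day=1)
        if entry < ts < exit_:
            bounds.add(ts)
    for a in AGE_BREAKS[1:]:
        ts = birth + pd.Timedelta(days=int(np.ceil(a * DAYS_PER_YEAR)))
        if entry < ts < exit_:
            bounds.add(ts)
    cuts = [entry] + sorted(bounds) + [exit_]
    out = []
    for b0, b1 in zip(cuts[:-1], cuts[1:]):
        out.append((b0, b1, b0.year, _age_group_of((b0 - birth).days)))
    return out


def person_years_by_stratum(
    population: pd.DataFrame,
    persons: pd.DataFrame,
    person_years: pd.DataFrame,
    area_ids: Sequence,
    window: StudyWindow = StudyWindow(),
) -> tuple:
    """Accumulate follow-up into (area, stratum) person-year and case arrays.

    Each person's interval is split at every 1 January (area and income
    reassignment), at every age-group-boundary birthday, and at exit;
    fragment lengths in days / 365.25 accumulate into ``T[area, stratum]``.
    Cases accumulate into ``cases[area, stratum]`` at the stratum and area in
    force at the exit date.

    Returns ``(T, cases)`` with shapes (n_areas, 24).
    """
    area_index = {a: i for i, a in enumerate(area_ids)}
    pinfo = persons.set_index("id")
    birth = pd.to_datetime(pinfo["birth_date"])
    sex = pinfo["sex"]
    assign: Dict = {}
    for row in person_years.itertuples(index=False):
        assign[(row.id, int(row.year))] = (row.area, row.income)

    T = np.zeros((len(area_ids), N_STRATA))
    cases = np.zeros((len(area_ids), N_STRATA), dtype=int)
    sex_idx = {s: i for i, s in enumerate(SEXES)}
    inc_idx = {g: i for i, g in enumerate(INCOME_GROUPS)}

    for row in population.itertuples(index=False):
        pid = row.id
        frags = _split_person(row.entry, row.exit, birth[pid])
        s_i = sex_idx[sex[pid]]
        last = None
        for b0, b1, year, ag in frags:
            key = (pid, year)
            if key not in assign:
                raise ValueError(f"no area/income assignment for person {pid}, year {year}")
            area, income = assign[key]
            if area not in area_index:
                raise ValueError(f"unknown area {area!r} for person {pid}")
            k = s_i * 12 + ag * 3 + inc_idx[income]
            T[area_index[area], k] += (b1 - b0).days / DAYS_PER_YEAR
            last = (area_index[area], k)
        if row.event:
            if last is None:  # zero-length interval: event on the entry date
                year = row.exit.year
                area, income = assign[(pid, year)]
                ag = _age_group_of((row.exit - birth[pid]).days)
                last = (area_index[area], s_i * 12 + ag * 3 + inc_idx[income])
            cases[last] += 1
    return T, cases


def national_rates(cases_by_stratum: np.ndarray, exposures: ExposureCube) -> NationalRates:
    """R[j, k] = national cases / national person-years within stratum k.

    ``cases_by_stratum`` has shape (n_areas, n_diseases, 24) or already
    nationally aggregated (n_diseases, 24).  Strata with zero cases get rate
    0; cases without person-years are an error.
    """
    c = np.asarray(cases_by_stratum, dtype=float)
    if c.ndim == 3:
        c = c.sum(axis=0)
    py = exposures.national_py()
    if np.any((c > 0) & (py == 0)):
        raise ValueError("stratum with cases but zero person-years")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(py > 0, c / np.where(py > 0, py, 1.0), 0.0)
    return NationalRates(R, exposures.diseases, exposures.stratum_labels)


def expected_counts(rates: NationalRates, exposures: ExposureCube,
                    observed: Optional[ObservedCounts] = None) -> ExpectedCounts:
    """E[i, j] = sum_k R[j, k] T[i, j, k].

    If ``observed`` is given, cells with E = 0 but Y > 0 raise (the Poisson
    model is undefined there).
    """
    if rates.R.shape != exposures.T.shape[1:]:
        raise ValueError("rates and exposure cube shapes do not align")
    E = np.einsum("jk,ijk->ij", rates.R, exposures.T)
    if observed is not None and np.any((E == 0) & (observed.Y > 0)):
        raise ValueError("cells with expected count 0 but observed cases > 0")
    return ExpectedCounts(E, exposures.area_ids, exposures.diseases)


# ---------------------------------------------------------------------------
# Crude-rate summary (cohort characteristics table)
# ---------------------------------------------------------------------------

def _ir(cases, py):
    return np.round(np.divide(cases, py, out=np.zeros_like(np.asarray(py, float)),
                              where=np.asarray(py) > 0) * 10_000, 1)


def crude_rate_table(cases_by_stratum: np.ndarray, exposures: ExposureCube) -> pd.DataFrame:
    """Cohort-characteristics summary: cases, person-years and crude IR per
    10,000 PY by total, sex, age group and income group, per disease."""
    c = np.asarray(cases_by_stratum, dtype=float)
    if c.ndim == 3:
        c = c.sum(axis=0)
    py = exposures.national_py()
    J = len(exposures.diseases)
    # reshape (disease, sex, age, income)
    c4 = c.reshape(J, 2, 4, 3)
    p4 = py.reshape(J, 2, 4, 3)
    rows = []
    for j, d in enumerate(exposures.diseases):
        rows.append((d, "Total", "", c4[j].sum(), p4[j].sum()))
        for s_i, s in enumerate(SEXES):
            rows.append((d, "Sex", s, c4[j, s_i].sum(), p4[j, s_i].sum()))
        for a_i, a in enumerate(AGE_GROUPS):
            rows.append((d, "Age", a, c4[j, :, a_i].sum(), p4[j, :, a_i].sum()))
        for i_i, g in enumerate(INCOME_GROUPS):
            rows.append((d, "Income", g, c4[j, :, :, i_i].sum(), p4[j, :, :, i_i].sum()))
    df = pd.DataFrame(rows, columns=["disease", "margin", "level", "cases", "person_years"])
    df["ir_per_10k"] = _ir(df["cases"].to_numpy(), df["person_years"].to_numpy())
    return df


def crude_rate_table_from_margins(margins: pd.DataFrame) -> pd.DataFrame:
    """Crude IRs (per 10,000 PY, one decimal) from pre-aggregated margins.

    ``margins`` needs columns disease, margin, level, cases, person_years —
    e.g. the printed characteristics table of a published cohort used as an
    aggregated input fixture.
    """
    df = margins.copy()
    df["ir_per_10k"] = _ir(df["cases"].to_numpy(float), df["person_years"].to_numpy(float))
    return df


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def cohort_to_mapping_inputs(
    cohort: SyntheticCohort,
    area_ids: Sequence,
    window: StudyWindow = StudyWindow(),
    diseases: Iterable[str] = DISEASES,
) -> dict:
    """Run the full cohort stage: study populations, exposure cube, national
    rates, observed and expected counts.

    Returns a dict with keys populations, exposures, cases_by_stratum,
    rates, observed, expected, crude_table.
    """
    diseases = tuple(diseases)
    n_areas = len(area_ids)
    T = np.zeros((n_areas, len(diseases), N_STRATA))
    C = np.zeros((n_areas, len(diseases), N_STRATA), dtype=int)
    populations = {}
    for j, d in enumerate(diseases):
        pop = build_study_population(cohort, d, window)
        populations[d] = pop
        T[:, j, :], C[:, j, :] = person_years_by_stratum(
            pop, cohort.persons, cohort.person_years, area_ids, window
        )
    exposures = ExposureCube(T, tuple(area_ids), diseases)
    rates = national_rates(C, exposures)
    observed = ObservedCounts(C.sum(axis=2), tuple(area_ids), diseases, by_stratum=C)
    expected = expected_counts(rates, exposures, observed)
    return {
        "populations": populations,
        "exposures": exposures,
        "cases_by_stratum": C,
        "rates": rates,
        "observed": observed,
        "expected": expected,
        "crude_table": crude_rate_table(C, exposures),
    }
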