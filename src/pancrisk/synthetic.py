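"""Synthetic longitudinal EHR cohort simulator with planted risk structure.

Real pancreatic-cancer EHR cohorts of the kind this package targets are
access-restricted, so all development and testing runs on simulated
cohorts.  The simulator emulates the statistical shape of such data:

* irregularly spaced diagnosis/medication events from a per-patient
  homogeneous Poisson visit process whose rate is itself log-normally
  distributed across patients (heavy-tailed trajectory lengths);
* per-visit codes drawn from stream-specific Zipf-like frequency
  distributions over opaque token vocabularies;
* demographic margins of a predominantly male clinical population (~87% male,
  ~80% White);
* a rare cancer outcome drawn from an exponential time-to-event model with
  a piecewise-constant age effect, where *planted risk codes* multiply the
  hazard from their first occurrence onward — making ground truth
  analytically checkable;
* optional *order pairs* (code A before code B) whose multiplier activates
  only when A precedes B, giving an order-sensitive signal that
  order-free representations cannot fully capture.

The base rate is calibrated by root-finding so that the expected case
fraction matches ``target_case_fraction``.  All dates are integer days from
1970-01-01; day precision throughout.  Given a seed, generation is
bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger("pancrisk")

EPOCH = date(1970, 1, 1)
DAYS_PER_YEAR = 365.25

#: hazard multiplier by attained-age band (band start year, multiplier)
AGE_HAZARD = ((0, 0.05), (50, 1.0), (60, 1.6), (70, 2.2), (80, 2.8))

#: age bands used for incidence stratification; 85+ is open-ended
AGE_BANDS = [(50, 55), (55, 60), (60, 65), (65, 70), (70, 75), (75, 80), (80, 85), (85, None)]
RACES = ("White", "Black", "Other")
SEXES = ("Male", "Female")


def day_to_iso(day: int) -> str:
    return (EPOCH + timedelta(days=int(day))).isoformat()


def iso_to_day(s: str) -> int:
    return (date.fromisoformat(s) - EPOCH).days


def age_band_label(age_years: float) -> str:
    """Stratification band containing an attained age; '<50' below fifty."""
    if age_years < 50:
        return "<50"
    for lo, hi in AGE_BANDS:
        if hi is None or age_years < hi:
            if age_years >= lo:
                return f"{lo}-{hi - 1}" if hi is not None else "85+"
    raise ValueError(f"unmapped age {age_years}")


def _age_mult(age_years: float) -> float:
    m = AGE_HAZARD[0][1]
    for start, mult in AGE_HAZARD:
        if age_years >= start:
            m = mult
    return m


def dx_code(i: int) -> str:
    """Opaque three-character diagnosis token (e.g. 'A07')."""
    return f"{chr(ord('A') + i // 100)}{i % 100:02d}"


def rx_code(i: int) -> str:
    """Opaque medication-ingredient token (e.g. 'M012')."""
    return f"M{i:03d}"


@dataclass
class PatientRecord:
    """One patient's demographics and ordered event history.

    ``events`` is an ordered list of ``(code, day, stream)`` with stream
    'dx' or 'rx'; all days are integer days since the epoch.
    """

    patient_id: str
    birth_day: int
    sex: str
    race: str
    events: list  # [(code: str, day: int, stream: str)]
    record_end: int
    cancer_day: int | None = None

    def validate(self) -> None:
        days = [d for _, d, _ in self.events]
        if any(a > b for a, b in zip(days, days[1:])):
            raise ValueError(f"{self.patient_id}: events not sorted by date")
        for code, d, stream in self.events:
            if stream not in ("dx", "rx"):
                raise ValueError(f"{self.patient_id}: unknown stream {stream!r}")
            if d < self.birth_day:
                raise ValueError(f"{self.patient_id}: event {code} predates birth")
        if self.cancer_day is not None and self.cancer_day > self.record_end:
            raise ValueError(f"{self.patient_id}: cancer_day after record_end")

    @property
    def is_case(self) -> bool:
        return self.cancer_day is not None

    def age_years(self, day: int) -> float:
        return (day - self.birth_day) / DAYS_PER_YEAR

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_id": self.patient_id,
                "birth_date": day_to_iso(self.birth_day),
                "sex": self.sex,
                "race": self.race,
                "cancer_date": None if self.cancer_day is None else day_to_iso(self.cancer_day),
                "record_end": day_to_iso(self.record_end),
                "events": [[c, day_to_iso(d), s] for c, d, s in self.events],
            },
            separators=(",", ":"),
        )

    @classmethod
    def from_json(cls, line: str) -> "PatientRecord":
        obj = json.loads(line)
        rec = cls(
            patient_id=obj["patient_id"],
            birth_day=iso_to_day(obj["birth_date"]),
            sex=obj["sex"],
            race=obj["race"],
            events=[(c, iso_to_day(d), s) for c, d, s in obj["events"]],
            record_end=iso_to_day(obj["record_end"]),
            cancer_day=None if obj.get("cancer_date") is None else iso_to_day(obj["cancer_date"]),
        )
        rec.validate()
        return rec


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort generator.

    Defaults emulate the margins of the target population: ~87% male, ~80%
    White, heavy-tailed trajectory lengths (median on the order of 10-20
    events/year over 2-14 year records) and a rare outcome (0.13% cases,
    the evaluation-cohort fraction; development-style cohorts enrich this).
    """

    n_patients: int = 10_000
    target_case_fraction: float = 0.0013
    n_dx_codes: int = 100
    n_rx_codes: int = 50
    planted_risk_codes: tuple = (("A60", 8.0), ("M035", 4.0))
    order_pairs: tuple = ()  # ((code_a, code_b, multiplier), ...)
    visit_rate: float = 18.0  # mean events/year across dx+rx
    rate_dispersion: float = 0.8  # sigma of the log-normal rate mixture
    p_dx: float = 0.65  # fraction of events that are diagnoses
    record_span_years: tuple = (2.0, 14.0)
    age_range_years: tuple = (52.0, 86.0)  # age at end of record
    male_fraction: float = 0.867
    race_fractions: tuple = (("White", 0.80), ("Black", 0.17), ("Other", 0.03))
    zipf_exponent: float = 1.1
    base_rate: float | None = None  # cases/person-year at age band 50-59; calibrated if None
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_dx_codes <= 0 or self.n_rx_codes <= 0:
            raise ValueError("vocabulary sizes must be positive")
        if not 0.0 <= self.target_case_fraction <= 1.0:
            raise ValueError("target_case_fraction must be in [0,1]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0,1]")
        fr = [f for _, f in self.race_fractions]
        if any(not 0 <= f <= 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("race fractions must be proportions summing to 1")
        for code, mult in self.planted_risk_codes:
            if mult < 1.0:
                raise ValueError(f"hazard multiplier for {code} must be >= 1")
        for a, b, mult in self.order_pairs:
            if mult < 1.0:
                raise ValueError(f"order-pair multiplier for ({a},{b}) must be >= 1")
        vocab = set(self.dx_vocab()) | set(self.rx_vocab())
        planted = [c for c, _ in self.planted_risk_codes]
        planted += [c for pair in self.order_pairs for c in pair[:2]]
        missing = [c for c in planted if c not in vocab]
        if missing:
            raise ValueError(f"planted codes not in vocabulary: {missing}")

    def dx_vocab(self) -> list[str]:
        return [dx_code(i) for i in range(self.n_dx_codes)]

    def rx_vocab(self) -> list[str]:
        return [rx_code(i) for i in range(self.n_rx_codes)]


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def _hazard_segments(rec: PatientRecord, start_day: int, modifiers: list) -> list:
    """Piecewise-constant hazard modifier timeline over [start_day, record_end).

    ``modifiers`` is a list of (activation_day, multiplier).  Returns
    [(t0, t1, modifier), ...] where modifier folds in the age effect.
    """
    breaks = {start_day, rec.record_end}
    for start, _ in AGE_HAZARD:
        day = rec.birth_day + int(round(start * DAYS_PER_YEAR))
        if start_day < day < rec.record_end:
            breaks.add(day)
    for day, _ in modifiers:
        if start_day < day < rec.record_end:
            breaks.add(day)
    cut = sorted(breaks)
    segs = []
    for t0, t1 in zip(cut, cut[1:]):
        # midpoint: cut days are rounded, so the age at t0 can sit a hair
        # below the band boundary the cut represents
        mod = _age_mult(rec.age_years((t0 + t1) / 2))
        for day, mult in modifiers:
            if day <= t0:
                mod *= mult
        segs.append((t0, t1, mod))
    return segs


def _active_modifiers(rec: PatientRecord, config: SimConfig) -> list:
    """Activation day and multiplier for every planted signal this patient carries."""
    first_occ: dict[str, int] = {}
    for code, day, _ in rec.events:
        if code not in first_occ:
            first_occ[code] = day
    mods = []
    for code, mult in config.planted_risk_codes:
        if code in first_occ:
            mods.append((first_occ[code], mult))
    for code_a, code_b, mult in config.order_pairs:
        if code_a in first_occ and code_b in first_occ and first_occ[code_a] < first_occ[code_b]:
            mods.append((first_occ[code_b], mult))
    return mods


def generate_cohort(config: SimConfig):
    """Simulate a cohort; returns ``(records, metadata)``.

    ``metadata`` carries the generator's ground truth: the calibrated base
    rate and, per patient, the carried planted signals, the integrated
    hazard modifier over the record, and the instantaneous hazard at the
    end of record (the quantity a perfect risk ranker would sort by).
    """
    rng = np.random.default_rng(config.seed)
    p_dx_codes = _zipf_probs(config.n_dx_codes, config.zipf_exponent)
    p_rx_codes = _zipf_probs(config.n_rx_codes, config.zipf_exponent)
    dx_vocab = np.array(config.dx_vocab())
    rx_vocab = np.array(config.rx_vocab())
    race_names = [r for r, _ in config.race_fractions]
    race_p = [f for _, f in config.race_fractions]

    records: list[PatientRecord] = []
    for i in range(config.n_patients):
        sex = "Male" if rng.random() < config.male_fraction else "Female"
        race = race_names[rng.choice(len(race_names), p=race_p)]
        age_end = rng.uniform(*config.age_range_years)
        span = rng.uniform(*config.record_span_years)
        start_day = int(rng.integers(0, 3650))
        record_end = start_day + int(round(span * DAYS_PER_YEAR))
        birth_day = record_end - int(round(age_end * DAYS_PER_YEAR))

        rate = config.visit_rate * rng.lognormal(-config.rate_dispersion**2 / 2, config.rate_dispersion)
        n_events = rng.poisson(rate * span)
        days = np.sort(rng.integers(start_day, record_end + 1, size=n_events))
        is_dx = rng.random(n_events) < config.p_dx
        codes = np.where(
            is_dx,
            dx_vocab[rng.choice(config.n_dx_codes, size=n_events, p=p_dx_codes)],
            rx_vocab[rng.choice(config.n_rx_codes, size=n_events, p=p_rx_codes)],
        )
        events = [
            (str(c), int(d), "dx" if f else "rx") for c, d, f in zip(codes, days, is_dx)
        ]
        records.append(
            PatientRecord(
                patient_id=f"P{i:06d}",
                birth_day=birth_day,
                sex=sex,
                race=race,
                events=events,
                record_end=record_end,
            )
        )

    # integrated hazard modifier per patient (person-years weighted by the
    # age- and code-dependent multiplier), for base-rate calibration
    seg_cache = []
    integrated = np.zeros(config.n_patients)
    for i, rec in enumerate(records):
        start_day = rec.events[0][1] if rec.events else rec.record_end
        segs = _hazard_segments(rec, start_day, _active_modifiers(rec, config))
        seg_cache.append(segs)
        integrated[i] = sum((t1 - t0) / DAYS_PER_YEAR * m for t0, t1, m in segs)

    if config.base_rate is not None:
        base = config.base_rate
    elif config.target_case_fraction <= 0 or integrated.sum() == 0:
        base = 0.0
    else:

        def excess(b):
            return np.mean(1.0 - np.exp(-b * integrated)) - config.target_case_fraction

        hi = 1.0
        while excess(hi) < 0 and hi < 1e6:
            hi *= 10
        base = brentq(excess, 0.0, hi, xtol=1e-12)

    # draw cancer onsets: exponential threshold per patient
    thresholds = rng.exponential(1.0, size=config.n_patients)
    meta_patients = {}
    for i, rec in enumerate(records):
        cum = 0.0
        for t0, t1, mod in seg_cache[i]:
            lam = base * mod / DAYS_PER_YEAR  # hazard per day
            seg_haz = lam * (t1 - t0)
            if cum + seg_haz >= thresholds[i] and lam > 0:
                onset = t0 + (thresholds[i] - cum) / lam
                rec.cancer_day = min(int(onset), rec.record_end)
                break
            cum += seg_haz
        end_mod = seg_cache[i][-1][2] if seg_cache[i] else _age_mult(rec.age_years(rec.record_end))
        meta_patients[rec.patient_id] = {
            "carried": [c for c, _ in config.planted_risk_codes if any(e[0] == c for e in rec.events)],
            "integrated_modifier": float(integrated[i]),
            "hazard_at_end": float(base * end_mod),
            "is_case": rec.is_case,
        }
    metadata = {
        "base_rate": float(base),
        "planted_risk_codes": list(map(list, config.planted_risk_codes)),
        "order_pairs": list(map(list, config.order_pairs)),
        "patients": meta_patients,
        "config": asdict(config),
    }
    return records, metadata


# ---------------------------------------------------------------------------
# incidence table
# ---------------------------------------------------------------------------


class IncidenceTable:
    """Annual incidence rate per (age band, race, sex) stratum.

    Backed by a DataFrame with columns ``age_group, race, sex, annual_rate``.
    Strata with zero person-years carry a missing rate and are flagged.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"age_group", "race", "sex", "annual_rate"}
        if not required.issubset(df.columns):
            raise ValueError(f"incidence table needs columns {sorted(required)}")
        if df.duplicated(["age_group", "race", "sex"]).any():
            raise ValueError("duplicate strata in incidence table")
        if (df["annual_rate"].dropna() < 0).any():
            raise ValueError("negative incidence rate")
        self.df = df.reset_index(drop=True)
        self._lookup = {
            (r.age_group, r.race, r.sex): r.annual_rate for r in df.itertuples()
        }

    def rate(self, age_years: float, race: str, sex: str) -> float:
        key = (age_band_label(age_years), race, sex)
        if key not in self._lookup:
            raise KeyError(f"stratum not in incidence table: {key}")
        val = self._lookup[key]
        if pd.isna(val):
            raise KeyError(f"stratum has no person-time in incidence table: {key}")
        return float(val)

    def to_csv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.df.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path) -> "IncidenceTable":
        return cls(pd.read_csv(path, comment="#"))


def build_incidence_table(cohort: list) -> IncidenceTable:
    """Stratified annual incidence observed in a cohort.

    Person-time runs from each patient's first event to cancer diagnosis or
    end of record, split at age-band boundaries; each case counts once in
    the stratum where the diagnosis fell.  Applying the table back to the
    same cohort reproduces the total case count exactly.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    py: dict[tuple, float] = {}
    cases: dict[tuple, int] = {}
    band_starts = [50 + 5 * k for k in range(8)]
    for rec in cohort:
        start = rec.events[0][1] if rec.events else rec.record_end
        end = rec.cancer_day if rec.cancer_day is not None else rec.record_end
        if end < start:
            start = end
        cuts = {start, end}
        for b in band_starts:
            day = rec.birth_day + int(round(b * DAYS_PER_YEAR))
            if start < day < end:
                cuts.add(day)
        cut = sorted(cuts)
        for t0, t1 in zip(cut, cut[1:]):
            key = (age_band_label(rec.age_years((t0 + t1) / 2)), rec.race, rec.sex)
            py[key] = py.get(key, 0.0) + (t1 - t0) / DAYS_PER_YEAR
        if rec.cancer_day is not None:
            key = (age_band_label(rec.age_years(rec.cancer_day)), rec.race, rec.sex)
            cases[key] = cases.get(key, 0) + 1
            py.setdefault(key, 0.0)

    labels = ["<50"] + [age_band_label(b) for b in band_starts]
    rows = []
    for label in labels:
        for race in RACES:
            for sex in SEXES:
                key = (label, race, sex)
                if key not in py:
                    continue
                if py[key] > 0:
                    rate = cases.get(key, 0) / py[key]
                else:
                    rate = float("nan")
                    logger.warning("stratum %s has cases but zero person-years", key)
                rows.append({"age_group": label, "race": race, "sex": sex, "annual_rate": rate})
    return IncidenceTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------


def write_cohort(cohort: list, path, header: str | None = None) -> None:
    """Write one JSON patient record per line; optional '#' header line."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for rec in cohort:
            fh.write(rec.to_json() + "\n")


def read_cohort(path) -> list:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                records.append(PatientRecord.from_json(line))
            except (ValueError, KeyError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid patient record: {exc}") from exc
    if not records:
        logger.warning("cohort file %s is empty", path)
    return records
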