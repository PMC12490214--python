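"""Turn patient records into model-ready trajectories.

A *trajectory* is a prediction-ready subsequence of a patient's history: all
events up to a chosen endpoint (capped at the most recent ``max_len``),
each carrying its time delta in days to the endpoint, plus five cumulative
binary labels y1..y5 for the horizons 0-3, 0-6, 0-12, 0-36 and 0-60 months.

Preparation applies the protocol's filtering and sampling rules:

* diagnosis codes are truncated to three-character categories; medication
  codes on an inactive-ingredient stoplist are dropped;
* for cancer patients, all events within an exclusion window (0, 3 or 12
  months) before diagnosis are removed, suppressing quasi-symptoms;
* training endpoints are sampled uniformly among eligible events — strictly
  before (diagnosis - exclusion window) for cases, and at least two years
  before end of record for controls (so a missed diagnosis shortly after
  the record would be unlikely);
* evaluation uses the last four eligible endpoints, deterministically.

Cancer patients can legitimately produce all-zero labels when the endpoint
falls more than 60 months before diagnosis; such trajectories are hard
negatives, not errors.  Horizons that extend beyond a control's end of
record are marked unobservable in ``censor_mask`` (optionally zero-filled
instead, which reproduces the simpler convention of treating them as
negative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import PatientRecord

logger = logging.getLogger("pancrisk")

HORIZON_MONTHS = (3, 6, 12, 36, 60)
DAYS_PER_MONTH = 30.44
#: horizon boundaries in days: round(months * 30.44)
HORIZON_DAYS = tuple(int(round(m * DAYS_PER_MONTH)) for m in HORIZON_MONTHS)
CONTROL_LOOKAHEAD_DAYS = 730  # two-year negative-sampling rule
PAD_TOKEN = "<pad>"


@dataclass
class Trajectory:
    """A prediction-ready subsequence ending at ``endpoint_day``."""

    patient_id: str
    tokens: list  # joint-vocabulary tokens, "DX:"/"RX:" prefixed
    deltas: np.ndarray  # days before endpoint, >= 0
    endpoint_day: int
    age_days: int  # patient age at endpoint, in days
    labels: np.ndarray  # y1..y5, cumulative indicators
    censor_mask: np.ndarray  # 1 where the horizon is observable
    sex: str = ""
    race: str = ""
    days_to_cancer: int | None = None  # endpoint -> diagnosis gap, cases only

    def __post_init__(self):
        self.deltas = np.asarray(self.deltas, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.censor_mask = np.asarray(self.censor_mask, dtype=np.int64)
        if (self.deltas < 0).any():
            raise ValueError("negative time delta")
        if (np.diff(self.labels) < 0).any():
            raise ValueError("labels must be non-decreasing across horizons")


def normalize_codes(record: PatientRecord, inactive_stoplist: set | frozenset = frozenset()) -> PatientRecord:
    """Truncate dx codes to three characters and drop stoplisted rx codes.

    Event order is preserved.  Diagnosis codes shorter than three characters
    are kept verbatim with a warning.
    """
    events = []
    for code, day, stream in record.events:
        if stream == "dx":
            if len(code) < 3:
                logger.warning("%s: dx code %r shorter than 3 characters", record.patient_id, code)
            events.append((code[:3], day, stream))
        else:
            if code not in inactive_stoplist:
                events.append((code, day, stream))
    return PatientRecord(
        patient_id=record.patient_id,
        birth_day=record.birth_day,
        sex=record.sex,
        race=record.race,
        events=events,
        record_end=record.record_end,
        cancer_day=record.cancer_day,
    )


def exclusion_window_days(window_months: int) -> int:
    return int(round(window_months * DAYS_PER_MONTH))


def apply_exclusion_window(record: PatientRecord, window_months: int) -> PatientRecord:
    """Drop events within ``window_months`` before the cancer diagnosis.

    An event exactly at the boundary (``cancer_day - event_day == window``)
    is retained.  Controls and window 0 pass through unchanged.
    """
    if record.cancer_day is None or window_months == 0:
        return record
    window = exclusion_window_days(window_months)
    events = [e for e in record.events if record.cancer_day - e[1] >= window]
    if record.events and not events:
        logger.warning("%s: all events fall in the exclusion window", record.patient_id)
    return PatientRecord(
        patient_id=record.patient_id,
        birth_day=record.birth_day,
        sex=record.sex,
        race=record.race,
        events=events,
        record_end=record.record_end,
        cancer_day=record.cancer_day,
    )


def make_interval_labels(
    endpoint_day: int,
    cancer_day: int | None,
    record_end: int,
    censoring: str = "mask",
) -> tuple[np.ndarray, np.ndarray]:
    """Five cumulative labels and their observability mask for one endpoint.

    ``y_t = 1`` iff cancer occurs within horizon t of the endpoint (boundary
    inclusive).  For horizons with ``y_t = 0``, the horizon is observable
    only if follow-up (to diagnosis or end of record) covers it; with
    ``censoring='zero_fill'`` every horizon is treated as observed.
    """
    if cancer_day is not None and endpoint_day >= cancer_day:
        raise ValueError("endpoint must precede the cancer diagnosis")
    labels = np.zeros(5, dtype=np.int64)
    mask = np.ones(5, dtype=np.int64)
    followup = (cancer_day if cancer_day is not None else record_end) - endpoint_day
    for t, h in enumerate(HORIZON_DAYS):
        if cancer_day is not None and cancer_day - endpoint_day <= h:
            labels[t] = 1
        elif followup < h:
            mask[t] = 0
    if censoring == "zero_fill":
        mask[:] = 1
    elif censoring != "mask":
        raise ValueError("censoring must be 'mask' or 'zero_fill'")
    return labels, mask


def _eligible_endpoint_indices(record: PatientRecord, exclusion_months: int) -> list[int]:
    if record.cancer_day is not None:
        limit = record.cancer_day - exclusion_window_days(exclusion_months)
        return [i for i, e in enumerate(record.events) if e[1] < limit]
    limit = record.record_end - CONTROL_LOOKAHEAD_DAYS
    return [i for i, e in enumerate(record.events) if e[1] <= limit]


def _build_trajectory(
    record: PatientRecord,
    endpoint_idx: int,
    max_len: int,
    censoring: str,
) -> Trajectory:
    endpoint_day = record.events[endpoint_idx][1]
    window = record.events[max(0, endpoint_idx + 1 - max_len) : endpoint_idx + 1]
    tokens = [f"{s.upper()}:{c}" for c, _, s in window]
    deltas = np.array([endpoint_day - d for _, d, _ in window], dtype=np.int64)
    labels, mask = make_interval_labels(endpoint_day, record.cancer_day, record.record_end, censoring)
    return Trajectory(
        patient_id=record.patient_id,
        tokens=tokens,
        deltas=deltas,
        endpoint_day=endpoint_day,
        age_days=endpoint_day - record.birth_day,
        labels=labels,
        censor_mask=mask,
        sex=record.sex,
        race=record.race,
        days_to_cancer=None if record.cancer_day is None else record.cancer_day - endpoint_day,
    )


def sample_training_trajectories(
    record: PatientRecord,
    k: int,
    rng: np.random.Generator,
    max_len: int = 300,
    exclusion_months: int = 0,
    censoring: str = "mask",
) -> list[Trajectory]:
    """Sample up to ``k`` random-endpoint trajectories from one patient.

    Endpoints are drawn uniformly without replacement among eligible events;
    a patient with no eligible endpoint yields an empty list (skipped this
    epoch).  The record must already be normalized and exclusion-filtered.
    """
    eligible = _eligible_endpoint_indices(record, exclusion_months)
    if not eligible:
        return []
    take = min(k, len(eligible))
    chosen = rng.choice(len(eligible), size=take, replace=False)
    return [_build_trajectory(record, eligible[i], max_len, censoring) for i in sorted(chosen)]


def select_eval_trajectories(
    record: PatientRecord,
    max_len: int = 300,
    exclusion_months: int = 0,
    censoring: str = "mask",
    n_last: int = 4,
) -> list[Trajectory]:
    """The (up to) four latest eligible endpoints — deterministic, seed-free."""
    eligible = _eligible_endpoint_indices(record, exclusion_months)
    return [_build_trajectory(record, i, max_len, censoring) for i in eligible[-n_last:]]


def prepare_cohort(
    cohort: list,
    exclusion_months: int = 3,
    inactive_stoplist: set | frozenset = frozenset(),
) -> list:
    """Normalize codes and apply the exclusion window to every record."""
    out = []
    for rec in cohort:
        rec = normalize_codes(rec, inactive_stoplist)
        rec = apply_exclusion_window(rec, exclusion_months)
        out.append(rec)
    return out


def build_vocab(cohort: list) -> dict[str, int]:
    """Joint dx+rx token vocabulary; index 0 is the padding token."""
    tokens = sorted({f"{s.upper()}:{c}" for rec in cohort for c, _, s in rec.events})
    vocab = {PAD_TOKEN: 0}
    for t in tokens:
        vocab[t] = len(vocab)
    return vocab


# --- JSONL persistence of prepared trajectories ----------------------------


def write_trajectories(trajs: list, path, header: str | None = None) -> None:
    import json

    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for t in trajs:
            fh.write(
                json.dumps(
                    {
                        "patient_id": t.patient_id,
                        "tokens": t.tokens,
                        "deltas": t.deltas.tolist(),
                        "endpoint_day": t.endpoint_day,
                        "age_days": t.age_days,
                        "labels": t.labels.tolist(),
                        "censor_mask": t.censor_mask.tolist(),
                        "sex": t.sex,
                        "race": t.race,
                        "days_to_cancer": t.days_to_cancer,
                    },
                    separators=(",", ":"),
                )
                + "\n"
            )


def read_trajectories(path) -> list:
    import json

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                obj = json.loads(line)
                out.append(
                    Trajectory(
                        patient_id=obj["patient_id"],
                        tokens=obj["tokens"],
                        deltas=np.array(obj["deltas"]),
                        endpoint_day=obj["endpoint_day"],
                        age_days=obj["age_days"],
                        labels=np.array(obj["labels"]),
                        censor_mask=np.array(obj["censor_mask"]),
                        sex=obj.get("sex", ""),
                        race=obj.get("race", ""),
                        days_to_cancer=obj.get("days_to_cancer"),
                    )
                )
            except (ValueError, KeyError, json.JSONDecodeError) as exc:
                raise ValueError(f"{path}:{lineno}: invalid trajectory: {exc}") from exc
    return out
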