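"""Surveillance-oriented evaluation: AUROC, PPV, IR, SIR, calibration.

A risk model is useful for surveillance if the few thousand patients it
ranks highest are truly at elevated risk.  Besides discrimination (AUROC
with a bootstrap CI), this module quantifies that directly:

* **PPV** — fraction of the top-N cohort who develop cancer within the
  horizon;
* **IR** — PPV divided by the population incidence for the horizon;
* **SIR** — observed cases in the top-N cohort divided by the cases
  *expected* from a stratified (age band x race x sex) annual incidence
  table, letting patients age across band boundaries year by year, with the
  95% CI ``(sqrt(N_obs) +/- 0.98)^2 / N_exp``.

A horizon of m months sums the yearly incidence over ``t in
{0 .. ceil(m/12)-1}`` attained years (sub-year horizons query only t=0;
ages are floored when querying the table).  A variant that sums one
extra year offset for multi-year windows is available via ``printed_T``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .synthetic import IncidenceTable, age_band_label

logger = logging.getLogger("pancrisk")


@dataclass
class EvalRecord:
    """One patient's evaluation summary at their highest-scoring endpoint."""

    patient_id: str
    score: float
    outcome: int  # cancer within the horizon of the scored endpoint
    observed: bool  # horizon covered by follow-up
    age_years: float  # at the scored endpoint
    race: str
    sex: str
    days_to_event: int | None = None  # endpoint -> diagnosis, cases only


def records_from_predictions(trajs: list, probs: np.ndarray, horizon_index: int = 3) -> list:
    """Patient-level eval records: max score across each patient's trajectories."""
    from .synthetic import DAYS_PER_YEAR

    best: dict[str, EvalRecord] = {}
    for t, p in zip(trajs, probs[:, horizon_index]):
        rec = EvalRecord(
            patient_id=t.patient_id,
            score=float(p),
            outcome=int(t.labels[horizon_index]),
            observed=bool(t.censor_mask[horizon_index]),
            age_years=t.age_days / DAYS_PER_YEAR,
            race=t.race,
            sex=t.sex,
            days_to_event=t.days_to_cancer,
        )
        cur = best.get(t.patient_id)
        if cur is None or rec.score > cur.score:
            best[t.patient_id] = rec
    return [best[k] for k in sorted(best)]


def auroc_with_ci(scores, labels, n_boot: int = 100, rng=None) -> tuple[float, float, float]:
    """Rank-based AUROC with a percentile bootstrap 95% CI."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    auroc = float(roc_auc_score(labels, scores))
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(labels), size=len(labels))
        if len(np.unique(labels[idx])) < 2:
            continue
        stats.append(roc_auc_score(labels[idx], scores[idx]))
    if not stats:
        return auroc, float("nan"), float("nan")
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return auroc, float(lo), float(hi)


def top_n_cohort(records: list, n: int, min_age: float | None = None) -> list:
    """The N highest-scoring patients (ties broken by patient id).

    ``min_age`` optionally restricts the cohort to patients at least that
    old at prediction (surveillance programs target ages >= 50).
    """
    pool = records if min_age is None else [r for r in records if r.age_years >= min_age]
    if n <= 0 or n > len(pool):
        raise ValueError(f"top-N size {n} out of range for population {len(pool)}")
    return sorted(pool, key=lambda r: (-r.score, r.patient_id))[:n]


def ppv_and_ir(high_risk: list, incidence_rate: float) -> tuple[float, float]:
    """PPV within the high-risk set and its ratio to the baseline incidence."""
    if not high_risk:
        raise ValueError("high-risk cohort is empty")
    if incidence_rate <= 0:
        raise ValueError("incidence rate must be positive")
    tp = sum(r.outcome for r in high_risk)
    ppv = tp / len(high_risk)
    return ppv, ppv / incidence_rate


def horizon_year_offsets(horizon_months: int, printed_T: bool = False) -> list[int]:
    """Year offsets T summed when querying the incidence table."""
    if horizon_months <= 12:
        return [0]
    n_years = math.ceil(horizon_months / 12)
    if printed_T:
        n_years += 1
    return list(range(n_years))


def expected_cases(high_risk: list, table: IncidenceTable, horizon_months: int,
                   printed_T: bool = False) -> float:
    """Expected cases in a cohort under the baseline incidence table.

    Each patient contributes ``sum_t Incidence(floor(age)+t, race, sex)``
    over the year offsets for the horizon, so patients age across band
    boundaries.  A stratum absent from the table raises ``KeyError`` naming
    the stratum.
    """
    offsets = horizon_year_offsets(horizon_months, printed_T)
    total = 0.0
    for r in high_risk:
        age = math.floor(r.age_years)
        for t in offsets:
            total += table.rate(age + t, r.race, r.sex)
    return total


def sir_with_ci(observed: float, expected: float) -> tuple[float, float, float]:
    """Standardized incidence ratio with the 95% CI (sqrt(N_obs)±0.98)²/N_exp.

    The subtrahend of the lower bound is clamped at zero so that zero
    observed cases give a lower bound of zero.
    """
    if expected <= 0:
        raise ValueError("expected cases must be positive")
    sir = observed / expected
    lo = max(math.sqrt(observed) - 0.98, 0.0) ** 2 / expected
    hi = (math.sqrt(observed) + 0.98) ** 2 / expected
    return sir, lo, hi


def observed_cases(high_risk: list) -> int:
    return int(sum(r.outcome for r in high_risk))


def surveillance_report(records: list, table: IncidenceTable, horizon_months: int,
                        top_n: int, incidence_rate: float | None = None,
                        min_age: float | None = 50.0, printed_T: bool = False) -> dict:
    """PPV, IR, SIR (+CI) for the top-N cohort of a scored population."""
    high = top_n_cohort(records, top_n, min_age=min_age)
    obs = observed_cases(high)
    exp = expected_cases(high, table, horizon_months, printed_T)
    sir, lo, hi = sir_with_ci(obs, exp)
    if incidence_rate is None:
        pool = records if min_age is None else [r for r in records if r.age_years >= min_age]
        observed_pool = [r for r in pool if r.observed]
        incidence_rate = (
            sum(r.outcome for r in observed_pool) / len(observed_pool) if observed_pool else float("nan")
        )
    ppv, ir = ppv_and_ir(high, incidence_rate) if incidence_rate and incidence_rate > 0 else (obs / top_n, float("nan"))
    return {
        "top_n": top_n,
        "observed": obs,
        "expected": exp,
        "sir": sir,
        "sir_ci": (lo, hi),
        "ppv": ppv,
        "incidence_rate": incidence_rate,
        "ir": ir,
    }


def subgroup_report(records: list, grouping: str, table: IncidenceTable | None = None,
                    horizon_months: int = 36, top_fraction: float = 0.1,
                    n_boot: int = 100, rng=None) -> pd.DataFrame:
    """Per-subgroup AUROC (+CI) and optionally SIR.

    ``grouping`` is 'race', 'sex' or 'age_band'.  Groups where a metric is
    not computable (single outcome class, no observed patients) carry NaN.
    """
    if grouping == "age_band":
        key = lambda r: age_band_label(r.age_years)
    elif grouping in ("race", "sex"):
        key = lambda r: getattr(r, grouping)
    else:
        raise ValueError("grouping must be 'race', 'sex' or 'age_band'")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    groups: dict[str, list] = {}
    for r in records:
        groups.setdefault(key(r), []).append(r)
    rows = []
    for name in sorted(groups):
        sub = [r for r in groups[name] if r.observed]
        row = {"group": name, "n": len(groups[name]), "n_cases": sum(r.outcome for r in sub),
               "auroc": np.nan, "auroc_lo": np.nan, "auroc_hi": np.nan,
               "sir": np.nan, "sir_lo": np.nan, "sir_hi": np.nan}
        scores = np.array([r.score for r in sub])
        labels = np.array([r.outcome for r in sub])
        if len(np.unique(labels)) == 2:
            row["auroc"], row["auroc_lo"], row["auroc_hi"] = auroc_with_ci(scores, labels, n_boot, rng)
        else:
            logger.warning("subgroup %s=%s has a single outcome class; AUROC not computable", grouping, name)
        if table is not None and sub:
            n_top = max(1, int(round(top_fraction * len(sub))))
            try:
                rep = surveillance_report(sub, table, horizon_months, n_top, min_age=None)
                row["sir"], (row["sir_lo"], row["sir_hi"]) = rep["sir"], rep["sir_ci"]
            except (KeyError, ValueError) as exc:
                logger.warning("subgroup %s=%s: SIR not computable (%s)", grouping, name, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def time_to_event_distribution(high_risk: list, threshold_days: int = 100, bins: int = 20):
    """Histogram of prediction-to-diagnosis gaps among cases in the cohort.

    Returns ``(counts, edges, fraction_beyond_threshold)``; the fraction is
    None (flagged) when the cohort contains no cases.
    """
    gaps = np.array([r.days_to_event for r in high_risk if r.outcome == 1 and r.days_to_event is not None])
    if gaps.size == 0:
        logger.warning("no cases in high-risk cohort; time-to-event fraction undefined")
        return np.array([]), np.array([]), None
    counts, edges = np.histogram(gaps, bins=bins)
    return counts, edges, float(np.mean(gaps > threshold_days))


def snapshot_eval_records(cohort: list, rng, horizon_days: int = 1096,
                          min_age: float = 50.0) -> list:
    """Prospective snapshot of a cohort for SIR calibration checks.

    Each patient gets one endpoint drawn uniformly among their events with at
    least ``horizon_days`` of remaining follow-up — a choice independent of
    any later diagnosis, so a random risk ranking is exactly calibrated
    against the cohort's own incidence table.  Patients already diagnosed by
    the drawn endpoint (prevalent cases) or younger than ``min_age`` there
    are excluded.  Scores are initialised to zero; the caller assigns them.
    """
    from .synthetic import DAYS_PER_YEAR

    recs = []
    for rec in cohort:
        limit = rec.record_end - horizon_days
        days = [d for _, d, _ in rec.events if d <= limit]
        if not days:
            continue
        ep = days[int(rng.integers(0, len(days)))]
        if rec.cancer_day is not None and rec.cancer_day <= ep:
            continue
        age = (ep - rec.birth_day) / DAYS_PER_YEAR
        if age < min_age:
            continue
        outcome = int(rec.cancer_day is not None and rec.cancer_day - ep <= horizon_days)
        recs.append(
            EvalRecord(
                patient_id=rec.patient_id, score=0.0, outcome=outcome, observed=True,
                age_years=age, race=rec.race, sex=rec.sex,
                days_to_event=None if rec.cancer_day is None else rec.cancer_day - ep,
            )
        )
    return recs


def calibration_curve(probs, outcomes, n_bins: int = 10):
    """Mean predicted vs observed outcome rate in equal-width bins on [0, 1].

    Empty bins are omitted.  Returns ``(mean_pred, obs_rate, counts)``.
    """
    probs = np.asarray(probs, dtype=np.float64)
    outcomes = np.asarray(outcomes, dtype=np.float64)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(probs, edges) - 1, 0, n_bins - 1)
    mean_pred, obs_rate, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        mean_pred.append(probs[sel].mean())
        obs_rate.append(outcomes[sel].mean())
        counts.append(int(sel.sum()))
    return np.array(mean_pred), np.array(obs_rate), np.array(counts)
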