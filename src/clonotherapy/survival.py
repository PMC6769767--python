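"""Kaplan–Meier estimation and log-rank comparison between patient strata.

The product-limit estimator and the two-group log-rank test are written
directly from their defining formulas so that the responder/non-responder
stratification can be tested end to end without external statistics
services.  Ties are handled by the standard hypergeometric-variance
formulation (several deaths may fall on one event time), and subjects
censored at an event time are counted at risk at that time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KaplanMeier",
    "km_estimate",
    "logrank_test",
    "median_survival",
    "stratified_os_analysis",
    "load_survival_tsv",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time in days, event indicator, group label."""

    patient_id: str
    time: float
    event: int  # 1 = death observed, 0 = censored
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.patient_id}: negative follow-up time {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1, got {self.event}")


class KaplanMeier:
    """Product-limit survival curve: a right-continuous step function.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i), where d_i is
    the number of deaths and n_i the number at risk at t_i.  S(0) = 1.
    """

    def __init__(self, event_times: np.ndarray, survival: np.ndarray,
                 at_risk: np.ndarray, deaths: np.ndarray):
        self.event_times = event_times  # distinct times with >= 1 death, ascending
        self.survival = survival  # S(t_i) after the drop at t_i
        self.at_risk = at_risk
        self.deaths = deaths

    def __call__(self, t):
        """Survival probability at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        steps = np.concatenate(([1.0], self.survival))
        out = steps[idx]
        return float(out) if out.ndim == 0 else out

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5; inf if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("inf")


def _times_events(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> KaplanMeier:
    """Fit the Kaplan–Meier product-limit estimator to follow-up records."""
    if not records:
        raise ValueError("km_estimate requires at least one record")
    t, e = _times_events(records)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n_at_risk = np.array([(t >= ti).sum() for ti in event_times], dtype=int)
    deaths = np.array([((t == ti) & (e == 1)).sum() for ti in event_times], dtype=int)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - deaths / n_at_risk) if event_times.size else np.array([])
    return KaplanMeier(event_times, surv, n_at_risk, deaths)


def median_survival(records: Sequence[SurvivalRecord]) -> float:
    return km_estimate(records).median()


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    At each distinct event time the observed deaths in group A are compared
    with their hypergeometric expectation given the pooled risk set;
    statistic = (sum(O - E))^2 / sum(V), p from chi-square with 1 df.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    event_times = np.unique(all_t[all_e == 1])
    # risk sets and death counts per distinct event time (vectorized)
    n_a = (ta[None, :] >= event_times[:, None]).sum(axis=1)
    n_b = (tb[None, :] >= event_times[:, None]).sum(axis=1)
    d_a = ((ta[None, :] == event_times[:, None]) & (ea[None, :] == 1)).sum(axis=1)
    d_b = ((tb[None, :] == event_times[:, None]) & (eb[None, :] == 1)).sum(axis=1)
    n = n_a + n_b
    d = d_a + d_b
    expected_a = d * n_a / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var_a = d * (n_a / n) * (n_b / n) * (n - d) / np.where(n > 1, n - 1, 1)
    var_a = np.where(n > 1, var_a, 0.0)
    v = var_a.sum()
    if v == 0:
        return 0.0, 1.0
    stat = float((d_a - expected_a).sum() ** 2 / v)
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def stratified_os_analysis(labels, records: Sequence[SurvivalRecord]) -> dict:
    """Overall-survival comparison between responder strata.

    Joins a-priori responder labels to survival records on patient id, fits
    a Kaplan–Meier curve per stratum, and compares the strata with the
    log-rank test.  Returns a report dict with group sizes, event counts,
    median survival per group, the test statistic and its p-value, plus the
    list of patient ids that failed to join.
    """
    label_by_pid = {lab.patient_id: lab.label for lab in labels}
    rec_by_pid = {r.patient_id: r for r in records}
    missing = sorted(set(label_by_pid) ^ set(rec_by_pid))
    strata: dict[str, list[SurvivalRecord]] = {"responder": [], "non_responder": []}
    for pid, lab in label_by_pid.items():
        if pid in rec_by_pid:
            strata[lab].append(rec_by_pid[pid])
    for name, recs in strata.items():
        if not recs:
            raise ValueError(f"stratum {name!r} is empty; cannot compare survival")
    stat, p = logrank_test(strata["responder"], strata["non_responder"])
    report = {
        "groups": {},
        "logrank_statistic": stat,
        "p_value": p,
        "unjoined_patients": missing,
    }
    for name, recs in strata.items():
        km = km_estimate(recs)
        report["groups"][name] = {
            "n": len(recs),
            "events": int(sum(r.event for r in recs)),
            "median_survival": km.median(),
        }
    report["km"] = {name: km_estimate(recs) for name, recs in strata.items()}
    return report


def load_survival_tsv(path: str | Path) -> list[SurvivalRecord]:
    """Read records from a TSV with columns ``patient_id time_days event [group]``."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].strip().lower() == "patient_id":
            continue
        pid, time, event = fields[0], float(fields[1]), int(fields[2])
        group = fields[3].strip() if len(fields) > 3 else ""
        out.append(SurvivalRecord(pid, time, event, group))
    return out
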