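"""Survival-analysis layer for competition bioassays.

The cage assays confine third-instar larvae (two arms of five larvae per
cage, four cages per treatment) on potted plants and record survival daily
for five days. Per-arm survival curves are estimated with the Kaplan-Meier
product-limit estimator and compared with the two-sample log-rank test; the
day-5 survival probability is the payoff rho_s fed to the simulator.

No raw assay data are deposited, so this module also carries a synthetic
record generator: each larva's death day follows a geometric model with a
constant daily hazard h chosen so that (1 - h)^days equals the target day-5
survival, and larvae alive past the last day are right-censored there.
Constant hazard is the minimal assumption consistent with an endpoint-only
target; the hazard shape is configurable for curve-shape experiments.

Estimation is delegated to lifelines (KaplanMeierFitter, logrank_test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .payoffs import PayoffEntry

RECORD_COLUMNS = ["subject", "arm", "cage", "day", "event"]


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit curve over daily observation times."""

    times: np.ndarray  # ordered event times
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray  # subjects at risk entering each time
    events: np.ndarray  # deaths at each time

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if len(s) and (np.diff(s) > 1e-12).any():
            raise ValueError("survival curve must be non-increasing")

    def survival_at(self, t: float) -> float:
        """S(t): product-limit estimate at time t (1.0 before the first event)."""
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
        return float(s)


@dataclass
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p_value: float


def hazard_for_endpoint(true_rho: float, days: int = 5) -> float:
    """Constant daily hazard h with (1 - h)^days == true_rho."""
    if not 0.0 <= true_rho <= 1.0:
        raise ValueError(f"survival probability must lie in [0, 1], got {true_rho}")
    return 1.0 - true_rho ** (1.0 / days)


def simulate_bioassay(
    true_rho: float,
    cages: int = 4,
    larvae_per_cage: int = 5,
    days: int = 5,
    seed: int | np.random.Generator = 0,
    arm: str = "arm",
    daily_hazards: np.ndarray | None = None,
) -> pd.DataFrame:
    """Synthetic survival records for one assay arm.

    Returns one row per larva with its death day (``event == "died"``) or the
    censoring day (``event == "censored"`` at ``days``). ``daily_hazards``
    optionally replaces the constant-hazard schedule (length ``days``); its
    product of (1 - h_d) need not match ``true_rho`` in that case.
    """
    if cages < 1 or larvae_per_cage < 1 or days < 1:
        raise ValueError("cages, larvae_per_cage and days must all be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if daily_hazards is None:
        daily_hazards = np.full(days, hazard_for_endpoint(true_rho, days))
    elif len(daily_hazards) != days:
        raise ValueError("daily_hazards must have one hazard per day")
    rows = []
    subject = 0
    for cage in range(cages):
        for _ in range(larvae_per_cage):
            day_of_death = None
            for day in range(1, days + 1):
                if rng.random() < daily_hazards[day - 1]:
                    day_of_death = day
                    break
            if day_of_death is None:
                rows.append((subject, arm, cage, days, "censored"))
            else:
                rows.append((subject, arm, cage, day_of_death, "died"))
            subject += 1
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("no survival records")
    if (records["day"] < 1).any():
        raise ValueError("record days must be >= 1")
    if records["subject"].duplicated().any():
        raise ValueError("each subject must appear exactly once")
    return records


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit curve from one arm's records.

    Cage (block) labels are carried in the records but ignored here, matching
    per-arm pooled curves.
    """
    records = _validate_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["day"], event_observed=records["event"] == "died")
    table = kmf.event_table.iloc[1:] if 0 in kmf.event_table.index else kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    survival = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in times]
    )
    return KMCurve(
        times=times,
        survival=survival,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
    )


def log_rank(arm_a: pd.DataFrame, arm_b: pd.DataFrame) -> LogRankResult:
    """Two-sample log-rank comparison of two arms (chi-square, 1 df)."""
    _validate_records(arm_a)
    _validate_records(arm_b)
    if (arm_a["event"] != "died").all() and (arm_b["event"] != "died").all():
        return LogRankResult(statistic=0.0, p_value=1.0)
    res = logrank_test(
        arm_a["day"],
        arm_b["day"],
        event_observed_A=arm_a["event"] == "died",
        event_observed_B=arm_b["event"] == "died",
    )
    return LogRankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def estimate_payoff(records: pd.DataFrame, day: int = 5) -> float:
    """Day-5 Kaplan-Meier survival of an arm: the payoff rho_s."""
    return km_estimate(records).survival_at(day)


def payoff_entry_from_records(records: pd.DataFrame, day: int = 5) -> PayoffEntry:
    """Round-trip an estimated survival into a payoff-matrix entry."""
    return PayoffEntry(rho=estimate_payoff(records, day), provenance="estimated")
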