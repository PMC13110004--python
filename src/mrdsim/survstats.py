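"""Survival summaries and trial-design analytics for simulated cohorts.

Kaplan–Meier estimation and the log-rank test are delegated to
``lifelines`` (the standard survival-analysis library) behind small,
typed wrappers; the module adds MRD-negativity landmarking and a
Monte-Carlo power driver that repeatedly simulates two-arm trials from a
pair of configurations and counts log-rank rejections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .cohort import Dataset, SimulationConfig, build_cohort

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "km_estimate",
    "logrank_test",
    "mrd_negativity_rate",
    "power_analysis",
    "summarize",
]


@dataclass(frozen=True)
class SurvivalRecord:
    time: float
    status: int  # 1 = event, 0 = censored
    group: str = ""

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"survival time must be > 0, got {self.time!r}")
        if self.status not in (0, 1):
            raise ValueError(f"status must be 0 or 1, got {self.status!r}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate over the distinct event times.

    ``survival[j]`` is S(t) just after ``times[j]``; ``at_risk[j]`` and
    ``n_events[j]`` are the risk-set size and event count at ``times[j]``.
    Ties between events and censorings at the same time are resolved
    events-first (the standard convention).
    """

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n_events: tuple[int, ...]

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event time."""
        s = 1.0
        for tj, sj in zip(self.times, self.survival):
            if tj <= t:
                s = sj
            else:
                break
        return s


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier product-limit estimator of the survival function."""
    if not records:
        raise ValueError("km_estimate needs at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.status for r in records])
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table  # indexed by time; includes censored-only rows
    event_rows = table[table["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        times=tuple(float(t) for t in event_rows.index),
        survival=tuple(float(surv.loc[t]) for t in event_rows.index),
        at_risk=tuple(int(v) for v in event_rows["at_risk"]),
        n_events=tuple(int(v) for v in event_rows["observed"]),
    )


def logrank_test(
    records: Sequence[SurvivalRecord],
) -> tuple[float, float, int]:
    """k-sample log-rank test.

    Returns (chi-square statistic, p-value, degrees of freedom = k-1).
    """
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError("logrank_test needs records from at least 2 groups")
    counts = {g: sum(1 for r in records if r.group == g) for g in groups}
    empty = [g for g, c in counts.items() if c == 0]
    if empty:  # pragma: no cover - unreachable via the set above
        raise ValueError(f"groups with zero records: {empty}")
    if not any(r.status == 1 for r in records):
        raise ValueError("logrank_test needs at least one event")
    res = multivariate_logrank_test(
        np.array([r.time for r in records]),
        np.array([groups.index(r.group) for r in records]),
        np.array([r.status for r in records]),
    )
    return float(res.test_statistic), float(res.p_value), len(groups) - 1


def dataset_records(
    dataset: Dataset, endpoint: Optional[str] = None, group_by: str = "subgroup"
) -> list[SurvivalRecord]:
    """Extract survival records from a dataset's endpoint table.

    ``group_by`` is ``"subgroup"`` or the name of a baseline covariate.
    """
    if endpoint is None:
        endpoint = next(iter(dataset.endpoints))
    smap = dataset.subject_map()
    recs = []
    for row in dataset.endpoints[endpoint]:
        subj = smap[row["subject_id"]]
        if group_by == "subgroup":
            g = subj.subgroup
        else:
            if group_by not in subj.covariates:
                raise KeyError(
                    f"unknown covariate {group_by!r}; available: "
                    f"{sorted(subj.covariates)}"
                )
            g = str(subj.covariates[group_by])
        recs.append(SurvivalRecord(time=row["time"], status=row["status"], group=g))
    return recs


def mrd_negativity_rate(
    dataset: Dataset, lod: float, landmark_time: float
) -> pd.DataFrame:
    """Fraction of subjects MRD-negative (below LoD) at a landmark time.

    For each subject the visit nearest ``landmark_time`` is used, provided
    it is non-missing and falls within a window of half the median
    inter-visit gap; subjects with no qualifying visit are tallied
    separately in ``n_unassessed``.
    """
    if not lod > 0:
        raise ValueError(f"lod must be > 0, got {lod!r}")
    if landmark_time < 0:
        raise ValueError("landmark_time must be >= 0")
    by_subject: dict[str, list] = {}
    for obs in dataset.observations:
        by_subject.setdefault(obs.subject_id, []).append(obs)
    gaps = []
    for obs_list in by_subject.values():
        ts = sorted(o.time for o in obs_list)
        gaps.extend(b - a for a, b in zip(ts, ts[1:]))
    window = (float(np.median(gaps)) / 2.0) if gaps else math.inf
    rows: dict[str, dict[str, int]] = {}
    for subj in dataset.subjects:
        tally = rows.setdefault(
            subj.subgroup, {"n_negative": 0, "n_assessed": 0, "n_unassessed": 0}
        )
        candidates = [
            o
            for o in by_subject.get(subj.id, [])
            if not o.missing and o.value is not None
            and abs(o.time - landmark_time) <= window
        ]
        if not candidates:
            tally["n_unassessed"] += 1
            continue
        nearest = min(candidates, key=lambda o: abs(o.time - landmark_time))
        tally["n_assessed"] += 1
        if nearest.value < lod:
            tally["n_negative"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subgroup"
    out["negativity_rate"] = np.where(
        out["n_assessed"] > 0, out["n_negative"] / out["n_assessed"], np.nan
    )
    return out


@dataclass
class PowerResult:
    power: float
    mc_standard_error: float
    n_reps: int
    alpha_level: float
    mean_events_control: float
    mean_events_treatment: float
    p_values: list[float] = field(default_factory=list)


def power_analysis(
    config_control: SimulationConfig,
    config_treatment: SimulationConfig,
    n_reps: int,
    alpha_level: float,
    seed: int,
    analysis: Optional[Callable[[Sequence[SurvivalRecord]], tuple]] = None,
) -> PowerResult:
    """Monte-Carlo power of a two-arm trial.

    Each replicate simulates one cohort per arm (with per-replicate seeds
    derived from the master seed), pools the survival records labelled by
    arm, and applies the analysis (log-rank by default, or any callable
    returning ``(statistic, p_value, ...)``).  Power is the fraction of
    replicates with ``p < alpha_level``; the Monte-Carlo standard error is
    the binomial one.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if not 0.0 < alpha_level < 1.0:
        raise ValueError(f"alpha_level must lie in (0,1), got {alpha_level}")
    if config_control.hazard.t_max != config_treatment.hazard.t_max:
        raise ValueError(
            "control and treatment configs must share t_max "
            f"({config_control.hazard.t_max} vs {config_treatment.hazard.t_max})"
        )
    test = analysis or logrank_test
    master = np.random.SeedSequence(seed)
    rep_seeds = master.generate_state(2 * n_reps) % (2**31 - 1)
    rejections = 0
    events_c, events_t, pvals = [], [], []
    for rep in range(n_reps):
        ds_c = build_cohort(config_control, int(rep_seeds[2 * rep]))
        ds_t = build_cohort(config_treatment, int(rep_seeds[2 * rep + 1]))
        recs = [
            SurvivalRecord(r["time"], r["status"], "control")
            for r in next(iter(ds_c.endpoints.values()))
        ] + [
            SurvivalRecord(r["time"], r["status"], "treatment")
            for r in next(iter(ds_t.endpoints.values()))
        ]
        _, p, *_ = test(recs)
        pvals.append(float(p))
        if p < alpha_level:
            rejections += 1
        events_c.append(sum(s.status for s in ds_c.subjects))
        events_t.append(sum(s.status for s in ds_t.subjects))
    power = rejections / n_reps
    se = math.sqrt(power * (1.0 - power) / n_reps)
    return PowerResult(
        power=power,
        mc_standard_error=se,
        n_reps=n_reps,
        alpha_level=alpha_level,
        mean_events_control=float(np.mean(events_c)),
        mean_events_treatment=float(np.mean(events_t)),
        p_values=pvals,
    )


def summarize(dataset: Dataset) -> pd.DataFrame:
    """Per-subgroup cohort summary table.

    Columns: cohort size, event/censoring counts, median follow-up,
    KM median event time (NaN when the curve never reaches 0.5), mean and
    median observed MRD across visits, and the fraction of non-missing
    measurements below the LoD.
    """
    if not dataset.subjects:
        raise ValueError("summarize needs a non-empty dataset")
    obs_by_group: dict[str, list] = {}
    smap = dataset.subject_map()
    for obs in dataset.observations:
        obs_by_group.setdefault(smap[obs.subject_id].subgroup, []).append(obs)
    rows = []
    for group in dict.fromkeys(s.subgroup for s in dataset.subjects):
        members = [s for s in dataset.subjects if s.subgroup == group]
        times = np.array([s.event_time for s in members])
        statuses = np.array([s.status for s in members])
        if statuses.any():
            kmf = KaplanMeierFitter()
            kmf.fit(times, event_observed=statuses)
            km_median = float(kmf.median_survival_time_)
        else:
            km_median = math.inf
        obs = obs_by_group.get(group, [])
        values = [o.value for o in obs if not o.missing and o.value is not None]
        n_flagged = sum(1 for o in obs if not o.missing and o.below_lod)
        rows.append(
            {
                "subgroup": group,
                "n": len(members),
                "n_events": int(statuses.sum()),
                "n_censored": int((1 - statuses).sum()),
                "median_followup": float(np.median(times)),
                "km_median_event_time": km_median,
                "mean_mrd": float(np.mean(values)) if values else math.nan,
                "median_mrd": float(np.median(values)) if values else math.nan,
                "frac_below_lod": (n_flagged / len(values)) if values else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("subgroup")
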