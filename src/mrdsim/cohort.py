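"""Synthetic cohort assembly.

Builds a full simulated study: for each response subgroup (e.g. CR, PR,
SD, PD) it samples subject-level trajectory parameters, baseline and
time-variant covariates, a joint event time from the trajectory-driven
hazard, an assessment schedule with optional visit jitter and
missingness, noisy MRD measurements, and limit-of-detection flags.

Population model per subgroup: baseline (``beta0``) and plateau
(``beta1``) levels are lognormal; a subject relapses with probability
``relapse_prob``, and when they do the relapse onset time is normal,
truncated below at the end-of-treatment time.  ``te``, ``beta2`` and
``sigma`` are subgroup constants.

Reproducibility contract: one master seed per dataset; per-subject
generators are spawned from ``numpy.random.SeedSequence(seed)`` in subject
order, and within a subject draws happen in a fixed documented order
(trajectory parameters, relapse occurrence, relapse time, covariates,
event uniform, dropout, visit jitter, missingness, then measurement noise
per visit).  The same (config, seed) therefore reproduces the dataset
bit for bit, and any subject can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .hazard import HazardSpec, sample_event_time_inversion
from .trajectory import TrajectoryParams, observe

__all__ = [
    "SubgroupSpec",
    "ScheduleSpec",
    "CovariateSpec",
    "SimulationConfig",
    "Subject",
    "Observation",
    "Dataset",
    "sample_subject_truth",
    "build_schedule",
    "generate_covariates",
    "apply_lod",
    "build_cohort",
]

_MAX_REJECTION_DRAWS = 1000


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SubgroupSpec:
    """Population distributions and cohort size for one response category."""

    name: str
    n: int
    beta0_meanlog: float
    beta0_sdlog: float
    beta1_meanlog: float
    beta1_sdlog: float
    te: float
    relapse_prob: float = 0.0
    relapse_mean: float = math.nan
    relapse_sd: float = 0.0
    beta2: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        errs = []
        if self.n < 1:
            errs.append(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.relapse_prob <= 1.0:
            errs.append(f"relapse_prob must lie in [0,1], got {self.relapse_prob}")
        if self.te <= 0:
            errs.append(f"te must be > 0, got {self.te}")
        if self.beta0_sdlog < 0 or self.beta1_sdlog < 0:
            errs.append("sdlog values must be >= 0")
        if self.relapse_sd < 0:
            errs.append(f"relapse_sd must be >= 0, got {self.relapse_sd}")
        if self.relapse_prob > 0 and not self.relapse_mean > self.te:
            errs.append(
                f"relapse_mean ({self.relapse_mean}) must exceed te ({self.te}) "
                "when relapse_prob > 0"
            )
        if self.beta2 < 0:
            errs.append(f"beta2 must be >= 0, got {self.beta2}")
        if self.sigma < 0:
            errs.append(f"sigma must be >= 0, got {self.sigma}")
        if errs:
            raise ConfigError(f"subgroup {self.name!r}: " + "; ".join(errs))


@dataclass(frozen=True)
class ScheduleSpec:
    """MRD assessment schedule: explicit visit times or a regular grid."""

    mode: str = "regular"  # "explicit" | "regular"
    visit_times: tuple[float, ...] = ()
    interval: float = math.nan
    horizon: float = math.nan
    jitter_sd: float = 0.0
    miss_prob: float = 0.0

    def __post_init__(self) -> None:
        errs = []
        if self.mode not in ("explicit", "regular"):
            errs.append(f"unknown schedule mode {self.mode!r}")
        elif self.mode == "explicit":
            vt = list(self.visit_times)
            if not vt:
                errs.append("explicit schedule needs visit_times")
            elif vt != sorted(vt) or any(t < 0 for t in vt):
                errs.append("visit_times must be non-negative and ascending")
        else:
            if not (self.interval > 0 and self.horizon >= 0):
                errs.append("regular schedule needs interval > 0 and horizon >= 0")
        if self.jitter_sd < 0:
            errs.append("jitter_sd must be >= 0")
        if not 0.0 <= self.miss_prob <= 1.0:
            errs.append(f"miss_prob must lie in [0,1], got {self.miss_prob}")
        if errs:
            raise ConfigError("schedule: " + "; ".join(errs))

    def nominal_times(self) -> list[float]:
        if self.mode == "explicit":
            return list(self.visit_times)
        n = int(math.floor(self.horizon / self.interval + 1e-9))
        return [i * self.interval for i in range(n + 1)]


@dataclass(frozen=True)
class CovariateSpec:
    """One baseline (or time-variant) covariate's generating distribution.

    ``kind``:
      - ``binary``: params ``{"p": success probability}``, values 0/1
      - ``categorical``: params ``{"levels": [...], "probs": [...]}``
      - ``continuous``: params ``{"mean": m, "sd": s}``

    ``change_times``, when non-empty, makes the covariate time-variant: a
    fresh value is drawn for each window between consecutive change times
    and the covariate is materialized as a piecewise-constant track.
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)
    change_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        errs = []
        if self.kind == "binary":
            p = self.params.get("p")
            if p is None or not 0.0 <= p <= 1.0:
                errs.append(f"binary covariate needs p in [0,1], got {p!r}")
        elif self.kind == "categorical":
            levels = self.params.get("levels", [])
            probs = self.params.get("probs", [])
            if len(levels) != len(probs) or not levels:
                errs.append("categorical covariate needs matching levels/probs")
            elif any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                errs.append("categorical probs must be >= 0 and sum to 1")
        elif self.kind == "continuous":
            if self.params.get("sd", 0.0) < 0:
                errs.append("continuous covariate sd must be >= 0")
        else:
            errs.append(f"unknown covariate kind {self.kind!r}")
        if list(self.change_times) != sorted(self.change_times) or any(
            t < 0 for t in self.change_times
        ):
            errs.append("change_times must be non-negative and ascending")
        if errs:
            raise ConfigError(f"covariate {self.name!r}: " + "; ".join(errs))

    @property
    def is_time_variant(self) -> bool:
        return len(self.change_times) > 0

    def draw(self, rng: np.random.Generator) -> Any:
        if self.kind == "binary":
            return int(rng.uniform() < self.params["p"])
        if self.kind == "categorical":
            u = rng.uniform()
            acc = 0.0
            for level, p in zip(self.params["levels"], self.params["probs"]):
                acc += p
                if u < acc:
                    return level
            return self.params["levels"][-1]
        return float(
            self.params.get("mean", 0.0) + self.params.get("sd", 0.0) * rng.normal()
        )

    def numeric(self, value: Any) -> float:
        """Encoding used in the hazard's linear predictor."""
        if self.kind == "categorical":
            return float(self.params["levels"].index(value))
        return float(value)


@dataclass(frozen=True)
class SimulationConfig:
    """Fully-resolved simulation configuration (the io module builds one
    from YAML/JSON; it can also be constructed programmatically)."""

    subgroups: tuple[SubgroupSpec, ...]
    hazard: HazardSpec
    schedule: ScheduleSpec
    covariates: tuple[CovariateSpec, ...] = ()
    noise_mode: str = "additive"
    lod: Optional[float] = None
    censor_at_lod: bool = False
    time_unit: str = "months"
    endpoint_name: str = "event_free_survival"
    colormaps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        errs = []
        if not self.subgroups:
            errs.append("at least one subgroup is required")
        names = [s.name for s in self.subgroups]
        if len(set(names)) != len(names):
            errs.append(f"duplicate subgroup names: {names}")
        n_baseline = sum(1 for c in self.covariates if not c.is_time_variant)
        if len(self.hazard.gamma) != n_baseline:
            errs.append(
                f"len(gamma)={len(self.hazard.gamma)} must equal the number of "
                f"baseline covariates ({n_baseline})"
            )
        if self.noise_mode not in ("additive", "multiplicative"):
            errs.append(f"unknown noise_mode {self.noise_mode!r}")
        if self.lod is not None and self.lod <= 0:
            errs.append(f"lod must be > 0, got {self.lod}")
        if errs:
            raise ConfigError("; ".join(errs))

    @property
    def baseline_covariates(self) -> tuple[CovariateSpec, ...]:
        return tuple(c for c in self.covariates if not c.is_time_variant)


@dataclass
class Subject:
    id: str
    subgroup: str
    covariates: dict[str, Any]
    tv_tracks: dict[str, list[tuple[float, Any]]]
    truth: Optional[TrajectoryParams]  # None for blinded datasets
    event_time: float
    status: int  # 1 = event, 0 = censored
    censor_reason: str  # "administrative" | "dropout" | "none"


@dataclass
class Observation:
    subject_id: str
    time: float
    value: Optional[float]
    raw_value: Optional[float]
    below_lod: bool
    missing: bool


@dataclass
class Dataset:
    """Cohort container: subjects, measurements, endpoints, ground truth."""

    metadata: dict
    subjects: list[Subject]
    observations: list[Observation]
    covariate_specs: list[CovariateSpec]
    endpoints: dict[str, list[dict]]
    ground_truth: Optional[dict] = None

    def subject_map(self) -> dict[str, Subject]:
        return {s.id: s for s in self.subjects}


# ---------------------------------------------------------------------------
# sampling operations


def sample_subject_truth(
    sub: SubgroupSpec, rng: np.random.Generator
) -> TrajectoryParams:
    """Draw one subject's ground-truth trajectory parameters.

    beta0 and beta1 are lognormal; with probability ``relapse_prob`` the
    relapse time is normal truncated to (te, inf) by rejection, otherwise
    ``tr = +inf``.
    """
    beta0 = math.exp(sub.beta0_meanlog + sub.beta0_sdlog * rng.normal())
    beta1 = math.exp(sub.beta1_meanlog + sub.beta1_sdlog * rng.normal())
    relapses = rng.uniform() < sub.relapse_prob
    if relapses:
        tr = math.nan
        for _ in range(_MAX_REJECTION_DRAWS):
            cand = sub.relapse_mean + sub.relapse_sd * rng.normal()
            if cand > sub.te:
                tr = cand
                break
        if math.isnan(tr):
            raise ConfigError(
                f"subgroup {sub.name!r}: failed to draw relapse time > te="
                f"{sub.te} after {_MAX_REJECTION_DRAWS} attempts "
                f"(relapse_mean={sub.relapse_mean} too small?)"
            )
    else:
        tr = math.inf
    return TrajectoryParams(
        beta0=beta0, beta1=beta1, beta2=sub.beta2, te=sub.te, tr=tr, sigma=sub.sigma
    )


def build_schedule(
    sched: ScheduleSpec, rng: np.random.Generator
) -> tuple[list[float], list[bool]]:
    """One subject's visit times (with jitter) and per-visit missing flags.

    Jitter is redrawn (up to 1000 times) until visit order is preserved;
    the first visit is pinned at its nominal time so t=0 baseline sampling
    survives jitter.
    """
    nominal = sched.nominal_times()
    if sched.jitter_sd > 0 and len(nominal) > 1:
        times = None
        for _ in range(_MAX_REJECTION_DRAWS):
            jit = [nominal[0]] + [
                t + sched.jitter_sd * rng.normal() for t in nominal[1:]
            ]
            if all(b > a for a, b in zip(jit, jit[1:])) and jit[0] >= 0:
                times = jit
                break
        if times is None:
            raise ConfigError(
                "visit jitter violates schedule monotonicity after "
                f"{_MAX_REJECTION_DRAWS} redraws (jitter_sd too large?)"
            )
    else:
        times = list(nominal)
    missing = [bool(rng.uniform() < sched.miss_prob) for _ in times]
    return times, missing


def generate_covariates(
    specs: list[CovariateSpec] | tuple[CovariateSpec, ...],
    rng: np.random.Generator,
    t_max: float = math.inf,
) -> tuple[dict[str, Any], dict[str, list[tuple[float, Any]]]]:
    """Draw baseline covariate values and time-variant tracks.

    Baseline covariates get one draw each; time-variant ones get a fresh
    draw per window between change times, materialized as piecewise-
    constant ``(start_time, value)`` tracks starting at t=0.
    """
    baseline: dict[str, Any] = {}
    tracks: dict[str, list[tuple[float, Any]]] = {}
    for spec in specs:
        if not spec.is_time_variant:
            baseline[spec.name] = spec.draw(rng)
        else:
            starts = [0.0] + [t for t in spec.change_times if t < t_max]
            tracks[spec.name] = [(s, spec.draw(rng)) for s in starts]
    return baseline, tracks


def apply_lod(
    observations: list[Observation], lod: float, censor_at_lod: bool = False
) -> list[Observation]:
    """Flag measurements below the limit of detection (strict ``<``).

    Values are left untouched by default — the flag *is* the MRD-
    negativity call; with ``censor_at_lod`` the stored value is replaced
    by the LoD itself for left-censored reporting.
    """
    if not lod > 0:
        raise ValueError(f"lod must be > 0, got {lod!r}")
    for obs in observations:
        if obs.missing or obs.value is None:
            continue
        obs.below_lod = obs.value < lod
        if obs.below_lod and censor_at_lod:
            obs.value = lod
    return observations


def _simulate_subject(
    subject_id: str,
    sub: SubgroupSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[Subject, list[Observation]]:
    """One subject, fixed draw order (see module docstring)."""
    truth = sample_subject_truth(sub, rng)
    baseline, tracks = generate_covariates(
        config.covariates, rng, t_max=config.hazard.t_max
    )
    cov_vector = [
        spec.numeric(baseline[spec.name]) for spec in config.baseline_covariates
    ]
    u = rng.uniform()
    while not 0.0 < u < 1.0:  # pragma: no cover - measure-zero guard
        u = rng.uniform()
    t_event, is_event = sample_event_time_inversion(
        config.hazard, cov_vector, truth, u
    )
    if config.hazard.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.hazard.dropout_rate)
    else:
        t_drop = math.inf
    if t_drop < t_event:
        event_time, status, reason = t_drop, 0, "dropout"
    elif is_event:
        event_time, status, reason = t_event, 1, "none"
    else:
        event_time, status, reason = config.hazard.t_max, 0, "administrative"

    visit_times, missing_flags = build_schedule(config.schedule, rng)
    observations: list[Observation] = []
    kept = [
        (t, m) for t, m in zip(visit_times, missing_flags) if t <= event_time
    ]
    measured_times = [t for t, m in kept if not m]
    noisy = dict(
        (t, (v, raw))
        for t, v, raw in observe(
            truth, measured_times, rng, noise_mode=config.noise_mode
        )
    )
    for t, is_missing in kept:
        if is_missing:
            observations.append(
                Observation(subject_id, t, None, None, False, True)
            )
        else:
            v, raw = noisy[t]
            observations.append(
                Observation(subject_id, t, v, raw, False, False)
            )
    subject = Subject(
        id=subject_id,
        subgroup=sub.name,
        covariates=baseline,
        tv_tracks=tracks,
        truth=truth,
        event_time=event_time,
        status=status,
        censor_reason=reason,
    )
    return subject, observations


def build_cohort(config: SimulationConfig, seed: int) -> Dataset:
    """Simulate the full cohort described by ``config``.

    Deterministic given (config, seed): subject streams are spawned from
    the master seed in order, so the dataset serializes identically across
    runs and platforms.
    """
    master = np.random.SeedSequence(seed)
    total_n = sum(s.n for s in config.subgroups)
    children = master.spawn(total_n)
    subjects: list[Subject] = []
    observations: list[Observation] = []
    idx = 0
    for sub in config.subgroups:
        for j in range(sub.n):
            sid = f"{sub.name}-{j + 1:04d}"
            rng = np.random.default_rng(children[idx])
            subject, obs = _simulate_subject(sid, sub, config, rng)
            subjects.append(subject)
            observations.extend(obs)
            idx += 1
    if config.lod is not None:
        apply_lod(observations, config.lod, config.censor_at_lod)
    endpoints = {
        config.endpoint_name: [
            {"subject_id": s.id, "time": s.event_time, "status": s.status}
            for s in subjects
        ]
    }
    metadata = {
        "schema_version": "1.0",
        "time_unit": config.time_unit,
        "seed": seed,
        "n_subjects": total_n,
        "noise_mode": config.noise_mode,
        "lod": config.lod,
        "colormaps": dict(config.colormaps),
        "config": config_to_dict(config),
    }
    ground_truth = {
        "trajectories": {s.id: s.truth for s in subjects},
        "hazard": config.hazard,
        "subgroups": list(config.subgroups),
    }
    return Dataset(
        metadata=metadata,
        subjects=subjects,
        observations=observations,
        covariate_specs=list(config.covariates),
        endpoints=endpoints,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# config (de)serialization — the metadata echo plus the YAML/JSON loader's
# back end.  None stands in for non-finite sentinels (nan relapse_mean)
# so the echo stays strictly-valid JSON.


def _hazard_to_dict(h: HazardSpec) -> dict:
    return {
        "baseline_family": h.baseline_family,
        "baseline_params": dict(h.baseline_params),
        "gamma": list(h.gamma),
        "alpha1": h.alpha1,
        "alpha2": h.alpha2,
        "alpha3": h.alpha3,
        "link_scale": h.link_scale,
        "t_max": h.t_max,
        "dropout_rate": h.dropout_rate,
    }


def _hazard_from_dict(d: dict) -> HazardSpec:
    return HazardSpec(
        baseline_family=d.get("baseline_family", "exponential"),
        baseline_params=dict(d.get("baseline_params", {"rate": 0.1})),
        gamma=tuple(d.get("gamma", ())),
        alpha1=float(d.get("alpha1", 0.0)),
        alpha2=float(d.get("alpha2", 0.0)),
        alpha3=float(d.get("alpha3", 0.0)),
        link_scale=d.get("link_scale", "raw"),
        t_max=float(d.get("t_max", 100.0)),
        dropout_rate=float(d.get("dropout_rate", 0.0)),
    )


def _subgroup_to_dict(s: SubgroupSpec) -> dict:
    return {
        "name": s.name,
        "n": s.n,
        "beta0_meanlog": s.beta0_meanlog,
        "beta0_sdlog": s.beta0_sdlog,
        "beta1_meanlog": s.beta1_meanlog,
        "beta1_sdlog": s.beta1_sdlog,
        "te": s.te,
        "relapse_prob": s.relapse_prob,
        "relapse_mean": None if math.isnan(s.relapse_mean) else s.relapse_mean,
        "relapse_sd": s.relapse_sd,
        "beta2": s.beta2,
        "sigma": s.sigma,
    }


def _subgroup_from_dict(d: dict) -> SubgroupSpec:
    rm = d.get("relapse_mean")
    return SubgroupSpec(
        name=str(d["name"]),
        n=int(d["n"]),
        beta0_meanlog=float(d["beta0_meanlog"]),
        beta0_sdlog=float(d.get("beta0_sdlog", 0.0)),
        beta1_meanlog=float(d["beta1_meanlog"]),
        beta1_sdlog=float(d.get("beta1_sdlog", 0.0)),
        te=float(d["te"]),
        relapse_prob=float(d.get("relapse_prob", 0.0)),
        relapse_mean=math.nan if rm is None else float(rm),
        relapse_sd=float(d.get("relapse_sd", 0.0)),
        beta2=float(d.get("beta2", 0.0)),
        sigma=float(d.get("sigma", 0.0)),
    )


def _schedule_to_dict(s: ScheduleSpec) -> dict:
    return {
        "mode": s.mode,
        "visit_times": list(s.visit_times),
        "interval": None if math.isnan(s.interval) else s.interval,
        "horizon": None if math.isnan(s.horizon) else s.horizon,
        "jitter_sd": s.jitter_sd,
        "miss_prob": s.miss_prob,
    }


def _schedule_from_dict(d: dict) -> ScheduleSpec:
    return ScheduleSpec(
        mode=d.get("mode", "regular"),
        visit_times=tuple(d.get("visit_times", ())),
        interval=math.nan if d.get("interval") is None else float(d["interval"]),
        horizon=math.nan if d.get("horizon") is None else float(d["horizon"]),
        jitter_sd=float(d.get("jitter_sd", 0.0)),
        miss_prob=float(d.get("miss_prob", 0.0)),
    )


def _covariate_to_dict(c: CovariateSpec) -> dict:
    return {
        "name": c.name,
        "kind": c.kind,
        "params": dict(c.params),
        "change_times": list(c.change_times),
    }


def _covariate_from_dict(d: dict) -> CovariateSpec:
    return CovariateSpec(
        name=str(d["name"]),
        kind=str(d["kind"]),
        params=dict(d.get("params", {})),
        change_times=tuple(d.get("change_times", ())),
    )


def config_to_dict(config: SimulationConfig) -> dict:
    """Serialize a fully-resolved config to plain JSON-safe types."""
    return {
        "subgroups": [_subgroup_to_dict(s) for s in config.subgroups],
        "hazard": _hazard_to_dict(config.hazard),
        "schedule": _schedule_to_dict(config.schedule),
        "covariates": [_covariate_to_dict(c) for c in config.covariates],
        "noise_mode": config.noise_mode,
        "lod": config.lod,
        "censor_at_lod": config.censor_at_lod,
        "time_unit": config.time_unit,
        "endpoint_name": config.endpoint_name,
        "colormaps": dict(config.colormaps),
    }


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a validated SimulationConfig, aggregating all errors found.

    Unknown top-level keys produce a warning (forward compatibility);
    every validation failure across subgroups/hazard/schedule/covariates
    is collected and reported at once.
    """
    import warnings

    known = {
        "subgroups", "hazard", "schedule", "covariates", "noise_mode",
        "lod", "censor_at_lod", "time_unit", "endpoint_name", "colormaps",
        "metadata",
    }
    unknown = set(d) - known
    if unknown:
        warnings.warn(
            f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2
        )
    errors: list[str] = []
    subgroups: list[SubgroupSpec] = []
    for i, sd in enumerate(d.get("subgroups", [])):
        try:
            subgroups.append(_subgroup_from_dict(sd))
        except (ConfigError, KeyError, TypeError, ValueError) as e:
            errors.append(f"subgroups[{i}]: {e}")
    try:
        hz = _hazard_from_dict(d.get("hazard", {}))
    except (ValueError, TypeError) as e:
        errors.append(f"hazard: {e}")
        hz = None
    try:
        sched = _schedule_from_dict(d.get("schedule", {"mode": "regular",
                                                       "interval": 1.0,
                                                       "horizon": 10.0}))
    except (ConfigError, TypeError, ValueError) as e:
        errors.append(f"schedule: {e}")
        sched = None
    covs: list[CovariateSpec] = []
    for i, cd in enumerate(d.get("covariates", [])):
        try:
            covs.append(_covariate_from_dict(cd))
        except (ConfigError, KeyError, TypeError, ValueError) as e:
            errors.append(f"covariates[{i}]: {e}")
    if errors or hz is None or sched is None or not subgroups:
        if not d.get("subgroups"):
            errors.insert(0, "at least one subgroup is required")
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    try:
        return SimulationConfig(
            subgroups=tuple(subgroups),
            hazard=hz,
            schedule=sched,
            covariates=tuple(covs),
            noise_mode=d.get("noise_mode", "additive"),
            lod=d.get("lod"),
            censor_at_lod=bool(d.get("censor_at_lod", False)),
            time_unit=d.get("time_unit", "months"),
            endpoint_name=d.get("endpoint_name", "event_free_survival"),
            colormaps=dict(d.get("colormaps", {})),
        )
    except ConfigError as e:
        raise ConfigError(f"invalid configuration:\n  - {e}") from None
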