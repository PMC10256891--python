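"""Synthetic smoker cohort simulator.

Generates smokers with weekly movement templates over a small set of
labelled places, per-place smoking behaviour with situational context,
a post-quit lapse hazard modulated by cue exposure and fired support
messages, app installation/engagement processes, and the trial's
measurement model (follow-up response, abstinence misreporting and
differential saliva return).

Two fidelity levels are provided:

* ``detail="events"`` runs the decision engine in the loop on generated
  location-fix and smoking-report streams (slow; used for small n).
* ``detail="outcomes"`` collapses the daily lapse/relapse process to its
  closed-form survival probability per participant and vectorises the
  measurement model (fast; used for trial-scale calibration runs).

Everything downstream of a fixed seed is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional, Sequence

import numpy as np

from . import engine as eng
from .geo import GeoPoint, offset_point
from .stats import OutcomeRecord

__all__ = [
    "Place",
    "SmokerProfile",
    "EngagementModel",
    "SimulationParams",
    "SimulatedParticipant",
    "TrialDataset",
    "default_places",
    "default_schedule",
    "default_profile",
    "simulate_movement",
    "simulate_pre_quit",
    "simulate_post_quit",
    "simulate_measurement",
    "simulate_trial",
    "simulate_outcome_counts",
    "stratified_allocation",
    "calibrate_hazards",
    "draw_lapses",
]

UTC = timezone.utc
_EPOCH = datetime(2021, 3, 1, 0, 0, tzinfo=UTC)  # a Monday

_SITUATION_BY_PLACE = {
    "home": eng.Situation.HOME,
    "work": eng.Situation.WORK,
    "social": eng.Situation.SOCIALIZING,
    "other": eng.Situation.OTHER,
}


@dataclass(frozen=True)
class Place:
    label: str  # home | work | social | other
    center: GeoPoint
    pre_quit_smoking_rate: float  # events/hour while present
    # context distributions for reports made here
    urge_probs: tuple[float, ...] = (0.05, 0.1, 0.2, 0.3, 0.2, 0.15)
    stress_probs: tuple[float, ...] = (0.1, 0.2, 0.3, 0.2, 0.15, 0.05)
    mood_probs: tuple[float, ...] = (0.05, 0.15, 0.25, 0.3, 0.15, 0.1)
    others_present_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.pre_quit_smoking_rate < 0:
            raise ValueError("smoking rate must be nonnegative")
        for p in (self.urge_probs, self.stress_probs, self.mood_probs):
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("context distributions must sum to 1")


def default_places(origin: GeoPoint = GeoPoint(52.2, 0.12)) -> dict[str, Place]:
    return {
        "home": Place("home", origin, pre_quit_smoking_rate=0.7, others_present_prob=0.2),
        "work": Place(
            "work", offset_point(origin, 400, 2000), pre_quit_smoking_rate=0.6,
            others_present_prob=0.5,
        ),
        "social": Place(
            "social", offset_point(origin, 1200, -600), pre_quit_smoking_rate=1.2,
            others_present_prob=0.8,
        ),
        "other": Place(
            "other", offset_point(origin, -2500, 900), pre_quit_smoking_rate=0.3,
        ),
    }


def default_schedule() -> list[str]:
    """Weekly place-occupancy template, one label per hour (168 entries)."""
    sched: list[str] = []
    for day in range(7):
        for hour in range(24):
            if day < 5 and 9 <= hour < 17:
                sched.append("work")
            elif day in (4, 5) and 19 <= hour < 23:
                sched.append("social")
            elif hour in (18,) and day < 5:
                sched.append("other")
            else:
                sched.append("home")
    return sched


@dataclass(frozen=True)
class SmokerProfile:
    cigarettes_per_day: float
    heavy_smoker: bool
    low_ses: bool
    movement_schedule: tuple[str, ...]
    baseline_lapse_hazard: float = 0.01
    message_effect_multiplier: float = 0.5  # rho
    relapse_given_lapse: float = 0.3
    reporting_adherence: float = 0.8

    def __post_init__(self) -> None:
        if self.cigarettes_per_day <= 0:
            raise ValueError("cigarettes_per_day must be positive")
        for name in ("baseline_lapse_hazard", "relapse_given_lapse", "reporting_adherence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.message_effect_multiplier <= 1.0:
            raise ValueError("message_effect_multiplier must be in (0, 1]")
        if len(self.movement_schedule) != 168:
            raise ValueError("movement_schedule needs 168 hourly entries")


def default_profile(**overrides) -> SmokerProfile:
    base = dict(
        cigarettes_per_day=15.4,
        heavy_smoker=False,
        low_ses=False,
        movement_schedule=tuple(default_schedule()),
    )
    base.update(overrides)
    return SmokerProfile(**base)


@dataclass(frozen=True)
class EngagementModel:
    install_prob: float = 0.75
    set_quit_date_given_install: float = 1.0
    engagement_median_days: float = 10.0
    engagement_log_sigma: float = 1.5  # lognormal spread (heavy tail)
    followup_prob_6m: float = 0.77
    followup_prob_6w: float = 0.71
    saliva_return_prob_by_arm: dict = field(
        default_factory=lambda: {"app": 0.52, "usual_care": 0.19}
    )
    misreport_prob: float = 0.10

    def __post_init__(self) -> None:
        for v in (
            self.install_prob,
            self.set_quit_date_given_install,
            self.followup_prob_6m,
            self.followup_prob_6w,
            self.misreport_prob,
            *self.saliva_return_prob_by_arm.values(),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationParams:
    engagement: EngagementModel = EngagementModel()
    cigarettes_mean: float = 15.4
    cigarettes_sd: float = 7.1
    heavy_cutoff: int = 16
    low_ses_prob: float = 0.292
    train_days: int = 7
    horizon_days: int = 180
    week6_day: int = 42
    exposures_per_day: float = 4.0
    baseline_lapse_hazard: float = 0.012
    message_effect_multiplier: float = 0.5
    relapse_given_lapse: float = 0.3
    coverage_prob: float = 0.6  # chance a cue exposure is message-covered while engaged
    support_days: int = 90
    fix_interval_s: float = 300.0
    fix_accuracy_m: float = 10.0
    reporting_adherence: float = 0.8
    block_sizes: tuple[int, ...] = (2, 4)
    engine_config: eng.EngineConfig = eng.EngineConfig()


@dataclass
class SimulatedParticipant:
    id: str
    arm: str  # "app" | "usual_care"
    strata: tuple[bool, bool]  # (heavy_smoker, low_ses)
    profile: SmokerProfile
    installed: bool
    engagement_days: float
    true_quit_outcome_6m: bool
    true_7day_6m: bool
    true_7day_6w: bool
    lapse_first_2w: bool
    record: OutcomeRecord
    events: list = field(default_factory=list)
    decisions: list = field(default_factory=list)


@dataclass
class TrialDataset:
    participants: list[SimulatedParticipant]
    seed: int
    params: SimulationParams

    def arm_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.participants:
            sizes[p.arm] = sizes.get(p.arm, 0) + 1
        return sizes


# --------------------------------------------------------------------------
# movement and pre-quit behaviour
# --------------------------------------------------------------------------

def _place_at(schedule: Sequence[str], ts: datetime) -> str:
    hours = int((ts - _EPOCH).total_seconds() // 3600)
    return schedule[hours % 168]


def simulate_movement(
    profile: SmokerProfile,
    horizon_days: int,
    seed: int,
    places: Optional[dict[str, Place]] = None,
    start: datetime = _EPOCH,
    fix_interval_s: float = 300.0,
    accuracy_m: float = 10.0,
) -> list[eng.LocationFix]:
    """Location fixes following the weekly template with Gaussian noise."""
    if horizon_days < 1:
        raise ValueError("horizon must be at least one day")
    places = places or default_places()
    rng = np.random.default_rng(seed)
    n = int(horizon_days * 86400 / fix_interval_s)
    noise = rng.normal(0.0, accuracy_m, size=(n, 2))
    fixes = []
    for i in range(n):
        ts = start + timedelta(seconds=i * fix_interval_s)
        place = places[_place_at(profile.movement_schedule, ts)]
        pt = offset_point(place.center, noise[i, 0], noise[i, 1])
        fixes.append(eng.LocationFix(ts, pt, accuracy_m))
    return fixes


def _draw_report(
    rng: np.random.Generator, ts: datetime, place: Place, is_lapse: bool
) -> eng.SmokingReport:
    pt = offset_point(place.center, rng.normal(0, 10), rng.normal(0, 10))
    return eng.SmokingReport(
        timestamp=ts,
        point=pt,
        urge_strength=int(rng.choice(6, p=place.urge_probs)),
        stress=int(rng.choice(6, p=place.stress_probs)),
        mood=int(rng.choice(6, p=place.mood_probs)),
        situation=_SITUATION_BY_PLACE[place.label],
        others_present=bool(rng.random() < place.others_present_prob),
        is_lapse=is_lapse,
    )


def simulate_pre_quit(
    profile: SmokerProfile,
    places: Optional[dict[str, Place]] = None,
    train_days: int = 7,
    seed: int = 0,
    start: datetime = _EPOCH,
    adherence: Optional[float] = None,
) -> list[eng.SmokingReport]:
    """Training-stage smoking reports: counts Poisson with daily mean
    cigarettes_per_day x adherence, contexts from the occupied place."""
    if train_days < 1:
        raise ValueError("train_days must be at least one day")
    places = places or default_places()
    rng = np.random.default_rng(seed)
    adher = profile.reporting_adherence if adherence is None else adherence
    reports: list[eng.SmokingReport] = []
    for day in range(train_days):
        n = rng.poisson(profile.cigarettes_per_day * adher)
        # waking hours only: 07:00-23:00
        secs = np.sort(rng.uniform(7 * 3600, 23 * 3600, size=n))
        for s in secs:
            ts = start + timedelta(days=day, seconds=float(s))
            place = places[_place_at(profile.movement_schedule, ts)]
            reports.append(_draw_report(rng, ts, place, is_lapse=False))
    return reports


# --------------------------------------------------------------------------
# post-quit lapse process
# --------------------------------------------------------------------------

def draw_lapses(
    baseline_hazard: float,
    message_effect_multiplier: float,
    covered: Sequence[bool],
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli lapse outcomes for a batch of cue exposures.

    The per-exposure hazard is ``baseline_hazard``, multiplied by the
    message effect for exposures covered by a fired support message.
    """
    covered_arr = np.asarray(covered, dtype=bool)
    hazard = baseline_hazard * np.where(covered_arr, message_effect_multiplier, 1.0)
    return rng.random(covered_arr.shape) < hazard

def _schedule_entries(
    schedule: Sequence[str], start: datetime, horizon_days: int
) -> list[tuple[datetime, str, float]]:
    """(entry time, place label, duration hours) for each contiguous block."""
    out = []
    hours = horizon_days * 24
    prev = None
    t0 = None
    for h in range(hours):
        ts = start + timedelta(hours=h)
        label = _place_at(schedule, ts)
        if label != prev:
            if prev is not None:
                out.append((t0, prev, (ts - t0).total_seconds() / 3600))
            prev, t0 = label, ts
    out.append((t0, prev, (start + timedelta(hours=hours) - t0).total_seconds() / 3600))
    return out


def simulate_post_quit(
    profile: SmokerProfile,
    places: Optional[dict[str, Place]] = None,
    engine_state: Optional[eng.EngineState] = None,
    horizon_days: int = 180,
    seed: int = 0,
    quit_dt: Optional[datetime] = None,
    params: Optional[SimulationParams] = None,
    engagement_days: float = math.inf,
) -> tuple[list[eng.SmokingReport], np.ndarray, list[eng.TriggerDecision]]:
    """Run the post-quit lapse process, optionally with the engine in-loop.

    At each cue exposure (entry to a smoking place) a lapse occurs with
    probability ``baseline_lapse_hazard`` times the message effect
    multiplier when a fired message covers the exposure.  Lapses feed back
    into the engine as lapse reports.  Returns (lapse reports, daily
    smoking trajectory of length horizon_days, fired decisions).
    """
    places = places or default_places()
    params = params or SimulationParams()
    quit_dt = quit_dt or (_EPOCH + timedelta(days=params.train_days))
    rng = np.random.default_rng(seed)
    cfg = params.engine_config
    coverage_window = cfg.redecision_interval

    smoked = np.zeros(horizon_days, dtype=bool)
    lapses: list[eng.SmokingReport] = []
    fired: list[eng.TriggerDecision] = []
    relapsed = False

    for entry_ts, label, dur_h in _schedule_entries(
        profile.movement_schedule, quit_dt, horizon_days
    ):
        day = (entry_ts - quit_dt).days
        if relapsed:
            smoked[day:] = True
            break
        place = places[label]
        if place.pre_quit_smoking_rate <= 0:
            continue

        engaged = engine_state is not None and day < engagement_days
        # one cue exposure per entry to a smoking place
        exposure_ts = entry_ts + timedelta(minutes=min(30.0, dur_h * 30))
        exposure_done = False
        block_fired_at: Optional[datetime] = None

        def handle_exposure() -> None:
            nonlocal relapsed
            covered = (
                block_fired_at is not None
                and exposure_ts - block_fired_at <= coverage_window
            )
            if draw_lapses(
                profile.baseline_lapse_hazard,
                profile.message_effect_multiplier,
                [covered],
                rng,
            )[0]:
                smoked[day] = True
                report = _draw_report(rng, exposure_ts, place, is_lapse=True)
                lapses.append(report)
                if engaged:
                    eng.advance_stage(engine_state, exposure_ts, cfg)
                    eng.ingest_smoking_report(engine_state, report, cfg)
                if rng.random() < profile.relapse_given_lapse:
                    relapsed = True

        if engaged:
            # stream fixes through the engine, interleaving the cue exposure
            n_fix = max(1, int(dur_h * 3600 / params.fix_interval_s))
            for i in range(n_fix):
                ts = entry_ts + timedelta(seconds=i * params.fix_interval_s)
                if not exposure_done and ts >= exposure_ts:
                    handle_exposure()
                    exposure_done = True
                    if relapsed:
                        break
                eng.advance_stage(engine_state, ts, cfg)
                pt = offset_point(
                    place.center, rng.normal(0, params.fix_accuracy_m),
                    rng.normal(0, params.fix_accuracy_m),
                )
                _, decision = eng.ingest_location_fix(
                    engine_state, eng.LocationFix(ts, pt, params.fix_accuracy_m), cfg
                )
                if decision is not None and decision.fired:
                    fired.append(decision)
                    block_fired_at = ts
        if not exposure_done:
            handle_exposure()
    return lapses, smoked, fired


# --------------------------------------------------------------------------
# measurement model
# --------------------------------------------------------------------------

def simulate_measurement(
    arm: str,
    true_7day_6m: bool,
    true_prolonged_6m: bool,
    true_7day_6w: bool,
    engagement: EngagementModel,
    seed: int,
) -> OutcomeRecord:
    """Apply follow-up response, misreporting and saliva-return processes
    to a participant's true outcomes; unreturned saliva leaves the assay
    fields absent (downstream: missing = smoking)."""
    rng = np.random.default_rng(seed)
    responded_6w = rng.random() < engagement.followup_prob_6w
    responded_6m = rng.random() < engagement.followup_prob_6m

    def self_report(truth: bool) -> Optional[bool]:
        if truth:
            return True
        return bool(rng.random() < engagement.misreport_prob)

    sr_7d_6m = self_report(true_7day_6m) if responded_6m else None
    sr_prol = self_report(true_prolonged_6m) if responded_6m else None
    sr_7d_6w = self_report(true_7day_6w) if responded_6w else None

    cotinine = anabasine = None
    if sr_7d_6m is True:
        p_return = engagement.saliva_return_prob_by_arm.get(arm, 0.0)
        if rng.random() < p_return:
            if true_7day_6m:
                cotinine = float(rng.uniform(0.0, 5.0))
                anabasine = float(rng.uniform(0.0, 0.1))
            else:  # misreporter: assay reveals smoking
                cotinine = float(rng.uniform(50.0, 300.0))
                anabasine = float(rng.uniform(0.5, 5.0))
    return OutcomeRecord(
        arm=arm,
        self_report_prolonged=sr_prol,
        self_report_7day_6m=sr_7d_6m,
        self_report_7day_6w=sr_7d_6w,
        cotinine_ng_ml=cotinine,
        anabasine_ng_ml=anabasine,
    )


# --------------------------------------------------------------------------
# allocation
# --------------------------------------------------------------------------

def stratified_allocation(
    strata: Sequence[tuple], seed: int, block_sizes: tuple[int, ...] = (2, 4)
) -> list[str]:
    """Randomized arm labels via permuted blocks of varying size within each
    stratum.  Within a stratum the arm imbalance never exceeds
    max(block_sizes) - 1 at any prefix."""
    rng = np.random.default_rng(seed)
    pools: dict[tuple, list[str]] = {}
    arms: list[str] = []
    for s in strata:
        pool = pools.setdefault(s, [])
        if not pool:
            size = int(rng.choice(block_sizes))
            block = ["app"] * (size // 2) + ["usual_care"] * (size - size // 2)
            rng.shuffle(block)
            pool.extend(block)
        arms.append(pool.pop(0))
    return arms


# --------------------------------------------------------------------------
# closed-form daily survival (fast outcomes mode)
# --------------------------------------------------------------------------

def _daily_lapse_prob(hazard: np.ndarray, exposures_per_day: float) -> np.ndarray:
    return 1.0 - (1.0 - hazard) ** exposures_per_day


def calibrate_hazards(
    target_app_rate: float,
    target_usual_rate: float,
    params: SimulationParams,
) -> tuple[float, float]:
    """Solve (baseline_lapse_hazard, rho) so the closed-form true-abstinence
    survival over the horizon hits the target per-arm rates, assuming full
    coverage in the app arm and relapse_given_lapse = 1."""
    T = params.horizon_days
    k = params.exposures_per_day
    q_uc = 1.0 - target_usual_rate ** (1.0 / T)
    q_app = 1.0 - target_app_rate ** (1.0 / T)
    h_uc = 1.0 - (1.0 - q_uc) ** (1.0 / k)
    h_app = 1.0 - (1.0 - q_app) ** (1.0 / k)
    return h_uc, h_app / h_uc


def _simulate_arm_outcomes(
    n: int,
    arm: str,
    params: SimulationParams,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Vectorised truth + measurement for one arm (outcomes fidelity)."""
    em = params.engagement
    installed = (
        rng.random(n) < em.install_prob if arm == "app" else np.zeros(n, dtype=bool)
    )
    engagement_days = np.where(
        installed,
        rng.lognormal(math.log(em.engagement_median_days), em.engagement_log_sigma, n),
        0.0,
    )

    h0 = params.baseline_lapse_hazard
    rho = params.message_effect_multiplier
    c = params.coverage_prob
    h_cov = h0 * (1.0 - c + c * rho)  # mean per-exposure hazard while covered
    q_unc = 1.0 - (1.0 - h0) ** params.exposures_per_day
    q_cov = 1.0 - (1.0 - h_cov) ** params.exposures_per_day
    r = params.relapse_given_lapse

    T = params.horizon_days
    covered_days = np.clip(
        np.floor(np.minimum(engagement_days, params.support_days)), 0, T
    ).astype(int)
    # survival without a relapse-triggering lapse, day products in closed form
    surv_6m = (1 - r * q_cov) ** covered_days * (1 - r * q_unc) ** (T - covered_days)
    d6w = params.week6_day
    cov_6w = np.minimum(covered_days, d6w)
    surv_6w = (1 - r * q_cov) ** cov_6w * (1 - r * q_unc) ** (d6w - cov_6w)
    cov_2w = np.minimum(covered_days, 14)
    p_lapse_2w = 1.0 - (1 - q_cov) ** cov_2w * (1 - q_unc) ** (14 - cov_2w)

    u = rng.random(n)
    true_6m = u < surv_6m
    true_6w = u < surv_6w  # shared uniform: abstinent at 6m implies at 6w
    lapse_2w = rng.random(n) < p_lapse_2w

    responded_6m = rng.random(n) < em.followup_prob_6m
    responded_6w = rng.random(n) < em.followup_prob_6w
    misreport = rng.random(n) < em.misreport_prob
    sr_7d_6m = responded_6m & (true_6m | misreport)
    sr_prol = sr_7d_6m  # survival truth model: any abstainer is a prolonged abstainer
    sr_7d_6w = responded_6w & (true_6w | (rng.random(n) < em.misreport_prob))

    p_return = em.saliva_return_prob_by_arm.get(arm, 0.0)
    returned = sr_7d_6m & (rng.random(n) < p_return)
    validated = returned & true_6m

    return {
        "installed": installed,
        "engagement_days": engagement_days,
        "true_6m": true_6m,
        "true_6w": true_6w,
        "lapse_2w": lapse_2w,
        "responded_6m": responded_6m,
        "responded_6w": responded_6w,
        "sr_7day_6m": sr_7d_6m,
        "sr_prolonged": sr_prol,
        "sr_7day_6w": sr_7d_6w,
        "saliva_returned": returned,
        "validated_6m": validated,
    }


# --------------------------------------------------------------------------
# full trial
# --------------------------------------------------------------------------

def simulate_outcome_counts(
    n_app: int, n_usual: int, params: SimulationParams, seed: int
) -> dict[str, dict[str, int]]:
    """Arm-level outcome counts for one simulated trial (outcomes fidelity).

    Runs the same stratified allocation, truth and measurement pipeline as
    ``simulate_trial(detail="outcomes")`` but returns only per-arm counts —
    the cheap path for repeated-trial calibration studies.
    """
    params = params or SimulationParams()
    n = n_app + n_usual
    rng = np.random.default_rng(seed)
    _, heavy, low_ses = _draw_strata(n, params, rng)
    arms = np.array(
        stratified_allocation(
            list(zip(heavy.tolist(), low_ses.tolist())),
            seed=int(rng.integers(2**31)),
            block_sizes=params.block_sizes,
        )
    )
    out: dict[str, dict[str, int]] = {}
    for arm in ("app", "usual_care"):
        m = int((arms == arm).sum())
        data = _simulate_arm_outcomes(m, arm, params, rng)
        days = np.sort(data["engagement_days"][data["installed"]])
        out[arm] = {
            "n": m,
            "installed": int(data["installed"].sum()),
            "validated_6m": int(data["validated_6m"].sum()),
            "sr_7day_6m": int(data["sr_7day_6m"].sum()),
            "sr_7day_6w": int(data["sr_7day_6w"].sum()),
            "lapse_2w": int(data["lapse_2w"].sum()),
            "responded_6w": int(data["responded_6w"].sum()),
            "median_engagement_days": float(np.median(days)) if days.size else 0.0,
        }
    return out

def _draw_strata(n: int, params: SimulationParams, rng: np.random.Generator):
    cpd = np.maximum(1.0, rng.normal(params.cigarettes_mean, params.cigarettes_sd, n))
    heavy = cpd >= params.heavy_cutoff
    low_ses = rng.random(n) < params.low_ses_prob
    return cpd, heavy, low_ses


def simulate_trial(
    n_app: int,
    n_usual: int,
    params: Optional[SimulationParams] = None,
    seed: int = 0,
    detail: str = "outcomes",
) -> TrialDataset:
    """Simulate a full 2-arm trial.

    Allocation uses permuted blocks (sizes from ``params.block_sizes``)
    stratified by heavy smoking (>= 16/day) and low socioeconomic status;
    realized arm sizes may therefore differ from the requested split by up
    to the within-stratum block imbalance.
    """
    if n_app < 1 or n_usual < 1:
        raise ValueError("both arms need at least one participant")
    params = params or SimulationParams()
    n = n_app + n_usual
    rng = np.random.default_rng(seed)

    cpd, heavy, low_ses = _draw_strata(n, params, rng)
    strata = list(zip(heavy.tolist(), low_ses.tolist()))
    arms = stratified_allocation(
        strata, seed=int(rng.integers(2**31)), block_sizes=params.block_sizes
    )

    if detail == "outcomes":
        return _simulate_trial_outcomes(n, arms, cpd, strata, params, rng, seed)
    if detail == "events":
        return _simulate_trial_events(n, arms, cpd, strata, params, rng, seed)
    raise ValueError(f"unknown detail level {detail!r}")


def _simulate_trial_outcomes(
    n, arms, cpd, strata, params, rng, seed
) -> TrialDataset:
    arms_arr = np.array(arms)
    participants: list[SimulatedParticipant] = []
    cols = {}
    for arm in ("app", "usual_care"):
        idx = np.flatnonzero(arms_arr == arm)
        cols[arm] = (idx, _simulate_arm_outcomes(len(idx), arm, params, rng))

    by_index: dict[int, tuple[str, int]] = {}
    for arm, (idx, _) in cols.items():
        for j, i in enumerate(idx):
            by_index[int(i)] = (arm, j)

    for i in range(n):
        arm, j = by_index[i]
        _, data = cols[arm]
        cot = ana = None
        if data["saliva_returned"][j]:
            if data["true_6m"][j]:
                cot, ana = float(rng.uniform(0, 5)), float(rng.uniform(0, 0.1))
            else:
                cot, ana = float(rng.uniform(50, 300)), float(rng.uniform(0.5, 5))

        def _sr(value: np.bool_, responded: np.bool_) -> Optional[bool]:
            return bool(value) if responded else None

        record = OutcomeRecord(
            arm=arm,
            self_report_prolonged=_sr(data["sr_prolonged"][j], data["responded_6m"][j]),
            self_report_7day_6m=_sr(data["sr_7day_6m"][j], data["responded_6m"][j]),
            self_report_7day_6w=_sr(data["sr_7day_6w"][j], data["responded_6w"][j]),
            cotinine_ng_ml=cot,
            anabasine_ng_ml=ana,
        )
        profile = default_profile(
            cigarettes_per_day=float(cpd[i]),
            heavy_smoker=bool(strata[i][0]),
            low_ses=bool(strata[i][1]),
            baseline_lapse_hazard=params.baseline_lapse_hazard,
            message_effect_multiplier=params.message_effect_multiplier,
            relapse_given_lapse=params.relapse_given_lapse,
            reporting_adherence=params.reporting_adherence,
        )
        participants.append(
            SimulatedParticipant(
                id=f"p{i + 1:04d}",
                arm=arm,
                strata=strata[i],
                profile=profile,
                installed=bool(data["installed"][j]),
                engagement_days=float(data["engagement_days"][j]),
                true_quit_outcome_6m=bool(data["true_6m"][j]),
                true_7day_6m=bool(data["true_6m"][j]),
                true_7day_6w=bool(data["true_6w"][j]),
                lapse_first_2w=bool(data["lapse_2w"][j]),
                record=record,
            )
        )
    return TrialDataset(participants=participants, seed=seed, params=params)


def _simulate_trial_events(n, arms, cpd, strata, params, rng, seed) -> TrialDataset:
    em = params.engagement
    participants: list[SimulatedParticipant] = []
    quit_dt = _EPOCH + timedelta(days=params.train_days)
    for i in range(n):
        sub = int(rng.integers(2**31))
        prng = np.random.default_rng([seed, 7, sub])
        profile = default_profile(
            cigarettes_per_day=float(cpd[i]),
            heavy_smoker=bool(strata[i][0]),
            low_ses=bool(strata[i][1]),
            baseline_lapse_hazard=params.baseline_lapse_hazard,
            message_effect_multiplier=params.message_effect_multiplier,
            relapse_given_lapse=params.relapse_given_lapse,
            reporting_adherence=params.reporting_adherence,
        )
        arm = arms[i]
        installed = arm == "app" and bool(prng.random() < em.install_prob)
        engagement_days = (
            float(prng.lognormal(math.log(em.engagement_median_days), em.engagement_log_sigma))
            if installed
            else 0.0
        )

        state = None
        events: list = []
        if installed:
            state = eng.new_state(seed=sub, quit_date=quit_dt.date())
            reports = simulate_pre_quit(
                profile, train_days=params.train_days, seed=sub, start=_EPOCH
            )
            for r in reports:
                eng.ingest_smoking_report(state, r, params.engine_config)
            events.extend(reports)

        lapses, smoked, fired = simulate_post_quit(
            profile,
            engine_state=state,
            horizon_days=params.horizon_days,
            seed=int(prng.integers(2**31)),
            quit_dt=quit_dt,
            params=params,
            engagement_days=engagement_days,
        )
        events.extend(lapses)

        T = params.horizon_days
        true_6m = not smoked[T - 7 : T].any() and int(smoked.sum()) <= 5
        true_7d_6m = not smoked[T - 7 : T].any()
        d6w = params.week6_day
        true_7d_6w = not smoked[max(0, d6w - 7) : d6w].any()
        lapse_2w = bool(smoked[:14].any())

        record = simulate_measurement(
            arm, true_7d_6m, true_6m, true_7d_6w, em, seed=int(prng.integers(2**31))
        )
        participants.append(
            SimulatedParticipant(
                id=f"p{i + 1:04d}",
                arm=arm,
                strata=strata[i],
                profile=profile,
                installed=installed,
                engagement_days=engagement_days,
                true_quit_outcome_6m=true_6m,
                true_7day_6m=true_7d_6m,
                true_7day_6w=true_7d_6w,
                lapse_first_2w=lapse_2w,
                record=record,
                events=events,
                decisions=fired,
            )
        )
    return TrialDataset(participants=participants, seed=seed, params=params)
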