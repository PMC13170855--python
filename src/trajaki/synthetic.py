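"""Seeded synthetic ICU cohort generator.

Emulates the statistical structure the downstream analysis assumes: daily-scale
serum-creatinine series that may begin up to 48 h before ICU admission, ~10%
missing days, distinct trajectory regimes (stable, monotonic rise, fluctuating,
recovery), and near-term KRT/death outcomes whose daily hazard is a logistic
function of the current-to-baseline creatinine ratio — so outcome risk is
genuinely linked to trajectory shape. Not a joint-distribution match to any
real ICU database; see the package methods note for what is and is not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "AdmissionRecord",
    "generate_cohort",
    "sample_trajectory",
    "sample_outcomes",
    "cohort_to_frames",
    "write_cohort_csv",
    "read_cohort_csv",
]

REGIMES = ("stable", "monotonic_rise", "fluctuating", "recovery")

_EPOCH = pd.Timestamp("2024-01-01 00:00:00")

CREAT_MIN = 0.2   # mg/dL clip bounds for simulated values
CREAT_MAX = 20.0


@dataclass
class CohortConfig:
    """Generator parameters. Defaults define the reference study conditions."""

    n_admissions: int = 2000
    age_mean: float = 65.0
    age_sd: float = 16.0
    p_male: float = 0.56
    baseline_creat_log_mean: float = float(np.log(0.9))
    baseline_creat_log_sd: float = 0.35
    regime_probs: dict = field(
        default_factory=lambda: {
            "stable": 0.60,
            "monotonic_rise": 0.15,
            "fluctuating": 0.10,
            "recovery": 0.15,
        }
    )
    p_missing_day: float = 0.10
    los_mean: float = 7.0
    krt_target_rate: float = 0.03
    death_target_rate: float = 0.07
    measurement_noise_cv: float = 0.08
    seed: int = 0
    # secondary knobs
    p_first_preadmit: float = 0.70   # fraction anchored up to 48 h pre-ICU
    p_ckd: float = 0.12              # chronically elevated baselines (hidden-AKI case mix)
    ckd_baseline_log_mean: float = float(np.log(2.2))
    ckd_baseline_log_sd: float = 0.25
    ckd_krt_boost: float = 3.0       # acute-on-chronic: extra KRT log-odds per day
    ckd_death_boost: float = 0.5
    eskd_rate: float = 0.01          # exercises the ESKD exclusion filter
    krt_hazard_slope: float = 0.5    # logistic slope on (ratio - 1) per day
    death_hazard_slope: float = 0.5  # weaker trajectory link than KRT
    krt_change_slope: float = 2.0    # logistic slope on the positive day-over-day rise
    death_change_slope: float = 0.5
    krt_level_slope: float = 2.5     # logistic slope on log creatinine (uremia-driven KRT)
    death_level_slope: float = 0.5
    krt_random_frac: float = 0.35    # share of events from a trajectory-independent hazard
    death_random_frac: float = 0.50
    rise_ratio_range: tuple = (1.15, 1.35)
    p_extra_measurement: float = 0.10  # second lab draw in a day

    def validate(self) -> None:
        if self.n_admissions < 0:
            raise ValueError("n_admissions must be >= 0")
        probs = [self.regime_probs.get(r, 0.0) for r in REGIMES]
        if set(self.regime_probs) - set(REGIMES):
            raise ValueError(f"unknown regimes: {set(self.regime_probs) - set(REGIMES)}")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("regime_probs must sum to 1")
        for name in ("p_male", "p_missing_day", "krt_target_rate", "death_target_rate",
                     "p_first_preadmit", "eskd_rate", "p_extra_measurement"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(probs) < 0:
            raise ValueError("regime probabilities must be nonnegative")
        if self.los_mean < 2:
            raise ValueError("los_mean must be >= 2 days")


@dataclass
class AdmissionRecord:
    """One synthetic ICU admission with its raw timestamped creatinine series."""

    admission_id: str
    patient_id: str
    age: float
    sex: str
    icu_admit: pd.Timestamp
    icu_discharge: pd.Timestamp
    krt_time: Optional[pd.Timestamp]
    death_time: Optional[pd.Timestamp]
    eskd: bool
    creatinine_obs: list  # list of (pd.Timestamp, float mg/dL)
    regime: Optional[str] = None  # synthetic ground truth; absent for real data

    def validate(self) -> None:
        times = [t for t, _ in self.creatinine_obs]
        vals = [v for _, v in self.creatinine_obs]
        if any(v <= 0 for v in vals):
            raise ValueError("creatinine values must be positive")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("timestamps must be strictly increasing")
        if self.icu_discharge < self.icu_admit:
            raise ValueError("icu_discharge before icu_admit")
        for t in (self.krt_time, self.death_time):
            if t is not None and t < self.icu_admit:
                raise ValueError("event before icu_admit")


def sample_trajectory(regime, baseline, los, rng, noise_cv=0.08,
                      rise_ratio_range=(1.15, 1.45)):
    """Daily creatinine values (day offsets 0..los-1) for one regime.

    stable: multiplicative random walk with daily CV `noise_cv`.
    monotonic_rise: stable until a random onset day, then daily ratios drawn
    from `rise_ratio_range` (all >= 1.15).
    fluctuating: alternating-sign steps of 20-40%.
    recovery: a 2-3 day rise then geometric decay back toward baseline.
    Values are clipped to [0.2, 20] mg/dL.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    los = int(los)
    if los < 1:
        raise ValueError("los must be >= 1 day")
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")

    def walk_step(prev):
        if noise_cv == 0:
            return prev
        return prev * np.exp(noise_cv * rng.standard_normal() - 0.5 * noise_cv ** 2)

    vals = [float(baseline)]
    if regime == "stable":
        for _ in range(1, los):
            vals.append(walk_step(vals[-1]))
    elif regime == "monotonic_rise":
        onset = int(rng.integers(1, max(2, los - 1)))
        for d in range(1, los):
            if d < onset:
                vals.append(walk_step(vals[-1]))
            else:
                vals.append(vals[-1] * rng.uniform(*rise_ratio_range))
    elif regime == "fluctuating":
        sign = 1 if rng.random() < 0.5 else -1
        for _ in range(1, los):
            step = rng.uniform(0.20, 0.40)
            vals.append(vals[-1] * (1 + sign * step))
            sign = -sign
    else:  # recovery
        peak_day = int(rng.integers(1, max(2, min(4, los))))
        for d in range(1, los):
            if d <= peak_day:
                vals.append(vals[-1] * rng.uniform(1.2, 1.5))
            else:
                frac = rng.uniform(0.7, 0.9)
                vals.append(baseline + (vals[-1] - baseline) * frac)
    vals = np.clip(np.asarray(vals), CREAT_MIN, CREAT_MAX)
    return [(d, float(v)) for d, v in enumerate(vals)]


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


RECOVERY_DISCOUNT = 0.2  # hazard multiplier on the ratio term while creatinine falls


def _linear_predictor(day_values, baseline, ratio_slope, change_slope, level_slope,
                      boost=0.0):
    """Daily hazard linear predictor (without intercept) for one trajectory.

    Risk rides on persistent trajectory state rather than on any single
    threshold: the current-to-baseline ratio (discounted while creatinine is
    falling — a recovering kidney carries less risk than the same level on
    the way up), the positive day-over-day rise, and the absolute creatinine
    level (uremia-driven decisions). Increasing in the ratio throughout.
    """
    v = np.asarray(day_values, dtype=float)
    ratio = v / baseline
    rising = np.ones_like(v)
    rising[1:] = np.where(v[1:] >= v[:-1], 1.0, RECOVERY_DISCOUNT)
    rel_change = np.zeros_like(v)
    rel_change[1:] = np.maximum(0.0, v[1:] / v[:-1] - 1.0)
    return (rising * (ratio_slope * np.maximum(ratio - 1.0, 0.0)
                      + level_slope * np.log(v) + boost)
            + change_slope * rel_change)


def _calibrate_intercept(lp_lists, target_rate):
    """Bisection for the logistic-hazard intercept matching a marginal rate.

    Given per-admission arrays of daily linear predictors, find `a` so the
    expected fraction of admissions with >= 1 event under daily hazard
    sigmoid(a + lp) equals `target_rate`. A list of zero arrays calibrates
    the trajectory-independent component.
    """
    if target_rate <= 0:
        return -np.inf

    def expected_rate(a):
        tot = 0.0
        for lp in lp_lists:
            if len(lp) < 2:
                continue
            # day 0 is event-free (events need >= 1 prior step), mirror sampling
            h = _logistic(a + np.asarray(lp[1:]))
            tot += 1.0 - np.prod(1.0 - h)
        return tot / max(1, len(lp_lists))

    lo, hi = -20.0, 5.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_rate(mid) < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _event_hazard(lp, traj_intercept, rand_intercept):
    """Combined daily hazard: trajectory-linked plus trajectory-independent.

    The two components act as independent competing causes; the random
    component keeps a share of events unforecastable from creatinine alone,
    as in real ICU cohorts.
    """
    lp = np.asarray(lp, dtype=float)
    h_traj = _logistic(traj_intercept + lp) if np.isfinite(traj_intercept) else 0.0
    h_rand = _logistic(rand_intercept) if np.isfinite(rand_intercept) else 0.0
    return 1.0 - (1.0 - h_traj) * (1.0 - np.full_like(lp, h_rand))


def _sample_event_day(lp, rng, traj_intercept, rand_intercept=-np.inf):
    """First firing day (>= 1) under the combined daily hazard, else None."""
    n_days = len(lp)
    h = _event_hazard(lp, traj_intercept, rand_intercept)
    fires = rng.random(n_days) < h
    for d in range(1, n_days):  # day 0 event-free: needs >= 1 prior step
        if fires[d]:
            return d
    return None


_SAMPLE = object()  # sentinel: draw the death day inside sample_outcomes


def sample_outcomes(admission, krt_lp, death_lp, rng, krt_intercept, death_intercept,
                    day_times, death_day=_SAMPLE,
                    krt_rand_intercept=-np.inf, death_rand_intercept=-np.inf):
    """Attach KRT/death times by daily logistic hazards on the trajectory.

    `krt_lp`/`death_lp` are per-day linear predictors from `_linear_predictor`
    (increasing in creatinine ratio and day-over-day rise). Death truncates
    the observation series; KRT does not (creatinine is still measured on
    KRT). At most one of each event; a KRT sampled after death is discarded.
    Event hours are placed inside the firing day, after `icu_admit`. A
    pre-sampled `death_day` may be supplied (used by `generate_cohort` so the
    KRT hazard can be calibrated on death-truncated trajectories).
    """
    n_days = len(krt_lp)
    if death_day is _SAMPLE:
        death_day = _sample_event_day(death_lp, rng, death_intercept,
                                      death_rand_intercept)
    krt_day = None
    if np.isfinite(krt_intercept) or np.isfinite(krt_rand_intercept):
        last = n_days if death_day is None else death_day + 1
        h = _event_hazard(krt_lp[:last], krt_intercept, krt_rand_intercept)
        fires = rng.random(last) < h
        for d in range(1, last):
            if fires[d]:
                krt_day = d
                break

    def event_time(day, hour):
        t = day_times[day] + pd.Timedelta(hours=hour)
        return max(t, admission.icu_admit + pd.Timedelta(hours=float(rng.uniform(1, 12))))

    if krt_day is not None:
        admission.krt_time = event_time(krt_day, float(rng.uniform(1, 12)))
    if death_day is not None:
        admission.death_time = event_time(death_day, float(rng.uniform(12, 23)))
        if admission.krt_time is not None and admission.krt_time > admission.death_time:
            admission.krt_time = admission.death_time - pd.Timedelta(hours=1)
        # no labs after death; discharge coincides with death
        admission.creatinine_obs = [
            (t, v) for t, v in admission.creatinine_obs if t <= admission.death_time
        ]
        admission.icu_discharge = admission.death_time
    return admission


def generate_cohort(config: CohortConfig) -> list[AdmissionRecord]:
    """Generate a deterministic synthetic cohort from `config`.

    Hazard intercepts are calibrated against the sampled trajectories by
    bisection so realized KRT and mortality fractions match the configured
    targets in expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_admissions
    if n == 0:
        return []

    regime_names = list(REGIMES)
    regime_p = np.array([config.regime_probs.get(r, 0.0) for r in regime_names])

    admissions: list[AdmissionRecord] = []
    all_krt_lp: list[np.ndarray] = []
    all_death_lp: list[np.ndarray] = []
    all_day_times: list[list[pd.Timestamp]] = []

    for i in range(n):
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 99))
        sex = "male" if rng.random() < config.p_male else "female"
        is_ckd = rng.random() < config.p_ckd
        if is_ckd:
            baseline = float(np.exp(rng.normal(config.ckd_baseline_log_mean,
                                               config.ckd_baseline_log_sd)))
        else:
            baseline = float(np.exp(rng.normal(config.baseline_creat_log_mean,
                                               config.baseline_creat_log_sd)))
        eskd = rng.random() < config.eskd_rate
        if eskd:
            baseline = float(rng.uniform(3.0, 6.0))
        regime = regime_names[int(rng.choice(len(regime_names), p=regime_p))]
        los = max(2, int(round(rng.gamma(shape=4.0, scale=config.los_mean / 4.0))))

        icu_admit = _EPOCH + pd.Timedelta(days=int(rng.integers(0, 365)),
                                          hours=float(rng.uniform(0, 24)))
        if rng.random() < config.p_first_preadmit:
            t0 = icu_admit - pd.Timedelta(hours=float(rng.uniform(0, 48)))
        else:
            t0 = icu_admit + pd.Timedelta(hours=float(rng.uniform(0, 12)))

        traj = sample_trajectory(regime, baseline, los, rng,
                                 noise_cv=config.measurement_noise_cv,
                                 rise_ratio_range=config.rise_ratio_range)
        day_times = [t0 + pd.Timedelta(hours=24.0 * d) for d, _ in traj]

        obs: list[tuple[pd.Timestamp, float]] = []
        for d, v in traj:
            if d > 0 and rng.random() < config.p_missing_day:
                continue  # missing lab day
            jitter = 0.0 if d == 0 else float(rng.uniform(0, 8))
            t = day_times[d] + pd.Timedelta(hours=jitter)
            obs.append((t, v))
            if rng.random() < config.p_extra_measurement:
                t2 = day_times[d] + pd.Timedelta(hours=jitter + float(rng.uniform(2, 10)))
                if (t2 - day_times[d]) < pd.Timedelta(hours=24):
                    obs.append((t2, float(np.clip(v * rng.uniform(0.97, 1.03),
                                                  CREAT_MIN, CREAT_MAX))))

        discharge = day_times[-1] + pd.Timedelta(hours=float(rng.uniform(2, 20)))
        discharge = max(discharge, icu_admit + pd.Timedelta(hours=1))
        rec = AdmissionRecord(
            admission_id=f"adm{i:06d}", patient_id=f"pt{i:06d}",
            age=age, sex=sex, icu_admit=icu_admit, icu_discharge=discharge,
            krt_time=None, death_time=None, eskd=eskd,
            creatinine_obs=obs, regime=regime,
        )
        admissions.append(rec)
        day_vals = np.array([v for _, v in traj])
        all_krt_lp.append(_linear_predictor(day_vals, baseline,
                                            config.krt_hazard_slope,
                                            config.krt_change_slope,
                                            config.krt_level_slope,
                                            config.ckd_krt_boost if is_ckd else 0.0))
        all_death_lp.append(_linear_predictor(day_vals, baseline,
                                              config.death_hazard_slope,
                                              config.death_change_slope,
                                              config.death_level_slope,
                                              config.ckd_death_boost if is_ckd else 0.0))
        all_day_times.append(day_times)

    zero_lp = [np.zeros_like(lp) for lp in all_death_lp]
    death_a = _calibrate_intercept(
        all_death_lp, config.death_target_rate * (1 - config.death_random_frac))
    death_a0 = _calibrate_intercept(
        zero_lp, config.death_target_rate * config.death_random_frac)
    death_days = [_sample_event_day(lp, rng, death_a, death_a0)
                  for lp in all_death_lp]
    # KRT hazard calibrated on death-truncated trajectories so the realized
    # KRT fraction matches its target despite the competing event.
    truncated = [lp if d is None else lp[:d + 1]
                 for lp, d in zip(all_krt_lp, death_days)]
    krt_a = _calibrate_intercept(
        truncated, config.krt_target_rate * (1 - config.krt_random_frac))
    krt_a0 = _calibrate_intercept(
        [np.zeros_like(lp) for lp in truncated],
        config.krt_target_rate * config.krt_random_frac)
    for rec, klp, dlp, day_times, dd in zip(admissions, all_krt_lp, all_death_lp,
                                            all_day_times, death_days):
        sample_outcomes(rec, klp, dlp, rng, krt_a, death_a, day_times, death_day=dd,
                        krt_rand_intercept=krt_a0, death_rand_intercept=death_a0)
        rec.validate()
    return admissions


# ---------------------------------------------------------------------------
# CSV interchange (RFC-4180, ISO-8601 timestamps)

ADMISSION_COLUMNS = ["admission_id", "patient_id", "age", "sex", "icu_admit",
                     "icu_discharge", "krt_time", "death_time", "eskd", "regime"]
LAB_COLUMNS = ["admission_id", "charttime", "creatinine_mg_dl"]


def cohort_to_frames(cohort: list[AdmissionRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into an admissions table and a long-format labs table."""
    adm_rows, lab_rows = [], []
    for r in cohort:
        adm_rows.append({
            "admission_id": r.admission_id, "patient_id": r.patient_id,
            "age": r.age, "sex": r.sex,
            "icu_admit": r.icu_admit.isoformat(),
            "icu_discharge": r.icu_discharge.isoformat(),
            "krt_time": r.krt_time.isoformat() if r.krt_time is not None else "",
            "death_time": r.death_time.isoformat() if r.death_time is not None else "",
            "eskd": int(r.eskd), "regime": r.regime or "",
        })
        for t, v in r.creatinine_obs:
            lab_rows.append({"admission_id": r.admission_id,
                             "charttime": t.isoformat(), "creatinine_mg_dl": v})
    return (pd.DataFrame(adm_rows, columns=ADMISSION_COLUMNS),
            pd.DataFrame(lab_rows, columns=LAB_COLUMNS))


def write_cohort_csv(cohort, admissions_path, labs_path) -> None:
    adm, labs = cohort_to_frames(cohort)
    adm.to_csv(admissions_path, index=False)
    labs.to_csv(labs_path, index=False)


def read_cohort_csv(admissions_path, labs_path) -> list[AdmissionRecord]:
    """Load admissions + labs CSV back into AdmissionRecord objects."""
    adm = pd.read_csv(admissions_path, dtype={"admission_id": str, "patient_id": str},
                      keep_default_na=False)
    labs = pd.read_csv(labs_path, dtype={"admission_id": str})
    labs["charttime"] = pd.to_datetime(labs["charttime"])
    labs = labs.sort_values(["admission_id", "charttime"])
    grouped = {k: list(zip(g["charttime"], g["creatinine_mg_dl"]))
               for k, g in labs.groupby("admission_id")}
    cohort = []
    for row in adm.itertuples(index=False):
        cohort.append(AdmissionRecord(
            admission_id=row.admission_id, patient_id=row.patient_id,
            age=float(row.age), sex=row.sex,
            icu_admit=pd.Timestamp(row.icu_admit),
            icu_discharge=pd.Timestamp(row.icu_discharge),
            krt_time=pd.Timestamp(row.krt_time) if row.krt_time else None,
            death_time=pd.Timestamp(row.death_time) if row.death_time else None,
            eskd=bool(int(row.eskd)),
            creatinine_obs=grouped.get(row.admission_id, []),
            regime=row.regime or None,
        ))
    return cohort
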