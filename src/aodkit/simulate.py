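"""Synthetic-cohort generator.

Emulates the measurement structure of a cycle-ergometer AOD study so every
estimator and the comparison engine are testable with known ground truth:

* per-subject linear VO2-power relations (intercept ~0.50 mmol/s,
  slope ~8.8 umol/J);
* a slow-component drift: the 3-4-min VO2 sits below the 8-10-min steady
  state by a fraction 1/(1+drift), with drift +1.8 % below and +4.9 % at or
  above the lactate threshold;
* a non-linear VO2 excess at low powers, decaying quadratically to zero at
  the frequency-dependent threshold (75 W at 1.5 Hz, 30 W at 0.75 Hz);
* a cubic dependence of loadless-pedaling VO2 on pedaling frequency,
  VO2_loadless(f) = resting + k*f**3 with k = 0.1185 mmol s^-1 Hz^-3 (which
  anchors loadless VO2 at 1.5 Hz to 0.66 mmol/s for mean resting 0.26);
* a small offset of the stepwise protocol versus rested 4-min bouts
  (+0.015 mmol/s at 1.5 Hz, none at 0.75 Hz);
* blood lactate rising logistically through the 4.0 mmol/L criterion at the
  subject's threshold power;
* independent Gaussian measurement noise per recorded window
  (default SD 0.03 mmol/s).

Simulations are fully reproducible from (config, master seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .datamodel import Cohort, Measurement, Subject
from .errors import ConfigError

_EARLY_WINDOW = (180.0, 240.0)
_LATE_WINDOW = (480.0, 600.0)


@dataclass
class GeneratorConfig:
    """Population-level parameters of the synthetic cohort.

    Means and SDs mirror the cohort the generator emulates: 13 moderately
    trained adults (3 women, 10 men), VO2max 2.9 +/- 0.6 mmol/s, measured
    mostly at 1.5 Hz pedaling.  All rates are in the package's canonical
    units (mmol/s, W, umol/J).
    """

    n_subjects: int = 13
    frequencies: tuple = (1.5,)
    seed: int = 0

    intercept_mean: float = 0.50    # mmol/s
    intercept_sd: float = 0.05
    slope_mean: float = 8.8         # umol/J
    slope_sd: float = 0.8
    vo2max_mean: float = 2.9        # mmol/s
    vo2max_sd: float = 0.6
    resting_mean: float = 0.26      # mmol/s
    resting_sd: float = 0.03

    drift_below: float = 0.018      # fractional 4->10-min rise below LT
    drift_above: float = 0.049      # ... at or above LT
    lt_fraction: float = 0.75       # LT power as fraction of VO2max power
    min_vo2max_power: float = 150.0  # W; truncation floor for the VO2max draw

    female_fraction: float = 3 / 13
    mass_female_mean: float = 74.0  # kg
    mass_male_mean: float = 82.0
    mass_sd: float = 7.0

    freq_cubic_k: float = 0.1185    # mmol s^-1 Hz^-3
    f_ref: float = 1.5              # Hz
    nonlinear_thresholds: dict = field(
        default_factory=lambda: {1.5: 75.0, 0.75: 30.0})  # W by Hz
    step4_offsets: dict = field(
        default_factory=lambda: {1.5: 0.015, 0.75: 0.0})  # mmol/s by Hz

    noise_sd: float = 0.03          # mmol/s per recorded window
    lactate_noise_sd: float = 0.2   # mmol/L
    lactate_max: float = 8.0        # mmol/L logistic asymptote
    lactate_scale: float = 15.0     # W logistic scale

    bout_low_frac: float = 0.30     # lowest bout power / VO2max power
    bout_high_frac: float = 0.95
    max_step: float = 22.0          # W, largest bout-to-bout increment
    step4_increment_male: float = 22.0    # W per 4-min step
    step4_increment_female: float = 11.0
    include_step4: bool = True
    include_loadless: bool = True
    include_rest: bool = True

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        for name in ("intercept_sd", "slope_sd", "vo2max_sd", "resting_sd",
                     "mass_sd", "noise_sd", "lactate_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.drift_below <= self.drift_above:
            raise ConfigError("need 0 <= drift_below <= drift_above")

    def threshold(self, frequency: float) -> float:
        knots = sorted(self.nonlinear_thresholds.items())
        for f, t in knots:
            if math.isclose(f, frequency):
                return t
        return float(np.interp(frequency, [f for f, _ in knots],
                               [t for _, t in knots]))

    def step4_offset(self, frequency: float) -> float:
        knots = sorted(self.step4_offsets.items())
        for f, off in knots:
            if math.isclose(f, frequency):
                return off
        return float(np.interp(frequency, [f for f, _ in knots],
                               [o for _, o in knots]))


@dataclass
class SubjectTruth:
    """Generative parameters of one synthetic subject (the ground truth)."""

    subject_id: str
    sex: str
    intercept_true: float       # mmol/s
    slope_true: float           # umol/J
    vo2max: float               # mmol/s
    body_mass: float            # kg
    resting_vo2: float          # mmol/s
    loadless_excess_e0: float   # mmol/s above the intercept at f_ref
    lt_power: float             # W
    drift_below: float
    drift_above: float
    noise_sd: float

    @property
    def vo2max_power(self) -> float:
        """Power (W) at which the true linear relation predicts VO2max."""
        return (self.vo2max - self.intercept_true) / self.slope_true * 1000.0


def _truncated_normal(rng, mean, sd, lower, upper=math.inf, max_tries=1000):
    if sd == 0:
        if not lower <= mean <= upper:
            raise ConfigError(f"degenerate draw {mean} outside [{lower}, {upper}]")
        return float(mean)
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lower <= x <= upper:
            return float(x)
    raise ConfigError(
        f"truncation [{lower}, {upper}] incompatible with N({mean}, {sd})")


def sample_subject(cfg: GeneratorConfig, rng: np.random.Generator,
                   index: int = 0) -> SubjectTruth:
    """Draw one subject's ground truth from the population distributions.

    Truncation keeps the draws physiological (positive rates, VO2max above
    the intercept).  The low-power excess at the reference frequency is
    anchored so that loadless VO2 equals ``resting + k*f**3`` exactly.
    """
    sex = "F" if index < round(cfg.female_fraction * cfg.n_subjects) else "M"
    mass_mean = cfg.mass_female_mean if sex == "F" else cfg.mass_male_mean
    a = _truncated_normal(rng, cfg.intercept_mean, cfg.intercept_sd, 0.1)
    b = _truncated_normal(rng, cfg.slope_mean, cfg.slope_sd, 3.0)
    # every subject must be able to cycle the full submaximal grid: the
    # power at VO2max stays above a physiological floor
    vo2max = _truncated_normal(rng, cfg.vo2max_mean, cfg.vo2max_sd,
                               a + b * cfg.min_vo2max_power / 1000.0)
    resting = _truncated_normal(rng, cfg.resting_mean, cfg.resting_sd, 0.05)
    mass = _truncated_normal(rng, mass_mean, cfg.mass_sd, 40.0)
    e0 = max(0.0, resting + cfg.freq_cubic_k * cfg.f_ref ** 3 - a)
    p_max = (vo2max - a) / b * 1000.0
    return SubjectTruth(
        subject_id=f"S{index + 1:02d}", sex=sex,
        intercept_true=a, slope_true=b, vo2max=vo2max, body_mass=mass,
        resting_vo2=resting, loadless_excess_e0=e0,
        lt_power=cfg.lt_fraction * p_max,
        drift_below=cfg.drift_below, drift_above=cfg.drift_above,
        noise_sd=cfg.noise_sd,
    )


def low_power_excess(truth: SubjectTruth, power: float, frequency: float,
                     cfg: GeneratorConfig) -> float:
    """Non-linear VO2 excess (mmol/s): quadratic decay, zero at threshold."""
    e_f = max(0.0, truth.loadless_excess_e0
              + cfg.freq_cubic_k * (frequency ** 3 - cfg.f_ref ** 3))
    p_nl = cfg.threshold(frequency)
    if p_nl <= 0 or power >= p_nl:
        return 0.0
    return e_f * (1.0 - power / p_nl) ** 2


def expected_vo2(truth: SubjectTruth, power: float, frequency: float,
                 protocol: str, window: str = "late",
                 cfg: Optional[GeneratorConfig] = None) -> float:
    """Noise-free VO2 (mmol/s) for one measurement context.

    ``window`` is "late" (8-10 min, the steady state) or "early" (3-4 min,
    the steady state divided by 1 + drift).  The drift fraction depends on
    whether the power is at or above the subject's lactate-threshold power.
    """
    cfg = cfg if cfg is not None else GeneratorConfig()
    if protocol == "rest":
        return truth.resting_vo2
    steady = (truth.intercept_true + truth.slope_true * power / 1000.0
              + low_power_excess(truth, power, frequency, cfg))
    if protocol == "loadless":
        return steady
    if window not in ("early", "late"):
        raise ConfigError(f"unknown window {window!r}")
    if protocol in ("bout10", "bout4_rest"):
        if window == "late":
            return steady
        drift = truth.drift_below if power < truth.lt_power else truth.drift_above
        return steady / (1.0 + drift)
    if protocol == "step4":
        drift = truth.drift_below if power < truth.lt_power else truth.drift_above
        return steady / (1.0 + drift) + cfg.step4_offset(frequency)
    raise ConfigError(f"unknown protocol {protocol!r}")


def _lactate(truth: SubjectTruth, power: float, cfg: GeneratorConfig) -> float:
    """Logistic lactate-power curve crossing the 4.0 criterion at lt_power."""
    z = (power - truth.lt_power) / cfg.lactate_scale
    return cfg.lactate_max / (1.0 + math.exp(-z))


def _heart_rate(truth: SubjectTruth, demand: float,
                rng: np.random.Generator) -> float:
    frac = min(demand / truth.vo2max, 1.05)
    return round(float(60.0 + 130.0 * frac + rng.normal(0, 3.0)), 0)


def simulate_subject(truth: SubjectTruth, cfg: GeneratorConfig,
                     rng: np.random.Generator) -> Subject:
    """Generate the full measurement menu for one subject."""
    ms: list[Measurement] = []
    noise = lambda: float(rng.normal(0, cfg.noise_sd)) if cfg.noise_sd else 0.0
    p_max = truth.vo2max_power

    for f in cfg.frequencies:
        lo, hi = cfg.bout_low_frac * p_max, cfg.bout_high_frac * p_max
        n_bouts = int(math.ceil((hi - lo) / cfg.max_step)) + 1
        powers = np.linspace(lo, hi, n_bouts)
        for P in powers:
            P = float(round(P, 1))
            for window, (w0, w1) in (("early", _EARLY_WINDOW),
                                     ("late", _LATE_WINDOW)):
                v = max(0.0, expected_vo2(truth, P, f, "bout10", window, cfg) + noise())
                lac = None
                if window == "late":
                    lac = round(max(0.4, _lactate(truth, P, cfg)
                                    + float(rng.normal(0, cfg.lactate_noise_sd))), 2)
                ms.append(Measurement(
                    truth.subject_id, "bout10", f, P, w0, w1, v,
                    hr=_heart_rate(truth, v, rng), lactate=lac))
        if cfg.include_step4:
            step = (cfg.step4_increment_female if truth.sex == "F"
                    else cfg.step4_increment_male)
            P = 2.0 * step      # "rather low" starting power, < 100 W
            while P <= hi:
                v = max(0.0, expected_vo2(truth, P, f, "step4", "early", cfg) + noise())
                lac = round(max(0.4, _lactate(truth, P, cfg)
                                + float(rng.normal(0, cfg.lactate_noise_sd))), 2)
                ms.append(Measurement(
                    truth.subject_id, "step4", f, float(P),
                    *_EARLY_WINDOW, v, hr=_heart_rate(truth, v, rng), lactate=lac))
                P += step
        if cfg.include_loadless:
            v = max(0.0, expected_vo2(truth, 0.0, f, "loadless", "late", cfg) + noise())
            ms.append(Measurement(truth.subject_id, "loadless", f, 0.0,
                                  *_LATE_WINDOW, v))
    if cfg.include_rest:
        v = max(0.0, expected_vo2(truth, 0.0, 0.0, "rest", "late", cfg) + noise())
        ms.append(Measurement(truth.subject_id, "rest", 0.0, 0.0,
                              300.0, 600.0, v))
    return Subject(subject_id=truth.subject_id, sex=truth.sex,
                   body_mass=truth.body_mass, vo2max=truth.vo2max,
                   measurements=ms)


def simulate_cohort(cfg: GeneratorConfig) -> tuple[Cohort, list[SubjectTruth]]:
    """Generate a cohort and its ground truths from (config, master seed)."""
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    subjects, truths = [], []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        truth = sample_subject(cfg, rng, index=i)
        subjects.append(simulate_subject(truth, cfg, rng))
        truths.append(truth)
    return Cohort(subjects), truths


def truths_to_json(truths: Sequence[SubjectTruth], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([asdict(t) for t in truths], fh, indent=1)
        fh.write("\n")


def truths_from_json(path) -> list[SubjectTruth]:
    with open(path) as fh:
        return [SubjectTruth(**rec) for rec in json.load(fh)]
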