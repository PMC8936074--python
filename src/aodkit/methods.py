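"""The nine demand-relation methods (M0-M8).

Each method turns a subject's measurements into one linear power -> O2-demand
relation, differing in which measurements it uses and whether the intercept
is fitted or forced:

=====  ==============================================================
M0     reference: OLS on 8-10-min steady-state VO2 of 10-min bouts
M1     OLS on the 3-4-min window of rested bouts
M2     M1 points, intercept forced to the cohort common intercept
M3     OLS on the 4-min stepwise-increasing-power protocol
M4     OLS on all 10-min-bout points including low powers and loadless
M5     intercept = cohort mean of individual intercepts; slope through
       the highest-power steady-state point(s)
M6     gross efficiency: intercept 0, slope through the high point(s)
M7     net efficiency: intercept = resting VO2
M8     net efficiency: intercept = loadless-pedaling VO2 at the
       session frequency
=====  ==============================================================

Measurements at powers below a frequency-dependent threshold (default 75 W at
1.5 Hz, 30 W at 0.75 Hz) show a non-linear VO2 excess and are excluded from
every method except M4.  Power exactly at the threshold is kept (the excess
is taken to vanish there); this boundary convention is configurable.
Frequencies are never pooled: one relation per (subject, frequency).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .datamodel import Cohort, Measurement, Subject
from .errors import (ConfigError, InsufficientDataError, MissingProtocolError,
                     ThresholdNotReachedError)
from .regression import FrequencyPolynomial, LinearDemand

METHOD_IDS = tuple(f"M{i}" for i in range(9))

#: Methods whose intercept is estimated by regression (need >= 2 points).
REGRESSION_METHODS = ("M0", "M1", "M3", "M4")
#: Methods with a fixed intercept and a high-power anchor (need >= 1 point).
FIXED_INTERCEPT_METHODS = ("M2", "M5", "M6", "M7", "M8")


@dataclass(frozen=True)
class LinearRelation:
    """A fitted linear power -> O2-demand relation with provenance.

    intercept a in mmol s^-1, slope b in umol J^-1, so the demand at power P
    (W) is ``a + b*P/1000`` mmol s^-1.
    """

    intercept: float
    slope: float
    method_id: Optional[str] = None
    n_points: int = 0
    frequency: Optional[float] = None
    subject_id: Optional[str] = None

    def __post_init__(self):
        if not self.slope > 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")

    def demand_at_power(self, power: float) -> float:
        """O2 demand (mmol s^-1) at a power in W."""
        if power < 0:
            raise ValueError(f"power must be >= 0, got {power}")
        return self.intercept + self.slope * power / 1000.0

    def invert(self, demand: float) -> float:
        """Power (W) at which the relation predicts the given demand."""
        est = LinearDemand()
        est.intercept_, est.slope_, est.n_points_ = self.intercept, self.slope, 2
        est.n_features_in_ = 1
        return est.invert(demand)


@dataclass
class FitConfig:
    """Tunable knobs of the method builder.

    low_power_threshold maps pedaling frequency (Hz) to the inclusion
    threshold (W); unknown frequencies interpolate linearly between, and clamp
    to, the configured knots.  ``n_high_points`` is the number of top-power
    steady-state points averaged into the M5-M8 anchor (1 mirrors the original
    analysis; 2-3 is the recommended safeguard against a single bad
    measurement).  ``common_intercept`` overrides the cohort-derived value for
    M2/M5 when set.
    """

    low_power_threshold: Mapping[float, float] = field(
        default_factory=lambda: {1.5: 75.0, 0.75: 30.0})
    include_boundary: bool = True
    include_low_power: bool = False   # M4 sets this implicitly
    common_intercept: Optional[float] = None
    n_high_points: int = 1
    lactate_criterion: float = 4.0

    def __post_init__(self):
        if any(t < 0 for t in self.low_power_threshold.values()):
            raise ConfigError("thresholds must be >= 0")
        if self.n_high_points < 1:
            raise ConfigError("n_high_points must be >= 1")

    def threshold(self, frequency: float) -> float:
        """Low-power inclusion threshold (W) at a pedaling frequency."""
        knots = sorted(self.low_power_threshold.items())
        for f, t in knots:
            if math.isclose(f, frequency):
                return t
        fs = [f for f, _ in knots]
        ts = [t for _, t in knots]
        return float(np.interp(frequency, fs, ts))


@dataclass(frozen=True)
class PolyFit:
    """Polynomial VO2-frequency fit: coefficients ascending, domain in Hz."""

    degree: int
    coefficients: tuple
    domain: tuple
    r2: float

    def __call__(self, f):
        return np.polynomial.polynomial.polyval(f, self.coefficients)


# ---------------------------------------------------------------------------
# fitting primitives (thin wrappers over the estimators)

def fit_ols(points: Sequence, **provenance) -> LinearRelation:
    """Ordinary least squares on (power W, vo2 mmol/s) pairs."""
    pts = np.asarray(points, dtype=float)
    est = LinearDemand().fit(pts[:, :1], pts[:, 1])
    return LinearRelation(est.intercept_, est.slope_,
                          n_points=est.n_points_, **provenance)


def fit_ols_fixed_intercept(points: Sequence, a0: float, **provenance) -> LinearRelation:
    """Constrained least squares with the intercept forced to ``a0``."""
    pts = np.asarray(points, dtype=float)
    est = LinearDemand(fixed_intercept=a0).fit(pts[:, :1], pts[:, 1])
    return LinearRelation(est.intercept_, est.slope_,
                          n_points=est.n_points_, **provenance)


# ---------------------------------------------------------------------------
# inclusion rules

_METHOD_SELECTION = {
    # method: (protocols, late_window, apply_threshold)
    "M0": (("bout10",), True, True),
    "M1": (("bout10", "bout4_rest"), False, True),
    "M2": (("bout10", "bout4_rest"), False, True),
    "M3": (("step4",), False, True),
    "M4": (("bout10", "loadless"), True, False),
    "M5": (("bout10",), True, True),
    "M6": (("bout10",), True, True),
    "M7": (("bout10",), True, True),
    "M8": (("bout10",), True, True),
}


def apply_inclusion_rules(measurements: Iterable[Measurement], cfg: FitConfig,
                          method_id: str) -> np.ndarray:
    """Select and order the (power, vo2) points a method may use.

    All measurements must share one pedaling frequency (rest rows excluded
    upstream).  Returns an (n, 2) array sorted by power.  Raises
    :class:`InsufficientDataError`, naming the rule responsible, when a
    regression method is left with fewer than two points.
    """
    if method_id not in _METHOD_SELECTION:
        raise ConfigError(f"unknown method {method_id!r}")
    ms = list(measurements)
    freqs = {m.frequency for m in ms}
    if len(freqs) > 1:
        raise ConfigError(f"measurements mix frequencies {sorted(freqs)}; "
                          "fit one relation per frequency")
    protocols, late, use_threshold = _METHOD_SELECTION[method_id]
    sel = [m for m in ms if m.protocol in protocols]
    # bout4_rest has only an early window; the window rule applies to bout10
    if late:
        sel = [m for m in sel if m.protocol == "loadless" or m.is_late_window]
    else:
        sel = [m for m in sel if m.protocol != "bout10" or not m.is_late_window]
    n_before = len(sel)
    rule = "protocol/window selection"
    if use_threshold and sel:
        thr = cfg.threshold(sel[0].frequency)
        if cfg.include_boundary:
            sel = [m for m in sel if m.power >= thr]
        else:
            sel = [m for m in sel if m.power > thr]
        if len(sel) < n_before:
            rule = f"low-power threshold {thr:g} W"
    pts = np.array(sorted((m.power, m.vo2) for m in sel), dtype=float)
    if method_id in REGRESSION_METHODS and len(pts) < 2:
        raise InsufficientDataError(
            f"{method_id}: {len(pts)} point(s) survive after {rule}; need >= 2")
    if method_id in FIXED_INTERCEPT_METHODS and len(pts) < 1:
        raise InsufficientDataError(
            f"{method_id}: no points survive after {rule}")
    return pts.reshape(-1, 2)


def _high_anchor(points: np.ndarray, n_high: int) -> tuple[float, float]:
    """Mean (power, vo2) of the n_high highest-power points.

    Several bouts at the same top power are averaged first (tie-break), then
    the ``n_high`` highest distinct powers are averaged.
    """
    powers = points[:, 0]
    distinct = np.unique(powers)[::-1][:n_high]
    sel = points[np.isin(powers, distinct)]
    return float(sel[:, 0].mean()), float(sel[:, 1].mean())


# ---------------------------------------------------------------------------
# method builder

def build_method_relation(subject: Subject, method_id: str, cfg: FitConfig,
                          frequency: float,
                          common_intercept: Optional[float] = None) -> LinearRelation:
    """Build one method's linear relation for a subject at one frequency.

    ``common_intercept`` (mmol s^-1) is required by M2 and M5 unless already
    set in ``cfg``; compute it with :func:`cohort_common_intercept`.
    """
    prov = dict(method_id=method_id, frequency=frequency,
                subject_id=subject.subject_id)
    ms = subject.select(frequency=frequency)
    if method_id in REGRESSION_METHODS:
        pts = apply_inclusion_rules(ms, cfg, method_id)
        return fit_ols(pts, **prov)

    if method_id not in FIXED_INTERCEPT_METHODS:
        raise ConfigError(f"unknown method {method_id!r}")

    if method_id == "M2":
        a0 = common_intercept if common_intercept is not None else cfg.common_intercept
        if a0 is None:
            raise ConfigError("M2 needs a common intercept "
                              "(cohort mean of the M1 intercepts)")
        pts = apply_inclusion_rules(ms, cfg, "M2")
        return fit_ols_fixed_intercept(pts, a0, **prov)

    # M5-M8: fixed intercept, slope through the high-power anchor
    pts = apply_inclusion_rules(ms, cfg, method_id)
    p_hi, y_hi = _high_anchor(pts, cfg.n_high_points)
    if method_id == "M5":
        a0 = common_intercept if common_intercept is not None else cfg.common_intercept
        if a0 is None:
            raise ConfigError("M5 needs a common intercept "
                              "(cohort mean of the individual intercepts)")
    elif method_id == "M6":
        a0 = 0.0
    elif method_id == "M7":
        rest = subject.select(protocol="rest")
        if not rest:
            raise MissingProtocolError(
                f"{subject.subject_id}: M7 needs a resting measurement")
        a0 = float(np.mean([m.vo2 for m in rest]))
    else:  # M8
        loadless = subject.select(protocol="loadless", frequency=frequency)
        if not loadless:
            raise MissingProtocolError(
                f"{subject.subject_id}: M8 needs loadless pedaling at "
                f"{frequency} Hz")
        a0 = float(np.mean([m.vo2 for m in loadless]))
    b = (y_hi - a0) / p_hi * 1000.0
    n_used = int(np.isin(pts[:, 0], np.unique(pts[:, 0])[::-1][:cfg.n_high_points]).sum())
    return LinearRelation(a0, b, n_points=n_used, **prov)


def mean_common_intercept(relations: Iterable[LinearRelation]) -> float:
    """Unweighted mean of individual intercepts (the common intercept)."""
    intercepts = [r.intercept for r in relations]
    if not intercepts:
        raise ValueError("no relations given")
    return float(np.mean(intercepts))


def cohort_common_intercept(cohort: Cohort, cfg: FitConfig, frequency: float,
                            base_method: str = "M1") -> float:
    """Cohort mean of the individual intercepts of ``base_method``.

    M2 forces the mean of the 4-min-method (M1) intercepts; M5 conventionally
    uses the mean of the reference-method (M0) intercepts.  Subjects for whom
    the base method cannot be fitted are excluded subject-wise.
    """
    rels = []
    for s in cohort:
        try:
            rels.append(build_method_relation(s, base_method, cfg, frequency))
        except (InsufficientDataError, MissingProtocolError):
            continue
    if not rels:
        raise InsufficientDataError(
            f"no subject supports {base_method} at {frequency} Hz")
    return mean_common_intercept(rels)


def build_cohort_relations(cohort: Cohort, cfg: FitConfig, frequency: float,
                           methods: Sequence[str] = METHOD_IDS,
                           ) -> dict[str, dict[str, LinearRelation]]:
    """All requested relations: {subject_id: {method_id: LinearRelation}}.

    Methods a subject cannot support (missing protocol, too few points) are
    skipped for that subject with a warning.
    """
    common = {}
    for mid, base in (("M2", "M1"), ("M5", "M0")):
        if mid in methods and cfg.common_intercept is None:
            common[mid] = cohort_common_intercept(cohort, cfg, frequency, base)
    out: dict[str, dict[str, LinearRelation]] = {}
    for s in cohort:
        out[s.subject_id] = {}
        for mid in methods:
            try:
                rel = build_method_relation(
                    s, mid, cfg, frequency, common_intercept=common.get(mid))
            except (InsufficientDataError, MissingProtocolError) as exc:
                warnings.warn(f"skipping {mid} for {s.subject_id}: {exc}")
                continue
            out[s.subject_id][mid] = rel
    return out


# ---------------------------------------------------------------------------
# auxiliary fits

def lactate_threshold_power(lactate_points: Sequence, criterion: float = 4.0) -> float:
    """Power (W) at which blood lactate first reaches the criterion.

    ``lactate_points`` are (power, lactate) pairs sorted by power.  An exact
    hit returns that power; otherwise the first upward crossing is linearly
    interpolated between the bracketing points.  Raises
    :class:`ThresholdNotReachedError` if lactate never reaches the criterion,
    in which case all the subject's bouts classify as below-threshold.
    """
    pts = np.asarray(lactate_points, dtype=float).reshape(-1, 2)
    if np.any(np.diff(pts[:, 0]) < 0):
        raise ValueError("points must be sorted by power")
    P, lac = pts[:, 0], pts[:, 1]
    crossings = []
    for i in range(len(P)):
        if lac[i] == criterion:
            crossings.append(P[i])
        elif i > 0 and lac[i - 1] < criterion < lac[i]:
            frac = (criterion - lac[i - 1]) / (lac[i] - lac[i - 1])
            crossings.append(P[i - 1] + frac * (P[i] - P[i - 1]))
    if not crossings:
        if lac[0] > criterion:
            return float(P[0])   # already above at the lowest power measured
        raise ThresholdNotReachedError(
            f"lactate never reaches {criterion} mmol/L "
            f"(max {lac.max():g} mmol/L)")
    if len(crossings) > 1:
        warnings.warn("multiple lactate crossings; using the first")
    return float(crossings[0])


def fit_frequency_polynomial(points: Sequence, degree: int = 3) -> PolyFit:
    """Least-squares polynomial of VO2 (mmol/s) on pedaling frequency (Hz)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    est = FrequencyPolynomial(degree=degree).fit(pts[:, :1], pts[:, 1])
    return PolyFit(degree=degree, coefficients=tuple(est.coef_),
                   domain=est.domain_, r2=est.r2_)
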