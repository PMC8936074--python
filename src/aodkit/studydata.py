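"""Summary statistics of the original cycle-ergometry study.

The raw per-subject data behind the nine-method comparison are not deposited;
what is public is the summary table: per-method cohort-mean intercepts and
slopes, the AOD grid they imply under the five exercise models, cohort
anthropometrics by sex, and the 4 -> 10-min VO2 drift subgroup means.  These
constants serve as worked-example inputs (the README example and the
reproduction script feed them to the engine); nothing in the estimation code
depends on them.
"""

from __future__ import annotations

from .methods import LinearRelation

#: Cohort-mean intercept (mmol s^-1) and slope (umol J^-1) per method,
#: at 1.5 Hz pedaling.  M6's zero intercept is the gross-efficiency premise.
METHOD_COEFFICIENTS = {
    "M0": (0.48, 8.77),
    "M1": (0.50, 8.38),
    "M2": (0.50, 8.51),
    "M3": (0.45, 9.00),
    "M4": (0.60, 8.24),
    "M5": (0.48, 8.71),
    "M6": (0.00, 10.80),
    "M7": (0.26, 9.66),
    "M8": (0.66, 7.95),
}

#: Reported AOD grid (mmol per kg body mass), methods x exercise models
#: ordered (10 s, 30 s, 60 s, 120 s, 217 s).
REPORTED_AOD_PER_KG = {
    "M0": (0.82, 1.52, 1.73, 1.95, 1.97),
    "M1": (0.77, 1.42, 1.58, 1.71, 1.64),
    "M2": (0.78, 1.45, 1.62, 1.78, 1.74),
    "M3": (0.82, 1.53, 1.73, 1.94, 1.94),
    "M4": (0.77, 1.43, 1.63, 1.83, 1.86),
    "M5": (0.80, 1.48, 1.67, 1.86, 1.84),
    "M6": (0.94, 1.77, 1.99, 2.20, 2.07),
    "M7": (0.86, 1.61, 1.81, 2.01, 1.93),
    "M8": (0.75, 1.38, 1.56, 1.73, 1.75),
}

#: Cohort-mean maximal O2 uptake, mmol s^-1 (3.9 L_STPD min^-1).
VO2MAX_MEAN = 2.9

#: Group mean body masses (kg) and group sizes: (women, men).
BODY_MASS_GROUPS = ((74.0, 3), (82.0, 10))

#: Common intercept: cohort mean of the individual 4-min-method intercepts.
COMMON_INTERCEPT = 0.50

#: 4 -> 10-min VO2 increase at 1.5 Hz: (mean increase mmol s^-1, n pairs),
#: below and at-or-above the 4.0 mmol/L lactate threshold.
DRIFT_SUBGROUPS = ((0.026, 126), (0.113, 33))

#: Fractional 4 -> 10-min VO2 rise below / at-or-above the lactate threshold.
DRIFT_FRACTION_BELOW = 0.018
DRIFT_FRACTION_ABOVE = 0.049

#: Low-power inclusion thresholds (W) by pedaling frequency (Hz).
LOW_POWER_THRESHOLDS = {1.5: 75.0, 0.75: 30.0}


def reconstructed_mean_mass(groups=BODY_MASS_GROUPS) -> float:
    """Cohort mean body mass (kg) from the group means and sizes.

    The 13-subject mean is not reported directly; the size-weighted mean of
    the sex-group means, (3*74 + 10*82)/13 = 80.15 kg, reconstructs it and
    remains overridable wherever it is consumed.
    """
    total = sum(mass * n for mass, n in groups)
    n = sum(n for _, n in groups)
    if n == 0:
        raise ValueError("empty groups")
    return total / n


def method_relations() -> dict[str, LinearRelation]:
    """The reported per-method coefficients as LinearRelation objects."""
    return {
        mid: LinearRelation(a, b, method_id=mid, frequency=1.5,
                            subject_id="cohort-mean")
        for mid, (a, b) in METHOD_COEFFICIENTS.items()
    }
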