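"""Supramaximal exercise-intensity models.

AOD estimation extrapolates the fitted demand relation to intensities above
that eliciting maximal O2 uptake.  Five canonical constant-intensity
exercise-to-exhaustion models are used, spanning 100-250 % of the VO2max
intensity.  Times to exhaustion and the aerobic fraction of total energy
release (the share covered by accumulated O2 uptake) come from pooled prior
exhaustive-exercise data:

======== ============== ===================
fraction time (s)       aerobic fraction
======== ============== ===================
100 %    217 (3.6 min)  0.75
120 %    120            0.63
150 %     60            0.47
200 %     30            0.30
250 %     10            0.10
======== ============== ===================

The reference O2 demand of each model is ``fraction * cohort-mean VO2max``;
the corresponding power is obtained by inverting the reference linear
relation.  ``printed_exercise_models`` instead injects the historically
reported rounded demands and powers verbatim, which is what a worked-example
reproduction of the published AOD grid requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import NonPhysicalPowerError
from .methods import LinearRelation

INTENSITY_FRACTIONS = (1.00, 1.20, 1.50, 2.00, 2.50)
TIMES_TO_EXHAUSTION_S = (217.0, 120.0, 60.0, 30.0, 10.0)
AEROBIC_FRACTIONS = (0.75, 0.63, 0.47, 0.30, 0.10)

#: Rounded reference demands (mmol s^-1) and modeled powers (W) as printed in
#: the study this package reproduces as its worked example (VO2max mean
#: 2.9 mmol s^-1, reference coefficients a=0.48, b=8.77 before rounding).
PRINTED_DEMANDS = (2.9, 3.5, 4.4, 5.8, 7.3)
PRINTED_POWERS = (274.0, 343.0, 438.0, 603.0, 768.0)


@dataclass(frozen=True)
class ExerciseModel:
    """One supramaximal constant-intensity exercise-to-exhaustion scenario."""

    intensity_fraction: float     # fraction of VO2max (1.0 - 2.5)
    time_to_exhaustion: float     # s
    aerobic_fraction: float       # share of total energy from O2 uptake
    demand_ref: float             # reference O2 demand, mmol s^-1
    power: float                  # W

    def __post_init__(self):
        if not 0.0 <= self.aerobic_fraction <= 1.0:
            raise ValueError("aerobic_fraction must be in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.time_to_exhaustion:g} s, {self.intensity_fraction:.0%}"


def default_exercise_models(vo2max_mean: float,
                            reference: LinearRelation) -> list[ExerciseModel]:
    """The five models with demands/powers recomputed from the reference fit.

    demand_ref = intensity_fraction * vo2max_mean; power inverts the reference
    relation at that demand.  Raises :class:`NonPhysicalPowerError` if a
    demand falls below the reference intercept.
    """
    models = []
    for frac, t, aer in zip(INTENSITY_FRACTIONS, TIMES_TO_EXHAUSTION_S,
                            AEROBIC_FRACTIONS):
        demand = frac * vo2max_mean
        power = reference.invert(demand)
        models.append(ExerciseModel(frac, t, aer, demand, power))
    _check_monotone(models)
    return models


def printed_exercise_models() -> list[ExerciseModel]:
    """The five models with the historically printed demands and powers."""
    models = [
        ExerciseModel(frac, t, aer, d, p)
        for frac, t, aer, d, p in zip(
            INTENSITY_FRACTIONS, TIMES_TO_EXHAUSTION_S, AEROBIC_FRACTIONS,
            PRINTED_DEMANDS, PRINTED_POWERS)
    ]
    _check_monotone(models)
    return models


def _check_monotone(models: Sequence[ExerciseModel]) -> None:
    for lo, hi in zip(models, models[1:]):
        if not (hi.intensity_fraction > lo.intensity_fraction
                and hi.time_to_exhaustion < lo.time_to_exhaustion
                and hi.aerobic_fraction < lo.aerobic_fraction):
            raise ValueError("exercise models must be monotone: higher "
                             "intensity, shorter time, lower aerobic fraction")


def aerobic_fraction_at(time_to_exhaustion: float) -> float:
    """Aerobic fraction for an arbitrary time to exhaustion.

    Piecewise-linear interpolation in log(time) between the five canonical
    anchors, clamped outside [10, 217] s.
    """
    if time_to_exhaustion <= 0:
        raise ValueError("time to exhaustion must be positive")
    t = np.log(np.clip(time_to_exhaustion, 10.0, 217.0))
    knots = np.log(TIMES_TO_EXHAUSTION_S[::-1])
    vals = AEROBIC_FRACTIONS[::-1]
    return float(np.interp(t, knots, vals))


def invert_relation(rel: LinearRelation, demand: float) -> float:
    """Power (W) at which ``rel`` predicts the given demand (mmol s^-1)."""
    return rel.invert(demand)


def demand_at_power(rel: LinearRelation, power: float) -> float:
    """O2 demand (mmol s^-1) predicted by ``rel`` at a power (W)."""
    return rel.demand_at_power(power)
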