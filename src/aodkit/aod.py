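"""Accumulated O2 deficit computation and method comparison.

The accumulated O2 deficit is the accumulated O2 demand minus the accumulated
O2 uptake over an exhaustive bout.  The demand rate comes from a linear
relation extrapolated to the bout's power; the uptake either from the modeled
aerobic fraction or from an integrated measured VO2 series.

A deliberate anchoring choice: under the modeled-fraction mode the
accumulated uptake is ``aerobic_fraction * demand_ref * t`` -- the REFERENCE
total scales the uptake, identically for every test method.  All methods are
thus compared under the same power, time to exhaustion and accumulated O2
uptake, and differences in the deficit reflect only the demand relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ZeroVarianceError
from .exercise import ExerciseModel
from .methods import LinearRelation

MODEL_ORDER_NOTE = "models are reported shortest time to exhaustion first"


@dataclass(frozen=True)
class AODResult:
    """Accumulated demand/uptake/deficit for one (method, exercise model)."""

    method_id: Optional[str]
    model: ExerciseModel
    accumulated_demand: float     # mmol
    accumulated_uptake: float     # mmol
    deficit: float                # mmol
    deficit_per_kg: float         # mmol kg^-1
    negative_deficit: bool = False

    def __post_init__(self):
        if self.accumulated_uptake < 0:
            raise ValueError("accumulated uptake must be >= 0")
        if not math.isclose(self.deficit,
                            self.accumulated_demand - self.accumulated_uptake,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("deficit must equal demand minus uptake")


def accumulated_o2_deficit(test_rel: Optional[LinearRelation],
                           model: ExerciseModel,
                           body_mass: float,
                           mode: str = "modelled_fraction",
                           uptake_series: Optional[Sequence] = None,
                           demand_source: str = "relation") -> AODResult:
    """Accumulated O2 deficit for one demand relation under one model.

    Parameters
    ----------
    test_rel : LinearRelation or None
        The demand relation under test; may be None with
        ``demand_source="reference"``.
    model : ExerciseModel
        Supplies power, time to exhaustion, aerobic fraction and the
        reference demand.
    body_mass : float
        kg; divides the deficit for the per-kg figure.
    mode : {"modelled_fraction", "measured_uptake"}
        How the accumulated uptake is obtained: the modeled aerobic fraction
        of the reference total, or the trapezoidal integral of a measured
        (time s, vo2 mmol/s) series covering (0, time_to_exhaustion).
    demand_source : {"relation", "reference"}
        "relation" evaluates the test relation at the model power;
        "reference" uses ``model.demand_ref`` directly (the reference
        method's own row, immune to coefficient rounding).

    A negative deficit (demand relation below the uptake anchoring) is
    returned with ``negative_deficit=True`` rather than raised: it is a
    diagnostic of a too-low demand relation.
    """
    t = model.time_to_exhaustion
    if demand_source == "reference":
        demand_rate = model.demand_ref
    elif demand_source == "relation":
        if test_rel is None:
            raise ValueError("demand_source='relation' needs a test relation")
        demand_rate = test_rel.demand_at_power(model.power)
    else:
        raise ValueError(f"unknown demand_source {demand_source!r}")
    acc_demand = demand_rate * t

    if mode == "modelled_fraction":
        acc_uptake = model.aerobic_fraction * model.demand_ref * t
    elif mode == "measured_uptake":
        if uptake_series is None:
            raise ValueError("measured_uptake mode needs an uptake_series")
        series = np.asarray(uptake_series, dtype=float).reshape(-1, 2)
        ts, vs = series[:, 0], series[:, 1]
        if np.any(np.diff(ts) < 0):
            raise ValueError("uptake series must be sorted by time")
        if ts[0] > 0 or ts[-1] < t:
            raise ValueError(
                f"uptake series must cover (0, {t}) s, got ({ts[0]}, {ts[-1]})")
        grid = np.unique(np.concatenate([[0.0, t], ts[(ts > 0) & (ts < t)]]))
        acc_uptake = float(np.trapezoid(np.interp(grid, ts, vs), grid))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    deficit = acc_demand - acc_uptake
    return AODResult(
        method_id=None if test_rel is None else test_rel.method_id,
        model=model,
        accumulated_demand=float(acc_demand),
        accumulated_uptake=float(acc_uptake),
        deficit=float(deficit),
        deficit_per_kg=float(deficit / body_mass),
        negative_deficit=deficit < 0,
    )


def aod_table(relations: Mapping[str, LinearRelation],
              models: Sequence[ExerciseModel],
              body_mass: float,
              reference_id: str = "M0") -> pd.DataFrame:
    """Per-method AOD grid (mmol/kg), one row per method, one column per model.

    The reference method's row uses ``model.demand_ref`` directly; every other
    method evaluates its own relation at the common modeled power.
    """
    rows = {}
    for mid, rel in relations.items():
        source = "reference" if mid == reference_id else "relation"
        rows[mid] = {
            m.label: accumulated_o2_deficit(
                rel, m, body_mass, demand_source=source).deficit_per_kg
            for m in models
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "method_id"
    return df


def paired_t(differences: Sequence[float]) -> tuple[float, float]:
    """One-sample matched-pair t-test of the mean difference against zero.

    Returns (t, two-sided p) with n-1 degrees of freedom.  Raises
    :class:`ZeroVarianceError` on a degenerate (zero-spread) sample.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("paired differences have zero variance")
    t = d.mean() / (sd / math.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df=d.size - 1)
    return float(t), float(p)


def compare_methods(cohort_relations: Mapping[str, Mapping[str, LinearRelation]],
                    models: Sequence[ExerciseModel],
                    body_masses: Mapping[str, float],
                    reference_id: str = "M0",
                    bonferroni: bool = False) -> pd.DataFrame:
    """Method-vs-reference comparison across subjects.

    For every (test method, exercise model): per-subject residual = test AOD
    minus reference AOD (both per kg of the subject's own mass), then the
    mean bias, the between-subject SD of the residuals, and the matched-pair
    t-test against zero.  Subjects lacking either relation are excluded
    pairwise.  With fewer than two complete pairs the SD and test are
    reported as missing; a zero-variance sample flags the t as undefined.

    Returns a tidy frame: method_id, model, n, bias, sd, t, p
    (p Bonferroni-multiplied by the number of method contrasts if requested).
    """
    methods = sorted({mid for rels in cohort_relations.values() for mid in rels})
    n_contrasts = max(1, len([m for m in methods if m != reference_id]))
    records = []
    for mid in methods:
        for model in models:
            resid = []
            for sid, rels in cohort_relations.items():
                if mid not in rels or reference_id not in rels:
                    continue
                mass = body_masses[sid]
                ref = accumulated_o2_deficit(rels[reference_id], model, mass)
                test = accumulated_o2_deficit(rels[mid], model, mass)
                resid.append(test.deficit_per_kg - ref.deficit_per_kg)
            rec = {"method_id": mid, "model": model.label, "n": len(resid),
                   "bias": np.mean(resid) if resid else np.nan,
                   "sd": np.nan, "t": np.nan, "p": np.nan,
                   "degenerate": False}
            if len(resid) >= 2:
                rec["sd"] = float(np.std(resid, ddof=1))
                try:
                    t, p = paired_t(resid)
                    if bonferroni:
                        p = min(1.0, p * n_contrasts)
                    rec["t"], rec["p"] = t, p
                except ZeroVarianceError:
                    rec["degenerate"] = True
            records.append(rec)
    return pd.DataFrame.from_records(records)


def residuals_long(cohort_relations: Mapping[str, Mapping[str, LinearRelation]],
                   models: Sequence[ExerciseModel],
                   body_masses: Mapping[str, float],
                   reference_id: str = "M0") -> pd.DataFrame:
    """Plot-ready long table: subject, method, model, residual (mmol/kg)."""
    records = []
    for sid, rels in cohort_relations.items():
        if reference_id not in rels:
            continue
        mass = body_masses[sid]
        for model in models:
            ref = accumulated_o2_deficit(rels[reference_id], model, mass)
            for mid, rel in rels.items():
                test = accumulated_o2_deficit(rel, model, mass)
                records.append({
                    "subject_id": sid, "method_id": mid, "model": model.label,
                    "residual": test.deficit_per_kg - ref.deficit_per_kg,
                })
    return pd.DataFrame.from_records(records)


def pooled_drift(subgroup_means: Sequence[tuple[float, int]]) -> float:
    """n-weighted mean of subgroup mean VO2 increases (mmol s^-1).

    Pools the below- and at-or-above-lactate-threshold 4 -> 10-min drift
    subgroups into the overall mean increase.
    """
    groups = list(subgroup_means)
    if not groups:
        raise ValueError("no subgroups given")
    if any(n <= 0 for _, n in groups):
        raise ValueError("subgroup sizes must be positive")
    total_n = sum(n for _, n in groups)
    return sum(mean * n for mean, n in groups) / total_n
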