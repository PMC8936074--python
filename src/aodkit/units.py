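"""Unit conversions for O2-uptake quantities.

Canonical internal units throughout the package: VO2 in mmol s^-1, mechanical
power in W, demand-relation slopes in umol J^-1.  Numerically,

    slope[umol/J] * power[W] / 1000 = VO2[mmol/s]

so converters are needed only at the I/O edges, where the L_STPD min^-1
convention of indirect calorimetry is common.
"""

from __future__ import annotations

#: Molar volume of an ideal gas at standard temperature and pressure, dry
#: (L mol^-1).  22.4 reproduces the conventional 2.9 mmol/s = 3.9 L/min
#: correspondence; users preferring 22.393 may pass it explicitly.
STPD_MOLAR_VOLUME_L = 22.4


def vo2_mmol_per_s_to_l_per_min(v: float, molar_volume: float = STPD_MOLAR_VOLUME_L) -> float:
    """Convert an O2 uptake from mmol s^-1 to L_STPD min^-1.

    Parameters
    ----------
    v : float
        O2 uptake in mmol s^-1; must be non-negative.
    molar_volume : float
        STPD molar volume in L mol^-1.

    Returns
    -------
    float
        O2 uptake in L_STPD min^-1 (= v * 60 * molar_volume / 1000).
    """
    if v < 0:
        raise ValueError(f"O2 uptake must be non-negative, got {v}")
    return v * 60.0 * molar_volume / 1000.0


def vo2_l_per_min_to_mmol_per_s(v: float, molar_volume: float = STPD_MOLAR_VOLUME_L) -> float:
    """Inverse of :func:`vo2_mmol_per_s_to_l_per_min`."""
    if v < 0:
        raise ValueError(f"O2 uptake must be non-negative, got {v}")
    return v * 1000.0 / (60.0 * molar_volume)


def slope_umol_per_j_to_mmol_per_s_per_w(b: float) -> float:
    """Convert a demand-relation slope from umol J^-1 to mmol s^-1 W^-1."""
    return b / 1000.0
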