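"""Closed-form leaf physiology computations.

Small helpers around the gas-exchange and growth bookkeeping: the allometric
leaf-length -> leaf-area model, whole-plant leaf-area growth percentage with
sampled-leaf accounting, and intrinsic water-use efficiency.
"""

from __future__ import annotations

from typing import Iterable


def leaf_area_from_length(length_cm: float) -> float:
    """Leaf area (cm^2) from leaf length (cm): Area = 0.3281 x length^2.55."""
    if length_cm <= 0:
        raise ValueError("leaf length must be > 0")
    return 0.3281 * length_cm**2.55


def growth_percent(
    leaf_areas_day1: Iterable[float],
    leaf_areas_day7: Iterable[float],
    sampled_leaf_areas: Iterable[float] = (),
) -> float:
    """Leaf-area growth as a percent of the day-1 area.

    Leaves removed for sampling during the week count toward the final area:
    100 x ((sum day7 + sum sampled) - sum day1) / sum day1.
    """
    start = float(sum(leaf_areas_day1))
    if start <= 0:
        raise ValueError("day-1 leaf area must be > 0")
    end = float(sum(leaf_areas_day7)) + float(sum(sampled_leaf_areas))
    return 100.0 * (end - start) / start


def wuei(a_n: float, g_s: float) -> float:
    """Intrinsic water-use efficiency: net assimilation / stomatal conductance.

    a_n in umol CO2 m^-2 s^-1, g_s in mol H2O m^-2 s^-1, result in
    umol CO2 / mol H2O.
    """
    if g_s <= 0:
        raise ValueError("stomatal conductance must be > 0")
    return a_n / g_s
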