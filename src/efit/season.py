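"""Growing-season derivation from monthly climate.

A month belongs to the growing season when its mean temperature is at or
above the warmth threshold (default 0 degC, inclusive).  Season length is
the sum of the included months' calendar days on a non-leap calendar;
season temperature and radiation are unweighted means over the included
months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .climate_io import MONTH_DAYS, MonthlyClimate


def month_day_table() -> tuple[int, ...]:
    """Non-leap calendar days per month, January first."""
    return MONTH_DAYS


@dataclass(frozen=True)
class GrowingSeason:
    """Season length (days), mean temperature and mean radiation over the
    warm months; NaN for the means when no month qualifies."""

    g_days: int
    g_temp: float
    g_srad: float
    months_used: frozenset[int] = field(default_factory=frozenset)
    complete: bool = True

    @property
    def empty(self) -> bool:
        return self.g_days == 0


def derive_growing_season(
    climate: MonthlyClimate,
    warm_threshold: float = 0.0,
    strict: bool = False,
) -> GrowingSeason:
    """Derive the growing season from 12 monthly means.

    ``strict=False`` (default) includes months exactly at the threshold;
    ``strict=True`` requires the temperature to exceed it.  A month with a
    defined warm temperature but missing radiation still counts toward
    ``g_days`` and ``g_temp`` but is excluded from the radiation mean, and
    the result is marked incomplete.
    """
    temp = climate.temp
    srad = climate.srad
    defined = np.isfinite(temp)
    if strict:
        warm = defined & (temp > warm_threshold)
    else:
        warm = defined & (temp >= warm_threshold)
    months_used = frozenset(int(i) for i in np.nonzero(warm)[0])

    g_days = int(sum(climate.month_days[i] for i in months_used))
    if months_used:
        g_temp = float(np.mean(temp[warm]))
        warm_srad = srad[warm]
        warm_srad = warm_srad[np.isfinite(warm_srad)]
        g_srad = float(np.mean(warm_srad)) if warm_srad.size else math.nan
    else:
        g_temp = math.nan
        g_srad = math.nan

    complete = climate.is_complete()
    return GrowingSeason(
        g_days=g_days,
        g_temp=g_temp,
        g_srad=g_srad,
        months_used=months_used,
        complete=complete,
    )
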