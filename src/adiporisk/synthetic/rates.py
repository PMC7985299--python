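"""Synthetic age-specific incidence and all-cause mortality rate tables.

Stand-ins for national registry rates: one row per 1-year age band with
breast-cancer incidence and all-cause mortality per person-year.  Shapes are
deliberately simple (constant, linear ramp, Gompertz) — what matters
downstream is the competing-risk arithmetic, not demographic fidelity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def generate_rate_table(
    base_incidence: float,
    base_mortality: float,
    age_range: tuple[int, int] = (30, 95),
    incidence_shape: str = "constant",
    mortality_shape: str = "constant",
    incidence_slope: float = 0.0,
    gompertz_b: float = 0.09,
) -> pd.DataFrame:
    """Build a rate table with columns ``age, incidence_rate, mortality_rate``.

    ``incidence_shape``: ``constant`` or ``linear`` (adds ``incidence_slope``
    per year above the lower age bound, floored at 0).
    ``mortality_shape``: ``constant`` or ``gompertz``
    (``base_mortality * exp(gompertz_b * (age - age_range[0]))``).
    Rates are per person-year.
    """
    if base_incidence < 0 or base_mortality < 0:
        raise ValueError("rates must be >= 0")
    a0, a1 = age_range
    if a1 <= a0:
        raise ValueError("age_range must be increasing")
    ages = np.arange(a0, a1, dtype=int)

    if incidence_shape == "constant":
        inc = np.full(ages.shape, float(base_incidence))
    elif incidence_shape == "linear":
        inc = np.clip(base_incidence + incidence_slope * (ages - a0), 0.0, None)
    else:
        raise ValueError(f"unknown incidence_shape {incidence_shape!r}")

    if mortality_shape == "constant":
        mort = np.full(ages.shape, float(base_mortality))
    elif mortality_shape == "gompertz":
        mort = base_mortality * np.exp(gompertz_b * (ages - a0))
    else:
        raise ValueError(f"unknown mortality_shape {mortality_shape!r}")

    return pd.DataFrame(
        {"age": ages, "incidence_rate": inc, "mortality_rate": mort})
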