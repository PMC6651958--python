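"""Age grid and 5-year band conventions.

The model tracks single years of age from 15 to an open-ended top age
(100+) internally, while all rate tables, mortality schedules and reports
use the 5-year bands 15-19 ... 70-74 plus an open-ended 75+ band.
"""

from __future__ import annotations

import numpy as np

AGE_MIN = 15
AGE_MAX = 100  # open-ended: the top single age absorbs its predecessor
N_AGES = AGE_MAX - AGE_MIN + 1
AGES = np.arange(AGE_MIN, AGE_MAX + 1)

#: 5-year band labels in ascending order; the last band is open-ended.
BANDS = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65-69", "70-74", "75+",
)

SEXES = ("male", "female")


def age_to_band(age: int) -> str:
    """Map a single year of age to its 5-year band label."""
    if age < AGE_MIN:
        raise ValueError(f"age {age} below the modelled minimum of {AGE_MIN}")
    if age >= 75:
        return "75+"
    lo = (age // 5) * 5
    return f"{lo}-{lo + 4}"


def band_lower_age(band: str) -> int:
    """Lower age bound of a band label such as ``"35-39"`` or ``"75+"``."""
    label = band.strip().replace("–", "-")  # tolerate en-dash
    if label.endswith("+"):
        return int(label[:-1])
    return int(label.split("-")[0])


def band_ages(band: str) -> np.ndarray:
    """Single years of age covered by a band (75+ runs to the top age)."""
    lo = band_lower_age(band)
    hi = AGE_MAX if band.strip().endswith("+") else lo + 4
    return np.arange(lo, hi + 1)


#: band label per single year of age, aligned with ``AGES``
BAND_OF_AGE = np.array([age_to_band(a) for a in AGES])


def expand_band_values(values_by_band: dict[str, float]) -> np.ndarray:
    """Expand a {band: value} mapping to a per-single-age array.

    Every band must be present; a missing band raises ConfigurationError
    listing the gap.
    """
    from .errors import ConfigurationError

    missing = [b for b in BANDS if b not in values_by_band]
    if missing:
        raise ConfigurationError(f"rate table missing age bands: {missing}")
    return np.array([values_by_band[b] for b in BAND_OF_AGE], dtype=float)


def aggregate_by_band(per_age: np.ndarray) -> dict[str, float]:
    """Sum a per-single-age array into the 5-year bands."""
    out: dict[str, float] = {}
    for band in BANDS:
        mask = BAND_OF_AGE == band
        out[band] = float(np.sum(per_age[mask]))
    return out
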