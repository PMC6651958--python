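"""Packaged data: printed survey tables, rate tables and anchors.

The packaged CSV/JSON files carry the published 2014 Thai survey estimates
(state prevalences by sex and 5-year band, annual cessation rates by band,
annual initiation rates by band), the 2010 male prevalence anchor, and the
published 2016-2025 deaths table used for arithmetic cross-checks. Every
file is verified against a recorded SHA-256 checksum at load time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import FixtureIntegrityError

logger = logging.getLogger(__name__)

_DATA = resources.files("smokesim") / "data"


def _read_bytes(name: str) -> bytes:
    path = _DATA / name
    data = path.read_bytes()
    checksums = _checksums()
    if name in checksums:
        digest = hashlib.sha256(data).hexdigest()
        if digest != checksums[name]:
            raise FixtureIntegrityError(
                f"packaged file {name} has checksum {digest}, expected {checksums[name]}"
            )
    return data


@lru_cache(maxsize=1)
def _checksums() -> dict[str, str]:
    return json.loads((_DATA / "checksums.json").read_text())


def _read_csv(name: str) -> pd.DataFrame:
    from io import BytesIO

    return pd.read_csv(BytesIO(_read_bytes(name)))


@lru_cache(maxsize=1)
def load_prevalence_2014() -> pd.DataFrame:
    """2014 survey smoking-state prevalences (%) by sex and age band.

    Includes the published ``overall`` rows; band rows are used to
    initialize the projection.
    """
    return _read_csv("thai_prevalence_2014.csv")


@lru_cache(maxsize=1)
def load_cessation_2014() -> pd.DataFrame:
    """2014 annual cessation rates (proportions) for males by age band."""
    return _read_csv("thai_cessation_2014.csv")


@lru_cache(maxsize=1)
def load_initiation_2014() -> pd.DataFrame:
    """2014 annual initiation rates (proportions) for males by age band.

    The published table also reports small rates for 25-29 and 30+; the
    model applies initiation at ages 15-24 only, so the default schedule
    uses the first two bands.
    """
    return _read_csv("thai_initiation_2014.csv")


@lru_cache(maxsize=1)
def load_table4() -> pd.DataFrame:
    """Published yearly all-cause deaths and deaths averted, 2016-2025."""
    return _read_csv("table4_deaths_2016_2025.csv")


@lru_cache(maxsize=1)
def load_anchors() -> dict:
    """Published scalar anchors (2010 prevalence, targets, cumulative cells)."""
    return json.loads(_read_bytes("anchors.json"))


@lru_cache(maxsize=1)
def load_default_config() -> dict:
    """The shipped run configuration (base year, relapse, scenario presets)."""
    return yaml.safe_load(_read_bytes("default_config.yaml"))


def initial_prevalence_arrays(sex: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-single-age (p_never, p_current, p_former) proportions for one sex.

    Band percentages are renormalized to sum exactly to 1 (printed rounding
    leaves rows at 99.9-100.1%); the largest deviation is logged.
    """
    from .ages import BAND_OF_AGE

    table = load_prevalence_2014()
    sub = table[(table["sex"] == sex) & (table["age_group"] != "overall")]
    by_band = {}
    worst = 0.0
    for _, r in sub.iterrows():
        vals = np.array([r["p_never"], r["p_current"], r["p_former"]], dtype=float)
        worst = max(worst, abs(vals.sum() - 100.0))
        by_band[str(r["age_group"])] = vals / vals.sum()
    if worst > 0:
        logger.info("prevalence rows renormalized; largest deviation from 100%%: %.2f pp", worst)
    stacked = np.array([by_band[b] for b in BAND_OF_AGE])
    return stacked[:, 0], stacked[:, 1], stacked[:, 2]


def default_rate_tables(sex: str = "male") -> tuple[dict[str, float], dict[str, float]]:
    """(cessation, initiation) band->proportion dicts for the default run.

    Initiation covers 15-19 and 20-24 only (the modelled initiation ages).
    """
    cess_df = load_cessation_2014()
    init_df = load_initiation_2014()
    cess = {
        str(r["age_group"]): float(r["cessation"])
        for _, r in cess_df[cess_df["sex"] == sex].iterrows()
        if not str(r["age_group"]).startswith("all")
    }
    init = {
        str(r["age_group"]): float(r["initiation"])
        for _, r in init_df[init_df["sex"] == sex].iterrows()
        if str(r["age_group"]) in ("15-19", "20-24")
    }
    return cess, init


__all__ = [
    "load_prevalence_2014",
    "load_cessation_2014",
    "load_initiation_2014",
    "load_table4",
    "load_anchors",
    "load_default_config",
    "initial_prevalence_arrays",
    "default_rate_tables",
]
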