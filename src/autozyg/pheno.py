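"""Phenotype derivations and predictor standardization.

Egg volume follows the classical egg-geometry approximation V = k * L * W^2
with L and W in mm and a dimensionless-with-units constant k (default
0.51e-3 mL/mm^3), which puts a 50 x 38 mm egg at ~37 mL, inside the
observed 14.5-47.8 mL range. Continuous predictors are standardized by
centring and dividing by two standard deviations so that coefficients are
comparable across continuous and binary inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["egg_volume", "invert_egg_volume", "standardize", "count_data"]

EGG_K_DEFAULT = 0.51e-3  # mL per mm^3


def egg_volume(length_mm, width_mm, k: float = EGG_K_DEFAULT):
    """Egg volume in mL from length and width in mm: V = k * L * W^2."""
    length_mm = np.asarray(length_mm, dtype=float)
    width_mm = np.asarray(width_mm, dtype=float)
    if np.any(length_mm < 0) or np.any(width_mm < 0):
        raise ValueError("egg dimensions must be non-negative")
    v = k * length_mm * width_mm**2
    return float(v) if v.ndim == 0 else v


def invert_egg_volume(
    volume_ml: float, aspect: float, k: float = EGG_K_DEFAULT
) -> tuple[float, float]:
    """Back out (length, width) in mm from a volume and length/width ratio,
    such that ``egg_volume(length, width, k)`` reproduces the volume."""
    if volume_ml <= 0 or aspect <= 0:
        raise ValueError("volume and aspect ratio must be positive")
    width = (volume_ml / (k * aspect)) ** (1.0 / 3.0)
    return aspect * width, width


def standardize(x) -> np.ndarray:
    """Centre and divide by 2 SD (population SD). Degenerate (constant)
    predictors raise ``ValueError``."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant predictor")
    return (x - x.mean()) / (2.0 * sd)


def count_data(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Collapse the per-egg table to one row per female-year-clutch for the
    count traits (clutch size, eggs hatched)."""
    cols = [
        "female_id",
        "year",
        "clutch_id",
        "clutch_size",
        "eggs_hatched",
        "age",
        "generation",
    ]
    return (
        phenotypes[cols]
        .drop_duplicates(subset=["female_id", "year", "clutch_id"])
        .reset_index(drop=True)
    )
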