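"""Standardization, BMI, energy-residual adjustment and cross-wave descriptives.

Conventions used throughout the package (stated once here): sample (n-1)
standard deviations for every SD, correlation and explained-variation
computation; quantiles by linear interpolation between order statistics
(numpy's default, the "type 7" rule); Spearman correlations with average
ranks for ties, which matters because zero-inflated food columns tie heavily
at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import IntakeTable


@dataclass
class StandardizedMatrix:
    """Column-wise z-scored matrix with its standardization parameters.

    Keeping ``means``/``sds`` allows applying one wave's scaling to another
    wave's data, which confirmatory scoring needs.
    """

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    wave: str | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)


def compute_bmi(weight_kg, height_m):
    """Body mass index: weight in kilograms divided by height in meters squared."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if (weight_kg <= 0).any() or (height_m <= 0).any():
        raise ValueError("weight and height must be strictly positive")
    out = weight_kg / height_m**2
    return float(out) if out.ndim == 0 else out


def standardize(df: pd.DataFrame, wave: str | None = None) -> StandardizedMatrix:
    """Z-score each column (sample SD, ddof=1).

    Raises on constant columns, naming them: a zero-variance food group or
    response carries no pattern information and breaks the scaling.
    """
    if len(df) < 2:
        raise ValueError("standardization needs at least 2 rows")
    means = df.mean()
    sds = df.std(ddof=1)
    constant = sds.index[sds <= 0].tolist()
    if constant:
        raise ValueError(f"constant column(s), cannot standardize: {constant}")
    return StandardizedMatrix(values=(df - means) / sds, means=means, sds=sds, wave=wave)


def apply_standardization(
    df: pd.DataFrame, reference: StandardizedMatrix
) -> pd.DataFrame:
    """Scale ``df`` with another matrix's means/SDs (cross-wave scoring)."""
    cols = reference.means.index
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"columns missing from data: {missing}")
    return (df[cols] - reference.means) / reference.sds


def unstandardize(sm: StandardizedMatrix) -> pd.DataFrame:
    """Inverse of :func:`standardize` (identity to numerical precision)."""
    return sm.values * sm.sds + sm.means


def energy_adjust(intake: pd.Series, energy: pd.Series) -> pd.Series:
    """Energy-residual adjustment of one food column.

    Residual of the simple linear regression of intake on total energy, plus
    the intake mean, so the adjusted column keeps its units (g/day) and
    location but is uncorrelated with energy.
    """
    if energy.std(ddof=1) <= 0:
        raise ValueError("energy column is constant; residual method undefined")
    x = energy.to_numpy(dtype=float)
    y = intake.to_numpy(dtype=float)
    xc = x - x.mean()
    slope = float(xc @ (y - y.mean()) / (xc @ xc))
    resid = y - y.mean() - slope * xc
    return pd.Series(resid + y.mean(), index=intake.index, name=intake.name)


def energy_adjust_table(table: IntakeTable) -> IntakeTable:
    """Apply the residual method to every food column of an intake table."""
    if table.energy is None:
        raise ValueError("intake table has no energy column to adjust on")
    adjusted = {c: energy_adjust(table.foods[c], table.energy) for c in table.foods}
    df = pd.DataFrame(adjusted, index=table.participants)
    # residuals can dip below zero for near-zero intakes; they are analysis
    # values, not consumptions, so bypass the >= 0 intake check
    out = IntakeTable.__new__(IntakeTable)
    out.foods = df
    out.wave = table.wave
    out.energy = table.energy
    return out


def cross_wave_descriptives(
    wave1: IntakeTable, wave2: IntakeTable
) -> pd.DataFrame:
    """Per-food medians, 10th/90th percentiles per wave, and Spearman tracking.

    One row per food group. Spearman is computed on paired participants with
    average ranks for ties; a zero-variance column in either wave yields a
    missing (NaN) correlation rather than 0.
    """
    if wave1.food_names != wave2.food_names:
        raise ValueError("waves must share the same food columns, in order")
    if set(wave1.participants) != set(wave2.participants):
        raise ValueError("waves must cover the same participants")
    f2 = wave2.foods.reindex(wave1.participants)
    rows = []
    for food in wave1.food_names:
        a = wave1.foods[food].to_numpy(dtype=float)
        b = f2[food].to_numpy(dtype=float)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            rho = np.nan
        else:
            rho = float(stats.spearmanr(a, b).statistic)
        rows.append(
            {
                "food": food,
                "median_w1": float(np.median(a)),
                "p10_w1": float(np.percentile(a, 10)),
                "p90_w1": float(np.percentile(a, 90)),
                "median_w2": float(np.median(b)),
                "p10_w2": float(np.percentile(b, 10)),
                "p90_w2": float(np.percentile(b, 90)),
                "spearman": rho,
            }
        )
    return pd.DataFrame(rows).set_index("food")
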