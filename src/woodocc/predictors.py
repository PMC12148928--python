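"""Predictor preparation: patch shape index, centring/scaling, collinearity
screening and empirical marginal resampling.

All continuous predictors are centred and scaled (sample standard deviation,
``ddof=1``) before entering the occupancy model; the transform is stored so
that raw-scale scenario values can be mapped onto the model scale later.
Binary indicator columns (e.g. country) keep their 0/1 coding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "shape_index",
    "StandardizationTransform",
    "center_scale",
    "vif_screen",
    "empirical_marginal_sampler",
    "EmpiricalMarginalSampler",
]


def shape_index(perimeter: float, area: float) -> float:
    """Patch compactness: perimeter divided by the perimeter of the circle
    with the same area.

    Equals 1 for a perfect circle; larger values indicate less-compact
    patches. Units cancel as long as ``perimeter`` and ``area`` use the same
    length unit (m and m**2, say).

    Raises
    ------
    ValueError
        If either input is non-positive, or if the perimeter is below the
        isoperimetric minimum ``2*sqrt(pi*area)`` (no planar shape can have
        such a boundary).
    """
    if perimeter <= 0 or area <= 0:
        raise ValueError("perimeter and area must be positive")
    circle_perimeter = 2.0 * math.sqrt(math.pi * area)
    # tiny relative slack so an exact circle never trips the check
    if perimeter < circle_perimeter * (1.0 - 1e-12):
        raise ValueError(
            f"perimeter {perimeter:g} is below the isoperimetric minimum "
            f"{circle_perimeter:g} for area {area:g}"
        )
    return max(perimeter / circle_perimeter, 1.0)


@dataclass
class StandardizationTransform:
    """Per-column centring/scaling statistics from a training table.

    ``apply``/``invert`` round-trip to numerical tolerance. Columns absent
    from ``means`` (binary indicators) pass through untouched.
    """

    means: dict[str, float]
    sds: dict[str, float]
    #: observed raw-scale range per column, used to validate scenario grids
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, mu in self.means.items():
            if col in out:
                out[col] = (out[col] - mu) / self.sds[col]
        return out

    def invert(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, mu in self.means.items():
            if col in out:
                out[col] = out[col] * self.sds[col] + mu
        return out

    def apply_value(self, column: str, value: float | np.ndarray):
        """Map a raw-scale value of one column onto the model scale."""
        if column not in self.means:
            return value  # unscaled (indicator) column
        return (np.asarray(value, dtype=float) - self.means[column]) / self.sds[column]

    def to_frame(self) -> pd.DataFrame:
        cols = sorted(self.means)
        return pd.DataFrame(
            {
                "column": cols,
                "mean": [self.means[c] for c in cols],
                "sd": [self.sds[c] for c in cols],
                "min": [self.ranges.get(c, (np.nan, np.nan))[0] for c in cols],
                "max": [self.ranges.get(c, (np.nan, np.nan))[1] for c in cols],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StandardizationTransform":
        means = dict(zip(frame["column"], frame["mean"].astype(float)))
        sds = dict(zip(frame["column"], frame["sd"].astype(float)))
        ranges = {
            c: (float(lo), float(hi))
            for c, lo, hi in zip(frame["column"], frame["min"], frame["max"])
            if np.isfinite(lo) and np.isfinite(hi)
        }
        return cls(means=means, sds=sds, ranges=ranges)


def center_scale(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, StandardizationTransform]:
    """Centre and scale the named columns to sample mean 0 and sd 1.

    Parameters
    ----------
    table
        Covariate table, one row per site.
    columns
        Columns to standardize. Default: every numeric column with more than
        two distinct values (binary indicators keep their coding).

    Returns
    -------
    (scaled table, transform)

    Raises
    ------
    ValueError
        If fewer than 2 rows, or a selected column has zero variance (the
        offending column is named).
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to centre and scale")
    if columns is None:
        columns = [
            c
            for c in table.columns
            if pd.api.types.is_numeric_dtype(table[c]) and table[c].nunique() > 2
        ]
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    ranges: dict[str, tuple[float, float]] = {}
    out = table.copy()
    for col in columns:
        if col not in table:
            raise KeyError(f"unknown column {col!r}")
        x = table[col].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise ValueError(f"column {col!r} has zero variance; cannot scale")
        mu = float(np.mean(x))
        out[col] = (x - mu) / sd
        means[col], sds[col] = mu, sd
        ranges[col] = (float(x.min()), float(x.max()))
    return out, StandardizationTransform(means=means, sds=sds, ranges=ranges)


def vif_screen(
    table: pd.DataFrame, threshold: float = 2.5
) -> pd.DataFrame:
    """Variance inflation factors for every column of a design table.

    VIF_k = 1 / (1 - R^2_k), with R^2_k from the least-squares regression of
    column k on all other columns plus an intercept. Columns at or above
    ``threshold`` are flagged; the conventional screen used here passes a
    design when every VIF is below 2.5.

    Returns a frame with columns ``column``, ``vif``, ``flagged``.

    Raises
    ------
    ValueError
        On rank-deficient designs (an exactly collinear column is named) or
        when there are not more rows than columns.
    """
    cols = list(table.columns)
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than columns for a VIF screen")
    vifs = []
    for k, col in enumerate(cols):
        y = X[:, k]
        others = np.delete(X, k, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        yc = y - y.mean()
        ss_tot = float(yc @ yc)
        if ss_tot == 0.0:
            raise ValueError(f"column {col!r} is constant")
        r2 = 1.0 - ss_res / ss_tot
        if r2 > 1.0 - 1e-12:
            raise ValueError(
                f"column {col!r} is an exact linear combination of the others"
            )
        vifs.append(1.0 / (1.0 - r2))
    return pd.DataFrame(
        {"column": cols, "vif": vifs, "flagged": [v >= threshold for v in vifs]}
    )


class EmpiricalMarginalSampler:
    """Resampler of one column's observed values (marginal, with replacement).

    Draws reproduce the empirical distribution of the column: in the long
    run, each observed value appears with its sample frequency. No density is
    fitted — the marginal IS the data.
    """

    def __init__(self, values: np.ndarray, seed: int | np.random.Generator):
        values = np.asarray(values)
        values = values[~pd.isna(values)]
        if values.size == 0:
            raise ValueError("column has no non-missing values")
        self.values = values
        self._rng = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )

    def draw(self, size: int | None = None):
        idx = self._rng.integers(0, self.values.size, size=size)
        return self.values[idx]

    def __iter__(self):
        while True:
            yield self.draw()


def scale_visit_covariates(
    visit_covariates: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Standardize visit-level covariate arrays (shape (sites, visits)).

    Continuous covariates are centred/scaled over all cells (``ddof=1``);
    binary covariates (<= 2 distinct values) keep their coding. Used
    identically by the data generator and the fitting routine so the two
    sides agree on the model scale.
    """
    out: dict[str, np.ndarray] = {}
    for name, arr in visit_covariates.items():
        arr = np.asarray(arr, dtype=float)
        if np.unique(arr).size > 2:
            sd = float(arr.std(ddof=1))
            if sd == 0.0:
                raise ValueError(f"visit covariate {name!r} has zero variance")
            out[name] = (arr - arr.mean()) / sd
        else:
            out[name] = arr
    return out


def empirical_marginal_sampler(
    table: pd.DataFrame, column: str, seed: int | np.random.Generator
) -> EmpiricalMarginalSampler:
    """Build a marginal resampler for one covariate column."""
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}")
    return EmpiricalMarginalSampler(table[column].to_numpy(), seed)
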