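"""Covariate time series (paleotemperature, sea level, clade diversity).

A :class:`CovariateSeries` holds values on a strictly decreasing age grid
(Ma).  When a series is used as a piecewise-constant predictor, each value
extends from its own grid age toward younger ages until the next grid
point; the youngest value also covers ages at or below the youngest grid
age.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._piecewise import StepFunction
from .errors import DomainError

__all__ = ["CovariateSeries", "read_covariate", "covariate_to_step"]


@dataclass(frozen=True)
class CovariateSeries:
    ages: np.ndarray  # strictly decreasing, Ma
    values: np.ndarray
    label: str = ""
    constant_flag: bool = False  # set by rescaling when the input was constant

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)
        if ages.ndim != 1 or ages.shape != values.shape:
            raise DomainError("ages and values must be 1-D and equal length")
        if ages.size == 0:
            raise DomainError("empty covariate series")
        if np.any(np.diff(ages) >= 0):
            raise DomainError("ages must be strictly decreasing")
        if not np.all(np.isfinite(values)):
            raise DomainError("covariate values must be finite")

    def __len__(self):
        return self.ages.size

    def with_values(self, values, **kw) -> "CovariateSeries":
        return replace(self, values=np.asarray(values, dtype=float), **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_covariate(path, label: str = "") -> CovariateSeries:
    """Read a 2-column (age, value) CSV; rows are sorted old -> young."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DomainError("covariate CSV needs at least 2 columns (age, value)")
    age = df.iloc[:, 0].to_numpy(float)
    val = df.iloc[:, 1].to_numpy(float)
    order = np.argsort(-age)
    return CovariateSeries(age[order], val[order], label=label or str(path))


def covariate_to_step(series: CovariateSeries) -> StepFunction:
    """Piecewise-constant view of a covariate series (see module docstring)."""
    if len(series) == 1:
        return StepFunction.constant(series.values[0])
    return StepFunction(series.ages[1:], series.values)
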