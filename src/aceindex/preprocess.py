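"""Variable preparation for neighborhood index construction.

Neighborhood variables arrive on heterogeneous scales (percentages of a tract
population, counts per 10,000 residents) and in mixed directions: for most
variables a higher value signals a riskier environment, but for some
(homeownership, greenspace, transit access, ...) a higher value signals a
*less* risky one.  Every index method downstream assumes a common, risk-aligned
orientation, so this module provides:

- orientation (``max(x) - x`` inversion of protective variables),
- complete-case filtering with an explicit dropped-row count,
- centering/scaling for the PCA-based methods, and
- equal-frequency quantile (decile) scoring for the Bayesian index model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_TYPES = ("percent", "rate")
DIRECTIONS = ("risk_aligned", "inverse")


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one neighborhood variable.

    Parameters
    ----------
    name
        Column name, unique within a variable set.
    scale_type
        ``"percent"`` for variables bounded in [0, 100] or ``"rate"`` for
        non-negative counts per capita.
    direction
        ``"risk_aligned"`` when higher raw values align with higher adversity
        exposure, ``"inverse"`` when higher raw values are protective (these
        columns are flipped by :func:`orient_variables`).
    """

    name: str
    scale_type: str = "percent"
    direction: str = "risk_aligned"

    def __post_init__(self) -> None:
        if self.scale_type not in SCALE_TYPES:
            raise ValueError(f"scale_type must be one of {SCALE_TYPES}, got {self.scale_type!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")


def check_specs(specs: list[VariableSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate variable names in specs: {dupes}")


@dataclass
class OrientedMatrix:
    """A variable matrix after risk-alignment.

    ``values`` has one column per :class:`VariableSpec`; columns listed in
    ``inverted`` were replaced by ``max(x) - x`` (column maximum taken over the
    provided rows, recorded in ``column_max`` so the same transform can be
    re-applied to new data).
    """

    values: pd.DataFrame
    specs: list[VariableSpec] = field(default_factory=list)
    inverted: list[str] = field(default_factory=list)
    column_max: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.specs and self.values.shape[1] != len(self.specs):
            raise ValueError(
                f"column count {self.values.shape[1]} != spec count {len(self.specs)}"
            )

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)


def orient_variables(raw: pd.DataFrame, specs: list[VariableSpec]) -> OrientedMatrix:
    """Align all variables so that higher values mean higher adversity risk.

    Inverse-direction columns are replaced by ``max(x) - x_j`` where the max is
    the column maximum over the rows supplied here (i.e., the analysis set).
    Risk-aligned columns pass through unchanged.
    """
    check_specs(specs)
    missing = [s.name for s in specs if s.name not in raw.columns]
    if missing:
        raise KeyError(f"columns absent from input: {missing}")
    if len(raw) == 0:
        raise ValueError("cannot orient an empty table")

    out = raw[[s.name for s in specs]].astype(float).copy()
    inverted: list[str] = []
    column_max: dict[str, float] = {}
    for spec in specs:
        col = out[spec.name]
        if spec.direction == "inverse":
            if col.isna().any():
                raise ValueError(
                    f"inverse-direction column {spec.name!r} contains missing values; "
                    "drop incomplete rows first"
                )
            mx = float(col.max())
            out[spec.name] = mx - col
            inverted.append(spec.name)
            column_max[spec.name] = mx
    return OrientedMatrix(values=out, specs=list(specs), inverted=inverted, column_max=column_max)


def drop_incomplete(
    table: pd.DataFrame, required_columns: list[str]
) -> tuple[pd.DataFrame, int]:
    """Remove rows with a missing value in any required column.

    Returns the filtered table and the number of rows dropped.  Raises if
    nothing survives, since an empty analysis set is never intended.
    """
    missing_cols = [c for c in required_columns if c not in table.columns]
    if missing_cols:
        raise KeyError(f"required columns absent: {missing_cols}")
    mask = table[list(required_columns)].notna().all(axis=1)
    kept = table.loc[mask].copy()
    n_dropped = int((~mask).sum())
    if len(kept) == 0:
        raise ValueError(f"all {len(table)} rows dropped: no complete cases remain")
    if n_dropped:
        logger.info("dropped %d of %d rows with incomplete data", n_dropped, len(table))
    return kept, n_dropped


def standardize(X: OrientedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to sample SD 1 (denominator n-1).

    Constant columns cannot be scaled; they raise an error naming the column.
    """
    values = X.values if isinstance(X, OrientedMatrix) else X
    values = values.astype(float)
    sd = values.std(ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        raise ValueError(f"cannot standardize constant column(s): {constant}")
    return (values - values.mean()) / sd


@dataclass
class QuantileMatrix:
    """Integer quantile scores with the cutpoints that produced them.

    ``scores`` holds values in {0, ..., Q-1}; ``cutpoints[name]`` are the Q-1
    interior empirical quantiles of that column (non-decreasing).  Cutpoints
    are retained so scores can be assigned to new rows (e.g., participants
    scored with tract-level cutpoints) via :meth:`score_values`.
    """

    scores: pd.DataFrame
    n_quantiles: int
    cutpoints: dict[str, np.ndarray]

    def score_values(self, values: pd.DataFrame) -> pd.DataFrame:
        """Score new rows against the stored cutpoints."""
        missing = [c for c in self.cutpoints if c not in values.columns]
        if missing:
            raise KeyError(f"columns absent from input: {missing}")
        out = {}
        for name, cuts in self.cutpoints.items():
            out[name] = np.searchsorted(cuts, values[name].to_numpy(dtype=float), side="left")
        return pd.DataFrame(out, index=values.index)


def quantile_score(
    X: OrientedMatrix | pd.DataFrame, n_quantiles: int = 10
) -> QuantileMatrix:
    """Equal-frequency quantile scores (deciles by default), per column.

    Cutpoints are the interior empirical quantiles at k/Q (k = 1..Q-1),
    computed with the linear-interpolation ("type 7") convention.  A value's
    score is the number of cutpoints strictly below it, so all equal values
    share the score of the lowest bin containing them; a column with fewer
    distinct values than Q simply leaves some bins empty (a constant column
    scores 0 everywhere).
    """
    if n_quantiles < 2:
        raise ValueError(f"n_quantiles must be >= 2, got {n_quantiles}")
    values = X.values if isinstance(X, OrientedMatrix) else X
    values = values.astype(float)
    if values.isna().any().any():
        raise ValueError("quantile scoring requires complete data; drop incomplete rows first")
    probs = np.arange(1, n_quantiles) / n_quantiles
    cutpoints: dict[str, np.ndarray] = {}
    scores = {}
    for name in values.columns:
        col = values[name].to_numpy(dtype=float)
        cuts = np.quantile(col, probs)  # linear interpolation = "type 7"
        cutpoints[name] = cuts
        scores[name] = np.searchsorted(cuts, col, side="left")
    return QuantileMatrix(
        scores=pd.DataFrame(scores, index=values.index),
        n_quantiles=n_quantiles,
        cutpoints=cutpoints,
    )
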