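"""AIC-based comparison of candidate neighborhood indexes.

Each candidate index is scored per participant and entered, alone, as the
continuous predictor of the binary 4+ adversity outcome in a logistic
regression.  Models are ranked by AIC; a difference of at least 3 is read as
meaningful.  An index contributing several score columns (the threshold-based
PCA method can yield two components) is evaluated with one logistic model per
column, and the method is judged collectively worse when *any* of its columns
is meaningfully worse than the best model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

DEFAULT_PRIORITY = ("bayes", "first_pc", "supervised", "threshold")
MEANINGFUL_DELTA = 3.0


@dataclass
class LogisticFit:
    """One maximum-likelihood logistic fit of outcome on a single score column."""

    coefficients: dict[str, float]
    log_likelihood: float
    k: int
    aic: float
    converged: bool
    label: str = ""

    def __post_init__(self) -> None:
        if abs(self.aic - (2 * self.k - 2 * self.log_likelihood)) > 1e-8:
            raise ValueError("aic must equal 2k - 2*log_likelihood")


def aic(logL: float, k: int) -> float:
    """Akaike information criterion, 2k - 2 logL."""
    return 2.0 * k - 2.0 * logL


def fit_logistic(y: np.ndarray, score: np.ndarray, label: str = "") -> LogisticFit:
    """Fit ``logit P(y=1) = a + b*score`` by maximum likelihood.

    A constant score column degenerates to the closed-form intercept-only fit
    (k=1).  Perfect separation is flagged as non-convergence and the capped
    quasi-Newton fit is reported rather than raised.
    """
    y = np.asarray(y, dtype=float)
    score = np.asarray(score, dtype=float)
    if len(y) != len(score):
        raise ValueError("y and score must have equal length")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome has a single class")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")

    if np.ptp(score) == 0:
        p = y.mean()
        n = len(y)
        ll = n * (p * np.log(p) + (1 - p) * np.log(1 - p))
        return LogisticFit(
            coefficients={"intercept": float(np.log(p / (1 - p)))},
            log_likelihood=float(ll),
            k=1,
            aic=aic(ll, 1),
            converged=True,
            label=label,
        )

    X = sm.add_constant(score)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)

    ll = float(res.llf)
    return LogisticFit(
        coefficients={"intercept": float(res.params[0]), "slope": float(res.params[1])},
        log_likelihood=ll,
        k=2,
        aic=aic(ll, 2),
        converged=converged,
        label=label,
    )


@dataclass
class ComparisonReport:
    """Per-model AICs, deltas to the best model, and the selected method.

    ``table`` has one row per fitted model (method, label, aic, delta_aic,
    meaningfully_worse); ``collectively_worse`` judges whole methods, with a
    multi-column method worse when any of its models is.
    """

    table: pd.DataFrame
    collectively_worse: dict[str, bool]
    selected: str
    best_aic: float
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    meaningful_delta: float = MEANINGFUL_DELTA

    def to_text(self) -> str:
        lines = ["Method comparison (lower AIC is better)", ""]
        lines.append(f"{'model':<28} {'AIC':>10} {'dAIC':>8}  worse(dAIC>={self.meaningful_delta:g})")
        for _, row in self.table.iterrows():
            lines.append(
                f"{row['label']:<28} {row['aic']:>10.2f} {row['delta_aic']:>8.2f}  "
                f"{'yes' if row['meaningfully_worse'] else 'no'}"
            )
        lines.append("")
        for m, worse in self.collectively_worse.items():
            lines.append(f"method {m}: {'collectively worse' if worse else 'competitive'}")
        lines.append(f"selected method: {self.selected}")
        return "\n".join(lines)


def compare_indexes(
    fits: dict[str, LogisticFit | list[LogisticFit]],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    meaningful_delta: float = MEANINGFUL_DELTA,
) -> ComparisonReport:
    """Rank candidate index methods by the AIC of their logistic fits.

    The best model is the single fit with minimum AIC; ties between methods
    are broken by the fixed ``priority`` order (methods absent from it rank
    after, alphabetically).  A method with several fits is collectively worse
    when any of its fits sits at delta-AIC >= ``meaningful_delta``.
    """
    if not fits:
        raise ValueError("no fits to compare")
    rows = []
    for method, value in fits.items():
        flist = value if isinstance(value, list) else [value]
        if not flist:
            raise ValueError(f"method {method!r} supplied an empty fit list")
        multi = len(flist) > 1
        for i, f in enumerate(flist):
            label = f.label or (f"{method}_pc{i + 1}" if multi else method)
            rows.append({"method": method, "label": label, "aic": f.aic})
    table = pd.DataFrame(rows)
    best = float(table["aic"].min())
    table["delta_aic"] = table["aic"] - best
    table["meaningfully_worse"] = table["delta_aic"] >= meaningful_delta

    collectively_worse = {
        m: bool(table.loc[table["method"] == m, "meaningfully_worse"].any())
        for m in fits
    }

    def rank(method: str) -> tuple[int, str]:
        return (priority.index(method), "") if method in priority else (len(priority), method)

    tied = sorted(
        {m for m in fits if np.isclose(table.loc[table["method"] == m, "aic"].min(), best)},
        key=rank,
    )
    selected = tied[0]
    return ComparisonReport(
        table=table,
        collectively_worse=collectively_worse,
        selected=selected,
        best_aic=best,
        priority=tuple(priority),
        meaningful_delta=meaningful_delta,
    )
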