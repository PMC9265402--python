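"""PCA-based neighborhood index construction.

Three ways of collapsing a standardized tract-variable matrix into one (or
two) index columns:

``threshold_pca_index``
    Iterative variable reduction: grow the number of components while every
    component keeps at least ``min_vars_per_pc`` high-loading variables, then
    drop variables that load highly on no component and restart, until the
    variable set is stable.  The surviving components are used *collectively*
    as a (possibly multi-column) index.
``first_pc_index``
    The first principal component of all variables.
``supervised_pca_index``
    The leading direction of a response-dependence operator (linear response
    kernel), i.e., the direction maximizing dependence between the projected
    variables and a binary outcome.

All methods operate on a centered/scaled matrix (see
:func:`aceindex.preprocess.standardize`) and return an
:class:`IndexDefinition` that can be re-applied to new data deterministically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml


@dataclass
class PCASolution:
    """Loadings/eigenvalues of a k-component principal components fit.

    ``loadings`` is variables x components with orthonormal columns;
    ``prop_variance`` is each retained component's share of total variance.
    """

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    prop_variance: np.ndarray
    variable_names: list[str]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class HighLoadingRule:
    """Thresholds defining a "high loading" during threshold-based reduction.

    A variable loads highly on a component when its absolute loading is at
    least ``loading_min`` and exceeds its largest absolute loading on every
    other component by at least ``separation_min``.  A component is considered
    meaningful only if at least ``min_vars_per_pc`` variables load highly on
    it.
    """

    loading_min: float = 0.15
    separation_min: float = 0.10
    min_vars_per_pc: int = 4

    def __post_init__(self) -> None:
        if self.loading_min <= 0 or self.separation_min <= 0 or self.min_vars_per_pc <= 0:
            raise ValueError("all HighLoadingRule thresholds must be > 0")


@dataclass
class ThresholdIteration:
    n_vars: int
    k_final: int
    high_sets: dict[str, list[str]]
    dropped: list[str]
    note: str = ""


@dataclass
class ThresholdTrace:
    """Audit trail of the threshold-based reduction algorithm."""

    iterations: list[ThresholdIteration] = field(default_factory=list)
    stop_reason: str = ""
    warning: str | None = None


@dataclass
class IndexDefinition:
    """A rule mapping a standardized variable matrix to index score column(s).

    ``loadings`` is variables x score-columns; applying the index is the
    matrix product of the (column-matched) data with these loadings.
    ``provenance`` records preprocessing settings (orientation, quantile
    settings, ...) so the index can be re-applied bit-identically.
    """

    method: str
    variable_names: list[str]
    loadings: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.loadings.to_numpy())):
            raise ValueError("index loadings must be finite")
        if self.loadings.shape[1] < 1:
            raise ValueError("an index needs at least one score column")

    @property
    def n_score_columns(self) -> int:
        return self.loadings.shape[1]

    def to_yaml(self) -> str:
        doc = {
            "method": self.method,
            "variable_names": list(self.variable_names),
            "score_columns": list(self.loadings.columns),
            "loadings": {
                c: [float(v) for v in self.loadings[c]] for c in self.loadings.columns
            },
            "provenance": self.provenance,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "IndexDefinition":
        doc = yaml.safe_load(io.StringIO(text))
        loadings = pd.DataFrame(
            {c: doc["loadings"][c] for c in doc["score_columns"]},
            index=doc["variable_names"],
        )
        return cls(
            method=doc["method"],
            variable_names=list(doc["variable_names"]),
            loadings=loadings,
            provenance=doc.get("provenance", {}),
        )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: column sum positive, ties broken by
    making the largest-|entry| element positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        s = out[:, j].sum()
        if abs(s) > 1e-12:
            if s < 0:
                out[:, j] = -out[:, j]
        else:
            i = int(np.argmax(np.abs(out[:, j])))
            if out[i, j] < 0:
                out[:, j] = -out[:, j]
    return out


def _check_standardized(Z: pd.DataFrame) -> None:
    mu = Z.mean().abs().max()
    sd = (Z.std(ddof=1) - 1.0).abs().max()
    if mu > 1e-6 or sd > 1e-4:
        raise ValueError(
            "input matrix is not centered/scaled (per-column mean 0, sample SD 1); "
            "apply aceindex.preprocess.standardize first"
        )


def fit_pca(Z: pd.DataFrame, k: int) -> PCASolution:
    """Principal components of a standardized matrix, truncated to k components.

    Loadings are the top-k eigenvectors of the sample correlation matrix
    (which, for standardized input, is ``Z'Z/(n-1)``), with a deterministic
    sign convention.  ``prop_variance`` is relative to the total variance
    (the eigenvalue sum).
    """
    Z = pd.DataFrame(Z)
    n, p = Z.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} invalid for a {n}x{p} matrix (need 1 <= k <= min(n-1, p))")
    _check_standardized(Z)
    R = (Z.T @ Z).to_numpy() / (n - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    total = evals.sum()
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCASolution(
        loadings=pd.DataFrame(evecs[:, :k], index=Z.columns, columns=cols),
        eigenvalues=evals[:k],
        prop_variance=evals[:k] / total,
        variable_names=list(Z.columns),
    )


def classify_high_loading(
    solution: PCASolution, rule: HighLoadingRule
) -> pd.DataFrame:
    """Boolean variables x components table of the high-loading rule.

    With a single component the separation clause is vacuous and only the
    magnitude threshold applies.
    """
    if solution.k < 1:
        raise ValueError("solution has no components")
    absl = solution.loadings.abs().to_numpy()
    k = absl.shape[1]
    high = np.zeros_like(absl, dtype=bool)
    for a in range(k):
        if k == 1:
            margin_ok = np.ones(absl.shape[0], dtype=bool)
        else:
            others = np.delete(absl, a, axis=1).max(axis=1)
            margin_ok = (absl[:, a] - others) >= rule.separation_min
        high[:, a] = (absl[:, a] >= rule.loading_min) & margin_ok
    return pd.DataFrame(high, index=solution.loadings.index, columns=solution.loadings.columns)


def _high_sets(solution: PCASolution, rule: HighLoadingRule) -> dict[str, list[str]]:
    high = classify_high_loading(solution, rule)
    return {pc: high.index[high[pc]].tolist() for pc in high.columns}


def _all_pcs_meaningful(high_sets: dict[str, list[str]], rule: HighLoadingRule) -> bool:
    return all(len(v) >= rule.min_vars_per_pc for v in high_sets.values())


def threshold_pca_index(
    Z: pd.DataFrame,
    rule: HighLoadingRule | None = None,
    use_failing_solution: bool = False,
) -> tuple[IndexDefinition, ThresholdTrace]:
    """Iterative threshold-based variable reduction.

    Each pass starts from a 2-component fit and adds components while every
    component retains at least ``min_vars_per_pc`` high-loading variables.
    When adding a component breaks that condition, the last valid solution is
    kept (or, when the initial 2-component fit itself fails, that fit is kept
    — set ``use_failing_solution=True`` to instead use the failing k-component
    fit for dropping).  Variables that load highly on no retained component
    are dropped and the pass restarts on the reduced set; the algorithm stops
    when a pass drops nothing.  The retained components of the final solution
    form the index collectively (one score column per component).
    """
    rule = rule or HighLoadingRule()
    Z = pd.DataFrame(Z)
    if Z.shape[1] < rule.min_vars_per_pc:
        raise ValueError(
            f"need at least {rule.min_vars_per_pc} variables, got {Z.shape[1]}"
        )
    trace = ThresholdTrace()
    current = list(Z.columns)
    final_sol: PCASolution | None = None

    while True:
        sub = Z[current]
        k_max = min(sub.shape[0] - 1, sub.shape[1])
        sol = fit_pca(sub, min(2, k_max))
        hs = _high_sets(sol, rule)
        note = ""
        if not _all_pcs_meaningful(hs, rule):
            # the very first fit fails: it is itself used for dropping
            note = "initial 2-PC fit already below the high-loading floor"
        else:
            last_valid, last_hs = sol, hs
            failing = None
            k = sol.k
            while k < k_max:
                k += 1
                cand = fit_pca(sub, k)
                cand_hs = _high_sets(cand, rule)
                if _all_pcs_meaningful(cand_hs, rule):
                    last_valid, last_hs = cand, cand_hs
                else:
                    failing = (cand, cand_hs)
                    break
            else:
                note = f"component count reached its bound k={k_max}"
            if use_failing_solution and failing is not None:
                sol, hs = failing
            else:
                sol, hs = last_valid, last_hs

        high_any = sorted(set().union(*hs.values())) if hs else []
        drop = [v for v in current if v not in high_any]
        if drop and len(current) - len(drop) < rule.min_vars_per_pc:
            trace.iterations.append(
                ThresholdIteration(
                    n_vars=len(current), k_final=sol.k, high_sets=hs, dropped=[],
                    note=note or "dropping would leave too few variables",
                )
            )
            trace.warning = (
                f"dropping {len(drop)} variables would leave fewer than "
                f"{rule.min_vars_per_pc}; stopped with the prior solution"
            )
            trace.stop_reason = "too few variables after dropping"
            final_sol = sol
            break
        trace.iterations.append(
            ThresholdIteration(
                n_vars=len(current), k_final=sol.k, high_sets=hs, dropped=drop, note=note
            )
        )
        if not drop:
            trace.stop_reason = "no variables merited dropping"
            final_sol = sol
            break
        current = [v for v in current if v not in drop]

    assert final_sol is not None
    defn = IndexDefinition(
        method="threshold_pca",
        variable_names=list(final_sol.loadings.index),
        loadings=final_sol.loadings.copy(),
        provenance={"rule": {
            "loading_min": rule.loading_min,
            "separation_min": rule.separation_min,
            "min_vars_per_pc": rule.min_vars_per_pc,
        }},
    )
    return defn, trace


def first_pc_index(Z: pd.DataFrame) -> IndexDefinition:
    """The first principal component of all variables, as a one-column index."""
    sol = fit_pca(pd.DataFrame(Z), 1)
    return IndexDefinition(
        method="first_pc",
        variable_names=sol.variable_names,
        loadings=sol.loadings.copy(),
        provenance={"prop_variance_pc1": float(sol.prop_variance[0])},
    )


def supervised_pca_index(
    Z: pd.DataFrame,
    y: np.ndarray,
    variant: str = "dependence",
    screen_frac: float = 0.5,
) -> IndexDefinition:
    """Outcome-aware index: the leading direction of a response-dependence
    operator.

    With a linear kernel on the centered binary response the dependence
    operator ``Z' y_c y_c' Z`` is rank one, so its leading eigenvector is the
    (normalized) vector of covariances between each column and the centered
    response.  The default ``variant="dependence"`` uses that direction
    directly; ``variant="screening"`` first keeps the ``screen_frac`` fraction
    of variables most correlated with the response and then takes their first
    principal component.
    """
    Z = pd.DataFrame(Z)
    y = np.asarray(y, dtype=float)
    if len(y) != len(Z):
        raise ValueError("y length must match the number of rows")
    if np.unique(y).size < 2:
        raise ValueError("y is constant; supervised PCA needs both outcome classes")
    yc = y - y.mean()

    if variant == "screening":
        corr = Z.apply(lambda c: np.corrcoef(c, y)[0, 1]).abs()
        n_keep = max(2, int(np.ceil(screen_frac * Z.shape[1])))
        keep = corr.sort_values(ascending=False).index[:n_keep].tolist()
        keep = [c for c in Z.columns if c in keep]  # original order
        sol = fit_pca(Z[keep], 1)
        loadings = sol.loadings.copy()
        names = keep
    elif variant == "dependence":
        v = (Z.to_numpy().T @ yc) / (len(y) - 1)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("response is uncorrelated with every column; no direction exists")
        u = _fix_signs((v / norm)[:, None])
        loadings = pd.DataFrame(u, index=Z.columns, columns=["PC1"])
        names = list(Z.columns)
    else:
        raise ValueError(f"unknown variant {variant!r}")

    return IndexDefinition(
        method="supervised_pca",
        variable_names=names,
        loadings=loadings,
        provenance={"variant": variant},
    )


def apply_index(defn: IndexDefinition, Z: pd.DataFrame) -> pd.DataFrame:
    """Project a (column-matched) matrix onto an index definition.

    Returns one column per retained component.  Raises when the columns of
    ``Z`` do not exactly cover the definition's variable set.
    """
    Z = pd.DataFrame(Z)
    have = set(Z.columns)
    need = set(defn.variable_names)
    if have != need:
        missing = sorted(need - have)
        extra = sorted(have - need)
        raise ValueError(f"column mismatch: missing={missing} extra={extra}")
    scores = Z[defn.variable_names].to_numpy() @ defn.loadings.to_numpy()
    return pd.DataFrame(scores, index=Z.index, columns=list(defn.loadings.columns))
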