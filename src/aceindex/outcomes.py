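"""Multilevel outcome models linking the neighborhood index, adversity, and BMI.

Four random-intercept linear models, all on the same complete-case rows and
all accounting for census-tract clustering:

1. BMI ~ index
2. BMI ~ 4+ ACEs
3. BMI ~ index + 4+ ACEs
4. BMI ~ index + 4+ ACEs + age + sex + race/ethnicity

Model 3 against model 2 quantifies how far the index attenuates the
ACEs-BMI association; models 3 and 4 are screened for collinearity with
variance inflation factors.  Estimation is restricted maximum likelihood;
fixed-effect intervals and p-values are large-sample Wald.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

AGE_REFERENCE = "18-34"
SEX_REFERENCE = "male"
RACE_REFERENCE = "white"


@dataclass
class MultilevelFit:
    """Fixed effects (estimate, 95% CI, p), variance components, and sizes."""

    estimates: pd.DataFrame  # rows: terms; cols: beta, ci_low, ci_high, p_value
    tract_variance: float
    residual_variance: float
    n_obs: int
    n_clusters: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.tract_variance < 0 or self.residual_variance < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class VifReport:
    """Variance inflation factors for one fixed-effect design."""

    vif: pd.Series
    max_vif: float

    @property
    def has_collinearity(self) -> bool:
        return bool(self.max_vif >= 2.0)


@dataclass
class ModelSuite:
    """The four fitted models plus collinearity and attenuation summaries."""

    models: dict[str, MultilevelFit]
    vif_reports: dict[str, VifReport]
    attenuation: dict[str, float]
    n_obs: int

    def to_table(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.models.items():
            for term, r in fit.estimates.iterrows():
                rows.append(
                    {
                        "model": name,
                        "term": term,
                        "beta": r["beta"],
                        "ci_low": r["ci_low"],
                        "ci_high": r["ci_high"],
                        "p_value": r["p_value"],
                    }
                )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["Outcome models: BMI on neighborhood index and 4+ ACEs", ""]
        for name, fit in self.models.items():
            lines.append(f"{name} (n={fit.n_obs}, tracts={fit.n_clusters}, "
                         f"tract var={fit.tract_variance:.3f}, resid var={fit.residual_variance:.3f})")
            for term, r in fit.estimates.iterrows():
                lines.append(
                    f"  {term:<22} {r['beta']:>8.3f} ({r['ci_low']:.3f}, {r['ci_high']:.3f})"
                    f"  p={r['p_value']:.4g}"
                )
            if name in self.vif_reports:
                lines.append(f"  max VIF = {self.vif_reports[name].max_vif:.3f}")
            lines.append("")
        lines.append(
            "ACE coefficient attenuation (model 2 -> 3): "
            f"{self.attenuation['model2_ace4']:.3f} -> {self.attenuation['model3_ace4']:.3f} "
            f"(change {self.attenuation['change']:+.3f})"
        )
        return "\n".join(lines)


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    # pivoted QR: columns beyond the numerical rank are aliased
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_mlm(
    y: np.ndarray, X: pd.DataFrame, cluster: np.ndarray
) -> MultilevelFit:
    """Random-intercept linear mixed model fitted by REML.

    ``X`` holds the non-intercept fixed-effect columns; an intercept is added
    internally.  Raises when fewer than two clusters are present or when the
    design (with intercept) is rank deficient, naming the aliased columns.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    cluster = np.asarray(cluster)
    if len(y) != len(X) or len(y) != len(cluster):
        raise ValueError("y, X and cluster must have equal length")
    if len(np.unique(cluster)) < 2:
        raise ValueError("need at least 2 clusters for a random intercept")
    exog = sm.add_constant(X, has_constant="add").rename(columns={"const": "intercept"})
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        aliased = _find_aliased(exog.to_numpy(), list(exog.columns))
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")

    res = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=cluster)
        for method in ("bfgs", "lbfgs", "powell", "nm"):
            try:
                res = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
    if res is None:
        raise RuntimeError(f"mixed-model optimization failed: {last_exc}")

    fe_names = list(exog.columns)
    z = 1.959963984540054  # Phi^{-1}(0.975)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta = res.fe_params
        se = res.bse_fe
        est = pd.DataFrame(
            {
                "beta": beta.to_numpy(),
                "ci_low": (beta - z * se).to_numpy(),
                "ci_high": (beta + z * se).to_numpy(),
                "p_value": res.pvalues[fe_names].to_numpy(),
            },
            index=fe_names,
        )
    return MultilevelFit(
        estimates=est,
        tract_variance=max(float(res.cov_re.iloc[0, 0]), 0.0),
        residual_variance=float(res.scale),
        n_obs=len(y),
        n_clusters=int(len(np.unique(cluster))),
        converged=bool(res.converged),
    )


def vif(X: pd.DataFrame) -> VifReport:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j), with R2_j from an
    (intercept-included) regression of predictor j on the rest.  Perfectly
    collinear columns report infinite VIF."""
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 non-intercept predictors")
    out = {}
    for j, name in enumerate(X.columns):
        others = X.drop(columns=[name])
        exog = sm.add_constant(others.to_numpy())
        res = sm.OLS(X[name].to_numpy(), exog).fit()
        r2 = min(float(res.rsquared), 1.0)
        out[name] = np.inf if r2 > 1 - 1e-10 else 1.0 / (1.0 - r2)
    ser = pd.Series(out)
    return VifReport(vif=ser, max_vif=float(ser.max()))


def build_covariate_design(
    participants: pd.DataFrame,
    age_ref: str = AGE_REFERENCE,
    sex_ref: str = SEX_REFERENCE,
    race_ref: str = RACE_REFERENCE,
) -> pd.DataFrame:
    """Indicator columns for age group, sex, and race/ethnicity with the
    reference categories omitted."""
    cols = {}
    for level in sorted(participants["age_group"].astype(str).unique()):
        if level != age_ref:
            cols[f"age_{level}"] = (participants["age_group"].astype(str) == level).astype(float)
    for level in sorted(participants["sex"].astype(str).unique()):
        if level != sex_ref:
            cols[f"sex_{level}"] = (participants["sex"].astype(str) == level).astype(float)
    for level in sorted(participants["race"].astype(str).unique()):
        if level != race_ref:
            cols[f"race_{level}"] = (participants["race"].astype(str) == level).astype(float)
    return pd.DataFrame(cols, index=participants.index)


def run_model_suite(
    participants: pd.DataFrame,
    index_scores: pd.Series | np.ndarray,
    age_ref: str = AGE_REFERENCE,
    sex_ref: str = SEX_REFERENCE,
    race_ref: str = RACE_REFERENCE,
) -> ModelSuite:
    """Fit the four-model suite on common complete-case rows.

    ``participants`` must carry ``bmi``, ``ace4``, ``tract_id``,
    ``age_group``, ``sex``, and ``race``; ``index_scores`` is the continuous
    per-participant neighborhood index aligned to the table.
    """
    df = participants.copy()
    df["index"] = np.asarray(index_scores, dtype=float)
    needed = ["bmi", "ace4", "tract_id", "age_group", "sex", "race", "index"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"participant table lacks columns: {missing}")
    df = df.dropna(subset=needed)
    if len(df) == 0:
        raise ValueError("no complete cases across the suite variables")

    y = df["bmi"].to_numpy(dtype=float)
    cluster = df["tract_id"].to_numpy()
    covs = build_covariate_design(df, age_ref, sex_ref, race_ref)

    designs = {
        "model1": df[["index"]],
        "model2": df[["ace4"]].astype(float),
        "model3": df[["index", "ace4"]].astype(float),
        "model4": pd.concat([df[["index", "ace4"]].astype(float), covs], axis=1),
    }
    models: dict[str, MultilevelFit] = {}
    for name, X in designs.items():
        try:
            models[name] = fit_mlm(y, X, cluster)
        except Exception as exc:
            raise RuntimeError(f"{name} failed: {exc}") from exc

    vif_reports = {name: vif(designs[name]) for name in ("model3", "model4")}

    b2 = float(models["model2"].estimates.loc["ace4", "beta"])
    b3 = float(models["model3"].estimates.loc["ace4", "beta"])
    attenuation = {
        "model2_ace4": b2,
        "model3_ace4": b3,
        "change": b3 - b2,
        "sign": float(np.sign(b3 - b2)),
    }
    return ModelSuite(
        models=models,
        vif_reports=vif_reports,
        attenuation=attenuation,
        n_obs=len(df),
    )
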