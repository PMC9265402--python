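"""Synthetic tract and participant data with known ground truth.

The original survey's individual-level records are not publicly available, so
every downstream stage is exercised on generated data that mimics the study
design: ~380 census tracts carrying 25 correlated neighborhood variables on
mixed percent/rate scales, and ~1,680 participants nested in tracts.  The
binary 4+ ACEs outcome is generated from the same quantile-index logistic
model the Bayesian method fits (so weight recovery is checkable end to end),
and BMI is generated with a tract-level random intercept so the multilevel
models have true variance components to recover.

Tract variables come from a latent-factor model: a small number of shared
factors induce the co-occurrence seen in real neighborhood data (poverty,
crime, poor health cluster together), then each variable is pushed through a
logistic map onto [0, 100] (percent-type) or an exponential map onto
[0, inf) (rate-type).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .preprocess import VariableSpec, orient_variables, quantile_score

#: The 25 neighborhood variables emulated by the generator, with their scale
#: and direction.  Inverse-direction variables are the protective ones
#: (higher raw value = lower adversity risk).
DEFAULT_VARIABLES: list[VariableSpec] = [
    VariableSpec("residential_segregation", "percent", "risk_aligned"),
    VariableSpec("limited_english", "percent", "risk_aligned"),
    VariableSpec("unemployment", "percent", "risk_aligned"),
    VariableSpec("low_education", "percent", "risk_aligned"),
    VariableSpec("poverty", "percent", "risk_aligned"),
    VariableSpec("homeownership", "percent", "inverse"),
    VariableSpec("internet_access", "percent", "inverse"),
    VariableSpec("marital_support", "percent", "inverse"),
    VariableSpec("fast_food_access", "rate", "inverse"),
    VariableSpec("snap_retailer_access", "rate", "risk_aligned"),
    VariableSpec("low_supermarket_access", "percent", "risk_aligned"),
    VariableSpec("uninsured", "percent", "risk_aligned"),
    VariableSpec("health_center_access", "rate", "risk_aligned"),
    VariableSpec("mental_healthcare_access", "rate", "risk_aligned"),
    VariableSpec("sud_treatment_access", "rate", "risk_aligned"),
    VariableSpec("depression_diagnosis", "percent", "inverse"),
    VariableSpec("poor_mental_health", "percent", "risk_aligned"),
    VariableSpec("poor_physical_health", "percent", "risk_aligned"),
    VariableSpec("alcohol_access", "rate", "risk_aligned"),
    VariableSpec("nonviolent_crime", "rate", "risk_aligned"),
    VariableSpec("violent_crime", "rate", "risk_aligned"),
    VariableSpec("traffic_burden", "percent", "inverse"),
    VariableSpec("transit_access", "rate", "inverse"),
    VariableSpec("greenspace", "percent", "inverse"),
    VariableSpec("poor_air_quality", "percent", "risk_aligned"),
]


def variable_specs(n_vars: int) -> list[VariableSpec]:
    """The default 25-variable set, or a generic mixed set for other sizes."""
    if n_vars == len(DEFAULT_VARIABLES):
        return list(DEFAULT_VARIABLES)
    specs = []
    for j in range(n_vars):
        scale = "percent" if j % 2 == 0 else "rate"
        direction = "inverse" if j % 5 == 4 else "risk_aligned"
        specs.append(VariableSpec(f"var_{j + 1:02d}", scale, direction))
    return specs


def default_true_weights(n_vars: int) -> np.ndarray:
    """A realistic ground-truth weight vector: a minority of variables carry
    most of the index.  40% of variables share 70% of the weight, the rest
    share 30%; for the default 25 variables this is ten weights of 0.07 and
    fifteen of 0.02, bracketing the equal-weight reference 1/25 = 0.04."""
    n_major = max(1, round(0.4 * n_vars))
    w = np.full(n_vars, 0.3 / max(n_vars - n_major, 1))
    w[:n_major] = 0.7 / n_major
    if n_vars == n_major:
        w[:] = 1.0 / n_vars
    return w / w.sum()


# covariate distributions and BMI effects defaulting to the study sample's
# composition (sex/age/race frequencies) and the direction of its reported
# adjusted associations; magnitudes are generator choices.
DEFAULT_COVARIATE_FREQS: dict[str, dict[str, float]] = {
    "age_group": {"18-34": 0.109, "35-64": 0.607, "65+": 0.284},
    "sex": {"male": 0.275, "female": 0.725},
    "race": {"white": 0.479, "black": 0.455, "hispanic": 0.022, "asian": 0.012, "other": 0.032},
}

DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "age_group": {"35-64": 1.8, "65+": 0.5},
    "sex": {"female": -0.5},
    "race": {"black": 2.2, "hispanic": -0.2, "asian": -3.0, "other": 1.5},
}


@dataclass
class SimConfig:
    """Generating parameters for the synthetic study.

    Defaults mirror the study conditions: 380 tracts, 1,680 participants,
    25 neighborhood variables, a 4+ ACEs prevalence calibrated to 32.7%, and
    an index odds ratio of 1.24 per decile (beta1 = ln 1.24).
    """

    n_tracts: int = 380
    n_participants: int = 1680
    n_vars: int = 25
    n_factors: int = 2
    factor_loading_scale: float = 0.8
    noise_sd: float = 1.0
    true_weights: np.ndarray | None = None
    beta0: float = 0.0
    beta1: float = float(np.log(1.24))
    target_prevalence: float | None = 0.327
    bmi_intercept: float = 27.0
    gamma_index: float = 0.35
    gamma_ace: float = 0.85
    sigma_tract: float = 1.0
    sigma_resid: float = 6.0
    covariate_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_FREQS.items()}
    )
    covariate_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_EFFECTS.items()}
    )
    tract_skew: float = 0.0
    n_quantiles: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_weights is None:
            self.true_weights = default_true_weights(self.n_vars)
        self.true_weights = np.asarray(self.true_weights, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_tracts < 1 or self.n_participants < 1 or self.n_vars < 1:
            raise ValueError("counts must be positive")
        if self.n_factors > self.n_vars:
            raise ValueError(
                f"n_factors={self.n_factors} exceeds n_vars={self.n_vars}"
            )
        w = self.true_weights
        if w.shape != (self.n_vars,):
            raise ValueError(f"true_weights must have length {self.n_vars}")
        if np.any(w < 0) or np.any(w > 1) or abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("true_weights must lie in [0,1] and sum to 1")
        if self.sigma_tract < 0 or self.sigma_resid <= 0 or self.noise_sd < 0:
            raise ValueError("invalid standard deviations")
        if self.target_prevalence is not None and not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")
        for name, freqs in self.covariate_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-10:
                raise ValueError(f"covariate frequencies for {name!r} sum to {total}, not 1")


@dataclass
class TractTable:
    """Generated (or loaded) tract-level data plus its variable metadata."""

    data: pd.DataFrame  # tract_id + one column per variable
    specs: list[VariableSpec]

    @property
    def variable_names(self) -> list[str]:
        return [s.name for s in self.specs]


@dataclass
class TruthRecord:
    """Everything needed to check recovery: the generating parameters, the
    realized per-tract index scores, and the realized outcome prevalence."""

    config: dict
    beta0_solved: float
    tract_scores: pd.Series
    realized_prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.realized_prevalence <= 1.0:
            raise ValueError("realized prevalence must lie in [0, 1]")

    def to_yaml(self) -> str:
        doc = {
            "config": self.config,
            "beta0_solved": float(self.beta0_solved),
            "realized_prevalence": float(self.realized_prevalence),
            "tract_scores": {str(k): float(v) for k, v in self.tract_scores.items()},
        }
        return yaml.safe_dump(doc, sort_keys=False)


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["true_weights"] = [float(v) for v in config.true_weights]
    return d


def generate_tracts(config: SimConfig) -> TractTable:
    """Draw the tract-level variable matrix from the latent-factor model.

    Each variable j is a linear combination of ``n_factors`` shared standard
    normal factors (loadings ~ N(0, factor_loading_scale^2)) plus independent
    N(0, noise_sd^2) noise, then mapped to its scale: percent-type columns via
    ``100 * expit``, rate-type columns via ``exp`` — so percents stay in
    [0, 100] and rates stay non-negative.  Byte-identical for a given seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = variable_specs(config.n_vars)

    F = rng.standard_normal((config.n_tracts, config.n_factors))
    lam = rng.normal(0.0, config.factor_loading_scale, (config.n_vars, config.n_factors))
    eps = rng.normal(0.0, config.noise_sd, (config.n_tracts, config.n_vars))
    latent = F @ lam.T + eps

    # per-variable location offsets keep typical percents in the tens and
    # typical rates in single digits per 10k
    mu = rng.normal(-1.0, 0.8, config.n_vars)
    nu = rng.normal(1.0, 0.7, config.n_vars)

    cols = {}
    for j, spec in enumerate(specs):
        if spec.scale_type == "percent":
            cols[spec.name] = 100.0 * expit(mu[j] + latent[:, j])
        else:
            cols[spec.name] = np.exp(nu[j] + 0.4 * latent[:, j])
    data = pd.DataFrame(cols)
    data.insert(0, "tract_id", [f"T{i + 1:04d}" for i in range(config.n_tracts)])
    return TractTable(data=data, specs=specs)


def _solve_beta0(scores: np.ndarray, beta1: float, target: float, tol: float = 1e-6) -> float:
    """Bisection on the population-average inverse-logit prevalence."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        prev = float(expit(mid + beta1 * scores).mean())
        if abs(prev - target) < tol:
            return mid
        if prev < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_participants(
    tracts: TractTable, config: SimConfig
) -> tuple[pd.DataFrame, TruthRecord]:
    """Assign participants to tracts and draw outcomes from the ground truth.

    The per-tract true index score is the weighted sum of decile scores of the
    *oriented* tract variables with ``config.true_weights``.  The 4+ ACEs
    indicator is Bernoulli with ``logit p = beta0 + beta1 * score`` (beta0
    solved by bisection when ``target_prevalence`` is set); the raw ACE count
    is then drawn uniformly within the class range (0-3 or 4-14).  BMI adds a
    linear index effect, an additive ACEs effect, categorical covariate
    effects, a tract-level random intercept, and Gaussian noise.
    """
    config.validate()
    if len(tracts.data) == 0:
        raise ValueError("tract table is empty")
    rng = np.random.default_rng(config.seed + 1)

    oriented = orient_variables(tracts.data, tracts.specs)
    qm = quantile_score(oriented, config.n_quantiles)
    tract_scores = pd.Series(
        qm.scores.to_numpy() @ config.true_weights,
        index=tracts.data["tract_id"].to_numpy(),
        name="true_score",
    )

    n = config.n_participants
    n_tracts = len(tracts.data)
    probs = np.full(n_tracts, 1.0 / n_tracts)
    if config.tract_skew > 0:
        raw = np.exp(config.tract_skew * rng.standard_normal(n_tracts))
        probs = raw / raw.sum()
    tract_idx = rng.choice(n_tracts, size=n, p=probs)
    tract_ids = tracts.data["tract_id"].to_numpy()[tract_idx]
    scores = tract_scores.to_numpy()[tract_idx]

    if config.target_prevalence is not None:
        beta0 = _solve_beta0(scores, config.beta1, config.target_prevalence)
    else:
        beta0 = config.beta0
    p = expit(beta0 + config.beta1 * scores)
    ace4 = rng.binomial(1, p)
    ace_count = np.where(
        ace4 == 1, rng.integers(4, 15, size=n), rng.integers(0, 4, size=n)
    )

    cov_draws: dict[str, np.ndarray] = {}
    for name, freqs in config.covariate_freqs.items():
        levels = list(freqs)
        cov_draws[name] = rng.choice(levels, size=n, p=[freqs[k] for k in levels])

    cov_effect = np.zeros(n)
    for name, effects in config.covariate_effects.items():
        if name not in cov_draws:
            continue
        eff = np.vectorize(lambda lev: effects.get(lev, 0.0))(cov_draws[name])
        cov_effect += eff.astype(float)

    b_tract = rng.normal(0.0, config.sigma_tract, n_tracts)
    bmi = (
        config.bmi_intercept
        + config.gamma_index * scores
        + config.gamma_ace * ace4
        + cov_effect
        + b_tract[tract_idx]
        + rng.normal(0.0, config.sigma_resid, n)
    )

    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:05d}" for i in range(n)],
            "tract_id": tract_ids,
            "ace_count": ace_count.astype(int),
            "ace4": ace4.astype(int),
            "bmi": bmi,
            "age_group": cov_draws.get("age_group", np.full(n, "18-34")),
            "sex": cov_draws.get("sex", np.full(n, "male")),
            "race": cov_draws.get("race", np.full(n, "white")),
        }
    )
    truth = TruthRecord(
        config=_config_dict(config),
        beta0_solved=float(beta0),
        tract_scores=tract_scores,
        realized_prevalence=float(ace4.mean()),
    )
    return participants, truth


def write_simulation(
    outdir,
    tracts: TractTable,
    participants: pd.DataFrame,
    truth: TruthRecord,
) -> dict[str, str]:
    """Write tracts/participants as CSV and the truth record as YAML.
    The generating seed travels inside the truth record."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracts": outdir / "tracts.csv",
        "participants": outdir / "participants.csv",
        "truth": outdir / "truth.yaml",
        "variables": outdir / "variables.csv",
    }
    tracts.data.to_csv(paths["tracts"], index=False)
    participants.to_csv(paths["participants"], index=False)
    paths["truth"].write_text(truth.to_yaml())
    pd.DataFrame(
        [{"name": s.name, "scale_type": s.scale_type, "direction": s.direction}
         for s in tracts.specs]
    ).to_csv(paths["variables"], index=False)
    return {k: str(v) for k, v in paths.items()}
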