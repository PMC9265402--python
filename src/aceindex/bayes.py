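"""Bayesian quantile index regression with Dirichlet-constrained weights.

The model ties a binary adversity outcome to a weighted sum of per-variable
decile scores:

    logit(p_i) = beta0 + beta1 * sum_j w_j q_ij,

with the weight vector w constrained to the probability simplex (w_j in [0,1],
sum w_j = 1).  Priors: w ~ Dirichlet(1, ..., 1); beta1 ~ Normal(0, sigma1^2)
with sigma1 ~ Uniform(0, 100); beta0 ~ Normal(0, 100^2).  beta1 is the
log-odds change per one-decile increase of the whole index, so exp(beta1) is
an odds ratio per decile.

Weights are parametrized through unnormalized positive components
g_j ~ Gamma(1, 1) with w = g / sum(g), the standard Gamma representation of a
flat Dirichlet; this keeps every draw exactly on the simplex.  Sampling is
adaptive Metropolis-within-Gibbs: scalar random-walk updates for beta0,
beta1, sigma1 and each log g_j, with proposal scales tuned toward a 0.44
acceptance rate during an initial adaptation window only (then frozen, so
the post-adaptation chain satisfies detailed balance).

Convergence is screened with the Geweke diagnostic: a z-comparison of the
mean of an early chain segment against a late segment, with segment variances
taken from autoregressive spectral density estimates at frequency zero;
|z| < 2 is read as evidence of convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.linear_model import yule_walker

from .preprocess import QuantileMatrix

logger = logging.getLogger(__name__)

_WEIGHT_PREFIX = "w_"


@dataclass(frozen=True)
class McmcSettings:
    """Sampler schedule.  Defaults: 10,000 retained iterations after 5,000
    burn-in, of which the first 500 adapt proposal scales; thinning 1; decile
    (Q=10) scores."""

    n_iter: int = 10000
    n_burnin: int = 5000
    n_adapt: int = 500
    thin: int = 1
    n_quantiles: int = 10
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self) -> None:
        for name in ("n_iter", "n_burnin", "n_adapt", "thin", "n_quantiles", "n_chains"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_adapt > self.n_burnin:
            raise ValueError(
                "n_adapt must not exceed n_burnin: proposal adaptation must end "
                "before draws are retained"
            )


@dataclass
class PosteriorSummary:
    """Posterior medians, 95% credible intervals, and diagnostics.

    ``params`` has one row per sampled parameter (median / lower / upper at
    2.5% and 97.5%).  ``odds_ratio`` summarizes exp(beta1) draws; the index is
    flagged significant when that interval excludes 1.  ``geweke`` maps each
    parameter to its z score; ``converged`` is True when every finite z has
    absolute value below 2.
    """

    params: pd.DataFrame
    odds_ratio: tuple[float, float, float]  # (median, lower, upper)
    significant: bool
    geweke: dict[str, float]
    converged: bool
    weight_medians: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    variable_names: list[str] = field(default_factory=list)
    n_quantiles: int = 10

    def to_yaml(self) -> str:
        import yaml

        doc = {
            "params": {
                str(k): {c: float(self.params.loc[k, c]) for c in self.params.columns}
                for k in self.params.index
            },
            "odds_ratio": {
                "median": float(self.odds_ratio[0]),
                "cri_2.5": float(self.odds_ratio[1]),
                "cri_97.5": float(self.odds_ratio[2]),
            },
            "significant": bool(self.significant),
            "geweke_z": {k: float(v) for k, v in self.geweke.items()},
            "converged": bool(self.converged),
            "weight_medians": {k: float(v) for k, v in self.weight_medians.items()},
            "variable_names": list(self.variable_names),
            "n_quantiles": int(self.n_quantiles),
        }
        return yaml.safe_dump(doc, sort_keys=False)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log p(y | eta) for a Bernoulli-logit likelihood, stable for large |eta|
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_bayes_index(
    Q: QuantileMatrix | pd.DataFrame | np.ndarray,
    y: np.ndarray,
    settings: McmcSettings | None = None,
    fixed_weights: np.ndarray | None = None,
    fixed_sigma1: float | None = None,
    variable_names: list[str] | None = None,
) -> tuple[PosteriorSummary, pd.DataFrame]:
    """Fit the Bayesian index model by adaptive Metropolis-within-Gibbs.

    Parameters
    ----------
    Q
        Integer quantile scores, participants x variables.
    y
        Binary outcome (both classes required).
    settings
        Sampler schedule; the chain is fully reproducible from ``settings.seed``.
    fixed_weights
        When given, the weight vector is clamped to this simplex point and
        only (beta0, beta1, sigma1) are sampled — used for likelihood-oracle
        checks.
    fixed_sigma1
        When given, the beta1 prior SD is clamped (its Uniform(0,100) update
        is skipped); with ``fixed_weights`` this makes the joint posterior
        mode of (beta0, beta1) well defined for oracle comparisons.

    Returns
    -------
    (summary, chains)
        ``chains`` holds one retained draw per row: beta0, beta1, sigma1,
        one ``w_<name>`` column per variable, and the log posterior ``lp``.
    """
    settings = settings or McmcSettings()
    if settings.n_chains > 1:
        # diagnostic mode: independent chains from offset seeds, pooled for
        # summaries, distinguishable through the "chain" column
        parts = []
        for c in range(settings.n_chains):
            sub = McmcSettings(
                n_iter=settings.n_iter, n_burnin=settings.n_burnin,
                n_adapt=settings.n_adapt, thin=settings.thin,
                n_quantiles=settings.n_quantiles,
                seed=(settings.seed + 1000003 * c) % (2**31 - 1), n_chains=1,
            )
            _, ch = fit_bayes_index(
                Q, y, sub, fixed_weights=fixed_weights,
                fixed_sigma1=fixed_sigma1, variable_names=variable_names,
            )
            ch.insert(0, "chain", c)
            parts.append(ch)
        chains = pd.concat(parts, ignore_index=True)
        names_all = [c[len(_WEIGHT_PREFIX):] for c in chains.columns
                     if c.startswith(_WEIGHT_PREFIX)]
        summary = summarize_posterior(
            chains.drop(columns="chain"), settings, variable_names=names_all
        )
        return summary, chains

    if isinstance(Q, QuantileMatrix):
        names = list(Q.scores.columns)
        Qm = Q.scores.to_numpy()
    elif isinstance(Q, pd.DataFrame):
        names = list(Q.columns)
        Qm = Q.to_numpy()
    else:
        Qm = np.asarray(Q)
        names = variable_names or [f"v{j + 1}" for j in range(Qm.shape[1])]
    if variable_names is not None:
        names = list(variable_names)

    Qm = np.asarray(Qm)
    if not np.allclose(Qm, np.round(Qm)):
        raise ValueError("quantile scores must be integers")
    Qm = Qm.astype(float)
    y = np.asarray(y, dtype=float)
    if Qm.shape[0] != len(y):
        raise ValueError(f"{Qm.shape[0]} score rows but {len(y)} outcomes")
    if np.unique(y).size < 2:
        raise ValueError("outcome has a single class; the model is not estimable")
    n, C = Qm.shape

    rng = np.random.default_rng(settings.seed)

    # -- state ---------------------------------------------------------------
    ybar = y.mean()
    b0 = float(np.log(ybar / (1 - ybar)))
    b1 = 0.0
    sigma1 = 10.0 if fixed_sigma1 is None else float(fixed_sigma1)
    if not 0.0 < sigma1 < 100.0:
        raise ValueError("fixed_sigma1 must lie in (0, 100)")
    if fixed_weights is not None:
        w_fixed = np.asarray(fixed_weights, dtype=float)
        if w_fixed.shape != (C,) or np.any(w_fixed < 0) or abs(w_fixed.sum() - 1) > 1e-8:
            raise ValueError("fixed_weights must be a length-C simplex vector")
        g = w_fixed.copy()  # never updated
    else:
        g = np.ones(C)
    phi = np.log(np.maximum(g, 1e-300))
    t = Qm @ g
    sg = g.sum()
    s = t / sg  # per-row index score
    eta = b0 + b1 * s
    ll = _bernoulli_loglik(eta, y)

    sample_w = fixed_weights is None
    n_scalar = 3 + (C if sample_w else 0)
    log_step = np.full(n_scalar, np.log(0.1))  # b0, b1, sigma1, phi_1..phi_C
    target_acc = 0.44

    total = settings.n_burnin + settings.n_iter
    n_keep = settings.n_iter // settings.thin
    keep_cols = ["beta0", "beta1", "sigma1"] + [_WEIGHT_PREFIX + nm for nm in names] + ["lp"]
    draws = np.empty((n_keep, len(keep_cols)))
    kept = 0

    def log_prior_b0(v: float) -> float:
        return -0.5 * (v / 100.0) ** 2

    def log_prior_b1(v: float, sig: float) -> float:
        return -np.log(sig) - 0.5 * (v / sig) ** 2

    def log_post() -> float:
        # Gamma(1,1) components in log space: sum(-g_j + phi_j)
        lp = ll + log_prior_b0(b0) + log_prior_b1(b1, sigma1)
        if sample_w:
            lp += float(np.sum(phi - g))
        return lp

    for it in range(total):
        adapting = it < settings.n_adapt
        gamma = 1.0 / np.sqrt(it + 1.0) if adapting else 0.0

        # beta0
        prop = b0 + np.exp(log_step[0]) * rng.standard_normal()
        eta_p = eta + (prop - b0)
        ll_p = _bernoulli_loglik(eta_p, y)
        delta = ll_p - ll + log_prior_b0(prop) - log_prior_b0(b0)
        acc = np.log(rng.uniform()) < delta
        if acc:
            b0, eta, ll = prop, eta_p, ll_p
        if adapting:
            log_step[0] += gamma * ((1.0 if acc else 0.0) - target_acc)

        # beta1
        prop = b1 + np.exp(log_step[1]) * rng.standard_normal()
        eta_p = b0 + prop * s
        ll_p = _bernoulli_loglik(eta_p, y)
        delta = ll_p - ll + log_prior_b1(prop, sigma1) - log_prior_b1(b1, sigma1)
        acc = np.log(rng.uniform()) < delta
        if acc:
            b1, eta, ll = prop, eta_p, ll_p
        if adapting:
            log_step[1] += gamma * ((1.0 if acc else 0.0) - target_acc)

        # sigma1 (uniform(0,100) prior; likelihood is the beta1 prior density)
        if fixed_sigma1 is None:
            prop = sigma1 + np.exp(log_step[2]) * rng.standard_normal()
            if 0.0 < prop < 100.0:
                delta = log_prior_b1(b1, prop) - log_prior_b1(b1, sigma1)
                acc = np.log(rng.uniform()) < delta
                if acc:
                    sigma1 = prop
            else:
                acc = False
            if adapting:
                log_step[2] += gamma * ((1.0 if acc else 0.0) - target_acc)

        # weights, one component at a time on the log scale
        if sample_w:
            for j in range(C):
                step = np.exp(log_step[3 + j])
                phi_p = phi[j] + step * rng.standard_normal()
                g_p = np.exp(phi_p)
                dg = g_p - g[j]
                t_p = t + dg * Qm[:, j]
                sg_p = sg + dg
                s_p = t_p / sg_p
                eta_p = b0 + b1 * s_p
                ll_p = _bernoulli_loglik(eta_p, y)
                # Gamma(1,1) prior with log-scale Jacobian: phi_j - g_j
                delta = ll_p - ll + (phi_p - g_p) - (phi[j] - g[j])
                acc = np.log(rng.uniform()) < delta
                if acc:
                    phi[j], g[j] = phi_p, g_p
                    t, sg, s, eta, ll = t_p, sg_p, s_p, eta_p, ll_p
                if adapting:
                    log_step[3 + j] += gamma * ((1.0 if acc else 0.0) - target_acc)
            if (it + 1) % 500 == 0:
                # refresh running sums to cancel float drift
                t = Qm @ g
                sg = g.sum()
                s = t / sg
                eta = b0 + b1 * s
                ll = _bernoulli_loglik(eta, y)

        post_burn = it - settings.n_burnin
        if post_burn >= 0 and post_burn % settings.thin == 0 and kept < n_keep:
            w = g / sg
            draws[kept, 0] = b0
            draws[kept, 1] = b1
            draws[kept, 2] = sigma1
            draws[kept, 3:3 + C] = w
            draws[kept, 3 + C] = log_post()
            kept += 1

    chains = pd.DataFrame(draws[:kept], columns=keep_cols)
    summary = summarize_posterior(chains, settings, variable_names=names)
    if not summary.converged:
        logger.warning("Geweke diagnostic above 2 for at least one parameter")
    return summary, chains


def _spectrum0_ar(x: np.ndarray) -> float:
    """Spectral density at frequency zero via a Yule-Walker AR fit,
    order chosen by AIC (order 0 = the sample variance)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    v0 = float(np.var(x))
    if v0 == 0.0:
        return 0.0
    best_aic = n * np.log(v0)
    best_s0 = v0
    max_order = min(20, n // 10)
    for p in range(1, max_order + 1):
        try:
            rho, sigma = yule_walker(x, order=p, method="mle")
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate segment
            continue
        sigma2 = float(sigma) ** 2
        denom = 1.0 - float(np.sum(rho))
        if sigma2 <= 0 or abs(denom) < 1e-10:
            continue
        aic = n * np.log(sigma2) + 2 * p
        if aic < best_aic:
            best_aic = aic
            best_s0 = sigma2 / denom**2
    return best_s0


def geweke_z(
    chain: np.ndarray, frac_first: float = 0.10, frac_last: float = 0.50
) -> float:
    """Geweke convergence z score comparing early and late chain segments.

    The mean of the first ``frac_first`` of the chain is compared with the
    mean of the last ``frac_last``; each segment's variance-of-the-mean uses
    an AR spectral density estimate at frequency zero.  |z| < 2 is the
    conventional convergence call.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError(f"chain too short for the Geweke diagnostic (n={n} < 100)")
    if np.ptp(x) == 0:
        raise ValueError("constant chain: zero variance, z undefined")
    if not (0 < frac_first < 1 and 0 < frac_last < 1 and frac_first + frac_last <= 1):
        raise ValueError("segment fractions must lie in (0,1) and not overlap")
    na = int(np.floor(n * frac_first))
    nb = int(np.floor(n * frac_last))
    a, b = x[:na], x[n - nb:]
    var = _spectrum0_ar(a) / na + _spectrum0_ar(b) / nb
    if var == 0.0:
        return np.inf if a.mean() != b.mean() else 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))


def summarize_posterior(
    chains: pd.DataFrame,
    settings: McmcSettings | None = None,
    variable_names: list[str] | None = None,
) -> PosteriorSummary:
    """Medians, percentile credible intervals, and diagnostics from raw draws.

    The odds-ratio summary exponentiates the beta1 draws *before* taking
    percentiles.  Parameters whose chains are constant get a NaN Geweke score
    and are excluded from the convergence verdict.
    """
    settings = settings or McmcSettings()
    if len(chains) == 0:
        raise ValueError("no retained draws to summarize")
    param_cols = [c for c in chains.columns if c != "lp"]
    med = chains[param_cols].median()
    lo = chains[param_cols].quantile(0.025)
    hi = chains[param_cols].quantile(0.975)
    params = pd.DataFrame({"median": med, "cri_2.5": lo, "cri_97.5": hi})

    orr = np.exp(chains["beta1"].to_numpy())
    or_med = float(np.median(orr))
    or_lo, or_hi = (float(v) for v in np.quantile(orr, [0.025, 0.975]))
    significant = or_lo > 1.0 or or_hi < 1.0

    geweke: dict[str, float] = {}
    for c in param_cols:
        col = chains[c].to_numpy()
        try:
            geweke[c] = geweke_z(col)
        except ValueError:
            geweke[c] = float("nan")
    finite = [z for z in geweke.values() if np.isfinite(z)]
    converged = all(abs(z) < 2 for z in finite)

    w_cols = [c for c in param_cols if c.startswith(_WEIGHT_PREFIX)]
    weight_medians = med[w_cols].copy()
    weight_medians.index = [c[len(_WEIGHT_PREFIX):] for c in w_cols]
    names = variable_names or list(weight_medians.index)

    return PosteriorSummary(
        params=params,
        odds_ratio=(or_med, or_lo, or_hi),
        significant=bool(significant),
        geweke=geweke,
        converged=bool(converged),
        weight_medians=weight_medians,
        variable_names=names,
        n_quantiles=settings.n_quantiles,
    )


def apply_bayes_index(
    summary: PosteriorSummary,
    data: pd.DataFrame,
    mode: str = "quantile",
) -> pd.Series:
    """Score rows with the posterior-median weights.

    ``mode="quantile"`` (default) expects the per-variable decile scores the
    model was fitted on; ``mode="raw"`` accepts oriented raw variable values
    instead (weights applied directly to variable values).  Either way the
    score is ``sum_j median(w_j) * v_ij``.
    """
    if mode not in ("quantile", "raw"):
        raise ValueError(f"mode must be 'quantile' or 'raw', got {mode!r}")
    have = set(data.columns)
    need = set(summary.weight_medians.index)
    if have != need:
        raise ValueError(
            f"column mismatch: missing={sorted(need - have)} extra={sorted(have - need)}"
        )
    vals = data[list(summary.weight_medians.index)].astype(float)
    if mode == "quantile":
        arr = vals.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("quantile mode expects integer decile scores")
    scores = vals.to_numpy() @ summary.weight_medians.to_numpy()
    return pd.Series(scores, index=data.index, name="bayes_index")
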