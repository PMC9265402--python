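"""End-to-end orchestration: data in, indexes built, methods compared,
outcome suite run, artifacts written.

The pipeline reproduces the study workflow on either simulated or supplied
tables: complete-case filtering on the neighborhood variables, orientation
and scaling, the four index constructions, AIC comparison of one logistic
model per index column, and the four-model multilevel BMI suite using the
selected index.  Every run writes a manifest with the seed and a config hash
so deterministic stages are bit-reproducible and stochastic stages are
chain-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import McmcSettings, apply_bayes_index, fit_bayes_index
from .compare import DEFAULT_PRIORITY, ComparisonReport, compare_indexes, fit_logistic
from .outcomes import ModelSuite, run_model_suite
from .pca import (
    HighLoadingRule,
    apply_index,
    first_pc_index,
    supervised_pca_index,
    threshold_pca_index,
)
from .preprocess import (
    VariableSpec,
    drop_incomplete,
    orient_variables,
    quantile_score,
    standardize,
)
from .synthetic import SimConfig, TractTable, generate_participants, generate_tracts

logger = logging.getLogger(__name__)

ALL_METHODS = ("threshold_pca", "first_pc", "supervised_pca", "bayes")


class ValidationError(ValueError):
    """Raised for malformed input tables or configuration."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulate`` or the (``tract_path``, ``participant_path``)
    pair must be provided.
    """

    simulate: SimConfig | None = None
    tract_path: str | None = None
    participant_path: str | None = None
    variables_path: str | None = None
    methods: tuple[str, ...] = ALL_METHODS
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    rule: HighLoadingRule = field(default_factory=HighLoadingRule)
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    apply_mode: str = "quantile"
    outdir: str = "aceindex_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = self.tract_path is not None and self.participant_path is not None
        if self.simulate is None and not has_paths:
            raise ValidationError("provide either a simulate block or input table paths")
        unknown = [m for m in self.methods if m not in ALL_METHODS]
        if unknown:
            raise ValidationError(f"unknown methods: {unknown}")
        if not self.methods:
            raise ValidationError("method list is empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "simulate" in doc and doc["simulate"] is not None:
            kwargs["simulate"] = SimConfig(**doc["simulate"])
        for key in ("tract_path", "participant_path", "variables_path", "outdir",
                    "seed", "log_level", "apply_mode"):
            if key in doc:
                kwargs[key] = doc[key]
        if "methods" in doc:
            kwargs["methods"] = tuple(doc["methods"])
        if "priority" in doc:
            kwargs["priority"] = tuple(doc["priority"])
        if "mcmc" in doc:
            kwargs["mcmc"] = McmcSettings(**doc["mcmc"])
        if "rule" in doc:
            kwargs["rule"] = HighLoadingRule(**doc["rule"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d: dict = {
            "tract_path": self.tract_path,
            "participant_path": self.participant_path,
            "variables_path": self.variables_path,
            "methods": list(self.methods),
            "priority": list(self.priority),
            "apply_mode": self.apply_mode,
            "outdir": self.outdir,
            "seed": self.seed,
            "log_level": self.log_level,
            "mcmc": asdict(self.mcmc),
            "rule": asdict(self.rule),
        }
        if self.simulate is not None:
            sim = asdict(self.simulate)
            sim["true_weights"] = [float(v) for v in self.simulate.true_weights]
            d["simulate"] = sim
        return d


def read_variable_specs(path: str | Path) -> list[VariableSpec]:
    """Read variable metadata from a CSV with columns name/scale_type/direction."""
    df = pd.read_csv(path)
    needed = {"name", "scale_type", "direction"}
    if not needed <= set(df.columns):
        raise ValidationError(f"variables file must have columns {sorted(needed)}")
    return [
        VariableSpec(str(r["name"]), str(r["scale_type"]), str(r["direction"]))
        for _, r in df.iterrows()
    ]


def read_tables(
    tract_path: str | Path,
    participant_path: str | Path,
    specs: list[VariableSpec],
) -> tuple[TractTable, pd.DataFrame]:
    """Read and validate the tract and participant CSV tables.

    Checks: known columns, percent values in [0, 100], rates >= 0, ACE counts
    in 0-14, positive BMI, unique tract ids, and the participant->tract
    foreign key.  Violations raise :class:`ValidationError` naming rows.
    """
    tracts = pd.read_csv(tract_path)
    participants = pd.read_csv(participant_path)

    if "tract_id" not in tracts.columns:
        raise ValidationError("tract table lacks a tract_id column")
    dupes = tracts["tract_id"][tracts["tract_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate tract ids: {dupes[:5]}")
    for spec in specs:
        if spec.name not in tracts.columns:
            raise ValidationError(f"tract table lacks variable column {spec.name!r}")
        col = tracts[spec.name]
        if spec.scale_type == "percent":
            bad = tracts.index[(col < 0) | (col > 100)].tolist()
        else:
            bad = tracts.index[col < 0].tolist()
        if bad:
            raise ValidationError(
                f"{spec.scale_type} variable {spec.name!r} out of range at rows {bad[:5]}"
            )

    for col in ("tract_id", "ace_count", "ace4", "bmi"):
        if col not in participants.columns:
            raise ValidationError(f"participant table lacks column {col!r}")
    counts = participants["ace_count"]
    bad = participants.index[(counts < 0) | (counts > 14) | (counts != counts.round())].tolist()
    if bad:
        raise ValidationError(f"ace_count outside 0-14 at rows {bad[:5]}")
    mism = participants.index[
        (participants["ace4"] == 1) != (participants["ace_count"] >= 4)
    ].tolist()
    if mism:
        raise ValidationError(f"ace4 inconsistent with ace_count at rows {mism[:5]}")
    bad = participants.index[participants["bmi"].notna() & (participants["bmi"] <= 0)].tolist()
    if bad:
        raise ValidationError(f"non-positive BMI at rows {bad[:5]}")
    orphans = participants.index[
        ~participants["tract_id"].isin(set(tracts["tract_id"]))
    ].tolist()
    if orphans:
        raise ValidationError(
            f"participant tract_id missing from tract table at rows {orphans[:5]}"
        )
    return TractTable(data=tracts, specs=specs), participants


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    comparison: ComparisonReport | None
    suite: ModelSuite | None
    artifacts: dict[str, str]
    selected_scores: pd.Series | None = None
    bayes_converged: bool | None = None


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, stop_after: str = "outcome") -> PipelineResult:
    """Execute the workflow, writing each intermediate artifact.

    ``stop_after`` may be ``"simulate"``, ``"index"``, ``"compare"`` or
    ``"outcome"`` (full run).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    artifacts: dict[str, str] = {}

    def save_text(name: str, text: str) -> None:
        p = outdir / name
        p.write_text(text)
        artifacts[name] = str(p)

    def save_df(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        df.to_csv(p, **kw)
        artifacts[name] = str(p)

    # ---- stage: data -------------------------------------------------------
    try:
        if config.simulate is not None:
            logger.info("stage=data simulating tracts and participants")
            tracts = generate_tracts(config.simulate)
            participants, truth = generate_participants(tracts, config.simulate)
            save_df("tracts.csv", tracts.data, index=False)
            save_df("participants.csv", participants, index=False)
            save_text("truth.yaml", truth.to_yaml())
            save_df(
                "variables.csv",
                pd.DataFrame(
                    [{"name": s.name, "scale_type": s.scale_type, "direction": s.direction}
                     for s in tracts.specs]
                ),
                index=False,
            )
        else:
            logger.info("stage=data reading input tables")
            if config.variables_path is None:
                raise ValidationError("variables_path is required when reading tables")
            specs = read_variable_specs(config.variables_path)
            tracts, participants = read_tables(
                config.tract_path, config.participant_path, specs
            )
    except Exception:
        logger.exception("stage=data failed")
        raise

    if stop_after == "simulate":
        _write_manifest(outdir, config, artifacts, n_dropped=0)
        return PipelineResult(None, None, artifacts)

    # ---- stage: preprocess -------------------------------------------------
    logger.info("stage=preprocess orienting, scaling and decile-scoring")
    var_names = tracts.variable_names
    merged = participants.merge(tracts.data, on="tract_id", how="left", validate="m:1")
    merged, n_dropped = drop_incomplete(merged, var_names)
    merged = merged.reset_index(drop=True)
    logger.info("stage=preprocess dropped %d incomplete rows", n_dropped)

    oriented = orient_variables(merged[var_names], tracts.specs)
    Z = standardize(oriented)
    # decile cutpoints learned on the tract-level analysis set, applied to
    # participants through their tract
    tract_sub = (
        merged[["tract_id"] + var_names].drop_duplicates("tract_id").set_index("tract_id")
    )
    oriented_tracts = orient_variables(tract_sub, tracts.specs)
    qm = quantile_score(oriented_tracts, config.mcmc.n_quantiles)
    Qpart = qm.score_values(oriented.values)
    y = merged["ace4"].to_numpy(dtype=float)

    save_df(
        "oriented_summary.csv",
        oriented.values.describe().T.assign(
            inverted=[c in oriented.inverted for c in oriented.values.columns]
        ),
    )

    # ---- stage: indexes ----------------------------------------------------
    index_scores: dict[str, pd.DataFrame] = {}
    bayes_summary = None
    if "threshold_pca" in config.methods:
        logger.info("stage=index threshold-based PCA")
        defn_t, trace = threshold_pca_index(Z, config.rule)
        index_scores["threshold"] = apply_index(defn_t, Z[defn_t.variable_names])
        save_text("index_threshold.yaml", defn_t.to_yaml())
        save_text(
            "threshold_trace.yaml",
            yaml.safe_dump(
                {
                    "stop_reason": trace.stop_reason,
                    "warning": trace.warning,
                    "iterations": [
                        {
                            "n_vars": it.n_vars,
                            "k_final": it.k_final,
                            "high_sets": it.high_sets,
                            "dropped": it.dropped,
                            "note": it.note,
                        }
                        for it in trace.iterations
                    ],
                },
                sort_keys=False,
            ),
        )
    if "first_pc" in config.methods:
        logger.info("stage=index first principal component")
        defn_1 = first_pc_index(Z)
        index_scores["first_pc"] = apply_index(defn_1, Z)
        save_text("index_first_pc.yaml", defn_1.to_yaml())
    if "supervised_pca" in config.methods:
        logger.info("stage=index supervised PCA")
        defn_s = supervised_pca_index(Z, y)
        index_scores["supervised"] = apply_index(defn_s, Z[defn_s.variable_names])
        save_text("index_supervised.yaml", defn_s.to_yaml())
    if "bayes" in config.methods:
        logger.info("stage=index Bayesian index regression (MCMC)")
        settings = McmcSettings(
            n_iter=config.mcmc.n_iter,
            n_burnin=config.mcmc.n_burnin,
            n_adapt=config.mcmc.n_adapt,
            thin=config.mcmc.thin,
            n_quantiles=config.mcmc.n_quantiles,
            seed=config.seed if config.mcmc.seed == 0 else config.mcmc.seed,
            n_chains=config.mcmc.n_chains,
        )
        bayes_summary, chains = fit_bayes_index(Qpart, y, settings)
        if config.apply_mode == "quantile":
            bscores = apply_bayes_index(bayes_summary, Qpart, mode="quantile")
        else:
            bscores = apply_bayes_index(bayes_summary, oriented.values, mode="raw")
        index_scores["bayes"] = bscores.to_frame("index")
        save_df("chains.csv", chains, index=False)
        save_text("posterior.yaml", bayes_summary.to_yaml())

    if stop_after == "index":
        _write_manifest(outdir, config, artifacts, n_dropped)
        return PipelineResult(
            None, None, artifacts,
            bayes_converged=None if bayes_summary is None else bayes_summary.converged,
        )

    # ---- stage: compare ----------------------------------------------------
    logger.info("stage=compare per-index logistic models and AIC")
    fits = {}
    for method, scores in index_scores.items():
        flist = [
            fit_logistic(y, scores.iloc[:, i].to_numpy(),
                         label=method if scores.shape[1] == 1 else f"{method}_pc{i + 1}")
            for i in range(scores.shape[1])
        ]
        fits[method] = flist if len(flist) > 1 else flist[0]
    report = compare_indexes(fits, priority=config.priority)
    save_df("comparison.csv", report.table, index=False)
    save_text("comparison.txt", report.to_text())
    logger.info("stage=compare selected method: %s", report.selected)

    if stop_after == "compare":
        _write_manifest(outdir, config, artifacts, n_dropped)
        return PipelineResult(
            report, None, artifacts,
            bayes_converged=None if bayes_summary is None else bayes_summary.converged,
        )

    # ---- stage: outcome ----------------------------------------------------
    logger.info("stage=outcome multilevel BMI model suite")
    sel_scores = index_scores[report.selected]
    if sel_scores.shape[1] > 1:
        # multi-component index: carry its best-AIC column into the suite
        sel_fits = fits[report.selected]
        aics = [f.aic for f in sel_fits]
        sel = pd.Series(sel_scores.iloc[:, int(np.argmin(aics))].to_numpy(), index=merged.index)
    else:
        sel = pd.Series(sel_scores.iloc[:, 0].to_numpy(), index=merged.index)
    suite = run_model_suite(merged, sel)
    save_df("outcome_models.csv", suite.to_table(), index=False)
    save_text("outcome_models.txt", suite.to_text())

    _write_manifest(outdir, config, artifacts, n_dropped)
    return PipelineResult(
        report,
        suite,
        artifacts,
        selected_scores=sel,
        bayes_converged=None if bayes_summary is None else bayes_summary.converged,
    )


def _write_manifest(
    outdir: Path, config: RunConfig, artifacts: dict[str, str], n_dropped: int
) -> None:
    manifest = {
        "aceindex_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "n_dropped_incomplete": n_dropped,
        "artifacts": sorted(artifacts),
    }
    p = outdir / "manifest.yaml"
    p.write_text(yaml.safe_dump(manifest, sort_keys=False, default_flow_style=False))
    artifacts["manifest.yaml"] = str(p)
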