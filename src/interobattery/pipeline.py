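"""Two-step modelling pipeline.

Step 1 fits one PLSR per SF-36 subscale from the 21 interoceptive +
physiological predictors, with nested leave-one-out CV and permutation
inference.  The interoceptive predictors carrying significant weights in the
significant step-1 models are retained (union rule by default) and, in step 2,
combined with the 14 exteroceptive body-representation variables to refit the
significant outcomes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import registry
from .plsr import PlsrCvResult, permutation_inference

__all__ = [
    "PipelineConfig",
    "TwoStepReport",
    "run_step1",
    "select_retained_predictors",
    "run_step2",
    "run_two_step",
    "write_report",
    "read_report",
]

log = logging.getLogger("interobattery.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int  # master seed; per-model streams are spawned from it
    alpha: float = 0.05  # model-level and weight-level significance
    n_perm: int = 1000
    k_max: int = 10
    bonferroni: bool = False  # correct alpha across the eight step-1 models
    retention: str = "union"  # "union" | "per_model"
    reselect_k: bool = False  # re-select K inside each permutation

    def __post_init__(self):
        if self.retention not in ("union", "per_model"):
            raise ValueError("retention must be 'union' or 'per_model'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _model_alpha(config: PipelineConfig) -> float:
    return config.alpha / len(registry.OUTCOMES) if config.bonferroni else config.alpha


def _model_seeds(config: PipelineConfig, stage: str) -> dict[str, np.random.SeedSequence]:
    offset = {"step1": 0, "step2": 1}[stage]
    ss = np.random.SeedSequence(config.seed).spawn(2)[offset]
    return dict(zip(registry.OUTCOMES, ss.spawn(len(registry.OUTCOMES))))


def _fit_one(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    config: PipelineConfig,
    seed_seq: np.random.SeedSequence,
) -> PlsrCvResult:
    X = cohort[predictors].to_numpy(dtype=float)
    # median imputation within the full table; fold-internal refinement is not
    # needed because missingness is rare in practice and imputation uses no y
    if np.isnan(X).any():
        med = np.nanmedian(X, axis=0)
        X = np.where(np.isnan(X), med, X)
    y = cohort[outcome].to_numpy(dtype=float)
    return permutation_inference(
        X,
        y,
        k_max=config.k_max,
        n_perm=config.n_perm,
        seed=seed_seq,
        alpha=config.alpha,
        predictor_names=predictors,
        reselect_k=config.reselect_k,
    )


def run_step1(cohort: pd.DataFrame, config: PipelineConfig) -> dict[str, PlsrCvResult]:
    """One nested-CV + permutation PLSR per SF-36 subscale (8 models)."""
    registry.check_columns(cohort.columns, need_extero=False)
    if len(cohort) < 10:
        raise ValueError("cohort too small for nested cross-validation (need n >= 10)")
    seeds = _model_seeds(config, "step1")
    predictors = list(registry.STEP1_PREDICTORS)
    results = {}
    for outcome in registry.OUTCOMES:
        log.info("step1: fitting %s", outcome)
        results[outcome] = _fit_one(cohort, outcome, predictors, config, seeds[outcome])
    return results


def significant_outcomes(step1: dict[str, PlsrCvResult], config: PipelineConfig) -> list[str]:
    a = _model_alpha(config)
    return [o for o, res in step1.items() if res.p_perm < a]


def select_retained_predictors(
    step1: dict[str, PlsrCvResult], config: PipelineConfig
) -> list[str]:
    """Union over significant step-1 models of their significant-weight predictors."""
    sig_outcomes = significant_outcomes(step1, config)
    retained: set[str] = set()
    for o in sig_outcomes:
        retained.update(step1[o].significant_predictors())
    # keep the canonical registry order
    return [p for p in registry.STEP1_PREDICTORS if p in retained]


def run_step2(
    cohort: pd.DataFrame,
    retained: list[str],
    outcomes: list[str],
    config: PipelineConfig,
    step1: dict[str, PlsrCvResult] | None = None,
) -> dict[str, PlsrCvResult]:
    """Refit each significant outcome on retained + exteroceptive predictors."""
    if not retained and config.retention == "union":
        raise ValueError("retained predictor set is empty; nothing to combine in step 2")
    registry.check_columns(cohort.columns, need_extero=True)
    seeds = _model_seeds(config, "step2")
    results = {}
    for outcome in outcomes:
        if config.retention == "per_model":
            base = step1[outcome].significant_predictors() if step1 else retained
            keep = [p for p in registry.STEP1_PREDICTORS if p in set(base)]
        else:
            keep = list(retained)
        predictors = keep + list(registry.STEP2_EXTERO)
        log.info("step2: fitting %s with %d predictors", outcome, len(predictors))
        results[outcome] = _fit_one(cohort, outcome, predictors, config, seeds[outcome])
    return results


# --------------------------------------------------------------------------- #
# Report
# --------------------------------------------------------------------------- #

@dataclass
class TwoStepReport:
    config: PipelineConfig
    step1: dict  # outcome -> PlsrCvResult
    significant_outcomes: list
    retained_predictors: list
    step2: dict  # outcome -> PlsrCvResult (subset of significant outcomes)

    def __post_init__(self):
        extra = set(self.step2) - set(self.significant_outcomes)
        if extra:
            raise ValueError(f"step2 contains non-significant outcomes: {sorted(extra)}")

    @property
    def early_exit(self) -> bool:
        return not self.step2

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "step1": {o: _result_to_dict(r) for o, r in self.step1.items()},
            "significant_outcomes": list(self.significant_outcomes),
            "retained_predictors": list(self.retained_predictors),
            "step2": {o: _result_to_dict(r) for o, r in self.step2.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStepReport":
        return cls(
            config=PipelineConfig(**d["config"]),
            step1={o: _result_from_dict(r) for o, r in d["step1"].items()},
            significant_outcomes=list(d["significant_outcomes"]),
            retained_predictors=list(d["retained_predictors"]),
            step2={o: _result_from_dict(r) for o, r in d["step2"].items()},
        )

    def summary_table(self) -> str:
        """Human-readable outcome x dimension-class table of significant predictors."""
        if self.early_exit:
            return "no significant step-1 models; step 2 not run\n"
        roles = ("exteroceptive", "physiological", "interoceptive")
        header = ["dimension"] + [
            registry.REGISTRY[o].label or o for o in self.step2
        ]
        rows = [header]
        for role in roles:
            row = [role]
            members = set(registry.variables(role))
            for o in self.step2:
                sig = [p for p in self.step2[o].significant_predictors() if p in members]
                row.append(", ".join(sig) if sig else "-")
            rows.append(row)
        return "\n".join("\t".join(r) for r in rows) + "\n"


def _result_to_dict(res: PlsrCvResult) -> dict:
    def arr(a):
        return None if a is None else np.asarray(a).tolist()

    return {
        "predictions": arr(res.predictions),
        "chosen_k": arr(res.chosen_k),
        "modal_k": int(res.modal_k),
        "r": float(res.r),
        "p_perm": float(res.p_perm),
        "weights": arr(res.weights),
        "null_lo": arr(res.null_lo),
        "null_hi": arr(res.null_hi),
        "significant": arr(res.significant),
        "predictor_names": res.predictor_names,
    }


def _result_from_dict(d: dict) -> PlsrCvResult:
    def arr(x, dtype=float):
        return None if x is None else np.asarray(x, dtype=dtype)

    return PlsrCvResult(
        predictions=arr(d["predictions"]),
        chosen_k=arr(d["chosen_k"], int),
        modal_k=int(d["modal_k"]),
        r=float(d["r"]),
        p_perm=float(d["p_perm"]),
        weights=arr(d["weights"]),
        null_lo=arr(d["null_lo"]),
        null_hi=arr(d["null_hi"]),
        significant=arr(d["significant"], bool),
        predictor_names=d.get("predictor_names"),
    )


def run_two_step(cohort: pd.DataFrame, config: PipelineConfig) -> TwoStepReport:
    """End to end: step 1, retention, step 2 (or a clean early exit)."""
    step1 = run_step1(cohort, config)
    sig = significant_outcomes(step1, config)
    retained = select_retained_predictors(step1, config)
    if not sig or not retained:
        log.info("no significant step-1 models (or empty retained set): early exit")
        return TwoStepReport(config, step1, sig, retained, {})
    step2 = run_step2(cohort, retained, sig, config, step1)
    return TwoStepReport(config, step1, sig, retained, step2)


def write_report(report: TwoStepReport, path) -> dict[str, Path]:
    """Write ``report.json`` (machine) and ``summary.tsv`` (human) under *path*."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    json_path = path / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2))
    tsv_path = path / "summary.tsv"
    tsv_path.write_text(report.summary_table())
    return {"json": json_path, "summary": tsv_path}


def read_report(path) -> TwoStepReport:
    return TwoStepReport.from_dict(json.loads((Path(path) / "report.json").read_text()))
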