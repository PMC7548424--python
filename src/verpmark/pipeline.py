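"""Two-cohort orchestration: develop biomarkers + thresholds on cohort 1,
freeze them, validate on cohort 2.

All stage constants default to the canonical analysis values and are
carried in :class:`RunConfig`. A single master seed feeds simulation,
cross-validation and bootstrap resampling through fixed offsets, so a full
develop + validate run is deterministic end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .classification import (
    DEFAULT_COST_GRID,
    LinearBiomarkerModel,
    ThresholdRule,
    classify,
    svmp1_score,
    train_linear_svm,
)
from .data import VERP
from .evaluation import (
    bootstrap_auc_test,
    cohens_kappa,
    confusion_metrics,
    delong_ci,
    logistic_confound_model,
    ols_group_model,
    roc_curve,
    youden_threshold,
)
from .features import extract_features, has_p1, individual_p1_latency
from .io import artifact_hash
from .montage import Montage, standard_montage
from .preprocessing import preprocess_epochs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "cohort_features", "develop", "validate",
           "run_develop", "run_validate"]


@dataclass
class RunConfig:
    """Run parameters; numeric defaults are the canonical analysis constants."""

    seed: int = 0
    group_mode: str = "all"  # "all": CC vs DC+Control; "ccdc": CC vs DC
    lowpass_hz: float = 40.0
    apply_notch: bool = False
    notch_hz: float = 50.0
    ocular_window_ms: tuple = (-25.0, 175.0)
    blink_k: float = 5.0
    eye_k: float = 3.0
    response_window_ms: float = 500.0
    fixed_window_ms: tuple = (120.0, 170.0)
    cost_grid: Sequence[float] = DEFAULT_COST_GRID
    cv_folds: int = 5
    n_boot: int = 2000
    scaled: bool = False  # use the scaled-down simulation presets

    def design(self, cohort: str) -> synthetic.CohortDesign:
        if self.scaled:
            return synthetic.fast_design(cohort)
        return {"exp1": synthetic.exp1_design,
                "exp2": synthetic.exp2_design}[cohort]()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cost_grid"] = list(self.cost_grid)
        return d


def cohort_features(cohort, config: RunConfig,
                    montage: Optional[Montage] = None) -> pd.DataFrame:
    """Preprocess every participant and extract upper-field P1 features.

    Upper-field VERPs alone feed the biomarkers; lower-field VERPs are kept
    in the table metadata only through the latency/absent-P1 bookkeeping.
    """
    if montage is None:
        montage = standard_montage()
    rows = []
    for meta, epochs, ocular in cohort:
        verp_upper, verp_lower, counts = preprocess_epochs(
            epochs, ocular,
            responds_manually=meta.responds_manually,
            lowpass_hz=config.lowpass_hz,
            apply_notch=config.apply_notch,
            notch_hz=config.notch_hz,
            ocular_window_ms=config.ocular_window_ms,
            blink_k=config.blink_k,
            eye_k=config.eye_k,
            response_window_ms=config.response_window_ms,
        )
        feats = extract_features(verp_upper, montage,
                                 window_ms=config.fixed_window_ms)
        lat_lo, elec_lo = individual_p1_latency(verp_lower, montage)
        p1_present = has_p1(
            verp_upper, verp_lower, feats.latency_ms, lat_lo, montage,
            latency_electrode_upper=feats.latency_electrode,
            latency_electrode_lower=elec_lo,
        )
        row = {
            "pid": meta.pid,
            "group": meta.group,
            "age_years": meta.age_years,
            "age_at_surgery_months": meta.age_at_surgery_months,
            "time_since_surgery_months": meta.time_since_surgery_months,
            "latency_ms": feats.latency_ms if p1_present else np.nan,
            "latency_lower_ms": lat_lo if p1_present else np.nan,
            "has_p1": p1_present,
            "mpp1": feats.mpp1,
            "kept_upper": counts["kept_upper"],
            "kept_lower": counts["kept_lower"],
        }
        for name, z in zip(montage.names, feats.z_scores):
            row[f"z_{name}"] = z
        rows.append(row)
    return pd.DataFrame(rows)


def _posterior_matrix(table: pd.DataFrame, montage: Montage) -> np.ndarray:
    cols = [f"z_{name}" for name in montage.posterior]
    return table[cols].to_numpy(dtype=float)


def _subset(table: pd.DataFrame, group_mode: str) -> pd.DataFrame:
    if group_mode == "all":
        return table
    if group_mode == "ccdc":
        return table[table["group"].isin(["CC", "DC"])].reset_index(drop=True)
    raise ValueError(f"unknown group mode {group_mode!r}")


def _biomarker_eval(scores: np.ndarray, is_cc: np.ndarray, rule: ThresholdRule,
                    pids) -> dict:
    auc, lo, hi, se = delong_ci(scores, is_cc)
    predictions = np.array([classify(s, rule) == "CC" for s in scores])
    report = confusion_metrics(is_cc, predictions)
    return {
        "auc": auc,
        "auc_ci": [lo, hi],
        "threshold": rule.threshold,
        "counts": {"tp": report.tp, "fn": report.fn,
                   "tn": report.tn, "fp": report.fp},
        "metrics": report.as_row(),
        "predictions": {pid: bool(p) for pid, p in zip(pids, predictions)},
    }


def develop(table: pd.DataFrame, config: RunConfig,
            montage: Optional[Montage] = None,
            cohort_label: str = "exp1") -> dict:
    """Train the SVMP1 model and freeze Youden thresholds for both biomarkers."""
    if montage is None:
        montage = standard_montage()
    sub = _subset(table, config.group_mode)
    is_cc = (sub["group"] == "CC").to_numpy()
    X = _posterior_matrix(sub, montage)
    pids = sub["pid"].tolist()

    model = train_linear_svm(
        X, is_cc, cost_grid=config.cost_grid, electrodes=montage.posterior,
        cv_folds=config.cv_folds, seed=config.seed + 101,
        training_cohort=cohort_label,
    )
    scores = {
        "mpp1": sub["mpp1"].to_numpy(dtype=float),
        "svmp1": svmp1_score(model, X),
    }
    thresholds, evals = {}, {}
    for name, s in scores.items():
        roc = roc_curve(s, is_cc)
        rule = youden_threshold(roc, biomarker=name,
                                source_cohort=cohort_label)
        thresholds[name] = rule
        evals[name] = _biomarker_eval(s, is_cc, rule, pids)

    d_stat, p_boot = bootstrap_auc_test(
        scores["svmp1"], scores["mpp1"], is_cc,
        n_boot=config.n_boot, seed=config.seed + 202,
    )

    report = {
        "cohort": cohort_label,
        "group_mode": config.group_mode,
        "n": int(len(sub)),
        "biomarkers": evals,
        "auc_comparison": {"d": d_stat, "p": p_boot,
                           "n_boot": config.n_boot},
        "seed": config.seed,
    }
    if config.group_mode == "all":
        report["group_model"] = ols_group_model(
            table["mpp1"].to_numpy(), table["group"].to_numpy()
        )
    report["confound_models"] = _confound_models(sub, evals)

    artifacts = {
        "model": model.to_dict(),
        "thresholds": {k: v.to_dict() for k, v in thresholds.items()},
        "group_mode": config.group_mode,
        "cohort": cohort_label,
    }
    artifacts["hash"] = artifact_hash(
        {k: artifacts[k] for k in ("model", "thresholds", "group_mode")}
    )
    return {"artifacts": artifacts, "report": report}


def _confound_models(sub: pd.DataFrame, evals: dict) -> dict:
    """Logistic models of classification success on surgery covariates."""
    patients = sub[sub["group"].isin(["CC", "DC"])]
    out = {}
    for name, ev in evals.items():
        correct = np.array(
            [
                ev["predictions"][pid] == (grp == "CC")
                for pid, grp in zip(patients["pid"], patients["group"])
            ],
            dtype=float,
        )
        out[name] = logistic_confound_model(
            correct,
            patients["age_at_surgery_months"].to_numpy(dtype=float),
            patients["time_since_surgery_months"].to_numpy(dtype=float),
        )
    return out


def validate(table: pd.DataFrame, artifacts: dict, config: RunConfig,
             montage: Optional[Montage] = None,
             cohort_label: str = "exp2",
             dev_predictions: Optional[dict] = None,
             restrict_pids: Optional[Sequence[str]] = None) -> dict:
    """Score a held-out cohort with frozen weights and thresholds.

    No refitting occurs: the artifact hash is carried into the report so a
    validation run can always be traced to its development artifacts.
    ``restrict_pids`` reproduces new-participants-only analyses;
    ``dev_predictions`` (pid -> bool) enables inter-experiment agreement.
    """
    if montage is None:
        montage = standard_montage()
    sub = _subset(table, artifacts["group_mode"])
    if restrict_pids is not None:
        keep = sub["pid"].isin(list(restrict_pids)) | (sub["group"] == "Control")
        sub = sub[keep].reset_index(drop=True)
    is_cc = (sub["group"] == "CC").to_numpy()
    X = _posterior_matrix(sub, montage)
    pids = sub["pid"].tolist()

    model = LinearBiomarkerModel.from_dict(artifacts["model"])
    thresholds = {k: ThresholdRule.from_dict(v)
                  for k, v in artifacts["thresholds"].items()}
    scores = {
        "mpp1": sub["mpp1"].to_numpy(dtype=float),
        "svmp1": svmp1_score(model, X),
    }
    evals = {
        name: _biomarker_eval(s, is_cc, thresholds[name], pids)
        for name, s in scores.items()
    }
    d_stat, p_boot = bootstrap_auc_test(
        scores["svmp1"], scores["mpp1"], is_cc,
        n_boot=config.n_boot, seed=config.seed + 303,
    )
    report = {
        "cohort": cohort_label,
        "group_mode": artifacts["group_mode"],
        "n": int(len(sub)),
        "artifact_hash": artifacts["hash"],
        "biomarkers": evals,
        "auc_comparison": {"d": d_stat, "p": p_boot,
                           "n_boot": config.n_boot},
        "seed": config.seed,
    }
    if artifacts["group_mode"] == "all" and \
            set(sub["group"]) == {"CC", "DC", "Control"}:
        report["group_model"] = ols_group_model(
            sub["mpp1"].to_numpy(), sub["group"].to_numpy()
        )
    report["confound_models"] = _confound_models(sub, evals)

    if dev_predictions:
        agreement = {}
        for name, ev in evals.items():
            shared = sorted(set(ev["predictions"]) & set(dev_predictions))
            if shared:
                agreement[name] = {
                    "n_shared": len(shared),
                    "kappa": cohens_kappa(
                        [dev_predictions[p] for p in shared],
                        [ev["predictions"][p] for p in shared],
                    ),
                }
        if agreement:
            report["agreement"] = agreement
    return report


def run_develop(config: RunConfig, cohort=None) -> dict:
    """Simulate (or accept) cohort 1, preprocess, extract features, develop."""
    if cohort is None:
        cohort = synthetic.simulate_cohort(config.design("exp1"),
                                           seed=config.seed)
    table = cohort_features(cohort, config)
    out = develop(table, config, cohort_label="exp1")
    out["features"] = table
    return out


def run_validate(config: RunConfig, artifacts: dict, cohort=None,
                 **kwargs) -> dict:
    """Simulate (or accept) cohort 2 and score it with frozen artifacts."""
    if cohort is None:
        cohort = synthetic.simulate_cohort(config.design("exp2"),
                                           seed=config.seed + 1)
    table = cohort_features(cohort, config)
    report = validate(table, artifacts, config, cohort_label="exp2", **kwargs)
    return {"report": report, "features": table}
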