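"""Inferential machinery: ROC/Youden, DeLong CIs, bootstrap AUC comparison,
confusion metrics and likelihood ratios, Cohen's kappa, the spatiotemporal
cluster permutation test, and the group / confound regressions.

Score orientation: the positive class is CC throughout and, unless stated
otherwise, LOWER scores are more CC-like (``cc_low=True``), matching the
classification module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import ThresholdRule

__all__ = [
    "ROCResult",
    "ConfusionReport",
    "ClusterTestResult",
    "roc_curve",
    "youden_threshold",
    "delong_ci",
    "bootstrap_auc_test",
    "confusion_metrics",
    "likelihood_ratios_from_rates",
    "round_half_up",
    "cohens_kappa",
    "cluster_permutation_test",
    "ols_group_model",
    "logistic_confound_model",
]


# --------------------------------------------------------------------------
# ROC machinery
# --------------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray  # sorted unique scores
    sensitivity: np.ndarray  # per threshold
    specificity: np.ndarray
    auc: float
    cc_low: bool = True
    positive_class: str = "CC"
    ci: Optional[tuple] = None  # (level, low, high)


def _check_binary(scores: np.ndarray, is_cc: np.ndarray) -> tuple:
    scores = np.asarray(scores, dtype=float)
    is_cc = np.asarray(is_cc, dtype=bool)
    if scores.shape != is_cc.shape:
        raise ValueError("scores and labels must align")
    if is_cc.all() or not is_cc.any():
        raise ValueError("both classes must be present")
    return scores, is_cc


def _auc_mann_whitney(cases: np.ndarray, noncases: np.ndarray,
                      cc_low: bool) -> float:
    """AUC as the tie-adjusted concordance probability (U / n1*n0)."""
    diff = noncases[None, :] - cases[:, None]
    if not cc_low:
        diff = -diff
    return float(
        ((diff > 0).sum() + 0.5 * (diff == 0).sum())
        / (cases.size * noncases.size)
    )


def roc_curve(scores, is_cc, cc_low: bool = True) -> ROCResult:
    """Empirical ROC over all distinct score thresholds.

    With ``cc_low`` a score <= threshold predicts CC, so sensitivity rises
    with the threshold while specificity falls. AUC equals the Mann-Whitney
    statistic with ties counted 1/2.
    """
    scores, is_cc = _check_binary(scores, is_cc)
    thresholds = np.unique(scores)
    cases, noncases = scores[is_cc], scores[~is_cc]
    if cc_low:
        sens = (cases[None, :] <= thresholds[:, None]).mean(axis=1)
        spec = (noncases[None, :] > thresholds[:, None]).mean(axis=1)
    else:
        sens = (cases[None, :] >= thresholds[:, None]).mean(axis=1)
        spec = (noncases[None, :] < thresholds[:, None]).mean(axis=1)
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=_auc_mann_whitney(cases, noncases, cc_low), cc_low=cc_low,
    )


def youden_threshold(roc: ROCResult, biomarker: str = "",
                     source_cohort: str = "") -> ThresholdRule:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties resolve to the threshold with the higher specificity (and, if
    still tied, the more extreme threshold on the CC side).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.lexsort((roc.specificity, j))[-1]
    ties = np.flatnonzero(
        np.isclose(j, j[best]) & np.isclose(roc.specificity,
                                            roc.specificity[best])
    )
    idx = ties[0] if roc.cc_low else ties[-1]
    return ThresholdRule(
        biomarker=biomarker, threshold=float(roc.thresholds[idx]),
        cc_low=roc.cc_low, source_cohort=source_cohort,
    )


# --------------------------------------------------------------------------
# DeLong variance / CI
# --------------------------------------------------------------------------

def _delong_placements(cases: np.ndarray, noncases: np.ndarray) -> tuple:
    """Placement values under the cases-high convention (ties get 1/2)."""
    psi = (
        (cases[:, None] > noncases[None, :]).astype(float)
        + 0.5 * (cases[:, None] == noncases[None, :])
    )
    v10 = psi.mean(axis=1)  # per case
    v01 = psi.mean(axis=0)  # per noncase
    return v10, v01


def delong_ci(scores, is_cc, level: float = 0.95,
              cc_low: bool = True) -> tuple:
    """DeLong AUC confidence interval: (auc, low, high, se).

    Perfect separation yields a degenerate zero-width interval with a
    warning. The interval is truncated to [0, 1].
    """
    scores, is_cc = _check_binary(scores, is_cc)
    if min(is_cc.sum(), (~is_cc).sum()) < 2:
        raise ValueError("need at least 2 participants per class")
    oriented = -scores if cc_low else scores
    cases, noncases = oriented[is_cc], oriented[~is_cc]
    v10, v01 = _delong_placements(cases, noncases)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / cases.size + v01.var(ddof=1) / noncases.size
    se = float(np.sqrt(var))
    if se == 0.0:
        warnings.warn("degenerate AUC variance (perfect separation): "
                      "zero-width CI")
        return auc, auc, auc, 0.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        auc,
        float(max(0.0, auc - z * se)),
        float(min(1.0, auc + z * se)),
        se,
    )


def bootstrap_auc_test(scores_a, scores_b, is_cc, n_boot: int = 2000,
                       seed: int = 0, cc_low: bool = True) -> tuple:
    """Paired stratified-bootstrap comparison of two AUCs on the same sample.

    Cases and non-cases are resampled separately with replacement; both
    AUCs are recomputed on each resample. Returns ``(D, p)`` where
    D = (AUC_a - AUC_b) / SD_boot(delta) and p is two-sided normal.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    scores_a, is_cc = _check_binary(scores_a, is_cc)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_b.shape != scores_a.shape:
        raise ValueError("paired score vectors must align")
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(is_cc)
    non_idx = np.flatnonzero(~is_cc)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        ci = rng.choice(case_idx, size=case_idx.size, replace=True)
        ni = rng.choice(non_idx, size=non_idx.size, replace=True)
        auc_a = _auc_mann_whitney(scores_a[ci], scores_a[ni], cc_low)
        auc_b = _auc_mann_whitney(scores_b[ci], scores_b[ni], cc_low)
        deltas[b] = auc_a - auc_b
    observed = (
        _auc_mann_whitney(scores_a[case_idx], scores_a[non_idx], cc_low)
        - _auc_mann_whitney(scores_b[case_idx], scores_b[non_idx], cc_low)
    )
    sd = deltas.std(ddof=1)
    if sd == 0.0:
        return 0.0, 1.0
    d = float(observed / sd)
    p = float(2.0 * stats.norm.sf(abs(d)))
    return d, p


# --------------------------------------------------------------------------
# Confusion metrics / agreement
# --------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up, matching printed-table rounding conventions."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionReport:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def lr_positive(self) -> float:
        fpr = 1.0 - self.specificity
        return np.inf if fpr == 0 else self.sensitivity / fpr

    @property
    def lr_negative(self) -> float:
        return (1.0 - self.sensitivity) / self.specificity

    def as_row(self) -> dict:
        """Display rounding: 3 decimals for rates, 2 for likelihood ratios."""
        return {
            "sensitivity": round_half_up(self.sensitivity, 3),
            "specificity": round_half_up(self.specificity, 3),
            "lr_positive": round_half_up(self.lr_positive, 2),
            "lr_negative": round_half_up(self.lr_negative, 2),
            "accuracy": round_half_up(self.accuracy, 3),
        }


def confusion_metrics(is_cc, predicted_cc) -> ConfusionReport:
    """Confusion counts and derived rates for binary CC predictions."""
    y = np.asarray(is_cc, dtype=bool)
    p = np.asarray(predicted_cc, dtype=bool)
    if y.size == 0 or y.shape != p.shape:
        raise ValueError("labels and predictions must be non-empty and align")
    return ConfusionReport(
        tp=int((y & p).sum()), fn=int((y & ~p).sum()),
        tn=int((~y & ~p).sum()), fp=int((~y & p).sum()),
    )


def likelihood_ratios_from_rates(sensitivity, specificity) -> tuple:
    """LR+ and LR- from (possibly printed/rounded) sensitivity & specificity.

    Accepts decimal strings to avoid binary-float artifacts when
    reproducing table values; returns floats.
    """
    sens = Decimal(str(sensitivity))
    spec = Decimal(str(specificity))
    lr_pos = sens / (1 - spec)
    lr_neg = (1 - sens) / spec
    return float(lr_pos), float(lr_neg)


def cohens_kappa(pred_1, pred_2) -> float:
    """Chance-corrected agreement for two aligned binary ratings."""
    a = np.asarray(pred_1, dtype=bool)
    b = np.asarray(pred_2, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("rating vectors must be non-empty and align")
    po = float((a == b).mean())
    pe = float(a.mean() * b.mean() + (1 - a.mean()) * (1 - b.mean()))
    if pe == 1.0:
        warnings.warn("both ratings constant and equal: kappa defined as 1")
        return 1.0
    return (po - pe) / (1.0 - pe)


# --------------------------------------------------------------------------
# Cluster-based permutation test
# --------------------------------------------------------------------------

@dataclass
class ClusterTestResult:
    clusters: list  # dicts: cells [(elec, time)], mass, p
    n_perm: int
    t_threshold: float
    tail: str = "two"
    max_null: np.ndarray = field(default=None, repr=False)

    @property
    def min_p(self) -> float:
        return min((c["p"] for c in self.clusters), default=1.0)


def _find_clusters(mask: np.ndarray, adjacency: np.ndarray) -> list:
    """Connected components over (electrode, time) cells.

    Cells are connected when they share an electrode and are temporally
    adjacent, or share a time sample and their electrodes are spatial
    neighbors.
    """
    n_e, n_t = mask.shape
    visited = np.zeros_like(mask, dtype=bool)
    neighbors = [np.flatnonzero(adjacency[e]) for e in range(n_e)]
    clusters = []
    for e0 in range(n_e):
        for t0 in range(n_t):
            if not mask[e0, t0] or visited[e0, t0]:
                continue
            stack = [(e0, t0)]
            visited[e0, t0] = True
            cells = []
            while stack:
                e, t = stack.pop()
                cells.append((e, t))
                for tt in (t - 1, t + 1):
                    if 0 <= tt < n_t and mask[e, tt] and not visited[e, tt]:
                        visited[e, tt] = True
                        stack.append((e, tt))
                for ee in neighbors[e]:
                    if mask[ee, t] and not visited[ee, t]:
                        visited[ee, t] = True
                        stack.append((ee, t))
            clusters.append(cells)
    return clusters


def _paired_t(diff_flat: np.ndarray, n: int) -> np.ndarray:
    mean = diff_flat.mean(axis=0)
    sd = diff_flat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _signed_cluster_masses(t_map: np.ndarray, threshold: float,
                           adjacency: np.ndarray) -> list:
    out = []
    for sign in (1.0, -1.0):
        mask = sign * t_map > threshold
        for cells in _find_clusters(mask, adjacency):
            mass = float(sum(t_map[c] for c in cells))
            out.append((cells, mass))
    return out


def cluster_permutation_test(
    data_a: np.ndarray,
    data_b: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
) -> ClusterTestResult:
    """Two-tailed paired cluster permutation test over electrode x time cells.

    ``data_a``/``data_b`` are (participants, electrodes, times) paired
    condition arrays (already restricted to the electrode subset and time
    window of interest). Cluster-forming threshold is the two-tailed
    t-quantile at ``cluster_alpha`` with df = n - 1; cluster mass is the
    summed t-value; the null distribution is the maximal absolute cluster
    mass under random within-participant condition sign flips. Monte-Carlo
    p-values use the (1 + exceedances) / (n_perm + 1) convention.
    """
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("paired condition arrays must share shape (n, E, T)")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    diff = a - b
    n_e, n_t = diff.shape[1], diff.shape[2]
    flat = diff.reshape(n, -1)
    t_crit = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, df=n - 1))

    t_obs = _paired_t(flat, n).reshape(n_e, n_t)
    observed = _signed_cluster_masses(t_obs, t_crit, adjacency)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    max_null = np.zeros(n_perm)
    sq_sum = (flat**2).sum(axis=0)
    for p_i in range(n_perm):
        s = signs[p_i]
        mean = (s @ flat) / n
        var = (sq_sum - n * mean**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_map = np.where(var > 0, mean / np.sqrt(var / n), 0.0)
        t_map = t_map.reshape(n_e, n_t)
        masses = [abs(m) for _, m in
                  _signed_cluster_masses(t_map, t_crit, adjacency)]
        max_null[p_i] = max(masses, default=0.0)

    clusters = []
    for cells, mass in observed:
        exceed = int((max_null >= abs(mass)).sum())
        clusters.append(
            {
                "cells": cells,
                "mass": mass,
                "p": (1 + exceed) / (n_perm + 1),
            }
        )
    clusters.sort(key=lambda c: -abs(c["mass"]))
    return ClusterTestResult(
        clusters=clusters, n_perm=n_perm, t_threshold=t_crit,
        max_null=max_null,
    )


# --------------------------------------------------------------------------
# Regression models
# --------------------------------------------------------------------------

def ols_group_model(mpp1, groups) -> dict:
    """Dummy-coded OLS of MPP1 on group with Control as reference.

    Standardized coefficients divide the raw betas by the outcome SD
    (sample SD, ddof=1); this convention is an assumption, documented at
    the call sites that report it.
    """
    import statsmodels.api as sm

    y = np.asarray(mpp1, dtype=float)
    groups = np.asarray(groups)
    present = set(groups.tolist())
    if present != {"CC", "DC", "Control"}:
        raise ValueError("all three groups must be present")
    X = np.column_stack(
        [np.ones_like(y), (groups == "CC").astype(float),
         (groups == "DC").astype(float)]
    )
    fit = sm.OLS(y, X).fit()
    sd_y = y.std(ddof=1)
    return {
        "intercept": float(fit.params[0]),
        "beta_cc": float(fit.params[1]),
        "beta_dc": float(fit.params[2]),
        "se_cc": float(fit.bse[1]),
        "se_dc": float(fit.bse[2]),
        "p_cc": float(fit.pvalues[1]),
        "p_dc": float(fit.pvalues[2]),
        "std_beta_cc": float(fit.params[1] / sd_y),
        "std_beta_dc": float(fit.params[2] / sd_y),
        "adj_r2": float(fit.rsquared_adj),
        "f_stat": float(fit.fvalue),
        "f_pvalue": float(fit.f_pvalue),
        "n": int(y.size),
    }


def logistic_confound_model(correct, age_at_surgery_months,
                            time_since_surgery_months) -> dict:
    """Logit of classification success on standardized surgery covariates.

    Predictors are centred and scaled (ddof=1) so the intercept is the
    log-odds of correct classification at the mean age at surgery and mean
    recovery time. Perfect separation (including an all-constant outcome)
    is flagged and falls back to a ridge-penalized fit.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(correct, dtype=float)
    covs = []
    for v in (age_at_surgery_months, time_since_surgery_months):
        v = np.asarray(v, dtype=float)
        sd = v.std(ddof=1)
        covs.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
    X = np.column_stack([np.ones_like(y)] + covs)
    names = ("intercept", "age_at_surgery", "time_since_surgery")

    separated = bool(y.min() == y.max())
    fit = None
    if not separated:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                fit = sm.Logit(y, X).fit(disp=0)
            if np.any(np.abs(fit.params) > 15):
                separated = True
        except (PerfectSeparationError, Warning, np.linalg.LinAlgError):
            separated = True
    if separated or fit is None:
        # ridge fallback keeps estimates finite under separation
        fit = sm.Logit(y, X).fit_regularized(
            method="l1", alpha=1e-4, disp=0, trim_mode="off"
        ) if 0 < y.mean() < 1 else None
    if fit is None:
        return {
            "separated": True,
            "params": {n: np.nan for n in names},
            "se": {n: np.nan for n in names},
            "p": {n: np.nan for n in names},
        }
    params = np.asarray(fit.params, dtype=float)
    try:
        ses = np.asarray(fit.bse, dtype=float)
        ps = np.asarray(fit.pvalues, dtype=float)
    except Exception:
        ses = np.full(3, np.nan)
        ps = np.full(3, np.nan)
    return {
        "separated": separated,
        "params": dict(zip(names, params)),
        "se": dict(zip(names, ses)),
        "p": dict(zip(names, ps)),
    }
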