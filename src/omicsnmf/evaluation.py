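"""Downstream quality assessment of completed omics matrices.

Two complementary views of imputation quality are provided:

* reconstruction — mean squared error on validation or held-out rows;
* utility — does the completed matrix still support the analyses one would
  run on fully observed data?  Implemented as random-forest phenotype
  classification (stratified cross-validation over all samples, and a
  stricter train-on-observed / test-on-imputed protocol) and elastic-net Cox
  survival modeling with prognostic-index risk stratification and a log-rank
  test between the median-split risk groups.

Baselines (k-nearest-neighbour cross-omics transfer, per-feature linear
regression, column means) complete the same matrix so methods can be
compared split-for-split; `compare_methods` runs paired Wilcoxon signed-rank
tests with Holm correction across splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import wilcoxon
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv
from statsmodels.stats.multitest import multipletests

from .io import PairedOmicsDataset, SplitPlan
from .training import CompletedMatrix

__all__ = [
    "PhenotypeLabels",
    "SurvivalData",
    "CoxConfig",
    "EvalReport",
    "validation_mse",
    "overall_auc",
    "test_set_auc",
    "cox_fit",
    "prognostic_index",
    "median_risk_split",
    "logrank_pvalue",
    "kaplan_meier_plot",
    "baseline_knn_impute",
    "baseline_regression_impute",
    "baseline_mean_impute",
    "compare_methods",
]


@dataclass
class PhenotypeLabels:
    """Binary phenotype labels keyed by sample ID."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.sample_ids) != len(self.labels):
            raise ValueError("one label per sample required")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"labels must be binary, got classes {classes}")
        if counts.min() < 2:
            raise ValueError("need at least 2 samples per class")

    def subset(self, ids: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise ValueError(f"unlabeled samples: {missing}")
        return self.labels[[index[i] for i in ids]]

    @property
    def labeled_set(self) -> set[str]:
        return set(self.sample_ids)


@dataclass
class SurvivalData:
    """Right-censored survival outcomes keyed by sample ID."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    endpoint: str = "overall_survival"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.event = np.asarray(self.event)
        if (self.time < 0).any():
            raise ValueError("survival times must be >= 0")
        if not set(np.unique(self.event)) <= {0, 1, False, True}:
            raise ValueError("event indicators must be binary")
        self.event = self.event.astype(bool)

    def subset(self, ids: Sequence[str]) -> "SurvivalData":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[i] for i in ids]
        return SurvivalData(list(ids), self.time[rows], self.event[rows], self.endpoint)

    def to_structured(self) -> np.ndarray:
        return Surv.from_arrays(event=self.event, time=self.time)


@dataclass
class CoxConfig:
    """Elastic-net Cox settings: penalty weight and L1/L2 mixing ratio.

    ``shrinkage=None`` selects the penalty by 3-fold cross-validated
    concordance over a logarithmic path.
    """

    shrinkage: float | None = None
    l1_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ValueError("l1_ratio must lie in [0, 1]")
        if self.shrinkage is not None and self.shrinkage < 0:
            raise ValueError("shrinkage must be >= 0")


@dataclass
class EvalReport:
    """Aggregate of the downstream metrics for one (or many) splits."""

    overall_auc: dict[str, float] = field(default_factory=dict)
    test_set_auc: dict[str, float] = field(default_factory=dict)
    validation_mse: float | None = None
    logrank_p: dict[str, float] = field(default_factory=dict)
    per_split: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        import json

        d = {
            "overall_auc": self.overall_auc,
            "test_set_auc": self.test_set_auc,
            "validation_mse": self.validation_mse,
            "logrank_p": self.logrank_p,
        }
        Path(path).write_text(json.dumps(d, indent=1))


def validation_mse(generated: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared elementwise difference between matching row blocks."""
    generated = np.asarray(generated, float)
    truth = np.asarray(truth, float)
    if generated.shape != truth.shape:
        raise ValueError(f"shape mismatch: {generated.shape} vs {truth.shape}")
    return float(np.mean((generated - truth) ** 2))


def _rf(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=100, random_state=seed)


def overall_auc(
    cm: CompletedMatrix,
    labels: PhenotypeLabels,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean out-of-fold AUC of a random forest over ALL labeled samples.

    Observed and imputed rows are pooled, mirroring the use case where the
    completed matrix replaces the incomplete one for downstream modeling.
    """
    ids = [s for s in cm.sample_ids if s in labels.labeled_set]
    X = cm.rows(ids)
    y = labels.subset(ids)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} samples per class for {folds}-fold CV")
    pos = classes[1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        clf = _rf(seed).fit(X[tr], y[tr])
        proba = clf.predict_proba(X[te])[:, list(clf.classes_).index(pos)]
        aucs.append(roc_auc_score(y[te] == pos, proba))
    return float(np.mean(aucs))


def test_set_auc(
    cm: CompletedMatrix,
    labels: PhenotypeLabels,
    plan: SplitPlan,
    seed: int = 0,
) -> float:
    """AUC on imputed rows only, classifier trained on observed rows.

    The strictest protocol: the forest never sees an imputed profile during
    training, so the score measures whether imputation preserved the
    phenotype signal of samples that were genuinely missing.
    """
    observed = [s for s in plan.observed_ids if s in labels.labeled_set]
    imputed = [s for s in plan.missing_ids if s in labels.labeled_set]
    if not imputed:
        raise ValueError("no labeled imputed samples to evaluate")
    y_test = labels.subset(imputed)
    if len(np.unique(y_test)) < 2:
        raise ValueError(
            "imputed samples all belong to one class; AUC is undefined"
        )
    X_train = cm.rows(observed)
    y_train = labels.subset(observed)
    clf = _rf(seed).fit(X_train, y_train)
    pos = np.unique(y_train)[1]
    proba = clf.predict_proba(cm.rows(imputed))[:, list(clf.classes_).index(pos)]
    return float(roc_auc_score(y_test == pos, proba))


def cox_fit(Y: np.ndarray, surv: SurvivalData, cfg: CoxConfig | None = None) -> np.ndarray:
    """Fit an elastic-net penalized Cox model; returns the coefficient vector.

    The penalty is ``shrinkage * (r * sum|b_i| + (1-r)/2 * sum b_i^2)`` added
    to the negative log partial likelihood.  ``l1_ratio=0`` falls back to a
    ridge-penalized Cox fit, ``l1_ratio=1`` is the lasso.
    """
    cfg = cfg or CoxConfig()
    Y = np.asarray(Y, float)
    if Y.shape[0] != len(surv.sample_ids):
        raise ValueError("matrix rows must match survival records")
    if surv.event.sum() < 2:
        raise ValueError("need at least 2 observed events to fit a Cox model")
    y = surv.to_structured()
    if cfg.l1_ratio == 0.0:
        model = CoxPHSurvivalAnalysis(alpha=cfg.shrinkage if cfg.shrinkage else 1e-4)
        model.fit(Y, y)
        return np.asarray(model.coef_, float)
    if cfg.shrinkage is not None:
        model = CoxnetSurvivalAnalysis(
            l1_ratio=cfg.l1_ratio, alphas=[max(cfg.shrinkage, 1e-12)],
            fit_baseline_model=False,
        )
        model.fit(Y, y)
        return np.asarray(model.coef_[:, 0], float)
    # CV over a logarithmic path, selected by 3-fold concordance
    path_model = CoxnetSurvivalAnalysis(l1_ratio=cfg.l1_ratio, n_alphas=20)
    path_model.fit(Y, y)
    alphas = path_model.alphas_
    from sklearn.model_selection import KFold

    best_alpha, best_score = alphas[0], -np.inf
    kf = KFold(n_splits=3, shuffle=True, random_state=0)
    for a in alphas:
        scores = []
        for tr, te in kf.split(Y):
            if surv.event[tr].sum() < 2 or surv.event[te].sum() < 1:
                continue
            m = CoxnetSurvivalAnalysis(
                l1_ratio=cfg.l1_ratio, alphas=[a], fit_baseline_model=False
            )
            try:
                m.fit(Y[tr], y[tr])
                scores.append(m.score(Y[te], y[te]))
            except (ValueError, ArithmeticError):
                continue
        if scores and np.mean(scores) > best_score:
            best_score = float(np.mean(scores))
            best_alpha = a
    model = CoxnetSurvivalAnalysis(
        l1_ratio=cfg.l1_ratio, alphas=[best_alpha], fit_baseline_model=False
    )
    model.fit(Y, y)
    return np.asarray(model.coef_[:, 0], float)


def prognostic_index(beta: np.ndarray, Y_test: np.ndarray) -> np.ndarray:
    """Linear Cox risk score ``PI = beta . x`` per sample; higher = riskier."""
    beta = np.asarray(beta, float)
    Y_test = np.atleast_2d(np.asarray(Y_test, float))
    if Y_test.shape[1] != beta.shape[0]:
        raise ValueError(
            f"feature mismatch: {Y_test.shape[1]} columns vs {beta.shape[0]} coefficients"
        )
    return Y_test @ beta


def median_risk_split(scores: np.ndarray) -> dict[str, np.ndarray]:
    """Median split into equally sized low/high risk groups.

    Ties at the median go to the low-risk group in stable input order, so the
    group sizes always differ by at most one.
    """
    scores = np.asarray(scores, float)
    n = scores.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if np.all(scores == scores[0]):
        warnings.warn(
            "all risk scores identical; splitting by stable order",
            RuntimeWarning,
            stacklevel=2,
        )
    order = np.argsort(scores, kind="stable")
    n_low = (n + 1) // 2
    return {"low": np.sort(order[:n_low]), "high": np.sort(order[n_low:])}


def logrank_pvalue(groups: Mapping[str, np.ndarray], surv: SurvivalData) -> float:
    """Two-group log-rank test p-value on row indices into ``surv``."""
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (ga, gb) = (np.asarray(g, int) for g in groups.values())
    if ga.size == 0 or gb.size == 0:
        raise ValueError("both groups must be non-empty")
    if surv.event[ga].sum() + surv.event[gb].sum() < 1:
        raise ValueError("log-rank test requires at least one observed event")
    res = logrank_test(
        surv.time[ga], surv.time[gb],
        event_observed_A=surv.event[ga], event_observed_B=surv.event[gb],
    )
    return float(res.p_value)


def kaplan_meier_plot(
    groups: Mapping[str, np.ndarray], surv: SurvivalData, path: str | Path
) -> None:
    """Kaplan–Meier curves per risk group, annotated with the log-rank p."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, idx in groups.items():
        idx = np.asarray(idx, int)
        km = KaplanMeierFitter()
        km.fit(surv.time[idx], surv.event[idx], label=f"{name} (n={idx.size})")
        km.plot_survival_function(ax=ax)
    p = logrank_pvalue(groups, surv)
    ax.set_xlabel(f"time ({surv.endpoint})")
    ax.set_ylabel("survival probability")
    ax.set_title(f"log-rank p = {p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _completed_from(ds: PairedOmicsDataset, imputed_rows: np.ndarray) -> CompletedMatrix:
    values = np.empty((ds.n, ds.target.n_features))
    provenance = []
    tgt_index = {s: i for i, s in enumerate(ds.target.sample_ids)}
    miss_index = {s: i for i, s in enumerate(ds.missing_ids)}
    for i, s in enumerate(ds.source.sample_ids):
        if s in miss_index:
            values[i] = imputed_rows[miss_index[s]]
            provenance.append("imputed")
        else:
            values[i] = ds.target.values[tgt_index[s]]
            provenance.append("observed")
    return CompletedMatrix(
        values, list(ds.source.sample_ids), list(ds.target.feature_ids), provenance
    )


def baseline_knn_impute(ds: PairedOmicsDataset, k_neighbors: int) -> CompletedMatrix:
    """Cross-omics k-nearest-neighbour transfer.

    Neighbours of each missing sample are found among observed samples in
    SOURCE space (Euclidean); its target row is the inverse-distance-weighted
    mean of the neighbours' TARGET rows.  Exact matches (distance 0) are
    averaged uniformly.
    """
    if not 1 <= k_neighbors <= ds.m:
        raise ValueError(f"k_neighbors must lie in [1, m={ds.m}]")
    X_obs = ds.source_rows(ds.observed_ids)
    Y_obs = ds.target.values
    imputed = np.zeros((ds.k, ds.target.n_features))
    if ds.k:
        X_miss = ds.source_rows(ds.missing_ids)
        for i in range(ds.k):
            d = np.linalg.norm(X_obs - X_miss[i], axis=1)
            nn = np.argsort(d, kind="stable")[:k_neighbors]
            dn = d[nn]
            if (dn == 0).any():
                w = (dn == 0).astype(float)
            else:
                w = 1.0 / dn
            w /= w.sum()
            imputed[i] = w @ Y_obs[nn]
    return _completed_from(ds, imputed)


def baseline_regression_impute(
    ds: PairedOmicsDataset, plan: SplitPlan
) -> CompletedMatrix:
    """Per-target-feature ordinary least squares on the source features.

    Fit on the training split only; predictions for missing samples are
    clipped at zero to preserve the non-negativity the NMF pipeline needs.
    Falls back to ridge when there are more source features than training
    samples.
    """
    if len(plan.train_ids) < 2:
        raise ValueError("need at least 2 training samples")
    X_train = ds.source_rows(plan.train_ids)
    Y_train = ds.target_rows(plan.train_ids)
    if ds.source.n_features > X_train.shape[0]:
        warnings.warn(
            "more source features than training samples; using ridge",
            RuntimeWarning,
            stacklevel=2,
        )
        model = Ridge(alpha=1.0)
    else:
        model = LinearRegression()
    model.fit(X_train, Y_train)
    imputed = np.zeros((ds.k, ds.target.n_features))
    if ds.k:
        imputed = np.clip(model.predict(ds.source_rows(ds.missing_ids)), 0.0, None)
    return _completed_from(ds, imputed)


def baseline_mean_impute(ds: PairedOmicsDataset) -> CompletedMatrix:
    """Column means of the observed target rows for every missing sample."""
    mean_row = ds.target.values.mean(axis=0)
    imputed = np.tile(mean_row, (ds.k, 1))
    return _completed_from(ds, imputed)


def compare_methods(per_split_metrics: pd.DataFrame) -> pd.DataFrame:
    """Pairwise paired Wilcoxon signed-rank tests across shared splits.

    ``per_split_metrics`` has one row per split and one column per method.
    Returns a long table (method_a, method_b, p_raw, p_holm); identical
    methods (all-zero differences) get p = 1.
    """
    if per_split_metrics.isna().any().any():
        raise ValueError("all methods must be evaluated on all splits")
    if len(per_split_metrics) < 10:
        raise ValueError("need at least 10 shared splits")
    methods = list(per_split_metrics.columns)
    pairs, raw = [], []
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            diff = per_split_metrics[a].to_numpy() - per_split_metrics[b].to_numpy()
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                p = float(wilcoxon(diff, zero_method="wilcox").pvalue)
            pairs.append((a, b))
            raw.append(p)
    _, p_holm, _, _ = multipletests(raw, method="holm")
    return pd.DataFrame(
        {
            "method_a": [a for a, _ in pairs],
            "method_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_holm": p_holm,
        }
    )
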