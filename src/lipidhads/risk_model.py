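"""Lasso logistic risk model: clinical training, randomized CV, cohort transfer.

An L1-penalized logistic regression separates patients with clinical
depression (positive class) from non-depressed controls.  Model selection
follows a randomized cross-validation protocol: many random test–train splits
with a fixed number of test samples per class, metrics at the 0.5 probability
cutoff plus rank-based ROC AUC, summarized by means and (2.5%, 97.5%)
subsampling intervals.  The regularization strength C (inverse penalty) is
chosen by the mean number of non-zero predictors rather than raw CV score,
because C is sensitive to training-set size.  A model trained on the full
clinical set is then transferred to the population cohort: subjects are scored
with the *training* standardization vectors, training subjects are excluded
downstream, and performance is profiled across HADS-D severity brackets.

By default standardization uses all training-cohort samples before splitting,
reproducing the original protocol (a mild leak across CV splits);
``strict_cv=True`` standardizes within each training fold instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

COEF_TOL = 1e-8  #: |w| above this counts as a selected predictor
C_GRID_DEFAULT = (0.01, 0.1, 0.5, 10, 100, 500, 1000)


class RiskModelError(ValueError):
    pass


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the rank / Mann–Whitney identity, ties counted 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise RiskModelError("ROC AUC needs both classes present")
    ranks = stats.rankdata(scores)  # average ranks on ties
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class RiskModel:
    """Fitted sparse logistic model plus its standardization vectors."""

    features: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    C: float

    @property
    def n_predictors(self) -> int:
        return int(np.sum(np.abs(self.coefficients) > COEF_TOL))

    def predict_proba(self, X: pd.DataFrame) -> pd.Series:
        """Logistic probabilities for new subjects (training standardization)."""
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise RiskModelError(f"missing model features: {missing[:5]}...")
        Z = (X[self.features].to_numpy(float) - self.feature_means) / self.feature_sds
        eta = Z @ self.coefficients + self.intercept
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=X.index, name="probability")

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "C": float(self.C),
            "n_predictors": self.n_predictors,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            features=list(d["features"]),
            feature_means=np.asarray(d["feature_means"], float),
            feature_sds=np.asarray(d["feature_sds"], float),
            coefficients=np.asarray(d["coefficients"], float),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
        )


def standardization(X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and SD (ddof=0) over a training cohort."""
    means = X.to_numpy(float).mean(axis=0)
    sds = X.to_numpy(float).std(axis=0)
    if np.any(sds == 0):
        flat = list(X.columns[sds == 0])
        raise RiskModelError(f"zero-variance features: {flat}")
    return means, sds


def fit_lasso_logistic(
    X: np.ndarray, y: np.ndarray, C: float, features: list[str] | None = None,
    means: np.ndarray | None = None, sds: np.ndarray | None = None,
) -> RiskModel:
    """Fit the L1 logistic model on an already-standardized matrix.

    ``means``/``sds`` record the standardization used so the model can score
    new cohorts on the training scale; they default to zeros/ones (X taken as
    already on the model scale).
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise RiskModelError("training labels contain a single class")
    # pure L1 penalty (lasso); liblinear coordinate descent
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", tol=1e-6, max_iter=2000,
        random_state=0,
    )
    clf.fit(X, y)
    p = X.shape[1]
    return RiskModel(
        features=list(features) if features is not None else [f"f{j}" for j in range(p)],
        feature_means=np.zeros(p) if means is None else np.asarray(means, float),
        feature_sds=np.ones(p) if sds is None else np.asarray(sds, float),
        coefficients=clf.coef_.ravel().astype(float),
        intercept=float(clf.intercept_[0]),
        C=float(C),
    )


def train_risk_model(X: pd.DataFrame, y: np.ndarray, C: float) -> RiskModel:
    """Standardize over the full training cohort, then fit at strength C."""
    means, sds = standardization(X)
    Z = (X.to_numpy(float) - means) / sds
    return fit_lasso_logistic(Z, y, C, features=list(X.columns), means=means, sds=sds)


@dataclass
class CVSummary:
    """Randomized-CV performance with subsampling intervals."""

    metrics: dict[str, dict[str, float]]  # metric -> {mean, low, high}
    n_predictors_mean: float
    n_predictors_sd: float
    n_splits: int
    k_test_per_class: int
    C: float
    per_split: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "n_predictors_mean": float(self.n_predictors_mean),
            "n_predictors_sd": float(self.n_predictors_sd),
            "n_splits": int(self.n_splits),
            "k_test_per_class": int(self.k_test_per_class),
            "C": float(self.C),
        }


def randomized_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    C: float,
    n_splits: int = 1000,
    k_test: int = 10,
    seed: int = 0,
    strict_cv: bool = False,
) -> CVSummary:
    """Random test–train splits with k_test samples per class held out.

    Split i draws from an independent substream of (seed, i).  Metrics:
    rank-based ROC AUC plus accuracy / sensitivity (patients) / specificity
    (controls) at the 0.5 probability cutoff.
    """
    y = np.asarray(y).astype(int)
    idx_pos = np.nonzero(y == 1)[0]
    idx_neg = np.nonzero(y == 0)[0]
    if min(idx_pos.size, idx_neg.size) < k_test + 1:
        raise RiskModelError("each class needs at least k_test + 1 samples")
    Xv = X.to_numpy(float)
    if not strict_cv:
        means, sds = standardization(X)
        Z_all = (Xv - means) / sds

    children = np.random.SeedSequence(seed).spawn(n_splits)
    rows = np.empty((n_splits, 5))
    for i in range(n_splits):
        rng = np.random.default_rng(children[i])
        test_pos = rng.choice(idx_pos, size=k_test, replace=False)
        test_neg = rng.choice(idx_neg, size=k_test, replace=False)
        test = np.concatenate([test_pos, test_neg])
        train = np.setdiff1d(np.arange(y.size), test)
        if strict_cv:
            mu = Xv[train].mean(axis=0)
            sd = Xv[train].std(axis=0)
            sd[sd == 0] = 1.0
            Z_train, Z_test = (Xv[train] - mu) / sd, (Xv[test] - mu) / sd
        else:
            Z_train, Z_test = Z_all[train], Z_all[test]
        model = fit_lasso_logistic(Z_train, y[train], C)
        eta = Z_test @ model.coefficients + model.intercept
        prob = 1.0 / (1.0 + np.exp(-eta))
        pred = (prob >= 0.5).astype(int)
        yt = y[test]
        rows[i] = (
            roc_auc(prob, yt == 1),
            float(np.mean(pred == yt)),
            float(np.mean(pred[yt == 1] == 1)),
            float(np.mean(pred[yt == 0] == 0)),
            model.n_predictors,
        )
    per_split = pd.DataFrame(
        rows, columns=["roc_auc", "accuracy", "sensitivity", "specificity", "n_predictors"]
    )
    metrics = {}
    for m in ("roc_auc", "accuracy", "sensitivity", "specificity"):
        lo, hi = np.percentile(per_split[m], [2.5, 97.5])
        metrics[m] = {
            "mean": float(per_split[m].mean()),
            "low": float(lo),
            "high": float(hi),
        }
    return CVSummary(
        metrics=metrics,
        n_predictors_mean=float(per_split["n_predictors"].mean()),
        n_predictors_sd=float(per_split["n_predictors"].std(ddof=1)),
        n_splits=n_splits,
        k_test_per_class=k_test,
        C=C,
        per_split=per_split,
    )


def choose_C(
    X: pd.DataFrame,
    y: np.ndarray,
    target_predictors: float,
    grid: tuple[float, ...] = C_GRID_DEFAULT,
    n_splits: int = 200,
    k_test: int = 10,
    seed: int = 0,
    strict_cv: bool = False,
) -> dict:
    """CV over a C grid; choose the C whose mean predictor count is nearest target."""
    if not grid:
        raise RiskModelError("empty C grid")
    records = []
    summaries = {}
    for j, C in enumerate(grid):
        s = randomized_cv(
            X, y, C=C, n_splits=n_splits, k_test=k_test, seed=seed + j,
            strict_cv=strict_cv,
        )
        summaries[C] = s
        records.append(
            {
                "C": C,
                "n_predictors_mean": s.n_predictors_mean,
                "n_predictors_sd": s.n_predictors_sd,
                "roc_auc_mean": s.metrics["roc_auc"]["mean"],
            }
        )
    table = pd.DataFrame(records)
    gap = (table["n_predictors_mean"] - target_predictors).abs()
    chosen = float(table.loc[gap.idxmin(), "C"])
    return {"table": table, "chosen_C": chosen, "summaries": summaries}


def score_cohort(
    model: RiskModel, X_new: pd.DataFrame, training_ids: set | None = None
) -> pd.DataFrame:
    """Score a cohort with a fixed model.

    Returns subject_id-indexed probabilities and an ``excluded`` flag marking
    subjects that entered model training (to be dropped from evaluation).
    """
    prob = model.predict_proba(X_new)
    excluded = X_new.index.isin(training_ids or set())
    return pd.DataFrame({"probability": prob, "excluded": excluded}, index=X_new.index)


def score_vs_hads(scores: pd.Series, hads: pd.Series) -> dict:
    """Spearman over all subjects + Pearson over per-HADS-value mean scores."""
    if not scores.index.equals(hads.index):
        hads = hads[scores.index]
    sp = stats.spearmanr(scores.to_numpy(float), hads.to_numpy(float))
    binned = scores.groupby(hads).mean()
    if len(binned) < 3:
        raise RiskModelError("fewer than 3 distinct HADS values for binned Pearson")
    pe = stats.pearsonr(binned.index.to_numpy(float), binned.to_numpy(float))
    return {
        "spearman_all": {"c": float(sp.statistic), "p": float(sp.pvalue),
                         "n": int(len(scores))},
        "pearson_binned": {"c": float(pe.statistic), "p": float(pe.pvalue),
                           "n": int(len(binned))},
    }


def bracket_roc(
    scores: pd.Series, hads_d: pd.Series, thresholds: list[int]
) -> pd.DataFrame:
    """ROC AUC per severity bracket: {HADS-D >= t} vs controls {HADS-D <= 7}.

    Brackets with no cases are omitted and recorded with a warning flag.
    """
    if not scores.index.equals(hads_d.index):
        hads_d = hads_d[scores.index]
    h = hads_d.to_numpy(float)
    s = scores.to_numpy(float)
    controls = h <= 7
    if controls.sum() == 0:
        raise RiskModelError("no control subjects (HADS-D <= 7)")
    rows = []
    for t in thresholds:
        cases = h >= t
        if cases.sum() == 0:
            rows.append({"threshold": t, "roc_auc": np.nan, "n_cases": 0,
                         "n_controls": int(controls.sum()), "warning": "no cases"})
            continue
        mask = cases | controls
        rows.append(
            {
                "threshold": t,
                "roc_auc": roc_auc(s[mask], cases[mask]),
                "n_cases": int(cases.sum()),
                "n_controls": int(controls.sum()),
                "warning": "",
            }
        )
    return pd.DataFrame(rows)
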