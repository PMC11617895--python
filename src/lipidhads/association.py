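"""Covariate-adjusted lipid–HADS association analysis.

Each lipid (log2 abundance) is first residualized on age, sex and BMI by
ordinary least squares; the residuals are then correlated (Pearson) with a
HADS subscale score.  Per-lipid two-sided p-values come from the exact
t-transform of r, multiplicity is controlled by Benjamini–Hochberg, and 95%
confidence intervals for r are percentile bootstrap over (residual, score)
pairs.  The study-level test is a permutation null on the *count* of lipids
significant at FDR 10%: scores are shuffled across subjects (after
residualization), the BH-significant count is recomputed per shuffle, and the
permutation p-value is the plain proportion of shuffles whose count reaches
the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class AssociationError(ValueError):
    pass


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    """Intercept + age + sex(female=1) + BMI design."""
    required = ["age", "sex", "bmi"]
    missing = [c for c in required if c not in covariates.columns]
    if missing:
        raise AssociationError(f"missing covariate columns: {missing}")
    if covariates[required].isna().any().any():
        raise AssociationError("covariates contain missing values")
    sex = covariates["sex"]
    if sex.dtype == object:
        sex_num = sex.map({"female": 1.0, "male": 0.0})
        if sex_num.isna().any():
            bad = sorted(set(sex[sex_num.isna()]))
            raise AssociationError(f"unrecognized sex labels: {bad}")
    else:
        sex_num = sex.astype(float)
    X = np.column_stack(
        [
            np.ones(len(covariates)),
            covariates["age"].to_numpy(float),
            sex_num.to_numpy(float),
            covariates["bmi"].to_numpy(float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AssociationError("rank-deficient covariate design (constant column?)")
    return X


def residualize(lipids: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """OLS residuals of each lipid on age, sex and BMI (with intercept).

    Residuals have zero mean and zero sample correlation with each covariate.
    """
    if len(lipids) != len(covariates):
        raise AssociationError(
            f"{len(lipids)} lipid rows vs {len(covariates)} covariate rows"
        )
    X = _design_matrix(covariates)
    Y = lipids.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid, index=lipids.index, columns=lipids.columns)


def bh_adjust(pvals: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise AssociationError("bh_adjust expects a 1-d array")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise AssociationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _pearson_vector(resid: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r of every column of resid with scores (columns must vary)."""
    rc = resid - resid.mean(axis=0)
    sc = scores - scores.mean()
    denom = np.sqrt((rc**2).sum(axis=0) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc.T @ sc) / denom
    return r


def _r_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r at sample size n (t-transform)."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def correlate_with_scale(
    residuals: pd.DataFrame,
    scores: pd.Series | np.ndarray,
    n_boot: int = 10_000,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-lipid Pearson association with a HADS subscale.

    Returns a DataFrame indexed by lipid with columns ``r``, ``ci_low``,
    ``ci_high`` (95% percentile bootstrap over subject pairs), ``p``
    (two-sided) and ``q`` (BH over all lipids).
    """
    scores = np.asarray(scores, dtype=float)
    resid = residuals.to_numpy(float)
    n = resid.shape[0]
    if scores.shape[0] != n:
        raise AssociationError("residuals and scores have different lengths")
    if np.std(scores) == 0:
        raise AssociationError("scores have zero variance")
    sds = resid.std(axis=0)
    if np.any(sds == 0):
        flat = list(residuals.columns[sds == 0])
        raise AssociationError(f"zero-variance lipids: {flat}")

    r = _pearson_vector(resid, scores)
    p = _r_pvalues(r, n)
    q = bh_adjust(p)

    ci_low = np.full(resid.shape[1], np.nan)
    ci_high = np.full(resid.shape[1], np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, resid.shape[1]))
        chunk = max(1, int(2_000_000 // max(n, 1)))
        done = 0
        while done < n_boot:
            b = min(chunk, n_boot - done)
            idx = rng.integers(0, n, size=(b, n))
            for i in range(b):
                boot[done + i] = _pearson_vector(resid[idx[i]], scores[idx[i]])
            done += b
        ci_low, ci_high = np.nanpercentile(boot, [2.5, 97.5], axis=0)

    return pd.DataFrame(
        {"r": r, "ci_low": ci_low, "ci_high": ci_high, "p": p, "q": q},
        index=residuals.columns,
    )


def association_report(assoc: pd.DataFrame) -> pd.DataFrame:
    """Export view of an association table: lipid, class, c, CI, p, q."""
    from .lipid_annotation import parse_lipid_name

    out = assoc.copy()
    out.insert(0, "lipid", out.index)
    out.insert(1, "class", [parse_lipid_name(n).lipid_class for n in out.index])
    out = out.rename(columns={"r": "c"})
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


@dataclass
class PermutationResult:
    """Permutation null on the number of FDR-significant lipids.

    ``p_perm`` is the plain proportion of the B null counts that are ≥ the
    observed count.  ``p_perm_randomized`` breaks ties among counts at random
    and pools the observation with the nulls, giving a statistic that is
    exactly uniform on {1/(B+1), …, 1} under exchangeability — useful for
    calibration diagnostics on the discrete count statistic.
    """

    observed_count: int
    null_counts: np.ndarray
    p_perm: float
    p_perm_randomized: float
    B: int
    fdr: float

    def to_dict(self) -> dict:
        return {
            "observed_count": int(self.observed_count),
            "p_perm": float(self.p_perm),
            "p_perm_randomized": float(self.p_perm_randomized),
            "B": int(self.B),
            "fdr": float(self.fdr),
        }


def _bh_count(p: np.ndarray, fdr: float) -> int:
    """Number of BH rejections at level fdr (step-up, no full q-vector needed)."""
    m = p.size
    p_sorted = np.sort(p)
    thresh = fdr * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= thresh)[0]
    return 0 if passing.size == 0 else int(passing[-1] + 1)


def permutation_test(
    residuals: pd.DataFrame,
    scores: pd.Series | np.ndarray,
    B: int = 1000,
    fdr: float = 0.1,
    seed: int = 0,
) -> PermutationResult:
    """Shuffle scores across subjects B times; count lipids with BH q < fdr.

    Permutation i draws its shuffle from an independent substream derived from
    (seed, i), so results do not depend on evaluation order.
    """
    if B < 1:
        raise AssociationError("B must be >= 1")
    scores = np.asarray(scores, dtype=float)
    resid = residuals.to_numpy(float)
    n = resid.shape[0]
    if scores.shape[0] != n:
        raise AssociationError("residuals and scores have different lengths")
    if np.std(scores) == 0:
        raise AssociationError("scores have zero variance")

    # Standardize once: r is then a single matrix-vector product per shuffle.
    rc = resid - resid.mean(axis=0)
    norms = np.sqrt((rc**2).sum(axis=0))
    if np.any(norms == 0):
        flat = list(residuals.columns[norms == 0])
        raise AssociationError(f"zero-variance lipids: {flat}")
    Z = rc / norms

    def count_for(s: np.ndarray) -> int:
        sc = s - s.mean()
        sc /= np.sqrt((sc**2).sum())
        r = Z.T @ sc
        p = _r_pvalues(r, n)
        return _bh_count(p, fdr)

    observed = count_for(scores)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B + 1)
    null_counts = np.empty(B, dtype=int)
    for i in range(B):
        rng = np.random.default_rng(children[i])
        null_counts[i] = count_for(scores[rng.permutation(n)])
    p_perm = float(np.mean(null_counts >= observed))

    greater = int(np.sum(null_counts > observed))
    ties = int(np.sum(null_counts == observed))
    tie_rng = np.random.default_rng(children[B])
    v = int(tie_rng.integers(0, ties + 1))
    p_rand = (greater + v + 1) / (B + 1)

    return PermutationResult(
        observed_count=observed,
        null_counts=null_counts,
        p_perm=p_perm,
        p_perm_randomized=float(p_rand),
        B=B,
        fdr=fdr,
    )
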