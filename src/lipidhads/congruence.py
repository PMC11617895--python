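"""Congruence of clinical fold-changes with population effect sizes.

For each lipid the clinical alteration is the mean log2 fold-change between
patients with clinical depression and the volunteer (general-population)
cohort; congruence with the per-lipid HADS-D Pearson coefficients from the
volunteer cohort is summarized by a Spearman correlation, overall and on
class-defined subsets (all lipids, excluding triglycerides, ether
phospholipids only, triglycerides only — the latter reported descriptively).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lipid_annotation import LipidSpecies

SUBSETS = ("all", "no_tag", "ether_only", "tag_only")


class CongruenceError(ValueError):
    pass


def fold_changes(patients: pd.DataFrame, reference: pd.DataFrame) -> pd.Series:
    """Per-lipid mean log2 difference: mean over patients − mean over reference."""
    if patients.empty or reference.empty:
        raise CongruenceError("both cohorts must be non-empty")
    if set(patients.columns) != set(reference.columns):
        diff = set(patients.columns) ^ set(reference.columns)
        raise CongruenceError(f"feature mismatch between cohorts: {sorted(diff)}")
    reference = reference[patients.columns]
    return patients.mean(axis=0) - reference.mean(axis=0)


def _subset_mask(subset: str, species: Mapping[str, LipidSpecies], names) -> np.ndarray:
    if subset == "all":
        return np.ones(len(names), dtype=bool)
    if subset == "no_tag":
        return np.array([species[n].lipid_class != "TAG" for n in names])
    if subset == "ether_only":
        return np.array([species[n].ether for n in names])
    if subset == "tag_only":
        return np.array([species[n].lipid_class == "TAG" for n in names])
    raise CongruenceError(f"unknown subset {subset!r}; expected one of {SUBSETS}")


@dataclass
class CongruenceResult:
    subset: str
    spearman_c: float
    p: float
    ci_low: float
    ci_high: float
    n_lipids: int

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "spearman_c": float(self.spearman_c),
            "p": float(self.p),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "n_lipids": int(self.n_lipids),
        }


def effect_congruence(
    assoc_r: pd.Series,
    fc: pd.Series,
    subset: str = "all",
    species: Mapping[str, LipidSpecies] | None = None,
    n_boot: int = 10_000,
    seed: int | None = 0,
) -> CongruenceResult:
    """Spearman correlation between association coefficients and fold-changes.

    Ties get average (mid-) ranks; the 95% CI is a percentile bootstrap over
    lipid pairs.  Subsets other than "all" require species annotations.
    """
    if not assoc_r.index.equals(fc.index):
        if set(assoc_r.index) != set(fc.index):
            raise CongruenceError("assoc_r and fc must cover the same lipids")
        fc = fc[assoc_r.index]
    names = list(assoc_r.index)
    if subset != "all" and species is None:
        raise CongruenceError("species annotations required for class subsets")
    mask = _subset_mask(subset, species or {}, names)
    x = assoc_r.to_numpy(float)[mask]
    y = fc.to_numpy(float)[mask]
    n = x.size
    if n < 3:
        raise CongruenceError(f"subset {subset!r} has fewer than 3 lipids")
    c, p = stats.spearmanr(x, y)
    ci_low = ci_high = np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = np.empty(n_boot)
        for i in range(n_boot):
            xb, yb = x[idx[i]], y[idx[i]]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                boot[i] = np.nan
                continue
            boot[i] = stats.spearmanr(xb, yb).statistic
        ci_low, ci_high = np.nanpercentile(boot, [2.5, 97.5])
    return CongruenceResult(
        subset=subset,
        spearman_c=float(c),
        p=float(p),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_lipids=int(n),
    )


def congruence_table(
    assoc_r: pd.Series,
    fc: pd.Series,
    species: Mapping[str, LipidSpecies],
    subsets: Sequence[str] = SUBSETS,
    n_boot: int = 10_000,
    seed: int | None = 0,
) -> list[CongruenceResult]:
    """Congruence results for every requested subset (same bootstrap seed base)."""
    out = []
    for k, subset in enumerate(subsets):
        out.append(
            effect_congruence(
                assoc_r, fc, subset=subset, species=species,
                n_boot=n_boot, seed=None if seed is None else seed + k,
            )
        )
    return out


def per_lipid_table(
    assoc_r: pd.Series, fc: pd.Series, species: Mapping[str, LipidSpecies]
) -> pd.DataFrame:
    """Scatter-plot export: lipid, class, ether, dbi, assoc_r, fold_change."""
    rows = []
    for name in assoc_r.index:
        s = species[name]
        rows.append(
            {
                "lipid": name,
                "class": s.lipid_class,
                "ether": s.ether,
                "double_bonds": s.double_bonds,
                "dbi": float(s.dbi),
                "assoc_r": float(assoc_r[name]),
                "fold_change": float(fc[name]),
            }
        )
    return pd.DataFrame(rows)
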