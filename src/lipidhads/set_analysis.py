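"""Lipid-class over-representation and unsaturation comparison.

Among the lipids significant at FDR 10%, each biochemical group (lipid class,
or a merged group such as all ether phospholipids) is tested for
over-representation with a one-sided hypergeometric (Fisher) test, and its
enrichment ratio is the observed hit count divided by the expected count
N_sign × N_group / N_total.  Polyunsaturation is compared between significant
and remaining lipids on the double-bond index with a Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lipid_annotation import ETHER_CLASSES, LipidSpecies, median_dbi


class SetAnalysisError(ValueError):
    pass


def enrichment_ratio(n_hits: int, n_sign: int, n_group: int, n_total: int) -> float:
    """Observed over expected hits: n_hits / (n_sign * n_group / n_total)."""
    _check_counts(n_hits, n_sign, n_group, n_total)
    expected = n_sign * n_group / n_total
    return n_hits / expected


def hypergeom_enrichment(n_hits: int, n_sign: int, n_group: int, n_total: int) -> float:
    """Upper-tail P(X >= n_hits), X ~ Hypergeom(N=n_total, K=n_group, n=n_sign)."""
    _check_counts(n_hits, n_sign, n_group, n_total)
    return float(stats.hypergeom.sf(n_hits - 1, n_total, n_group, n_sign))


def _check_counts(n_hits: int, n_sign: int, n_group: int, n_total: int) -> None:
    if n_group < 1 or n_total < 1:
        raise SetAnalysisError("n_group and n_total must be positive")
    if n_sign > n_total or n_group > n_total:
        raise SetAnalysisError("margins exceed the panel size")
    if not (0 <= n_hits <= min(n_sign, n_group)):
        raise SetAnalysisError(
            f"inconsistent counts: n_hits={n_hits}, n_sign={n_sign}, n_group={n_group}"
        )


@dataclass
class EnrichmentResult:
    group: str
    n_hits: int
    n_sign: int
    n_group: int
    n_total: int
    expected: float
    ratio: float
    p: float


def class_enrichment(
    significant: Sequence[LipidSpecies],
    panel: Sequence[LipidSpecies],
    merge_ether: bool = True,
) -> pd.DataFrame:
    """Per-class (and merged ether) over-representation among significant lipids.

    Classes absent from the quantified panel are skipped.  Counts come from
    the panel at hand, never from a hard-coded inventory.
    """
    if not panel:
        raise SetAnalysisError("empty lipid panel")
    sig_names = {s.name for s in significant}
    if not sig_names <= {s.name for s in panel}:
        raise SetAnalysisError("significant lipids must be a subset of the panel")
    n_total = len(panel)
    n_sign = len(significant)
    groups: dict[str, set[str]] = {}
    for s in panel:
        groups.setdefault(s.lipid_class, set()).add(s.name)
    if merge_ether:
        ether = {s.name for s in panel if s.ether}
        if ether:
            groups["ether (PC O- + PE P- + LPC O-)"] = ether
    rows = []
    for name, members in groups.items():
        n_group = len(members)
        n_hits = len(sig_names & members)
        expected = n_sign * n_group / n_total
        rows.append(
            EnrichmentResult(
                group=name,
                n_hits=n_hits,
                n_sign=n_sign,
                n_group=n_group,
                n_total=n_total,
                expected=expected,
                ratio=n_hits / expected if expected > 0 else np.nan,
                p=hypergeom_enrichment(n_hits, n_sign, n_group, n_total),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).sort_values("p", kind="mergesort")
    return df.reset_index(drop=True)


def mann_whitney_dbi(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney U p-value.

    Exact enumeration for small tie-free samples (both groups <= 8), otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    small = max(len(x), len(y)) <= 8
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_dbi(
    significant: Sequence[LipidSpecies], rest: Sequence[LipidSpecies]
) -> dict:
    """Median DBI of each group and the Mann–Whitney p-value on DBI values."""
    if not significant or not rest:
        raise SetAnalysisError("both groups must be non-empty")
    dbi_sig = np.array([float(s.dbi) for s in significant])
    dbi_rest = np.array([float(s.dbi) for s in rest])
    return {
        "median_sig": float(median_dbi(significant)),
        "median_rest": float(median_dbi(rest)),
        "p_mw": mann_whitney_dbi(dbi_sig, dbi_rest),
        "n_sig": len(significant),
        "n_rest": len(rest),
    }
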