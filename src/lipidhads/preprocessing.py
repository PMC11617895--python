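"""Post-processing of identified-feature intensity tables from DI-MS lipidomics.

The chain takes a raw samples × features table carrying per-sample roles
(plasma / qc / ltr / blank), 96-plasma-sample measurement batches and two large
temporal batches, and applies, in this order:

1. drop features with > 10% zero values across plasma samples,
2. replace remaining zeros by 0.9 × the feature's minimum non-zero plasma value,
3. log2 transform,
4. drop contaminants (mean plasma − mean blank < 1 on log2 scale),
5. per-batch QC-median correction (re-centred on the pooled QC median),
6. drop unstable features (SD over QC samples > 0.5 in log2),
7. align the second temporal batch to the first using LTR medians,

returning the plasma-only matrix and a per-step audit trail.  Filters remove
features, never samples.  All thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

ROLES = ("plasma", "qc", "ltr", "blank")

META_COLUMNS = ("sample_id", "role", "batch", "temporal_batch")


class PreprocessingError(ValueError):
    pass


@dataclass
class IntensityTable:
    """Samples × lipid-features intensity matrix with acquisition metadata.

    ``values`` is indexed by sample id with feature names as columns;
    ``role``, ``batch`` and ``temporal_batch`` are per-sample series sharing
    that index.  ``scale`` is ``"raw"`` (non-negative intensities) or
    ``"log2"``.
    """

    values: pd.DataFrame
    role: pd.Series
    batch: pd.Series
    temporal_batch: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise PreprocessingError(f"unknown scale {self.scale!r}")
        if not self.values.index.is_unique:
            raise PreprocessingError("sample ids must be unique")
        if not self.values.columns.is_unique:
            raise PreprocessingError("feature names must be unique")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise PreprocessingError("intensity values must be finite")
        if self.scale == "raw" and (vals < 0).any():
            raise PreprocessingError("raw-scale intensities must be non-negative")
        for s, name in ((self.role, "role"), (self.batch, "batch"),
                        (self.temporal_batch, "temporal_batch")):
            if not s.index.equals(self.values.index):
                raise PreprocessingError(f"{name} index must match sample ids")
        bad = set(self.role) - set(ROLES)
        if bad:
            raise PreprocessingError(f"unknown sample roles: {sorted(bad)}")

    # -- convenience -----------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    def mask(self, role: str) -> pd.Series:
        return self.role == role

    def subset_features(self, keep: Iterable[str]) -> "IntensityTable":
        keep = list(keep)
        return replace(self, values=self.values[keep])

    def restrict_to_plasma(self) -> "IntensityTable":
        m = self.mask("plasma")
        return IntensityTable(
            values=self.values.loc[m],
            role=self.role.loc[m],
            batch=self.batch.loc[m],
            temporal_batch=self.temporal_batch.loc[m],
            scale=self.scale,
        )

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "role": self.role.to_numpy(),
                "batch": self.batch.to_numpy(),
                "temporal_batch": self.temporal_batch.to_numpy(),
            },
            index=self.sample_ids,
        )
        return pd.concat([meta, self.values], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = "raw") -> "IntensityTable":
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise PreprocessingError(f"missing metadata columns: {missing}")
        df = df.set_index("sample_id")
        feats = [c for c in df.columns if c not in META_COLUMNS]
        return cls(
            values=df[feats].astype(float),
            role=df["role"].astype(str),
            batch=df["batch"].astype(int),
            temporal_batch=df["temporal_batch"].astype(int),
            scale=scale,
        )

    @classmethod
    def from_csv(cls, path, scale: str = "raw") -> "IntensityTable":
        return cls.from_frame(pd.read_csv(path), scale=scale)


@dataclass
class FilterReport:
    """Audit record of one filtering step.

    ``rule_values`` holds the per-feature diagnostic the rule was decided on
    (zero fraction, plasma−blank delta, or QC SD) for every input feature.
    """

    step: str
    threshold: float
    removed_features: list[str] = field(default_factory=list)
    rule_values: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "threshold": self.threshold,
            "removed_features": list(self.removed_features),
            "rule_values": {k: float(v) for k, v in self.rule_values.items()},
        }


def _require_scale(table: IntensityTable, scale: str, op: str) -> None:
    if table.scale != scale:
        raise PreprocessingError(f"{op} requires a {scale}-scale table, got {table.scale}")


def filter_zero_features(
    table: IntensityTable, max_zero_frac: float = 0.10
) -> tuple[IntensityTable, FilterReport]:
    """Drop features whose zero fraction across *plasma* samples exceeds the cap.

    The fraction is computed over plasma samples only ("more than" is strict, so
    a feature exactly at the cap is retained).
    """
    _require_scale(table, "raw", "filter_zero_features")
    plasma = table.values.loc[table.mask("plasma")]
    if plasma.empty:
        raise PreprocessingError("table contains no plasma samples")
    zero_frac = (plasma == 0).mean(axis=0)
    removed = zero_frac.index[zero_frac > max_zero_frac]
    report = FilterReport(
        step="zero_fraction",
        threshold=max_zero_frac,
        removed_features=list(removed),
        rule_values=zero_frac.to_dict(),
    )
    keep = [f for f in table.feature_names if f not in set(removed)]
    return table.subset_features(keep), report


def impute_zeros(table: IntensityTable) -> IntensityTable:
    """Replace zeros by 0.9 × the feature's minimum non-zero plasma value.

    The minimum is taken over plasma samples only, but the replacement is
    applied to zeros in every role so blanks and QCs remain usable at log2
    scale downstream.
    """
    _require_scale(table, "raw", "impute_zeros")
    plasma = table.values.loc[table.mask("plasma")]
    masked = plasma.where(plasma > 0)
    if masked.isna().all(axis=0).any():
        offenders = list(masked.columns[masked.isna().all(axis=0)])
        raise PreprocessingError(
            f"features with all-zero plasma values {offenders}; "
            "run filter_zero_features first"
        )
    floor = 0.9 * masked.min(axis=0)
    values = table.values.mask(table.values == 0, floor, axis=1)
    return replace(table, values=values)


def log2_transform(table: IntensityTable) -> IntensityTable:
    """Element-wise log2; flips the scale flag."""
    _require_scale(table, "raw", "log2_transform")
    vals = table.values.to_numpy()
    if (vals <= 0).any():
        raise PreprocessingError("log2 transform requires strictly positive values")
    return replace(table, values=np.log2(table.values), scale="log2")


def remove_contaminants(
    table: IntensityTable, min_blank_delta: float = 1.0
) -> tuple[IntensityTable, FilterReport]:
    """Drop features not clearly above blank level.

    Rule: mean log2 over plasma − mean log2 over blanks < 1 (strict) → removed.
    """
    _require_scale(table, "log2", "remove_contaminants")
    blanks = table.values.loc[table.mask("blank")]
    if blanks.empty:
        raise PreprocessingError("contaminant removal requires blank samples")
    delta = table.values.loc[table.mask("plasma")].mean(axis=0) - blanks.mean(axis=0)
    removed = delta.index[delta < min_blank_delta]
    report = FilterReport(
        step="blank_delta",
        threshold=min_blank_delta,
        removed_features=list(removed),
        rule_values=delta.to_dict(),
    )
    keep = [f for f in table.feature_names if f not in set(removed)]
    return table.subset_features(keep), report


def correct_batches(table: IntensityTable) -> IntensityTable:
    """Per-batch QC-median correction.

    For each feature and measurement batch, subtract the median over that
    batch's QC samples, then add back the feature's pooled QC median over all
    batches ("return to original scale").  After correction the within-batch QC
    median of every feature equals the pooled grand median.
    """
    _require_scale(table, "log2", "correct_batches")
    qc_mask = table.mask("qc")
    batches = pd.unique(table.batch)
    for b in batches:
        if not (qc_mask & (table.batch == b)).any():
            raise PreprocessingError(f"batch {b} has no QC sample")
    grand = table.values.loc[qc_mask].median(axis=0)
    values = table.values.copy()
    for b in batches:
        in_batch = table.batch == b
        qc_med = table.values.loc[qc_mask & in_batch].median(axis=0)
        values.loc[in_batch] = values.loc[in_batch] - qc_med + grand
    return replace(table, values=values)


def filter_unstable_features(
    table: IntensityTable, max_qc_sd: float = 0.5
) -> tuple[IntensityTable, FilterReport]:
    """Drop features with log2 SD over QC samples > the cap (sample SD, n−1)."""
    _require_scale(table, "log2", "filter_unstable_features")
    qc = table.values.loc[table.mask("qc")]
    if len(qc) < 2:
        raise PreprocessingError("QC SD filter requires at least 2 QC samples")
    sd = qc.std(axis=0, ddof=1)
    removed = sd.index[sd > max_qc_sd]
    report = FilterReport(
        step="qc_sd",
        threshold=max_qc_sd,
        removed_features=list(removed),
        rule_values=sd.to_dict(),
    )
    keep = [f for f in table.feature_names if f not in set(removed)]
    return table.subset_features(keep), report


def align_temporal_batches(table: IntensityTable) -> IntensityTable:
    """Align the second temporal batch to the first via LTR medians.

    Every sample in temporal batch 2 is shifted, per feature, by
    median(LTR, batch 1) − median(LTR, batch 2), so LTR medians agree across
    the two measurement epochs afterwards.  A single temporal batch is a no-op.
    """
    _require_scale(table, "log2", "align_temporal_batches")
    tbs = sorted(pd.unique(table.temporal_batch))
    if len(tbs) == 1:
        return replace(table, values=table.values.copy())
    if len(tbs) != 2:
        raise PreprocessingError(f"expected at most 2 temporal batches, got {tbs}")
    ltr_mask = table.mask("ltr")
    first, second = tbs
    med = {}
    for tb in tbs:
        sel = ltr_mask & (table.temporal_batch == tb)
        if not sel.any():
            raise PreprocessingError(f"temporal batch {tb} has no LTR sample")
        med[tb] = table.values.loc[sel].median(axis=0)
    shift = med[first] - med[second]
    values = table.values.copy()
    in_second = table.temporal_batch == second
    values.loc[in_second] = values.loc[in_second] + shift
    return replace(table, values=values)


@dataclass
class PostprocessConfig:
    max_zero_frac: float = 0.10
    blank_delta: float = 1.0
    max_qc_sd: float = 0.5


def run_postprocessing(
    raw: IntensityTable, config: PostprocessConfig | None = None
) -> tuple[IntensityTable, list[FilterReport]]:
    """Full post-processing chain; returns the plasma-only log2 matrix + audit trail."""
    config = config or PostprocessConfig()
    table, rep_zero = filter_zero_features(raw, config.max_zero_frac)
    table = impute_zeros(table)
    table = log2_transform(table)
    table, rep_blank = remove_contaminants(table, config.blank_delta)
    table = correct_batches(table)
    table, rep_qc = filter_unstable_features(table, config.max_qc_sd)
    table = align_temporal_batches(table)
    return table.restrict_to_plasma(), [rep_zero, rep_blank, rep_qc]
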