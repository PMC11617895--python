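"""End-to-end study replica: simulate → preprocess → associate → enrich →
congruence → risk model → report.

One config and one root seed drive every stage; stage randomness flows
through named substreams spawned from the root seed, so reports are
byte-identical across reruns.  The report is a plain-dict bundle whose every
numeric field is the direct output of one upstream module.
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
from .association import (association_report, correlate_with_scale,
                          permutation_test, residualize)
from .congruence import congruence_table, fold_changes, per_lipid_table
from .lipid_annotation import parse_lipid_name
from .preprocessing import PostprocessConfig, run_postprocessing
from .risk_model import (
    bracket_roc,
    randomized_cv,
    score_cohort,
    score_vs_hads,
    train_risk_model,
)
from .set_analysis import class_enrichment, compare_dbi
from .synthetic_data import (
    GeneratorConfig,
    apply_technical_layer,
    build_ground_truth,
    generate_clinical,
    generate_lipidome,
    generate_phenotypes,
)

log = logging.getLogger("lipidhads")


@dataclass
class StudyConfig:
    """Run-level knobs on top of the generator's study conditions."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    fdr: float = 0.1
    permutations: int = 1000
    n_boot: int = 2000
    cv_splits: int = 1000
    cv_k_test: int = 10
    cv_C: float = 0.5
    final_C: float = 0.3
    n_training_volunteers: int = 15
    bracket_thresholds: tuple[int, ...] = (8, 11, 14, 15)

    def to_dict(self) -> dict:
        d = {
            "generator": self.generator.to_dict(),
            "postprocess": vars(self.postprocess).copy(),
            "fdr": self.fdr,
            "permutations": self.permutations,
            "n_boot": self.n_boot,
            "cv_splits": self.cv_splits,
            "cv_k_test": self.cv_k_test,
            "cv_C": self.cv_C,
            "final_C": self.final_C,
            "n_training_volunteers": self.n_training_volunteers,
            "bracket_thresholds": list(self.bracket_thresholds),
        }
        return d

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        post = PostprocessConfig(**raw.pop("postprocess", {}))
        if "bracket_thresholds" in raw:
            raw["bracket_thresholds"] = tuple(raw["bracket_thresholds"])
        return cls(generator=gen, postprocess=post, **raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _substreams(seed: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_study(config: StudyConfig | None = None, seed: int = 0,
              outdir: str | Path | None = None) -> dict:
    """Execute all stages in order; return (and optionally write) the report."""
    config = config or StudyConfig()
    seeds = _substreams(
        seed,
        ["phenotypes", "lipidome", "technical", "clinical", "association",
         "congruence", "model", "training_volunteers"],
    )
    gen = config.generator
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": int(seed),
            "version": __version__,
        }
    }

    def stage(name, fn):
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - fail fast with provenance
            raise StageError(name, exc) from exc
        log.info("stage %s done", name)
        return out

    # --- simulate ---------------------------------------------------------
    pheno, latents = stage(
        "phenotypes", lambda: generate_phenotypes(gen, seeds["phenotypes"])
    )
    gt = build_ground_truth(gen)
    clean, _ = stage(
        "lipidome", lambda: generate_lipidome(pheno, latents, gen,
                                              seeds["lipidome"], gt)
    )
    raw = stage(
        "technical", lambda: apply_technical_layer(clean, gen,
                                                   seeds["technical"], gt)
    )
    report["cohort"] = {
        "n_volunteers": int(len(pheno)),
        "pct_female": float((pheno["sex"] == "female").mean()),
        "age_mean": float(pheno["age"].mean()),
        "age_sd": float(pheno["age"].std(ddof=1)),
        "corr_hads_a_d": float(np.corrcoef(pheno["hads_a"], pheno["hads_d"])[0, 1]),
        "frac_hads_d_le7": float((pheno["hads_d"] <= 7).mean()),
        "frac_hads_a_le7": float((pheno["hads_a"] <= 7).mean()),
        "frac_hads_d_ge15": float((pheno["hads_d"] >= 15).mean()),
    }

    # --- preprocess -------------------------------------------------------
    processed, reports = stage(
        "preprocess", lambda: run_postprocessing(raw, config.postprocess)
    )
    report["preprocessing"] = {
        "n_features_out": int(processed.values.shape[1]),
        "n_plasma": int(processed.values.shape[0]),
        "filters": [r.to_dict() for r in reports],
    }
    matrix = processed.values.loc[pheno.index]
    species = {n: parse_lipid_name(n) for n in matrix.columns}

    # --- association ------------------------------------------------------
    def assoc_stage():
        resid = residualize(matrix, pheno[["age", "sex", "bmi"]])
        out = {}
        for scale in ("hads_d", "hads_a"):
            table = correlate_with_scale(
                resid, pheno[scale], n_boot=config.n_boot,
                seed=seeds["association"],
            )
            perm = permutation_test(
                resid, pheno[scale], B=config.permutations, fdr=config.fdr,
                seed=seeds["association"] + (0 if scale == "hads_d" else 1),
            )
            out[scale] = (table, perm)
        return resid, out

    resid, assoc = stage("association", assoc_stage)
    assoc_d, perm_d = assoc["hads_d"]
    report["association"] = {
        scale: {
            "n_significant": int((tbl["q"] < config.fdr).sum()),
            "permutation": perm.to_dict(),
        }
        for scale, (tbl, perm) in assoc.items()
    }

    # --- enrichment / unsaturation ---------------------------------------
    def enrich_stage():
        sig_names = assoc_d.index[assoc_d["q"] < config.fdr]
        sig = [species[n] for n in sig_names]
        rest = [species[n] for n in assoc_d.index if n not in set(sig_names)]
        enr = class_enrichment(sig, list(species.values())) if sig else None
        dbi = compare_dbi(sig, rest) if sig and rest else None
        return enr, dbi

    enr, dbi_cmp = stage("set_analysis", enrich_stage)
    report["enrichment"] = {
        "table": enr.to_dict(orient="records") if enr is not None else [],
        "dbi_comparison": dbi_cmp,
    }

    # --- clinical cohort + congruence ------------------------------------
    clinical, labels, clin_pheno = stage(
        "clinical", lambda: generate_clinical(gt, gen, seeds["clinical"])
    )
    patients = clinical.values.loc[labels == 1]

    def congruence_stage():
        fc = fold_changes(patients[matrix.columns], matrix)
        results = congruence_table(
            assoc_d["r"], fc, species, n_boot=config.n_boot,
            seed=seeds["congruence"],
        )
        return fc, results

    fc, congr = stage("congruence", congruence_stage)
    report["congruence"] = {r.subset: r.to_dict() for r in congr}

    # --- risk model -------------------------------------------------------
    def model_stage():
        rng = np.random.default_rng(seeds["training_volunteers"])
        eligible = pheno.index[(pheno["hads_d"] <= 7) & (pheno["hads_a"] <= 7)]
        k = min(config.n_training_volunteers, len(eligible))
        training_vols = pd.Index(
            rng.choice(eligible.to_numpy(), size=k, replace=False)
        )
        X_train = pd.concat(
            [clinical.values[matrix.columns], matrix.loc[training_vols]]
        )
        y_train = np.concatenate([labels.to_numpy(), np.zeros(k, dtype=int)])
        cv = randomized_cv(
            X_train, y_train, C=config.cv_C, n_splits=config.cv_splits,
            k_test=config.cv_k_test, seed=seeds["model"],
        )
        model = train_risk_model(X_train, y_train, C=config.final_C)
        scored = score_cohort(model, matrix, training_ids=set(training_vols))
        eval_scores = scored.loc[~scored["excluded"], "probability"]
        hads_d = pheno.loc[eval_scores.index, "hads_d"]
        hads_a = pheno.loc[eval_scores.index, "hads_a"]
        brackets = bracket_roc(eval_scores, hads_d, list(config.bracket_thresholds))
        clin_scores = model.predict_proba(clinical.values[matrix.columns])
        ctrl = eval_scores[hads_d <= 7]
        clin_vs_ctrl = float(
            _clinical_auc(clin_scores[labels == 1], ctrl)
        )
        return {
            "training_volunteers": list(map(str, training_vols)),
            "cv": cv.to_dict(),
            "final_n_predictors": model.n_predictors,
            "score_vs_hads_d": score_vs_hads(eval_scores, hads_d),
            "score_vs_hads_a": score_vs_hads(eval_scores, hads_a),
            "bracket_roc": brackets.to_dict(orient="records"),
            "clinical_vs_controls_auc": clin_vs_ctrl,
            "model": model,
            "scores": scored,
        }

    model_out = stage("risk_model", model_stage)
    report["risk_model"] = {
        k: v for k, v in model_out.items() if k not in ("model", "scores")
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pheno.to_csv(outdir / "pheno.csv")
        association_report(assoc_d).to_csv(
            outdir / "association_hads_d.tsv", sep="\t", index=False
        )
        if enr is not None:
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        per_lipid_table(assoc_d["r"], fc, species).to_csv(
            outdir / "congruence_lipids.tsv", sep="\t", index=False
        )
        model_out["model"].to_json(outdir / "risk_model.json")
        model_out["scores"].to_csv(outdir / "volunteer_scores.csv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonify)
    return report


def _clinical_auc(patient_scores: pd.Series, control_scores: pd.Series) -> float:
    from .risk_model import roc_auc

    s = np.concatenate([patient_scores.to_numpy(float),
                        control_scores.to_numpy(float)])
    y = np.concatenate([np.ones(len(patient_scores), bool),
                        np.zeros(len(control_scores), bool)])
    return roc_auc(s, y)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
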