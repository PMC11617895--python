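"""Synthetic cohorts emulating the lipidome–depression study design.

The generator produces, with full ground truth:

* a volunteer cohort (default n = 604, 72% female, age 30 ± 10) with HADS-A/D
  scores built from a bivariate-normal latent (anxiety, depression) through
  7 ordinal items per subscale — thresholds and latent correlation are
  calibrated (see ``scripts/calibrate_phenotypes.py``) so the *emergent*
  score-level correlation (~0.55) and category proportions (81% / 65% in the
  healthy range for D / A, 1.5% severe D) match the population anchors
  without being parameterized directly;
* a 186-lipid, 14-class panel with class-structured covariance and planted
  HADS-D effects concentrated on eight designated ether/PUFA species
  (per-lipid target r between −0.12 and −0.15), a weak negative ether/PUFA
  background elsewhere, and age/sex/BMI loadings;
* a clinical cohort (32 patients / 21 controls) whose fold-change profile is
  congruent with the volunteer effect vector except for a discordant
  saturated-triglyceride block (double-bond index < 1);
* a technical layer inverting the post-processing assumptions: 96-sample
  measurement batches with per-batch feature shifts tracked by QC samples,
  two temporal epochs with an LTR-detectable drift, extraction blanks,
  background dropout zeros, and planted high-zero / contaminant / unstable
  features that each violate exactly one filtering rule.

All randomness flows through explicit seeds; identical (config, seed) gives
byte-identical outputs.  The panel itself (names, baselines, effect vectors)
is drawn from a dedicated ``panel_seed`` so the "true" study stays fixed
while sampling noise varies across run seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .lipid_annotation import (
    ETHER_CLASSES,
    chains_for_class,
    format_lipid_name,
    parse_lipid_name,
)
from .preprocessing import IntensityTable


class GeneratorError(ValueError):
    pass


#: Per-class species counts (sum 186).  The real per-class inventory is not
#: published; this split follows the usual positive-mode DI-MS plasma profile
#: (triglyceride-dominated, strong PC/SM representation).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "TAG": 60, "PC": 30, "SM": 18, "PC O-": 14, "LPC": 10,
    "PE": 8, "PE P-": 8, "DAG": 8, "CE": 8, "Cer": 6,
    "LPE": 4, "LPC O-": 4, "CAR": 4, "PI": 4,
}

#: (carbon range, double-bond range) per class for name generation.
_CLASS_RANGES: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "CAR": ((10, 20), (0, 2)),
    "CE": ((14, 22), (0, 6)),
    "DAG": ((30, 40), (0, 6)),
    "TAG": ((42, 60), (0, 12)),
    "Cer": ((30, 44), (0, 3)),
    "SM": ((30, 44), (0, 4)),
    "PE": ((32, 40), (0, 8)),
    "PE P-": ((32, 40), (1, 8)),
    "LPE": ((16, 22), (0, 4)),
    "PC": ((30, 40), (0, 8)),
    "PC O-": ((30, 40), (0, 8)),
    "LPC": ((14, 22), (0, 4)),
    "LPC O-": ((14, 20), (0, 2)),
    "PI": ((32, 40), (0, 8)),
}

#: The eight designated effect carriers with their target correlations
#: (population-scale Pearson r with HADS-D after covariate adjustment).
DESIGNATED_EFFECTS: dict[str, float] = {
    "PC O-34:3": -0.15,
    "PC O-36:6": -0.15,
    "PC O-38:7": -0.14,
    "PE P-38:6": -0.14,
    "PC O-38:6": -0.13,
    "PC O-36:5": -0.13,
    "PC 38:6": -0.12,
    "TAG 58:8": -0.12,
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters; defaults are the emulated study's design."""

    # cohort sizes and demographics
    n_volunteers: int = 604
    n_patients: int = 32
    n_controls: int = 21
    pct_female: float = 0.72
    age_mean: float = 30.0
    age_sd: float = 10.0
    age_min: float = 18.0
    age_max: float = 70.0
    patient_age_mean: float = 33.0
    patient_age_sd: float = 13.0
    patient_pct_female: float = 0.47
    control_age_mean: float = 29.0
    control_age_sd: float = 8.0
    control_pct_female: float = 0.52
    bmi_mean: float = 24.0
    bmi_sd: float = 4.0
    bmi_min: float = 15.0
    bmi_max: float = 45.0

    # latent-item HADS model (calibrated constants; see calibration script)
    rho_latent: float = 0.6875
    sigma_item: float = 1.0
    tau_a: tuple[float, float, float] = (-0.528278, 1.142130, 2.678864)
    tau_d: tuple[float, float, float] = (0.337775, 1.406331, 2.994790)
    age_to_anx: float = -0.245
    sex_to_anx: float = 0.17
    age_to_dep: float = -0.10
    #: corr(HADS-D score, depression latent) under the calibrated model;
    #: converts target lipid-score correlations into latent loadings.
    lambda_d: float = 0.861184
    #: residual attenuation of realized lipid–score correlations beyond
    #: lambda_d (covariate residualization plus post-processing residue),
    #: measured end-to-end and compensated so the analysis-level correlations
    #: land on the target anchors.
    effect_attenuation: float = 0.96

    # lipid panel
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    panel_seed: int = 20240604
    rho_class: float = 0.4
    base_log2_mean_range: tuple[float, float] = (12.0, 20.0)
    lipid_sd_log_mean: float = -0.75  # lognormal log2-SD: median ~0.47
    lipid_sd_log_sd: float = 0.30

    # effect model
    background_r_sd: float = 0.012
    ether_r_shift: float = -0.012
    dbi_r_slope: float = -0.006
    r_clip: float = 0.05
    #: global multiplier on the whole association-target vector; 0 gives a
    #: fully null lipidome (type-I-error calibration input)
    effect_scale: float = 1.0
    covariate_loading_sd: float = 0.12  # log2 units per standardized covariate

    # clinical fold-change model: delta = fc_scale * r + discordance + noise
    fc_scale: float = 2.0
    fc_noise_sd: float = 0.08
    tag_discordance: float = 0.30
    sat_tag_dbi_max: float = 1.0

    # technical layer
    batch_size: int = 96
    qc_period: int = 12
    n_blanks: int = 6
    batch_shift_sd: float = 0.3
    temporal_offset_sd: float = 0.4
    qc_noise_sd: float = 0.08
    ltr_noise_sd: float = 0.08
    blank_log2_offset: float = -7.0
    blank_noise_sd: float = 0.3
    dropout_rate: float = 0.02
    planted_zero_rate: float = 0.20
    n_contaminants: int = 10
    n_unstable: int = 6
    n_high_zero: int = 8
    contaminant_blank_delta: float = 0.2
    unstable_qc_sd: float = 0.9

    def validate(self) -> None:
        if any(c < 1 for c in self.class_counts.values()):
            raise GeneratorError("class counts must be positive")
        if not (self.tau_a[0] < self.tau_a[1] < self.tau_a[2]):
            raise GeneratorError("tau_a thresholds must be strictly increasing")
        if not (self.tau_d[0] < self.tau_d[1] < self.tau_d[2]):
            raise GeneratorError("tau_d thresholds must be strictly increasing")
        for name in ("age_sd", "bmi_sd", "sigma_item"):
            if getattr(self, name) <= 0:
                raise GeneratorError(f"{name} must be positive")
        if not -1.0 <= self.rho_latent <= 1.0:
            raise GeneratorError("rho_latent must lie in [-1, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _trunc_moments(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Mean and SD of the truncated normal actually being sampled, so
    standardized covariates are mean-zero/unit-variance by construction."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    d = stats.truncnorm(a, b, loc=mean, scale=sd)
    return float(d.mean()), float(d.std())


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _items_from_latent(rng, z, tau, sigma):
    prop = z[:, None] + sigma * rng.standard_normal((z.size, 7))
    return np.digitize(prop, np.asarray(tau)).sum(axis=1)


def generate_phenotypes(
    config: GeneratorConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Volunteer phenotypes plus ground-truth latent traits.

    Returns (pheno, latents): pheno has subject_id (index), age, sex, bmi,
    hads_a, hads_d, cohort; latents has z_anx, z_dep (the standardized latent
    severities the lipid effects act on).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_volunteers
    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            config.age_min, config.age_max, n)
    female = rng.random(n) < config.pct_female
    bmi = _truncated_normal(rng, config.bmi_mean, config.bmi_sd,
                            config.bmi_min, config.bmi_max, n)
    age_m, age_s = _trunc_moments(config.age_mean, config.age_sd,
                                  config.age_min, config.age_max)
    age_std = (age - age_m) / age_s
    p = config.pct_female
    sex_std = (female.astype(float) - p) / np.sqrt(p * (1 - p))

    rho = config.rho_latent
    e = rng.standard_normal((n, 2))
    e_anx = e[:, 0]
    e_dep = rho * e[:, 0] + np.sqrt(1 - rho**2) * e[:, 1]

    a1, a2, d1 = config.age_to_anx, config.sex_to_anx, config.age_to_dep
    z_anx = a1 * age_std + a2 * sex_std + np.sqrt(max(1 - a1**2 - a2**2, 0.0)) * e_anx
    z_dep = d1 * age_std + np.sqrt(1 - d1**2) * e_dep

    hads_a = _items_from_latent(rng, z_anx, config.tau_a, config.sigma_item)
    hads_d = _items_from_latent(rng, z_dep, config.tau_d, config.sigma_item)

    ids = pd.Index([f"V{i:04d}" for i in range(n)], name="subject_id")
    pheno = pd.DataFrame(
        {
            "age": np.round(age, 1),
            "sex": np.where(female, "female", "male"),
            "bmi": np.round(bmi, 1),
            "hads_a": hads_a.astype(int),
            "hads_d": hads_d.astype(int),
            "cohort": "volunteer",
        },
        index=ids,
    )
    latents = pd.DataFrame({"z_anx": z_anx, "z_dep": z_dep}, index=ids)
    return pheno, latents


# ---------------------------------------------------------------------------
# panel / ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """The 'true' study: panel annotation with effect vectors, planted features."""

    panel: pd.DataFrame  # per-lipid: class, ether, dbi, mu, sd, r_target, beta,
    #                      delta, load_age, load_sex, load_bmi
    designated: list[str]
    sat_tag: list[str]
    planted: dict[str, list[str]]  # rule name -> feature names
    planted_profiles: pd.DataFrame  # per planted feature: mu, sd
    ltr_offset: pd.Series  # per feature (panel + planted) LTR material offset

    def to_json(self, path) -> None:
        payload = {
            "panel": self.panel.to_dict(orient="index"),
            "designated": self.designated,
            "sat_tag": self.sat_tag,
            "planted": self.planted,
            "planted_profiles": self.planted_profiles.to_dict(orient="index"),
            "ltr_offset": {k: float(v) for k, v in self.ltr_offset.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _sample_panel_names(config: GeneratorConfig, rng) -> list[str]:
    """Unique shorthand names per class; even carbon counts; designated forced in."""
    designated = {name: parse_lipid_name(name) for name in DESIGNATED_EFFECTS}
    names: list[str] = []
    for cls, count in config.class_counts.items():
        (c_lo, c_hi), (d_lo, d_hi) = _CLASS_RANGES[cls]
        pool = [
            (c, d)
            for c in range(c_lo, c_hi + 1, 2)
            for d in range(d_lo, d_hi + 1)
        ]
        forced = [
            (s.carbons, s.double_bonds)
            for s in designated.values()
            if s.lipid_class == cls
        ]
        if cls == "TAG":
            # guarantee a saturated block (double-bond index < 1, i.e. db <= 2)
            sat_pool = [p for p in pool if p[1] <= 2 and p not in forced]
            sat_pick = [tuple(p) for p in
                        np.array(sat_pool)[rng.choice(len(sat_pool), 12, replace=False)]]
            forced = forced + sat_pick
        rest = [p for p in pool if p not in forced]
        need = count - len(forced)
        if need < 0 or need > len(rest):
            raise GeneratorError(f"cannot draw {count} species for class {cls}")
        picked = [tuple(p) for p in
                  np.array(rest)[rng.choice(len(rest), need, replace=False)]]
        names.extend(format_lipid_name(cls, c, d) for c, d in forced + picked)
    return names


def build_ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Deterministic 'true study' from config.panel_seed."""
    config.validate()
    rng = np.random.default_rng(config.panel_seed)
    names = _sample_panel_names(config, rng)
    species = {n: parse_lipid_name(n) for n in names}

    lo, hi = config.base_log2_mean_range
    mu = rng.uniform(lo, hi, size=len(names))
    sd = np.exp(rng.normal(config.lipid_sd_log_mean, config.lipid_sd_log_sd,
                           size=len(names)))

    ether = np.array([species[n].ether for n in names])
    dbi = np.array([float(species[n].dbi) for n in names])
    cls = np.array([species[n].lipid_class for n in names])
    sat_tag = (cls == "TAG") & (dbi < config.sat_tag_dbi_max)

    r = (
        config.ether_r_shift * ether
        + config.dbi_r_slope * (dbi - 1.5)
        + rng.normal(0.0, config.background_r_sd, size=len(names))
    )
    r = np.clip(r, -config.r_clip, config.r_clip)
    # saturated TAGs: weakly negative by construction (discordance sign anchor)
    r[sat_tag] = -np.abs(rng.normal(0.02, 0.008, size=sat_tag.sum()))
    r[sat_tag] = np.minimum(r[sat_tag], -0.005)
    for name, target in DESIGNATED_EFFECTS.items():
        r[names.index(name)] = target
    r = r * config.effect_scale

    beta = r / (config.lambda_d * config.effect_attenuation)

    delta = config.fc_scale * r + rng.normal(0.0, config.fc_noise_sd, size=len(names))
    delta[sat_tag] = np.maximum(
        config.tag_discordance + rng.normal(0.0, config.fc_noise_sd,
                                            size=sat_tag.sum()),
        0.05,
    )

    loads = rng.normal(0.0, config.covariate_loading_sd, size=(len(names), 3))

    panel = pd.DataFrame(
        {
            "class": cls,
            "ether": ether,
            "dbi": dbi,
            "mu": mu,
            "sd": sd,
            "r_target": r,
            "beta": beta,
            "delta": delta,
            "load_age": loads[:, 0],
            "load_sex": loads[:, 1],
            "load_bmi": loads[:, 2],
        },
        index=pd.Index(names, name="lipid"),
    )

    planted = {
        "zero_fraction": [f"SYN-HIZERO-{i + 1:02d}" for i in range(config.n_high_zero)],
        "blank_delta": [f"SYN-CONTAM-{i + 1:02d}" for i in range(config.n_contaminants)],
        "qc_sd": [f"SYN-UNSTABLE-{i + 1:02d}" for i in range(config.n_unstable)],
    }
    planted_names = [n for group in planted.values() for n in group]
    planted_profiles = pd.DataFrame(
        {
            "mu": rng.uniform(lo, hi, size=len(planted_names)),
            "sd": np.exp(rng.normal(config.lipid_sd_log_mean, config.lipid_sd_log_sd,
                                    size=len(planted_names))),
        },
        index=pd.Index(planted_names, name="feature"),
    )

    all_features = names + planted_names
    ltr_offset = pd.Series(rng.normal(0.0, 1.0, size=len(all_features)),
                           index=all_features)
    return GroundTruth(
        panel=panel,
        designated=list(DESIGNATED_EFFECTS),
        sat_tag=[n for n, s in zip(names, sat_tag) if s],
        planted=planted,
        planted_profiles=planted_profiles,
        ltr_offset=ltr_offset,
    )


# ---------------------------------------------------------------------------
# lipidomes
# ---------------------------------------------------------------------------

def _class_correlated_noise(rng, cls: np.ndarray, n: int, rho: float) -> np.ndarray:
    """Standard normal noise with equicorrelation rho within each class block."""
    classes = pd.unique(cls)
    g = rng.standard_normal((n, len(classes)))
    class_idx = {c: j for j, c in enumerate(classes)}
    shared = g[:, [class_idx[c] for c in cls]]
    eps = rng.standard_normal((n, cls.size))
    return np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps


def _covariate_terms(panel: pd.DataFrame, pheno: pd.DataFrame,
                     config: GeneratorConfig) -> np.ndarray:
    # volunteer-cohort scale for every cohort, so loadings are comparable
    age_m, age_s = _trunc_moments(config.age_mean, config.age_sd,
                                  config.age_min, config.age_max)
    bmi_m, bmi_s = _trunc_moments(config.bmi_mean, config.bmi_sd,
                                  config.bmi_min, config.bmi_max)
    age_std = (pheno["age"].to_numpy(float) - age_m) / age_s
    p = config.pct_female
    sex_std = ((pheno["sex"] == "female").to_numpy(float) - p) / np.sqrt(p * (1 - p))
    bmi_std = (pheno["bmi"].to_numpy(float) - bmi_m) / bmi_s
    C = np.column_stack([age_std, sex_std, bmi_std])
    L = panel[["load_age", "load_sex", "load_bmi"]].to_numpy(float)
    return C @ L.T


def generate_lipidome(
    pheno: pd.DataFrame,
    latents: pd.DataFrame,
    config: GeneratorConfig,
    seed: int,
    ground_truth: GroundTruth | None = None,
) -> tuple[IntensityTable, GroundTruth]:
    """Clean log2 volunteer lipidome with planted HADS-D effects.

    Per subject: class-correlated Gaussian baseline, mixed with the
    standardized depression latent at loading beta (variance-preserving), plus
    age/sex/BMI loadings in log2 units.
    """
    gt = ground_truth or build_ground_truth(config)
    if len(pheno) != len(latents):
        raise GeneratorError("pheno and latents must align")
    rng = np.random.default_rng(seed)
    panel = gt.panel
    n = len(pheno)
    u = _class_correlated_noise(rng, panel["class"].to_numpy(), n, config.rho_class)
    beta = panel["beta"].to_numpy(float)
    z = latents["z_dep"].to_numpy(float)
    x = np.sqrt(np.maximum(1 - beta**2, 0.0)) * u + z[:, None] * beta[None, :]
    values = (
        panel["mu"].to_numpy(float)[None, :]
        + panel["sd"].to_numpy(float)[None, :] * x
        + _covariate_terms(panel, pheno, config)
    )
    df = pd.DataFrame(values, index=pheno.index, columns=panel.index)
    idx = pheno.index
    table = IntensityTable(
        values=df,
        role=pd.Series("plasma", index=idx),
        batch=pd.Series(1, index=idx),
        temporal_batch=pd.Series(1, index=idx),
        scale="log2",
    )
    return table, gt


def generate_clinical(
    ground_truth: GroundTruth, config: GeneratorConfig, seed: int
) -> tuple[IntensityTable, pd.Series, pd.DataFrame]:
    """Clinical cohort: 32 patients shifted by delta, 21 matched controls.

    Returns (clean log2 table, labels [1 = patient], clinical phenotypes).
    """
    if config.n_patients < 1 or config.n_controls < 1:
        raise GeneratorError("clinical cohort sizes must be positive")
    rng = np.random.default_rng(seed)
    panel = ground_truth.panel
    groups = []
    phenos = []
    for label, n, age_m, age_s, pf, prefix in (
        (1, config.n_patients, config.patient_age_mean, config.patient_age_sd,
         config.patient_pct_female, "P"),
        (0, config.n_controls, config.control_age_mean, config.control_age_sd,
         config.control_pct_female, "C"),
    ):
        age = _truncated_normal(rng, age_m, age_s, config.age_min, config.age_max, n)
        female = rng.random(n) < pf
        bmi = _truncated_normal(rng, config.bmi_mean, config.bmi_sd,
                                config.bmi_min, config.bmi_max, n)
        ids = pd.Index([f"{prefix}{i:03d}" for i in range(n)], name="subject_id")
        ph = pd.DataFrame(
            {
                "age": np.round(age, 1),
                "sex": np.where(female, "female", "male"),
                "bmi": np.round(bmi, 1),
                "hads_a": np.nan,
                "hads_d": np.nan,
                "cohort": "patient" if label else "control",
            },
            index=ids,
        )
        u = _class_correlated_noise(rng, panel["class"].to_numpy(), n, config.rho_class)
        values = (
            panel["mu"].to_numpy(float)[None, :]
            + panel["sd"].to_numpy(float)[None, :] * u
            + _covariate_terms(panel, ph, config)
        )
        if label:
            values = values + panel["delta"].to_numpy(float)[None, :]
        groups.append(pd.DataFrame(values, index=ids, columns=panel.index))
        phenos.append(ph)
    values = pd.concat(groups)
    pheno = pd.concat(phenos)
    labels = pd.Series(
        (pheno["cohort"] == "patient").astype(int), index=pheno.index, name="label"
    )
    idx = values.index
    table = IntensityTable(
        values=values,
        role=pd.Series("plasma", index=idx),
        batch=pd.Series(1, index=idx),
        temporal_batch=pd.Series(1, index=idx),
        scale="log2",
    )
    return table, labels, pheno


# ---------------------------------------------------------------------------
# technical layer
# ---------------------------------------------------------------------------

def apply_technical_layer(
    clean: IntensityTable,
    config: GeneratorConfig,
    seed: int,
    ground_truth: GroundTruth | None = None,
) -> IntensityTable:
    """Raw-scale acquisition table: batches, QC/LTR/blanks, zeros, planted features.

    Per-batch per-feature shifts apply to every role (so QC correction can
    remove them); the temporal drift between the two measurement epochs
    applies to plasma/LTR/blank but not QC (batch-local QC pools track their
    own batch, so long-term drift is only visible against the LTR material).
    """
    if clean.scale != "log2":
        raise GeneratorError("technical layer expects a clean log2 table")
    gt = ground_truth or build_ground_truth(config)
    planted_names = [n for grp in gt.planted.values() for n in grp]
    if len(planted_names) >= config.batch_size:
        raise GeneratorError("more planted features than a batch can carry")
    rng = np.random.default_rng(seed)

    plasma_ids = list(clean.sample_ids)
    n_plasma = len(plasma_ids)
    n_batches = int(np.ceil(n_plasma / config.batch_size))

    # plasma log2 values for panel + planted features
    planted_mu = gt.planted_profiles["mu"].to_numpy(float)
    planted_sd = gt.planted_profiles["sd"].to_numpy(float)
    planted_plasma = planted_mu[None, :] + planted_sd[None, :] * rng.standard_normal(
        (n_plasma, len(planted_names))
    )
    plasma_log2 = pd.concat(
        [
            clean.values,
            pd.DataFrame(planted_plasma, index=clean.values.index,
                         columns=planted_names),
        ],
        axis=1,
    )
    features = list(plasma_log2.columns)
    m = len(features)
    unstable_mask = np.isin(features, gt.planted["qc_sd"])
    contam_mask = np.isin(features, gt.planted["blank_delta"])
    hizero_mask = np.isin(features, gt.planted["zero_fraction"])

    plasma_mean = plasma_log2.mean(axis=0).to_numpy(float)
    ltr_profile = plasma_mean + gt.ltr_offset[features].to_numpy(float)

    batch_shift = rng.normal(0.0, config.batch_shift_sd, size=(n_batches, m))
    temporal_drift = rng.normal(0.0, config.temporal_offset_sd, size=m)
    tb_of_batch = np.where(np.arange(n_batches) < (n_batches + 1) // 2, 1, 2)
    if n_batches == 1:
        tb_of_batch[:] = 1

    rows: list[np.ndarray] = []
    ids: list[str] = []
    roles: list[str] = []
    batches: list[int] = []
    tbs: list[int] = []

    def add(row, sid, role, b):
        rows.append(row)
        ids.append(sid)
        roles.append(role)
        batches.append(b + 1)
        tbs.append(int(tb_of_batch[b]))

    def qc_row(pool_mean, b):
        noise_sd = np.where(unstable_mask, config.unstable_qc_sd, config.qc_noise_sd)
        return pool_mean + batch_shift[b] + noise_sd * rng.standard_normal(m)

    def ltr_row(b):
        row = ltr_profile + batch_shift[b] + config.ltr_noise_sd * rng.standard_normal(m)
        if tb_of_batch[b] == 2:
            row = row + temporal_drift
        return row

    def blank_row(b):
        row = np.where(
            contam_mask,
            plasma_mean - config.contaminant_blank_delta
            + 0.1 * rng.standard_normal(m),
            plasma_mean + config.blank_log2_offset
            + config.blank_noise_sd * rng.standard_normal(m),
        )
        row = row + batch_shift[b]
        if tb_of_batch[b] == 2:
            row = row + temporal_drift
        return row

    blanks_left = config.n_blanks
    for b in range(n_batches):
        start, stop = b * config.batch_size, min((b + 1) * config.batch_size, n_plasma)
        batch_ids = plasma_ids[start:stop]
        pool_mean = plasma_log2.iloc[start:stop].mean(axis=0).to_numpy(float)
        n_qc = 1 + len(batch_ids) // config.qc_period
        n_ltr = max(len(batch_ids) // config.qc_period, 1)
        for i in range(n_qc):
            add(qc_row(pool_mean, b), f"QC_b{b + 1}_{i + 1}", "qc", b)
        for i in range(n_ltr):
            add(ltr_row(b), f"LTR_b{b + 1}_{i + 1}", "ltr", b)
        for sid in batch_ids:
            row = plasma_log2.loc[sid].to_numpy(float) + batch_shift[b]
            if tb_of_batch[b] == 2:
                row = row + temporal_drift
            add(row, sid, "plasma", b)
        if blanks_left > 0:
            add(blank_row(b), f"BLANK_b{b + 1}", "blank", b)
            blanks_left -= 1

    log2_matrix = np.vstack(rows)
    raw = np.power(2.0, log2_matrix)

    # dropout zeros on plasma entries: detection-limit censoring — the lowest
    # raw intensities of a feature fall below the limit and read as zero, so
    # the 0.9 x min-nonzero imputation recovers them nearly exactly
    role_arr = np.array(roles)
    plasma_rows = role_arr == "plasma"
    drop_p = np.where(hizero_mask, config.planted_zero_rate, config.dropout_rate)
    if drop_p.max() > 0:
        sub = raw[plasma_rows]
        # per-feature jitter of the censoring rate so zero counts vary
        rate = np.clip(drop_p * rng.uniform(0.75, 1.25, size=m), 0.0, 0.95)
        limits = np.quantile(sub, rate, axis=0, method="lower").diagonal()
        mask = sub < limits[None, :]
        all_zero = mask.all(axis=0)
        mask[:, all_zero] = False
        sub[mask] = 0.0
        raw[plasma_rows] = sub

    idx = pd.Index(ids, name="sample_id")
    return IntensityTable(
        values=pd.DataFrame(raw, index=idx, columns=features),
        role=pd.Series(roles, index=idx),
        batch=pd.Series(batches, index=idx),
        temporal_batch=pd.Series(tbs, index=idx),
        scale="raw",
    )
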