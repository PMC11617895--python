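import numpy as np
import pandas as pd
import pytest

from lipidhads.association import correlate_with_scale, residualize
from lipidhads.lipid_annotation import parse_lipid_name
from lipidhads.preprocessing import run_postprocessing
from lipidhads.synthetic_data import (
    DESIGNATED_EFFECTS,
    GeneratorConfig,
    GeneratorError,
    apply_technical_layer,
    build_ground_truth,
    generate_clinical,
    generate_lipidome,
    generate_phenotypes,
)


class TestPhenotypes:
    def test_scores_bounded_for_any_parameters(self):
        cfg = GeneratorConfig(n_volunteers=300, sigma_item=3.0,
                              tau_a=(-2.0, 0.0, 0.5), tau_d=(-1.0, -0.5, 0.2))
        ph, _ = generate_phenotypes(cfg, 0)
        for col in ("hads_a", "hads_d"):
            assert ph[col].between(0, 21).all()
        assert ph["age"].between(cfg.age_min, cfg.age_max).all()

    def test_degenerate_limit_equal_subscales(self):
        # no item noise, perfectly shared latent, identical thresholds,
        # no covariate couplings: the two subscales coincide
        cfg = GeneratorConfig(
            n_volunteers=200, sigma_item=1e-9, rho_latent=1.0,
            tau_a=(0.3, 1.4, 3.0), tau_d=(0.3, 1.4, 3.0),
            age_to_anx=0.0, sex_to_anx=0.0, age_to_dep=0.0,
        )
        ph, _ = generate_phenotypes(cfg, 0)
        assert (ph["hads_a"] == ph["hads_d"]).all()

    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(n_volunteers=100)
        a, la = generate_phenotypes(cfg, 5)
        b, lb = generate_phenotypes(cfg, 5)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(la, lb)

    def test_invalid_thresholds_error(self):
        cfg = GeneratorConfig(tau_d=(1.0, 0.5, 2.0))
        with pytest.raises(GeneratorError):
            generate_phenotypes(cfg, 0)


class TestGroundTruth:
    def test_panel_size_and_classes(self, ground_truth):
        panel = ground_truth.panel
        assert len(panel) == 186
        assert panel["class"].nunique() == 14
        counts = panel["class"].value_counts()
        assert counts["TAG"] == 60 and counts["PC O-"] == 14

    def test_all_names_parse_and_designated_present(self, ground_truth):
        for name in ground_truth.panel.index:
            parse_lipid_name(name)
        assert set(DESIGNATED_EFFECTS) <= set(ground_truth.panel.index)
        for name, target in DESIGNATED_EFFECTS.items():
            assert ground_truth.panel.loc[name, "r_target"] == target

    def test_planted_sets_disjoint(self, ground_truth):
        groups = list(ground_truth.planted.values())
        names = [n for g in groups for n in g]
        assert len(names) == len(set(names))
        assert not set(names) & set(ground_truth.panel.index)

    def test_saturated_tag_block_discordant_by_construction(self, ground_truth):
        panel = ground_truth.panel
        sat = panel.loc[ground_truth.sat_tag]
        assert (sat["class"] == "TAG").all() and (sat["dbi"] < 1).all()
        assert (sat["r_target"] < 0).all()
        assert (sat["delta"] > 0).all()

    def test_deterministic(self, default_config, ground_truth):
        again = build_ground_truth(default_config)
        pd.testing.assert_frame_equal(again.panel, ground_truth.panel)


class TestLipidome:
    def test_null_config_yields_no_associations(self):
        cfg = GeneratorConfig(n_volunteers=250, effect_scale=0.0)
        gt = build_ground_truth(cfg)
        ph, la = generate_phenotypes(cfg, 0)
        clean, _ = generate_lipidome(ph, la, cfg, 1, gt)
        resid = residualize(clean.values, ph[["age", "sex", "bmi"]])
        assoc = correlate_with_scale(resid, ph["hads_d"], n_boot=0)
        assert (assoc["q"] < 0.1).sum() <= 2

    def test_designated_lipids_carry_largest_effects(self, default_config,
                                                     ground_truth):
        hits = 0
        for s in range(5):
            ph, la = generate_phenotypes(default_config, 100 + s)
            clean, _ = generate_lipidome(ph, la, default_config, 200 + s,
                                         ground_truth)
            resid = residualize(clean.values, ph[["age", "sex", "bmi"]])
            assoc = correlate_with_scale(resid, ph["hads_d"], n_boot=0)
            top8 = set(assoc["r"].abs().nlargest(8).index)
            hits += len(top8 & set(DESIGNATED_EFFECTS))
        assert hits >= 30  # >= 6/8 on average across seeds

    def test_confounding_inflates_naive_correlation(self):
        # with beta = 0 but age loadings on lipids and age in the depression
        # latent, unadjusted correlations exceed residualized ones on average
        cfg = GeneratorConfig(n_volunteers=400, effect_scale=0.0,
                              covariate_loading_sd=0.4, age_to_dep=-0.35)
        gt = build_ground_truth(cfg)
        ph, la = generate_phenotypes(cfg, 3)
        clean, _ = generate_lipidome(ph, la, cfg, 4, gt)
        naive = clean.values.apply(
            lambda c: abs(np.corrcoef(c, ph["hads_d"])[0, 1])
        )
        resid = residualize(clean.values, ph[["age", "sex", "bmi"]])
        adj = correlate_with_scale(resid, ph["hads_d"], n_boot=0)["r"].abs()
        assert naive.mean() > adj.mean()


class TestClinical:
    def test_sizes_and_labels(self, default_config, ground_truth):
        table, labels, pheno = generate_clinical(ground_truth, default_config, 0)
        assert (labels == 1).sum() == 32 and (labels == 0).sum() == 21
        assert set(pheno["cohort"]) == {"patient", "control"}
        assert table.values.shape == (53, 186)

    def test_patients_shifted_by_delta(self, default_config, ground_truth):
        deltas = []
        for s in range(10):
            table, labels, _ = generate_clinical(ground_truth, default_config, s)
            deltas.append(
                table.values.loc[labels == 1].mean()
                - table.values.loc[labels == 0].mean()
            )
        est = pd.concat(deltas, axis=1).mean(axis=1)
        true = ground_truth.panel["delta"]
        # recovered within a few SEM of the planted fold-change vector
        resid = (est - true).abs()
        assert resid.mean() < 0.15


class TestTechnicalLayer:
    def test_roundtrip_recovers_clean_feature_set(self, default_config,
                                                  ground_truth):
        ph, la = generate_phenotypes(default_config, 11)
        clean, _ = generate_lipidome(ph, la, default_config, 12, ground_truth)
        raw = apply_technical_layer(clean, default_config, 13, ground_truth)
        assert raw.scale == "raw"
        processed, reports = run_postprocessing(raw)
        assert list(processed.feature_names) == list(clean.feature_names)
        by_step = {r.step: set(r.removed_features) for r in reports}
        for rule, names in ground_truth.planted.items():
            assert by_step[rule] == set(names)

    def test_batch_structure(self, default_config, ground_truth):
        ph, la = generate_phenotypes(default_config, 21)
        clean, _ = generate_lipidome(ph, la, default_config, 22, ground_truth)
        raw = apply_technical_layer(clean, default_config, 23, ground_truth)
        for b in raw.batch.unique():
            roles = raw.role[raw.batch == b]
            assert (roles == "qc").any()
        assert set(raw.temporal_batch) == {1, 2}
        for tb in (1, 2):
            assert ((raw.temporal_batch == tb) & (raw.role == "ltr")).any()

    def test_zero_technical_config_is_identity(self):
        cfg = GeneratorConfig(
            n_volunteers=80, batch_size=200, n_blanks=1,
            batch_shift_sd=0.0, temporal_offset_sd=0.0,
            qc_noise_sd=0.0, ltr_noise_sd=0.0, blank_noise_sd=0.0,
            dropout_rate=0.0, planted_zero_rate=0.0,
            n_contaminants=0, n_unstable=0, n_high_zero=0,
        )
        gt = build_ground_truth(cfg)
        ph, la = generate_phenotypes(cfg, 0)
        clean, _ = generate_lipidome(ph, la, cfg, 1, gt)
        raw = apply_technical_layer(clean, cfg, 2, gt)
        processed, reports = run_postprocessing(raw)
        assert all(not r.removed_features for r in reports)
        out = processed.values.loc[clean.values.index]
        shift = (out - clean.values).to_numpy()
        # single batch, no noise: QC correction is the only transform and
        # cancels exactly, so the table comes back unchanged
        assert np.abs(shift).max() < 1e-9

    def test_byte_identical_given_seed(self, default_config, ground_truth):
        ph, la = generate_phenotypes(default_config, 31)
        clean, _ = generate_lipidome(ph, la, default_config, 32, ground_truth)
        a = apply_technical_layer(clean, default_config, 33, ground_truth)
        b = apply_technical_layer(clean, default_config, 33, ground_truth)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
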