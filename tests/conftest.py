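import numpy as np
import pandas as pd
import pytest

from lipidhads.preprocessing import IntensityTable
from lipidhads.synthetic_data import GeneratorConfig, build_ground_truth


def make_table(
    values: dict[str, list[float]],
    roles: list[str],
    batch: list[int] | None = None,
    temporal_batch: list[int] | None = None,
    scale: str = "raw",
) -> IntensityTable:
    """Small intensity table from per-feature value lists."""
    n = len(roles)
    idx = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    return IntensityTable(
        values=pd.DataFrame(values, index=idx, dtype=float),
        role=pd.Series(roles, index=idx),
        batch=pd.Series(batch or [1] * n, index=idx),
        temporal_batch=pd.Series(temporal_batch or [1] * n, index=idx),
        scale=scale,
    )


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def ground_truth(default_config):
    return build_ground_truth(default_config)


@pytest.fixture(scope="session")
def study_artifacts(default_config, ground_truth):
    """Twenty full pipeline runs at study scale, shared by the slower checks.

    Per seed: phenotypes, processed plasma matrix, HADS-D association table,
    permutation p-value, clinical fold-changes and congruence subsets.
    """
    from lipidhads.association import (
        correlate_with_scale,
        permutation_test,
        residualize,
    )
    from lipidhads.congruence import effect_congruence, fold_changes
    from lipidhads.lipid_annotation import parse_lipid_name
    from lipidhads.preprocessing import run_postprocessing
    from lipidhads.synthetic_data import (
        apply_technical_layer,
        generate_clinical,
        generate_lipidome,
        generate_phenotypes,
    )

    cfg, gt = default_config, ground_truth
    runs = []
    species = None
    for s in range(20):
        ph, la = generate_phenotypes(cfg, s)
        clean, _ = generate_lipidome(ph, la, cfg, 1000 + s, gt)
        raw = apply_technical_layer(clean, cfg, 2000 + s, gt)
        proc, reports = run_postprocessing(raw)
        m = proc.values.loc[ph.index]
        if species is None:
            species = {n: parse_lipid_name(n) for n in m.columns}
        resid = residualize(m, ph[["age", "sex", "bmi"]])
        assoc = correlate_with_scale(resid, ph["hads_d"], n_boot=0)
        perm = permutation_test(resid, ph["hads_d"], B=200, fdr=0.1, seed=4000 + s)
        clin, labels, _ = generate_clinical(gt, cfg, 3000 + s)
        fc = fold_changes(clin.values.loc[labels == 1], m)
        congr = {
            sub: effect_congruence(assoc["r"], fc, sub, species, n_boot=0).spearman_c
            for sub in ("all", "no_tag", "ether_only")
        }
        runs.append(
            {
                "pheno": ph,
                "processed": m,
                "reports": reports,
                "assoc": assoc,
                "perm_p": perm.p_perm,
                "congruence": congr,
            }
        )
    return {"runs": runs, "species": species}
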