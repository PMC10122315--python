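"""Shared fixtures.

The expensive simulation studies (null calibration over many seeds, the
planted-DMR pipeline, the bootstrap stability run, the effect-recovery
replicates) are session-scoped so that unit and acceptance tests can share
one computation.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import xwaskit as xk

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_dataset():
    """A small trio dataset with parents and detection p-values."""
    cfg = xk.SyntheticConfig(n_trios_art=20, n_trios_nonart=20, n_cpgs=100,
                             seed=1)
    return xk.generate_trio_dataset(cfg)


@pytest.fixture(scope="session")
def null_calibration():
    """Full pipeline (preprocess -> M1 XWAS -> empirical null -> BH) on
    synthetic null data: 2,000 CpGs, 200 ART + 200 non-ART children, female
    stratum (n = 200), over 50 seeds.

    Returns the raw p < 0.05 fraction of the first seed and the list of
    FDR < 0.01 discovery counts across all 50 seeds.
    """
    seeds = [42 + i for i in range(50)]
    discoveries = []
    first_frac = None
    for i, s in enumerate(seeds):
        cfg = xk.SyntheticConfig(n_trios_art=200, n_trios_nonart=200,
                                 n_cpgs=2000, block_rho=0.0,
                                 include_parents=False, seed=s)
        mat, sheet, man, truth = xk.generate_trio_dataset(cfg)
        assert len(truth.entries) == 0
        out = xk.run_full_pipeline(mat, man, sheet, model_id="M1", sex="F",
                                   seed=s + 1)
        p_raw = out.results["p_raw"].to_numpy(dtype=float)
        if i == 0:
            first_frac = float(np.mean(p_raw[np.isfinite(p_raw)] < 0.05))
        q = out.results["q"].to_numpy(dtype=float)
        discoveries.append(int(np.nansum(q < 0.01)))
    return {"first_raw_p_frac": first_frac, "discoveries": discoveries,
            "n_cpgs": 2000, "n_seeds": len(seeds)}


@pytest.fixture(scope="session")
def dmr_recovery_run():
    """Pipeline run with 5 planted 4-CpG regions (delta 0.5 M-units,
    n = 150 girls per exposure group)."""
    planted = [xk.PlantedEffect((b * 4, b * 4 + 3), 0.5, "F")
               for b in (25, 75, 125, 175, 225)]
    cfg = xk.SyntheticConfig(n_trios_art=300, n_trios_nonart=300, n_cpgs=1000,
                             block_size=4, include_parents=False,
                             planted_effects=planted, seed=7)
    mat, sheet, man, truth = xk.generate_trio_dataset(cfg)
    out = xk.run_full_pipeline(mat, man, sheet, model_id="M1", sex="F",
                               seed=11, call_regions=True)
    return {"result": out, "truth": truth}


@pytest.fixture(scope="session")
def bootstrap_run():
    """Stratified bootstrap (n_boot = 100) on a dataset with planted deltas
    0.4 / 0.8 / 1.2 M-units at three CpGs, 120 girls per exposure group."""
    planted = [xk.PlantedEffect(50, 0.4, "F"), xk.PlantedEffect(250, 0.8, "F"),
               xk.PlantedEffect(450, 1.2, "F")]
    # uncompressed probes put every planted CpG in the same standard-error
    # regime, so selection proportions are comparable across deltas
    cfg = xk.SyntheticConfig(n_trios_art=240, n_trios_nonart=240, n_cpgs=600,
                             include_parents=False, type2_compression=1.0,
                             planted_effects=planted, seed=13)
    mat, sheet, man, truth = xk.generate_trio_dataset(cfg)
    _, m_vals, _ = xk.preprocess_pipeline(mat, man, sheet, run_gap_scan=False,
                                          run_bmiq=False)
    summary = xk.bootstrap_consistency(m_vals, sheet, model_id="M1", sex="F",
                                       n_boot=100, fdr=0.01, seed=3)
    return {"summary": summary, "truth": truth,
            "planted_delta": {"cg0000050": 0.4, "cg0000250": 0.8,
                              "cg0000450": 1.2}}


@pytest.fixture(scope="session")
def effect_recovery():
    """200 replicates of a planted single-CpG effect (delta = 0.5 M-units,
    150 girls per group); probes are generated without type II compression so
    the replicates isolate the regression estimator."""
    delta = 0.5
    ests, ses = [], []
    for rep in range(200):
        cfg = xk.SyntheticConfig(
            n_trios_art=300, n_trios_nonart=300, n_cpgs=12,
            include_parents=False, with_detection_p=False,
            type2_compression=1.0,
            planted_effects=[xk.PlantedEffect(5, delta, "F")],
            seed=10_000 + rep)
        mat, sheet, man, _ = xk.generate_trio_dataset(cfg)
        m = xk.beta_to_m(mat.beta)
        res = xk.run_xwas(m, sheet, model_id="M1", sex="F",
                          probes=["cg0000005"])
        ests.append(float(res["effect"].iloc[0]))
        ses.append(float(res["se"].iloc[0]))
    return {"delta": delta, "estimates": np.array(ests), "ses": np.array(ses)}
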