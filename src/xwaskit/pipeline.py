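"""End-to-end drivers tying the stages together.

`analyze_stratum` runs the single-CpG chain (XWAS -> empirical null ->
rescale -> BH) on a preprocessed M-matrix; `run_full_pipeline` additionally
starts from raw betas and applies the QC/normalization chain first.  FDR is
computed within each sex stratum (strata are analyzed one at a time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inflation import EmpiricalNull, adjust_results, estimate_empirical_null
from .preprocess import QCReport, preprocess_pipeline
from .regions import call_dmrs
from .types import DmrResult, MethylationMatrix, ProbeManifest, SampleSheet
from .xwas import run_xwas


@dataclass
class StratumResult:
    """Everything the single-CpG analysis of one (model, sex) stratum yields."""

    results: pd.DataFrame       # per-CpG table incl. z_adj, p_adj, q
    null: EmpiricalNull
    dmrs: list[DmrResult] | None = None
    qc: QCReport | None = None


def analyze_stratum(m_matrix: pd.DataFrame, sheet: SampleSheet,
                    model_id: str = "M1", sex: str = "F", seed: int = 0,
                    fdr: float = 0.01, null_n_iter: int = 5000,
                    null_burn_in: int = 1000, null_min_n: int = 500,
                    manifest: ProbeManifest | None = None,
                    call_regions: bool = False, maxgap_bp: int = 500,
                    p_enter: float = 0.05, min_cpgs: int = 3,
                    ) -> StratumResult:
    res = run_xwas(m_matrix, sheet, model_id=model_id, sex=sex)
    z = res["z_raw"].to_numpy(dtype=float)
    null = estimate_empirical_null(z[np.isfinite(z)], seed=seed,
                                   n_iter=null_n_iter, burn_in=null_burn_in,
                                   min_n=null_min_n)
    adj = adjust_results(res, null)
    dmrs = None
    if call_regions:
        if manifest is None:
            raise ValueError("call_regions=True requires a manifest")
        kids = sheet.children(sex)
        sample_ids = [s for s in kids.index if s in m_matrix.columns]
        dmrs = call_dmrs(adj, m_matrix, manifest, sample_ids,
                         maxgap_bp=maxgap_bp, p_enter=p_enter,
                         min_cpgs=min_cpgs, fdr=fdr,
                         se_scale=null.sigma0)
    return StratumResult(results=adj, null=null, dmrs=dmrs)


def run_full_pipeline(matrix: MethylationMatrix, manifest: ProbeManifest,
                      sheet: SampleSheet, model_id: str = "M1", sex: str = "F",
                      seed: int = 0, fdr: float = 0.01,
                      detection_threshold: float = 0.01,
                      max_unreliable_frac: float = 0.05,
                      run_bmiq: bool = True, run_gap_scan: bool = True,
                      call_regions: bool = False, **stratum_kwargs,
                      ) -> StratumResult:
    """QC/normalize raw betas, then run the stratum analysis."""
    _, m_values, qc = preprocess_pipeline(
        matrix, manifest, sheet, detection_threshold=detection_threshold,
        max_unreliable_frac=max_unreliable_frac, run_bmiq=run_bmiq,
        run_gap_scan=run_gap_scan)
    out = analyze_stratum(m_values, sheet, model_id=model_id, sex=sex,
                          seed=seed, fdr=fdr, manifest=manifest,
                          call_regions=call_regions, **stratum_kwargs)
    out.qc = qc
    return out
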