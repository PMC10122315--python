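"""Bootstrap stability of significant CpGs.

Trios are resampled with replacement separately within the ART and non-ART
strata, so every replicate keeps exactly the original group sizes.  The full
single-CpG analysis — association scan, empirical-null estimation, rescaling
and FDR selection — is re-run per replicate, and the per-CpG proportion of
replicates in which it was selected summarizes how stable each finding is.
The resampling unit is the trio (child plus its parents), which keeps the
parental-adjustment models well defined inside each replicate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inflation import adjust_results, estimate_empirical_null
from .types import SampleSheet, ValidationError
from .xwas import run_xwas


def bootstrap_consistency(m_matrix: pd.DataFrame, sheet: SampleSheet,
                          model_id: str = "M1", sex: str = "F",
                          n_boot: int = 1000, fdr: float = 0.01,
                          seed: int = 0, null_min_n: int = 500,
                          null_n_iter: int = 5000, null_burn_in: int = 1000,
                          ) -> pd.DataFrame:
    """Run ``n_boot`` stratified trio resamples and score per-CpG selection.

    Returns a table with columns probe_id, n_selected, proportion, rank
    (descending proportion, ties broken by probe_id).  Replicate seeds are
    spawned deterministically from ``seed``.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    kids = sheet.children(sex)
    art_ids = list(kids.index[kids["art"] == 1])
    non_ids = list(kids.index[kids["art"] == 0])
    if not art_ids or not non_ids:
        raise ValidationError(
            f"stratum {sex} needs children in both exposure groups "
            f"(ART: {len(art_ids)}, non-ART: {len(non_ids)})")

    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2 ** 31 - 1, size=2 * n_boot)

    counts: pd.Series | None = None
    total_discoveries = 0
    for b in range(n_boot):
        rng = np.random.default_rng(rep_seeds[2 * b])
        resampled = (list(rng.choice(art_ids, size=len(art_ids), replace=True))
                     + list(rng.choice(non_ids, size=len(non_ids), replace=True)))
        res = run_xwas(m_matrix, sheet, model_id=model_id, sex=sex,
                       child_ids=resampled)
        z = res["z_raw"].to_numpy(dtype=float)
        null = estimate_empirical_null(z[np.isfinite(z)],
                                       seed=int(rep_seeds[2 * b + 1]),
                                       n_iter=null_n_iter, burn_in=null_burn_in,
                                       min_n=null_min_n)
        adj = adjust_results(res, null)
        hit = adj.set_index("probe_id")["q"] < fdr
        total_discoveries += int(hit.sum())
        counts = hit.astype(int) if counts is None else counts.add(hit.astype(int),
                                                                   fill_value=0)

    out = pd.DataFrame({
        "probe_id": counts.index,
        "n_selected": counts.to_numpy(dtype=int),
    })
    out["proportion"] = out["n_selected"] / n_boot
    out = out.sort_values(["proportion", "probe_id"],
                          ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["n_boot"] = n_boot
    out.attrs["total_discoveries"] = total_discoveries
    return out.reset_index(drop=True)
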