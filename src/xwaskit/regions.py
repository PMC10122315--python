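"""Region-level statistics: DMR detection and co-methylation windows.

DMR candidates are maximal runs of consecutive CpGs that pass a nominal
p-value screen with a consistent effect direction and inter-CpG gaps no
larger than ``maxgap_bp``.  Each candidate is summarized by the
correlation-adjusted inverse-variance combination of its members' effects:

    w_i = 1 / se_i^2
    B   = sum_i w_i b_i / sum_i w_i
    var(B) = sum_ij w_i w_j R_ij se_i se_j / (sum_i w_i)^2

where R is the empirical correlation of the members' M-values across the
stratum's children.  With R = I this reduces to classical fixed-effect
meta-analysis; with perfectly correlated members no precision is gained.
A region is called significant when it has at least ``min_cpgs`` members and
a BH-adjusted p-value below the FDR threshold.

Co-methylation reports collect all probes within a fixed genomic window
(default 50 kb total, i.e. +/- 25 kb) around a center CpG and compute the
pairwise Pearson correlation matrix with Benjamini-Yekutieli adjusted
p-values over the upper triangle.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import pearsonr

from .inflation import bh_fdr, by_fdr
from .types import CoMethylationReport, DmrResult, ProbeManifest, ValidationError

log = logging.getLogger(__name__)


def find_candidates(results: pd.DataFrame, manifest: ProbeManifest,
                    maxgap_bp: int = 500, p_enter: float = 0.05,
                    p_column: str = "p_adj") -> list[list[str]]:
    """Maximal runs of position-consecutive CpGs with ``p < p_enter``,
    identical effect sign and inter-CpG gap <= ``maxgap_bp``."""
    shared = results["probe_id"][results["probe_id"].isin(manifest.probe_ids)]
    if len(shared) < len(results):
        missing = set(results["probe_id"]) - set(shared)
        raise ValidationError(f"probes absent from manifest: {sorted(missing)[:5]}")
    tab = results.set_index("probe_id")
    ann = manifest.table.loc[tab.index, ["chromosome", "position"]]
    tab = tab.join(ann).sort_values(["chromosome", "position"], kind="stable")

    candidates: list[list[str]] = []
    run: list[str] = []
    prev_pos = prev_sign = prev_chrom = None
    for pid, row in tab.iterrows():
        p = row[p_column]
        passing = np.isfinite(p) and p < p_enter and np.isfinite(row["effect"])
        sign = np.sign(row["effect"]) if passing else None
        if passing and run and row["chromosome"] == prev_chrom \
                and row["position"] - prev_pos <= maxgap_bp and sign == prev_sign:
            run.append(pid)
        else:
            if run:
                candidates.append(run)
            run = [pid] if passing else []
        if passing:
            prev_pos, prev_sign, prev_chrom = row["position"], sign, row["chromosome"]
    if run:
        candidates.append(run)
    return candidates


def dmr_stat(b, se, R) -> tuple[float, float, float, float]:
    """Correlation-adjusted inverse-variance combination of member effects.

    Returns (B, se_B, z, p).  Raises if the combined variance is not
    positive (non-positive-definite correlation input).
    """
    b = np.asarray(b, dtype=float)
    se = np.asarray(se, dtype=float)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    k = len(b)
    if not (len(se) == k and R.shape == (k, k)):
        raise ValidationError("b, se and R must share the member dimension")
    if np.any(se <= 0):
        raise ValidationError("member SEs must be positive")
    w = 1.0 / se ** 2
    sw = w.sum()
    B = float(w @ b / sw)
    var = float((w * se) @ R @ (w * se)) / sw ** 2
    if var <= 0:
        raise ValidationError("combined variance is non-positive; check R")
    se_B = float(np.sqrt(var))
    z = B / se_B
    p = max(2.0 * float(ndtr(-abs(z))), 5e-324)
    return B, se_B, z, p


def member_correlation(m_matrix: pd.DataFrame, probe_ids, sample_ids,
                       min_obs: int = 10) -> np.ndarray:
    """Pairwise-complete Pearson correlation of member M-values across the
    given samples; pairs with fewer than ``min_obs`` complete observations
    are set to 0 with a warning."""
    missing = pd.Index(probe_ids).difference(m_matrix.index)
    if len(missing):
        raise ValidationError(f"candidate members missing from M-matrix: "
                              f"{missing[:5].tolist()}")
    sub = m_matrix.loc[probe_ids, sample_ids].T.astype(float)
    R = sub.corr(min_periods=min_obs).to_numpy()
    counts = sub.notna().astype(int).T @ sub.notna().astype(int)
    low = np.isnan(R) | (counts.to_numpy() < min_obs)
    np.fill_diagonal(low, False)
    if low.any():
        log.warning("member_correlation: %d pairs with < %d complete "
                    "observations set to 0", int(low.sum()) // 2, min_obs)
        R[low] = 0.0
    np.fill_diagonal(R, 1.0)
    return R


def call_dmrs(results: pd.DataFrame, m_matrix: pd.DataFrame,
              manifest: ProbeManifest, sample_ids, maxgap_bp: int = 500,
              p_enter: float = 0.05, min_cpgs: int = 3, fdr: float = 0.01,
              se_scale: float = 1.0, p_column: str = "p_adj",
              scan_subregions: bool = True) -> list[DmrResult]:
    """Detect DMRs from per-CpG summary statistics in one stratum.

    ``sample_ids`` are the stratum's children, used to estimate the member
    M-value correlation matrix.  ``se_scale`` lets the caller propagate an
    empirical-null inflation factor into the member SEs (se * sigma0), so
    that region statistics share the calibration of the single-CpG scan.
    With ``scan_subregions`` (the default) every contiguous sub-run of a
    candidate is evaluated, the best one is kept, and its p-value is
    Bonferroni-corrected by the number of sub-runs scanned.  The correction
    also accounts for the candidate having been *selected* for small member
    p-values: without it, the two-stage procedure is anticonservative over
    co-methylated null blocks (a shared within-block fluctuation yields a
    same-sign run whose combined statistic looks too clean).  Candidates are
    BH-adjusted jointly; a region is significant iff it has at least
    ``min_cpgs`` members and q < ``fdr``.
    """
    candidates = find_candidates(results, manifest, maxgap_bp, p_enter, p_column)
    if not candidates:
        return []
    tab = results.set_index("probe_id")
    out: list[DmrResult] = []
    for members in candidates:
        rows = tab.loc[members]
        pos = manifest.table.loc[members, "position"]
        order = np.argsort(pos.to_numpy(), kind="stable")
        members = [members[i] for i in order]
        rows = rows.iloc[order]
        R = member_correlation(m_matrix, members, sample_ids)
        b_all = rows["effect"].to_numpy()
        se_all = rows["se"].to_numpy() * se_scale
        if scan_subregions and len(members) > 1:
            spans = [(i, j) for i in range(len(members))
                     for j in range(i, len(members))]
            best = None
            for i, j in spans:
                stat = dmr_stat(b_all[i:j + 1], se_all[i:j + 1],
                                R[i:j + 1, i:j + 1])
                if best is None or stat[3] < best[1][3]:
                    best = ((i, j), stat)
            (i, j), (B, se_B, z, p) = best
            members = members[i:j + 1]
            p = min(p * len(spans), 1.0)  # Bonferroni over scanned sub-runs
        else:
            B, se_B, z, p = dmr_stat(b_all, se_all, R)
        chrom = manifest.table.loc[members[0], "chromosome"]
        pos_sorted = manifest.table.loc[members, "position"]
        out.append(DmrResult(
            chromosome=str(chrom), start=int(pos_sorted.iloc[0]),
            end=int(pos_sorted.iloc[-1]), n_cpgs=len(members),
            member_probe_ids=list(members), effect_B=B, se_B=se_B, z=z, p=p))
    q = bh_fdr([d.p for d in out])
    for d, qv in zip(out, q):
        d.q = float(qv)
        d.significant = bool(d.n_cpgs >= min_cpgs and d.q < fdr)
    return out


def comethylation(matrix: pd.DataFrame, manifest: ProbeManifest,
                  center_probe: str, window_bp: int = 50_000,
                  half_window: bool = False, alpha: float = 0.05,
                  min_obs: int = 3) -> CoMethylationReport:
    """Pairwise correlation report for the probes around ``center_probe``.

    The window is ``window_bp`` in total (+/- window_bp/2 around the center),
    closed at its boundaries; ``half_window=True`` switches to +/- window_bp.
    P-values are two-sided per pair and Benjamini-Yekutieli adjusted over the
    upper triangle; entries with adjusted p >= ``alpha`` are reported but
    considered non-significant.
    """
    if center_probe not in manifest.probe_ids:
        raise ValidationError(f"center probe {center_probe!r} not in manifest")
    if center_probe not in matrix.index:
        raise ValidationError(f"center probe {center_probe!r} not in matrix")
    ann = manifest.table
    c_chrom = ann.loc[center_probe, "chromosome"]
    c_pos = ann.loc[center_probe, "position"]
    reach = window_bp if half_window else window_bp // 2
    sel = ann[(ann["chromosome"] == c_chrom)
              & (ann["position"] - c_pos).abs().le(reach)]
    members = [p for p in sel.sort_values("position").index if p in matrix.index]
    k = len(members)
    r = np.eye(k)
    praw = np.full((k, k), np.nan)
    sub = matrix.loc[members].to_numpy(dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(sub[i]) & np.isfinite(sub[j])
            if ok.sum() < min_obs or np.std(sub[i][ok]) == 0 or np.std(sub[j][ok]) == 0:
                rv, pv = 0.0, 1.0
            else:
                rv, pv = pearsonr(sub[i][ok], sub[j][ok])
            r[i, j] = r[j, i] = rv
            praw[i, j] = praw[j, i] = max(pv, 5e-324)
    iu = np.triu_indices(k, 1)
    padj = np.zeros((k, k))
    if len(iu[0]):
        adj = by_fdr(praw[iu])
        padj[iu] = adj
        padj = padj + padj.T
    np.fill_diagonal(padj, 0.0)
    idx = pd.Index(members, name="probe_id")
    return CoMethylationReport(
        center_probe_id=center_probe, window_bp=window_bp,
        member_probe_ids=members,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p_adj=pd.DataFrame(padj, index=idx, columns=idx))


def plot_comethylation(report: CoMethylationReport, path) -> None:
    """Save a simple correlation heatmap for a co-methylation report."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(report.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(report.member_probe_ids)))
    ax.set_yticks(range(len(report.member_probe_ids)))
    ax.set_xticklabels(report.member_probe_ids, rotation=90, fontsize=6)
    ax.set_yticklabels(report.member_probe_ids, fontsize=6)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title(f"Co-methylation around {report.center_probe_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
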