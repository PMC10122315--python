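"""Quality control and normalization of beta-value matrices.

The fixed stage order is: flagged-probe exclusion (cross-reactive probes and
probes whose last three bases overlap a SNP) -> detection-p masking -> greedy
probe/sample filtering -> per-sex multimodality ("gap") scan -> beta-mixture
quantile normalization of type II probes against type I -> logit2 transform
to M-values.  No stage combines information across the sexes: the gap scan is
run per sex, and normalization is strictly per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from .types import GapScan, MethylationMatrix, ProbeManifest, SampleSheet, ValidationError

log = logging.getLogger(__name__)

#: open-interval clip applied before the logit2 transform; well below array
#: quantization, prevents infinite M-values at beta exactly 0 or 1
EPSILON = 1e-6


def beta_to_m(beta):
    """M = log2(beta / (1 - beta)), with beta nudged into (0, 1) by EPSILON."""
    b = np.clip(np.asarray(beta, dtype=float), EPSILON, 1.0 - EPSILON)
    out = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def m_to_beta(m):
    """Inverse logit2: beta = 2^m / (2^m + 1), computed stably."""
    x = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-x))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index)
    return out


def exclude_flagged_probes(matrix: MethylationMatrix,
                           manifest: ProbeManifest) -> MethylationMatrix:
    """Drop cross-reactive probes and probes whose last three bases overlap a
    SNP; relative probe order is preserved."""
    missing = matrix.probes.difference(manifest.probe_ids)
    if len(missing):
        raise ValidationError(f"probes absent from manifest: {missing[:5].tolist()}")
    flags = manifest.table.loc[matrix.probes]
    bad = flags["cross_reactive"].astype(bool) | flags["snp_overlap_last3"].astype(bool)
    keep = matrix.probes[~bad.to_numpy()]
    if len(keep) == 0:
        log.warning("all %d probes flagged for exclusion; empty matrix returned",
                    len(matrix.probes))
    return matrix.subset_probes(keep)


def mask_by_detection(matrix: MethylationMatrix,
                      threshold: float = 0.01) -> MethylationMatrix:
    """Set beta entries with detection p > threshold to missing, then drop
    probes that are missing in every sample."""
    if matrix.detection_p is None:
        raise ValidationError(
            "matrix has no detection p-values; skip the masking stage explicitly "
            "if detection data are unavailable"
        )
    beta = matrix.beta.where(~(matrix.detection_p > threshold))
    keep = beta.index[~beta.isna().all(axis=1).to_numpy()]
    if len(keep) < len(beta.index):
        log.info("mask_by_detection dropped %d all-missing probes",
                 len(beta.index) - len(keep))
    return MethylationMatrix(beta.loc[keep], matrix.detection_p.loc[keep])


def greedy_filter(matrix: MethylationMatrix, max_unreliable_frac: float = 0.05
                  ) -> tuple[MethylationMatrix, list[str], list[str]]:
    """Iteratively remove the single probe OR sample with the highest fraction
    of unreliable (missing) entries until the worst fraction is at or below
    ``max_unreliable_frac``.

    Ties are broken deterministically: a probe wins over a sample, and within
    an axis the lowest index wins.  Fractions are recomputed after every
    removal, so the result depends only on the missingness pattern, not on
    row/column order beyond the documented tie-break.
    """
    miss = matrix.beta.isna().to_numpy()
    probe_keep = np.ones(miss.shape[0], dtype=bool)
    sample_keep = np.ones(miss.shape[1], dtype=bool)
    removed_probes: list[str] = []
    removed_samples: list[str] = []
    while probe_keep.any() and sample_keep.any():
        sub = miss[np.ix_(probe_keep, sample_keep)]
        probe_frac = sub.mean(axis=1)
        sample_frac = sub.mean(axis=0)
        worst_p = probe_frac.max() if len(probe_frac) else 0.0
        worst_s = sample_frac.max() if len(sample_frac) else 0.0
        worst = max(worst_p, worst_s)
        if worst <= max_unreliable_frac:
            break
        if worst_p >= worst_s:  # probe before sample on ties
            local = int(np.argmax(probe_frac))  # argmax -> lowest index on ties
            gi = np.flatnonzero(probe_keep)[local]
            probe_keep[gi] = False
            removed_probes.append(str(matrix.probes[gi]))
        else:
            local = int(np.argmax(sample_frac))
            gi = np.flatnonzero(sample_keep)[local]
            sample_keep[gi] = False
            removed_samples.append(str(matrix.samples[gi]))
    if not probe_keep.any() or not sample_keep.any():
        log.warning("greedy_filter removed an entire axis; empty matrix returned")
    out = matrix.subset_probes(matrix.probes[probe_keep]).subset_samples(
        matrix.samples[sample_keep])
    return out, removed_probes, removed_samples


def detect_gaps(values, gap_threshold: float = 0.05,
                outlier_frac: float = 0.01) -> GapScan:
    """Sorted-gap scan for multimodal beta distributions at one probe.

    Sort the non-missing values; any gap between consecutive sorted values
    larger than ``gap_threshold`` starts a new group.  The probe is flagged as
    genuinely multimodal when there are at least two groups and every group
    holds more than ``outlier_frac * n`` samples (so that a lone outlier does
    not flag the probe).
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    n = len(v)
    if n == 0:
        raise ValidationError("detect_gaps requires at least one non-missing value")
    order = np.argsort(v, kind="stable")
    sv = v[order]
    breaks = np.diff(sv) > gap_threshold
    group_sorted = np.concatenate([[0], np.cumsum(breaks)])
    assignment = np.empty(n, dtype=int)
    assignment[order] = group_sorted
    n_groups = int(group_sorted[-1]) + 1
    sizes = np.bincount(group_sorted)
    flagged = bool(n_groups >= 2 and np.all(sizes > outlier_frac * n))
    return GapScan(n_groups=n_groups, assignment=assignment, flagged=flagged)


def scan_multimodality(matrix: MethylationMatrix, sheet: SampleSheet,
                       gap_threshold: float = 0.05,
                       outlier_frac: float = 0.01) -> pd.DataFrame:
    """Run the gap scan per probe, separately for girls and boys (children
    only); returns a probe x {flagged_F, flagged_M, n_groups_F, n_groups_M}
    table.  Flag-only: no probes are removed here."""
    out = {}
    for sex in ("F", "M"):
        ids = sheet.children(sex).index.intersection(matrix.samples)
        flags, groups = [], []
        for probe in matrix.probes:
            row = matrix.beta.loc[probe, ids]
            if row.notna().sum() == 0:
                flags.append(False)
                groups.append(0)
                continue
            scan = detect_gaps(row, gap_threshold, outlier_frac)
            flags.append(scan.flagged)
            groups.append(scan.n_groups)
        out[f"flagged_{sex}"] = flags
        out[f"n_groups_{sex}"] = groups
    return pd.DataFrame(out, index=matrix.probes)


# ---------------------------------------------------------------------------
# Beta-mixture quantile normalization of type II probes against type I
# ---------------------------------------------------------------------------

def _beta_logpdf(logx, log1mx, a, b):
    # a, b broadcast over the value arrays; betaln handles normalization
    return (a - 1.0) * logx + (b - 1.0) * log1mx - betaln(a, b)


def _moments_to_ab(mean, var):
    """Method-of-moments beta parameters, guarded away from degeneracy."""
    mean = np.clip(mean, 1e-3, 1 - 1e-3)
    var = np.clip(var, 1e-6, mean * (1 - mean) * 0.999)
    common = mean * (1 - mean) / var - 1.0
    a = np.clip(mean * common, 0.05, 500.0)
    b = np.clip((1 - mean) * common, 0.05, 500.0)
    return a, b


def _fit_beta_mixture(values: np.ndarray, max_iter: int = 100,
                      tol: float = 1e-6, prior: tuple | None = None,
                      prior_strength: float = 0.0,
                      init_centers: np.ndarray | None = None):
    """EM fit of a three-state (unmethylated / hemimethylated / methylated)
    beta mixture, vectorized across samples.

    ``values``: (n_samples, n_probes) array in (0, 1); NaN entries are
    ignored.  States (0 = unmethylated, 1 = hemimethylated, 2 = methylated)
    are initialized by assigning each value to the nearest of the per-sample
    0.1 / 0.5 / 0.9 quantiles, which finds the three modes even when the
    distribution is compressed toward 0.5.  The M-step uses weighted
    method-of-moments updates for the beta parameters.

    ``prior`` = (mean0, var0, w0) (each length 3) with ``prior_strength``
    n0 > 0 adds n0*w0_k pseudo-observations with the prior moments to every
    component update, shrinking each sample's fit toward a common fit.  This
    caps the sample-to-sample variance of the normalization map, which would
    otherwise act as a shared technical factor across a sample's probes.

    Returns (a, b, w) each of shape (n_samples, 3) with components sorted by
    mean, plus a per-sample convergence flag.
    """
    x = np.clip(values, EPSILON, 1 - EPSILON)
    obs = ~np.isnan(values)
    x = np.where(obs, x, 0.5)
    S, P = x.shape
    logx, log1mx = np.log(x), np.log1p(-x)

    if prior is not None and prior_strength > 0:
        mean0, var0, w0 = (np.asarray(v, dtype=float) for v in prior)
        n0 = prior_strength * w0
    else:
        mean0 = var0 = None
        n0 = np.zeros(3)

    if init_centers is None:
        centers = np.nanquantile(np.where(obs, x, np.nan), (0.1, 0.5, 0.9),
                                 axis=1).T
    else:
        centers = np.broadcast_to(np.asarray(init_centers, dtype=float),
                                  (S, 3)).copy()
    # guard against collapsed centers on near-constant samples
    centers = np.maximum.accumulate(
        centers + np.array([-1e-6, 0.0, 1e-6]), axis=1)
    init = np.argmin(np.abs(x[..., None] - centers[:, None, :]), axis=-1)
    resp = np.zeros((S, P, 3))
    for k in range(3):
        resp[..., k] = init == k
    resp[~obs] = 0.0

    a = np.empty((S, 3))
    b = np.empty((S, 3))
    w = np.full((S, 3), 1.0 / 3.0)
    prev_ll = np.full(S, -np.inf)
    done = np.zeros(S, dtype=bool)
    active = np.arange(S)  # converged samples drop out of the iteration
    for _ in range(max_iter):
        xa = x[active]
        ra = resp[active]
        oa = obs[active]
        for k in range(3):
            rk = ra[..., k]
            nk = rk.sum(axis=1)
            nk_eff = np.maximum(nk + n0[k], 1e-9)
            sx = (rk * xa).sum(axis=1)
            if mean0 is not None:
                mean = (sx + n0[k] * mean0[k]) / nk_eff
                sv = (rk * (xa - mean[:, None]) ** 2).sum(axis=1)
                sv = sv + n0[k] * (var0[k] + (mean0[k] - mean) ** 2)
                var = sv / nk_eff
            else:
                mean = sx / nk_eff
                var = (rk * (xa - mean[:, None]) ** 2).sum(axis=1) / nk_eff
            empty = nk + n0[k] < 1.0
            mean = np.where(empty, (0.05, 0.5, 0.95)[k], mean)
            var = np.where(empty, 0.01, var)
            a[active, k], b[active, k] = _moments_to_ab(mean, var)
            w[active, k] = nk + n0[k]
        wa = w[active]
        wa /= np.maximum(wa.sum(axis=1, keepdims=True), 1e-9)
        wa = np.clip(wa, 1e-6, 1.0)
        wa /= wa.sum(axis=1, keepdims=True)
        w[active] = wa
        logp = np.stack([
            np.log(wa[:, k])[:, None]
            + _beta_logpdf(logx[active], log1mx[active],
                           a[active, k, None], b[active, k, None])
            for k in range(3)
        ], axis=-1)
        mx = logp.max(axis=-1, keepdims=True)
        pk = np.exp(logp - mx)
        tot = pk.sum(axis=-1, keepdims=True)
        ra = pk / tot
        ra[~oa] = 0.0
        resp[active] = ra
        ll = ((np.log(tot[..., 0]) + mx[..., 0]) * oa).sum(axis=1)
        conv = np.abs(ll - prev_ll[active]) < tol * np.maximum(np.abs(prev_ll[active]), 1.0)
        prev_ll[active] = ll
        done[active] = conv
        active = active[~conv]
        if active.size == 0:
            break
    # canonical ordering: components sorted by mean (U < hemi < M)
    means = a / (a + b)
    order = np.argsort(means, axis=1)
    rows = np.arange(S)[:, None]
    return a[rows, order], b[rows, order], w[rows, order], done, prev_ll


def _pooled_prior(x: np.ndarray, max_iter: int, tol: float,
                  max_points: int = 60_000):
    """Fit the mixture once to the pooled values of a sample group and
    return it as prior moments (mean, var, w) for the per-sample fits.

    The EM is multi-started (data-quantile anchors and fixed 0.1/0.5/0.9
    anchors) and the higher-likelihood solution kept: a single quantile
    start can miss a small outer component (e.g. the minority of
    hypomethylated escape loci) and lose a state entirely, which would
    degrade every downstream per-sample map.
    """
    flat = x[np.isfinite(x)]
    if len(flat) > max_points:
        flat = flat[:: len(flat) // max_points + 1]
    best = None
    for init in (None, np.array([0.1, 0.5, 0.9])):
        a, b, w, _, ll = _fit_beta_mixture(flat[None, :], max_iter, tol,
                                           init_centers=init)
        if best is None or ll[0] > best[3]:
            best = (a[0], b[0], w[0], float(ll[0]))
    a, b, w, _ = best
    mean = a / (a + b)
    var = a * b / ((a + b) ** 2 * (a + b + 1.0))
    return mean, var, w


def bmiq_normalize(matrix: MethylationMatrix, manifest: ProbeManifest,
                   min_type_count: int = 50, max_iter: int = 100,
                   tol: float = 1e-6, groups=None,
                   prior_strength: float = 1000.0) -> MethylationMatrix:
    """Beta-mixture quantile normalization: map type II probe intensities onto
    the type I reference distribution, per sample.

    Per sample, a three-state beta mixture is fit by EM separately to the
    type I and type II betas.  Type I values are returned unchanged.  Type II
    values assigned to the unmethylated and methylated states are quantile
    mapped onto the corresponding type I component (CDF match); middle-state
    values are rescaled by the monotone dilation interpolating between the
    mapped state boundaries.  Within-type rank order is preserved exactly and
    output stays in [0, 1].

    The per-sample fits are stabilized by a pooled prior: the mixture is
    first fit to the pooled values of each sample group, and every sample's
    EM receives ``prior_strength`` pseudo-observations of that fit.  Without
    this, per-sample map estimation noise acts as a shared technical factor
    across a sample's probes and inflates downstream association statistics.
    ``groups`` assigns samples to pooling groups (e.g. the sex of the sample's
    X methylation profile, so that male- and female-profile distributions are
    never pooled); default: one group over all samples.

    Samples whose EM did not converge within ``max_iter`` iterations, or with
    fewer than ``min_type_count`` probes of either type, fall back to identity
    with a logged warning.
    """
    probes = matrix.probes
    missing = probes.difference(manifest.probe_ids)
    if len(missing):
        raise ValidationError(f"probes absent from manifest: {missing[:5].tolist()}")
    dt = manifest.table.loc[probes, "design_type"].to_numpy()
    is2 = dt == "II"
    vals = matrix.beta.to_numpy(dtype=float).T  # samples x probes
    n1 = int((~is2).sum())
    n2 = int(is2.sum())
    if min(n1, n2) < min_type_count:
        log.warning("bmiq: only %d type I / %d type II probes (< %d); identity",
                    n1, n2, min_type_count)
        return matrix

    x1 = vals[:, ~is2]
    x2 = vals[:, is2]
    S = vals.shape[0]
    if groups is None:
        codes = np.zeros(S, dtype=int)
    else:
        groups = pd.Series(groups)
        codes = pd.factorize(groups.reindex(matrix.samples).to_numpy())[0]
    a1 = np.empty((S, 3)); b1 = np.empty((S, 3)); w1 = np.empty((S, 3))
    a2 = np.empty((S, 3)); b2 = np.empty((S, 3)); w2 = np.empty((S, 3))
    ok = np.zeros(S, dtype=bool)
    for g in np.unique(codes):
        sel = codes == g
        p1 = _pooled_prior(x1[sel], max_iter, tol)
        p2 = _pooled_prior(x2[sel], max_iter, tol)
        a1[sel], b1[sel], w1[sel], k1, _ = _fit_beta_mixture(
            x1[sel], max_iter, tol, prior=p1, prior_strength=prior_strength)
        a2[sel], b2[sel], w2[sel], k2, _ = _fit_beta_mixture(
            x2[sel], max_iter, tol, prior=p2, prior_strength=prior_strength)
        ok[sel] = k1 & k2
    if not ok.all():
        log.warning("bmiq: EM did not converge for %d/%d samples; identity "
                    "fallback for those samples", int((~ok).sum()), len(ok))

    S = vals.shape[0]
    obs = ~np.isnan(x2)
    x2c = np.clip(np.where(obs, x2, 0.5), EPSILON, 1 - EPSILON)
    # state assignment of type II values by maximum responsibility
    logx2, log1mx2 = np.log(x2c), np.log1p(-x2c)
    logp = np.stack([
        np.log(w2[:, k])[:, None]
        + _beta_logpdf(logx2, log1mx2, a2[:, k, None], b2[:, k, None])
        for k in range(3)
    ], axis=-1)
    state = np.argmax(logp, axis=-1)

    mapped = x2c.copy()
    # U and M states: CDF quantile map II-component -> I-component, done as
    # two whole-array vectorized transforms.  Beyond the component's usable
    # quantile range the CDF saturates and would pin many values onto one
    # point; there the map continues as a constant shift, staying strictly
    # monotone in the input.
    q_lo, q_hi = 1e-6, 1.0 - 1e-6
    for k in (0, 2):
        sel = obs & (state == k)
        ak2, bk2 = a2[:, k, None], b2[:, k, None]
        ak1, bk1 = a1[:, k, None], b1[:, k, None]
        q = beta_dist.cdf(x2c, ak2, bk2)
        inner = (q > q_lo) & (q < q_hi)
        mk = beta_dist.ppf(np.clip(q, q_lo, q_hi), ak1, bk1)
        lo_shift = (beta_dist.ppf(q_lo, ak1, bk1)
                    - beta_dist.ppf(q_lo, ak2, bk2))
        hi_shift = (beta_dist.ppf(q_hi, ak1, bk1)
                    - beta_dist.ppf(q_hi, ak2, bk2))
        mk = np.where(inner, mk,
                      x2c + np.where(q >= q_hi, hi_shift, lo_shift))
        mapped[sel] = mk[sel]
    # middle state: per-sample monotone dilation between the mapped boundaries
    selu = obs & (state == 0)
    selm = obs & (state == 2)
    selh = obs & (state == 1)
    neg = np.full_like(x2c, -np.inf)
    pos = np.full_like(x2c, np.inf)
    lo_src = np.where(selu, x2c, neg).max(axis=1)
    hi_src = np.where(selm, x2c, pos).min(axis=1)
    lo_dst = np.where(selu, mapped, neg).max(axis=1)
    hi_dst = np.where(selm, mapped, pos).min(axis=1)
    hmin = np.where(selh, x2c, pos).min(axis=1)
    hmax = np.where(selh, x2c, neg).max(axis=1)
    lo_src = np.where(np.isfinite(lo_src), lo_src, hmin)
    hi_src = np.where(np.isfinite(hi_src), hi_src, hmax)
    lo_dst = np.where(np.isfinite(lo_dst), lo_dst, lo_src)
    hi_dst = np.where(np.isfinite(hi_dst), hi_dst, hi_src)
    # samples with no middle-state values never use these; keep them finite
    lo_src = np.where(np.isfinite(lo_src), lo_src, 0.0)
    hi_src = np.where(np.isfinite(hi_src), hi_src, 1.0)
    lo_dst = np.where(np.isfinite(lo_dst), lo_dst, 0.0)
    hi_dst = np.where(np.isfinite(hi_dst), hi_dst, 1.0)
    span_src = np.maximum(hi_src - lo_src, 1e-9)
    span_dst = np.maximum(hi_dst - lo_dst, 1e-9)
    # degenerate spans would crush the middle band onto a point; shift it
    # rigidly instead
    scale = np.where((hi_src - lo_src > 1e-6) & (hi_dst - lo_dst > 1e-6),
                     span_dst / span_src, 1.0)
    dil = lo_dst[:, None] + (x2c - lo_src[:, None]) * scale[:, None]
    mapped[selh] = dil[selh]

    out2 = x2.copy()
    for s in range(S):  # enforce exact within-sample monotonicity
        if not ok[s]:
            continue
        o = obs[s]
        order = np.argsort(x2c[s, o], kind="stable")
        mo = np.maximum.accumulate(mapped[s, o][order])
        tmp = mapped[s, o]
        tmp[order] = mo
        out2[s, o] = np.clip(tmp, 0.0, 1.0)

    new_vals = vals.copy()
    new_vals[:, is2] = out2
    beta = pd.DataFrame(new_vals.T, index=matrix.probes, columns=matrix.samples)
    return MethylationMatrix(beta, matrix.detection_p)


def profile_sex(sheet: SampleSheet) -> pd.Series:
    """Sex of each sample's X methylation profile: children by child_sex,
    mothers female, fathers male.  Used to keep normalization pooling
    within-sex."""
    t = sheet.table
    out = t["child_sex"].copy() if "child_sex" in t.columns else pd.Series(
        index=t.index, dtype=object)
    out[t["role"] == "mother"] = "F"
    out[t["role"] == "father"] = "M"
    return out


@dataclass
class QCReport:
    """Record of what each QC stage removed or flagged."""

    excluded_flagged: list[str] = field(default_factory=list)
    dropped_all_missing: list[str] = field(default_factory=list)
    greedy_removed_probes: list[str] = field(default_factory=list)
    greedy_removed_samples: list[str] = field(default_factory=list)
    gap_flags: pd.DataFrame | None = None
    n_probes_final: int = 0
    n_samples_final: int = 0


def preprocess_pipeline(matrix: MethylationMatrix, manifest: ProbeManifest,
                        sheet: SampleSheet, detection_threshold: float = 0.01,
                        max_unreliable_frac: float = 0.05,
                        gap_threshold: float = 0.05, outlier_frac: float = 0.01,
                        drop_gap_flagged: bool = False,
                        run_bmiq: bool = True,
                        run_gap_scan: bool = True,
                        ) -> tuple[MethylationMatrix, pd.DataFrame, QCReport]:
    """Run the full QC chain in its fixed order and return the cleaned beta
    matrix, the M-value matrix and a QC report.

    Gap-flagged probes are reported, not removed, unless ``drop_gap_flagged``
    (flagged in either sex) is set.
    """
    report = QCReport()
    before = set(map(str, matrix.probes))
    m1 = exclude_flagged_probes(matrix, manifest)
    report.excluded_flagged = sorted(before - set(map(str, m1.probes)))

    if m1.detection_p is not None:
        n_before = len(m1.probes)
        m1 = mask_by_detection(m1, detection_threshold)
        if len(m1.probes) < n_before:
            report.dropped_all_missing = sorted(
                (before - set(report.excluded_flagged)) - set(map(str, m1.probes)))
        m1, rp, rs = greedy_filter(m1, max_unreliable_frac)
        report.greedy_removed_probes = rp
        report.greedy_removed_samples = rs

    if run_gap_scan:
        flags = scan_multimodality(m1, sheet, gap_threshold, outlier_frac)
        report.gap_flags = flags
        if drop_gap_flagged:
            bad = flags.index[(flags["flagged_F"] | flags["flagged_M"]).to_numpy()]
            m1 = m1.subset_probes(m1.probes.difference(bad))

    if run_bmiq:
        m1 = bmiq_normalize(m1, manifest, groups=profile_sex(sheet))
    m_values = beta_to_m(m1.beta)
    report.n_probes_final, report.n_samples_final = m1.shape
    return m1, m_values, report
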