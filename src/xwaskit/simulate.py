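"""Synthetic mother-father-newborn trio methylation datasets.

The generator emulates the statistical structure that the X-chromosome
analysis assumes, so every downstream stage can be exercised and scored
against a known truth table:

* sex-specific X-linked beta distributions — males (one X) are bimodal near
  0 and 1; females show an intermediate mode ("bump") at probes subject to
  X-inactivation, modelled as the average of an active-X allelic state and a
  methylated inactive-X state; XCI-escape probes are hypomethylated in both
  sexes;
* probe-type structure — type II probes are compressed toward 0.5 relative
  to type I by a configurable factor, giving the normalization stage real
  work to do;
* plate batch effects, drawn once per (plate, probe) on the M scale;
* co-methylation blocks with a latent within-block correlation;
* parent-child correlation of residual M-values via a shared trio factor;
* confounder distributions anchored to the cohort characteristics of a large
  ART trio study (ART mothers older, more often past smokers and primiparous;
  ART newborns slightly lighter);
* planted ART effects (single CpGs or contiguous regions) added on the
  M scale to ART children of a designated sex.

Effects, batch, covariates and noise all operate on the M (logit2) scale;
betas are derived through the inverse-logit2 map and clipped to the open
unit interval.  Everything is driven by one integer seed and is bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EPSILON, beta_to_m, m_to_beta
from .types import (
    MethylationMatrix,
    ProbeManifest,
    SampleSheet,
    TruthTable,
    ValidationError,
)


@dataclass
class PlantedEffect:
    """An ART effect planted at one CpG (int index) or a span of CpG indices
    (start, end inclusive); ``delta`` is in M-value units, ``sex`` in
    {"M", "F", "both"}."""

    probes: int | tuple[int, int]
    delta: float
    sex: str = "both"

    def indices(self, n_cpgs: int) -> list[int]:
        if isinstance(self.probes, tuple):
            lo, hi = self.probes
            idx = list(range(lo, hi + 1))
        else:
            idx = [int(self.probes)]
        for i in idx:
            if not 0 <= i < n_cpgs:
                raise ValidationError(
                    f"planted effect references probe index {i} outside "
                    f"[0, {n_cpgs})")
        return idx


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults describe a mid-sized study slice
    with realistic X-chromosome structure (see the package methods note)."""

    n_trios_art: int = 100
    n_trios_nonart: int = 100
    n_cpgs: int = 1000
    frac_type2: float = 0.8        # EPIC-like predominance of type II probes
    frac_escape: float = 0.12      # ~12% of X-linked loci escape XCI
    block_size: int = 5
    block_rho: float = 0.4
    n_plates: int = 8
    plate_sd: float = 0.15         # SD of the plate intercept, M scale
    noise_sd: float = 0.35         # residual SD, M scale
    parent_child_rho: float = 0.25
    type2_compression: float = 0.9  # shrink type II betas toward 0.5
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    include_parents: bool = True
    with_detection_p: bool = True
    n_bad_samples: int = 0
    n_bad_probes: int = 0
    bad_fail_prob: float = 0.6     # per-cell failure rate on the bad sets
    background_fail_rate: float = 0.0
    missing_covariate_frac: float = 0.0
    within_block_spacing: int = 300   # bp between CpGs inside a block
    between_block_gap: int = 2500     # bp between consecutive blocks
    start_position: int = 1_000_000
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_type2", "frac_escape", "bad_fail_prob",
                     "background_fail_rate", "missing_covariate_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValidationError("block_rho must lie in [0, 1)")
        if not 0.0 <= self.parent_child_rho < 1.0:
            raise ValidationError("parent_child_rho must lie in [0, 1)")
        if self.n_cpgs < 1:
            raise ValidationError("n_cpgs must be >= 1")
        if self.n_trios_art < 1 or self.n_trios_nonart < 1:
            raise ValidationError("need at least one trio per exposure group")
        for e in self.planted_effects:
            if e.sex not in ("M", "F", "both"):
                raise ValidationError(f"planted effect sex must be M/F/both, got {e.sex!r}")
            if not np.isfinite(e.delta):
                raise ValidationError("planted delta must be finite")
            e.indices(self.n_cpgs)


# cohort-anchored covariate distributions (ART vs non-ART)
_SMOKING_P = {
    1: (0.516, 0.374, 0.064, 0.046),
    0: (0.501, 0.258, 0.135, 0.106),
}
_AGE_MEAN = {1: 33.0, 0: 30.0}
_AGE_SD = 4.0
_PRIMI_P = {1: 0.70, 0: 0.47}
_BW_MEAN = {1: 3540.0, 0: 3650.0}
_BW_SD = 480.0
_GA_MEAN, _GA_SD = 40.0, 1.3
_BMI_LOG_MEDIAN, _BMI_LOG_SD = np.log(23.0), 0.15

_SMOKING_LEVELS = ("Never", "Past", "FirstTrimester", "FirstTrimesterAndAfter")


def generate_trio_dataset(config: SyntheticConfig
                          ) -> tuple[MethylationMatrix, SampleSheet,
                                     ProbeManifest, TruthTable]:
    """Draw one synthetic dataset; returns (matrix, sheet, manifest, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    P = config.n_cpgs

    manifest = _make_manifest(rng, config)
    sheet = _make_samplesheet(rng, config)
    kids = sheet.table[sheet.table["role"] == "child"]

    # probe architecture -----------------------------------------------------
    escape = rng.random(P) < config.frac_escape
    state_high = rng.random(P) < 0.5          # active-X allelic state
    lo = rng.uniform(0.03, 0.10, size=P)
    hi = rng.uniform(0.88, 0.96, size=P)
    beta_male = np.where(escape, lo, np.where(state_high, hi, lo))
    # female non-escape: average of active-X state and methylated inactive X
    beta_female = np.where(escape, lo, (np.where(state_high, hi, lo) + hi) / 2.0)
    base_m = {"M": beta_to_m(beta_male), "F": beta_to_m(beta_female)}

    block_of = np.arange(P) // config.block_size
    n_blocks = int(block_of.max()) + 1

    samples = list(sheet.table.index)
    S = len(samples)
    plate_codes, plate_levels = pd.factorize(sheet.table["plate_id"])
    plate_fx = rng.normal(0.0, config.plate_sd, size=(len(plate_levels), P))

    # residual structure: trio factor (parent-child coupling) nested over
    # block factors (within-individual co-methylation)
    trios = kids["trio_id"].to_numpy()
    trio_pos = {t: i for i, t in enumerate(trios)}
    r_pc = config.parent_child_rho
    r_b = config.block_rho

    def block_structured(n_rows: int) -> np.ndarray:
        f = rng.standard_normal((n_rows, n_blocks))[:, block_of]
        zz = rng.standard_normal((n_rows, P))
        return np.sqrt(r_b) * f + np.sqrt(1.0 - r_b) * zz

    h_trio = block_structured(len(trios))

    M = np.empty((S, P))
    row_of = {s: i for i, s in enumerate(samples)}
    art = sheet.table["art"].to_numpy(dtype=float)
    child_sex = sheet.table["child_sex"]

    # covariate design on the child rows (standardized, M-scale slopes)
    cov_contrib = np.zeros(S)
    if config.covariate_effects:
        tab = sheet.table
        for cov, slope in config.covariate_effects.items():
            if cov not in tab.columns:
                raise ValidationError(f"unknown covariate {cov!r} in covariate_effects")
            v = pd.to_numeric(tab[cov], errors="coerce").to_numpy(dtype=float)
            mu, sd = np.nanmean(v), np.nanstd(v)
            z = (v - mu) / (sd if sd > 0 else 1.0)
            cov_contrib += slope * np.nan_to_num(z)

    for sid, srow in sheet.table.iterrows():
        i = row_of[sid]
        role = srow["role"]
        sex = srow["child_sex"] if role == "child" else ("F" if role == "mother" else "M")
        own = block_structured(1)[0]
        resid = (np.sqrt(r_pc) * h_trio[trio_pos[srow["trio_id"]]]
                 + np.sqrt(1.0 - r_pc) * own)
        M[i] = (base_m[sex] + plate_fx[plate_codes[i]]
                + config.noise_sd * resid)
        if role == "child":
            M[i] += cov_contrib[i]

    # planted ART effects (children only, matching sex, ART = 1)
    truth_entries = []
    probe_ids = list(manifest.probe_ids)
    for eff in config.planted_effects:
        idx = eff.indices(P)
        if eff.delta == 0.0:
            continue
        for sid, srow in kids.iterrows():
            if srow["art"] != 1:
                continue
            if eff.sex != "both" and srow["child_sex"] != eff.sex:
                continue
            M[row_of[sid], idx] += eff.delta
        truth_entries.append({"probe_ids": [probe_ids[i] for i in idx],
                              "delta": float(eff.delta), "sex": eff.sex})

    # beta scale, probe-type compression, clipping -----------------------------
    beta = m_to_beta(M)
    is2 = (manifest.table["design_type"] == "II").to_numpy()
    beta[:, is2] = 0.5 + (beta[:, is2] - 0.5) * config.type2_compression
    beta = np.clip(beta, EPSILON, 1.0 - EPSILON)
    beta_df = pd.DataFrame(beta.T, index=pd.Index(probe_ids, name="probe_id"),
                           columns=pd.Index(samples, name="sample_id"))

    detp_df = None
    if config.with_detection_p:
        detp = rng.uniform(0.0, 0.001, size=(S, P))
        fail = rng.random((S, P)) < config.background_fail_rate
        if config.n_bad_samples:
            bad_s = rng.choice(S, size=min(config.n_bad_samples, S), replace=False)
            fail[bad_s] |= rng.random((len(bad_s), P)) < config.bad_fail_prob
        if config.n_bad_probes:
            bad_p = rng.choice(P, size=min(config.n_bad_probes, P), replace=False)
            fail[:, bad_p] |= rng.random((S, len(bad_p))) < config.bad_fail_prob
        detp[fail] = rng.uniform(0.01, 1.0, size=int(fail.sum()))
        detp_df = pd.DataFrame(detp.T, index=beta_df.index, columns=beta_df.columns)

    matrix = MethylationMatrix(beta_df, detp_df)
    return matrix, sheet, manifest, TruthTable(truth_entries)


def truth_table(dataset) -> pd.DataFrame:
    """Planted effects of a generated dataset as a DataFrame (delta = 0
    entries were never recorded); accepts the 4-tuple returned by
    :func:`generate_trio_dataset` or a :class:`TruthTable`."""
    tt = dataset[3] if isinstance(dataset, tuple) else dataset
    return tt.to_frame()


def _make_manifest(rng, config: SyntheticConfig) -> ProbeManifest:
    P = config.n_cpgs
    block_of = np.arange(P) // config.block_size
    within = np.arange(P) % config.block_size
    block_span = (config.block_size - 1) * config.within_block_spacing
    positions = (config.start_position
                 + block_of * (block_span + config.between_block_gap)
                 + within * config.within_block_spacing)
    probe_ids = [f"cg{i:07d}" for i in range(P)]
    dtype = np.where(rng.random(P) < config.frac_type2, "II", "I")
    table = pd.DataFrame({
        "chromosome": "X",
        "position": positions.astype(int),
        "design_type": dtype,
        "cross_reactive": False,
        "snp_overlap_last3": False,
        "par_region": False,
    }, index=pd.Index(probe_ids, name="probe_id"))
    return ProbeManifest(table)


def _make_samplesheet(rng, config: SyntheticConfig) -> SampleSheet:
    rows = []
    n_total = config.n_trios_art + config.n_trios_nonart
    art_flags = [1] * config.n_trios_art + [0] * config.n_trios_nonart
    # deterministic alternating sex within each exposure group -> exact balance
    sex_counter = {0: 0, 1: 0}
    for t, a in enumerate(art_flags):
        sex = "F" if sex_counter[a] % 2 == 0 else "M"
        sex_counter[a] += 1
        trio = f"T{t:04d}"
        age = float(np.clip(rng.normal(_AGE_MEAN[a], _AGE_SD), 18, 45))
        bmi = float(np.clip(np.exp(rng.normal(_BMI_LOG_MEDIAN, _BMI_LOG_SD)), 15, 45))
        smoking = _SMOKING_LEVELS[rng.choice(4, p=_SMOKING_P[a])]
        primi = int(rng.random() < _PRIMI_P[a])
        bw = float(np.clip(rng.normal(_BW_MEAN[a], _BW_SD), 1500, 6000))
        ga = float(np.clip(rng.normal(_GA_MEAN, _GA_SD), 32, 43))
        common = dict(trio_id=trio, art=a, child_sex=sex, maternal_age=age,
                      maternal_smoking=smoking, maternal_bmi=bmi,
                      primiparity=primi, birthweight=bw, gestational_age=ga)
        rows.append(dict(sample_id=f"C{t:04d}", role="child", **common))
        if config.include_parents:
            rows.append(dict(sample_id=f"M{t:04d}", role="mother", **common))
            rows.append(dict(sample_id=f"F{t:04d}", role="father", **common))
    df = pd.DataFrame(rows).set_index("sample_id")
    df["plate_id"] = [f"P{p:02d}" for p in rng.integers(0, config.n_plates,
                                                        size=len(df))]
    if config.missing_covariate_frac > 0:
        from .types import COVARIATE_COLUMNS
        for col in COVARIATE_COLUMNS:
            mask = rng.random(len(df)) < config.missing_covariate_frac
            df.loc[mask, col] = np.nan
    return SampleSheet(df)
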