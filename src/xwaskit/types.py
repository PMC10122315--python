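"""Core domain types for the X-chromosome methylation association pipeline.

The pipeline operates on three tabular inputs — a probe-by-sample beta-value
matrix (optionally with aligned detection p-values), a probe manifest with
genomic coordinates and design/annotation flags, and a sample sheet describing
mother-father-child trios — plus the result containers produced downstream
(per-CpG association statistics, differentially methylated regions, bootstrap
stability summaries and windowed co-methylation reports).

All containers are thin, validated wrappers around :class:`pandas.DataFrame`
so that the usual pandas idioms (indexing, joins, I/O) remain available.
Coordinates are 1-based inclusive throughout the library; the single point of
conversion to other conventions is the BED writer in :mod:`xwaskit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DESIGN_TYPES = ("I", "II")
ROLES = ("child", "mother", "father")
SEXES = ("M", "F")
SMOKING_LEVELS = ("Never", "Past", "FirstTrimester", "FirstTrimesterAndAfter")
MODEL_IDS = ("M1", "M2", "M3", "M4")

#: covariate columns of the sample sheet that may legitimately be missing
COVARIATE_COLUMNS = (
    "maternal_age",
    "maternal_smoking",
    "maternal_bmi",
    "primiparity",
    "birthweight",
    "gestational_age",
)


class ValidationError(ValueError):
    """Raised when an input container violates a structural invariant."""


@dataclass
class ProbeManifest:
    """Per-probe genomic coordinates, design type and exclusion flags.

    ``table`` is indexed by probe_id and carries the columns ``chromosome``,
    ``position`` (1-based bp), ``design_type`` ("I"/"II"), ``cross_reactive``,
    ``snp_overlap_last3``, ``par_region`` and the optional free-text
    annotations ``gene_annotation`` / ``regulatory_annotation``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "probe_id":
            t = t.copy()
            t.index.name = "probe_id"
            self.table = t
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe_id values in manifest: {dups[:5]}")
        for col in ("chromosome", "position", "design_type"):
            if col not in t.columns:
                raise ValidationError(f"manifest is missing required column {col!r}")
        if (t["position"] < 1).any():
            bad = t.index[t["position"] < 1][0]
            raise ValidationError(f"probe {bad!r} has position < 1")
        bad_dt = set(t["design_type"].unique()) - set(DESIGN_TYPES)
        if bad_dt:
            raise ValidationError(
                f"unknown design_type values {sorted(bad_dt)}; allowed: {DESIGN_TYPES}"
            )
        for col, default in (
            ("cross_reactive", False),
            ("snp_overlap_last3", False),
            ("par_region", False),
            ("gene_annotation", None),
            ("regulatory_annotation", None),
        ):
            if col not in t.columns:
                t[col] = default

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def sort_by_position(self) -> "ProbeManifest":
        """Return a manifest sorted by (chromosome, position); required before
        any window/region computation."""
        return ProbeManifest(self.table.sort_values(["chromosome", "position"], kind="stable"))

    def subset(self, probe_ids) -> "ProbeManifest":
        missing = pd.Index(probe_ids).difference(self.table.index)
        if len(missing):
            raise ValidationError(f"probes absent from manifest: {missing[:5].tolist()}")
        return ProbeManifest(self.table.loc[probe_ids])


@dataclass
class MethylationMatrix:
    """Probe x sample beta values in [0, 1] with optional detection p-values.

    Missing measurements are NaN and stay NaN (never coerced to 0).  The
    optional ``detection_p`` matrix must share both axes with ``beta``.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        b = self.beta
        vals = b.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} out of [0, 1] at probe "
                f"{b.index[i]!r}, sample {b.columns[j]!r}"
            )
        if self.detection_p is not None:
            d = self.detection_p
            if not (d.index.equals(b.index) and d.columns.equals(b.columns)):
                raise ValidationError("detection_p axes do not match beta axes")
            dv = d.to_numpy(dtype=float)
            if np.any(((dv < 0) | (dv > 1)) & ~np.isnan(dv)):
                raise ValidationError("detection p-values must lie in [0, 1]")

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        d = self.detection_p.loc[probe_ids] if self.detection_p is not None else None
        return MethylationMatrix(self.beta.loc[probe_ids], d)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        d = self.detection_p[sample_ids] if self.detection_p is not None else None
        return MethylationMatrix(self.beta[sample_ids], d)


@dataclass
class SampleSheet:
    """Trio structure, child sex, ART status, plate and covariates.

    ``table`` is indexed by sample_id with columns ``trio_id``, ``role``
    (child/mother/father), ``child_sex`` ("M"/"F", defined on child rows),
    ``art`` (0/1, constant within trio), ``plate_id`` and the covariates in
    :data:`COVARIATE_COLUMNS`.  Covariates may be missing (NaN); missingness
    is handled downstream by complete-case analysis.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "sample_id":
            t = t.copy()
            t.index.name = "sample_id"
            self.table = t
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id values: {dups[:5]}")
        for col in ("trio_id", "role"):
            if col not in t.columns:
                raise ValidationError(f"sample sheet is missing required column {col!r}")
        bad_roles = set(t["role"].unique()) - set(ROLES)
        if bad_roles:
            raise ValidationError(f"unknown role values {sorted(bad_roles)}; allowed: {ROLES}")
        children = t[t["role"] == "child"]
        counts = children.groupby("trio_id").size()
        multi = counts[counts > 1]
        if len(multi):
            raise ValidationError(f"trios with more than one child row: {multi.index[:5].tolist()}")
        for role in ("mother", "father"):
            rc = t[t["role"] == role].groupby("trio_id").size()
            multi = rc[rc > 1]
            if len(multi):
                raise ValidationError(
                    f"trios with more than one {role} row: {multi.index[:5].tolist()}"
                )
        if "child_sex" in t.columns:
            sx = children["child_sex"].dropna()
            bad = set(sx.unique()) - set(SEXES)
            if bad:
                raise ValidationError(f"unknown child_sex values {sorted(bad)}; allowed: {SEXES}")
        if "maternal_smoking" in t.columns:
            sm = t["maternal_smoking"].dropna()
            bad = set(sm.unique()) - set(SMOKING_LEVELS)
            if bad:
                raise ValidationError(
                    f"unknown maternal_smoking values {sorted(bad)}; "
                    f"allowed levels: {SMOKING_LEVELS}"
                )
        if "art" in t.columns:
            nuniq = t.dropna(subset=["art"]).groupby("trio_id")["art"].nunique()
            mixed = nuniq[nuniq > 1]
            if len(mixed):
                raise ValidationError(
                    f"art status differs within trios: {mixed.index[:5].tolist()}"
                )

    def children(self, sex: str | None = None) -> pd.DataFrame:
        t = self.table
        out = t[t["role"] == "child"]
        if sex is not None:
            if sex not in SEXES:
                raise ValidationError(f"sex must be one of {SEXES}, got {sex!r}")
            out = out[out["child_sex"] == sex]
        return out

    def parent_of(self, role: str) -> pd.Series:
        """Map trio_id -> sample_id for the requested parent role."""
        t = self.table
        rows = t[t["role"] == role]
        return pd.Series(rows.index.values, index=rows["trio_id"].values)


@dataclass
class DmrResult:
    """A differentially methylated region: a run of nearby same-direction CpGs
    combined by the correlation-adjusted inverse-variance statistic."""

    chromosome: str
    start: int
    end: int
    n_cpgs: int
    member_probe_ids: list[str]
    effect_B: float
    se_B: float
    z: float
    p: float
    q: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"DMR start {self.start} > end {self.end}")


@dataclass
class CoMethylationReport:
    """Pairwise methylation correlations in a genomic window around one CpG."""

    center_probe_id: str
    window_bp: int
    member_probe_ids: list[str]
    r: pd.DataFrame
    p_adj: pd.DataFrame

    def __post_init__(self) -> None:
        k = len(self.member_probe_ids)
        if self.r.shape != (k, k) or self.p_adj.shape != (k, k):
            raise ValidationError("correlation matrices must be square over the window members")


@dataclass
class GapScan:
    """Result of the sorted-gap multimodality check for one probe/one sex."""

    n_groups: int
    assignment: np.ndarray
    flagged: bool


@dataclass
class TruthTable:
    """Planted differential-methylation effects of a synthetic dataset.

    One row per planted entry: ``probe_ids`` (list, a single CpG or the
    members of a planted region), ``delta`` (M-value units) and ``sex``.
    """

    entries: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        if not self.entries:
            return pd.DataFrame(columns=["probe_ids", "delta", "sex"])
        return pd.DataFrame(self.entries)

    @property
    def causal_probes(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            out.update(e["probe_ids"])
        return out
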