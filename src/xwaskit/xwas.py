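"""Sex-stratified per-CpG association scans (the XWAS stage).

Four nested regression models estimate the difference in M-values between
ART-conceived and naturally conceived newborns, separately for girls and
boys, with plate as a random intercept:

* M1 (main):  CpG ~ ART + maternal age + maternal smoking + maternal BMI
  + primiparity
* M2: M1 + parental M-values at the same CpG (maternal only in the boys
  stratum; maternal and paternal in the girls stratum)
* M3: M1 + birthweight + gestational age
* M4: M2 and M3 combined

Smoking is dummy-coded against the reference level "Never".  Children with
any missing required covariate are excluded (complete-case), as are children
with missing exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import fit_cpg
from .types import MODEL_IDS, SEXES, SMOKING_LEVELS, SampleSheet, ValidationError

_BASE_COVARIATES = ["maternal_age", "maternal_bmi", "primiparity"]
_M3_EXTRA = ["birthweight", "gestational_age"]


@dataclass
class Design:
    """A realized design for one (model, sex) stratum.

    ``X`` holds the per-child fixed-effect columns shared across CpGs;
    parental M-value columns (M2/M4) are appended per CpG at fit time using
    ``mother_ids`` / ``father_ids``.
    """

    model_id: str
    sex: str
    child_ids: list[str]
    X: np.ndarray
    columns: list[str]
    plate_ids: np.ndarray
    mother_ids: list[str] | None
    father_ids: list[str] | None
    n_excluded_incomplete: int


def model_covariates(model_id: str) -> list[str]:
    if model_id not in MODEL_IDS:
        raise ValidationError(f"model_id must be one of {MODEL_IDS}, got {model_id!r}")
    cols = list(_BASE_COVARIATES) + ["maternal_smoking"]
    if model_id in ("M3", "M4"):
        cols += _M3_EXTRA
    return cols


def uses_parental(model_id: str) -> bool:
    return model_id in ("M2", "M4")


def build_design(sheet: SampleSheet, model_id: str, sex: str,
                 child_ids=None) -> Design:
    """Construct the fixed-effect design for one stratum.

    ``child_ids`` optionally overrides the stratum membership (repeats
    allowed — this is how bootstrap replicates reuse the builder); by default
    all children of the requested sex with complete covariates are used.
    """
    if sex not in SEXES:
        raise ValidationError(f"sex must be one of {SEXES}, got {sex!r}")
    kids = sheet.children(sex)
    if child_ids is None:
        child_ids = list(kids.index)
    else:
        child_ids = list(child_ids)
        unknown = set(child_ids) - set(kids.index)
        if unknown:
            raise ValidationError(
                f"child_ids not children of sex {sex}: {sorted(unknown)[:5]}")
    if not child_ids:
        raise ValidationError(f"no children of sex {sex!r} in the sample sheet")

    rows = kids.loc[child_ids]
    needed = ["art"] + model_covariates(model_id)
    complete = rows[needed].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    rows = rows[complete.to_numpy()]
    if len(rows) == 0:
        raise ValidationError(
            f"no children with complete covariates for model {model_id}, sex {sex}")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(rows))}
    cols["art"] = rows["art"].to_numpy(dtype=float)
    for c in _BASE_COVARIATES:
        cols[c] = rows[c].to_numpy(dtype=float)
    for level in SMOKING_LEVELS[1:]:  # reference level: Never
        cols[f"smoking_{level}"] = (rows["maternal_smoking"] == level).to_numpy(float)
    if model_id in ("M3", "M4"):
        for c in _M3_EXTRA:
            cols[c] = rows[c].to_numpy(dtype=float)

    mother_ids = father_ids = None
    if uses_parental(model_id):
        mother_map = sheet.parent_of("mother")
        trios = rows["trio_id"]
        missing_m = [t for t in trios if t not in mother_map.index]
        if missing_m:
            raise ValidationError(
                f"model {model_id} needs maternal samples; missing for trios "
                f"{missing_m[:5]}")
        mother_ids = [mother_map[t] for t in trios]
        if sex == "F":
            father_map = sheet.parent_of("father")
            missing_f = [t for t in trios if t not in father_map.index]
            if missing_f:
                raise ValidationError(
                    f"girls-stratum model {model_id} needs paternal samples; "
                    f"missing for trios {missing_f[:5]}")
            father_ids = [father_map[t] for t in trios]

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    plate = rows["plate_id"].to_numpy() if "plate_id" in rows.columns else np.zeros(len(rows))
    return Design(model_id=model_id, sex=sex, child_ids=list(rows.index),
                  X=X, columns=names, plate_ids=plate,
                  mother_ids=mother_ids, father_ids=father_ids,
                  n_excluded_incomplete=n_excluded)


def run_xwas(m_matrix: pd.DataFrame, sheet: SampleSheet, model_id: str = "M1",
             sex: str = "F", child_ids=None,
             probes=None) -> pd.DataFrame:
    """Fit the per-CpG model over all (or the given) probes in one stratum.

    ``m_matrix`` is a probe x sample M-value DataFrame covering the stratum's
    children (and, for M2/M4, their parents).  Returns one row per CpG with
    columns probe_id, model_id, sex, effect, se, z_raw, p_raw, n_used.
    Per-CpG failures (e.g. all-missing response) are recorded with NaN
    statistics rather than aborting the scan.
    """
    design = build_design(sheet, model_id, sex, child_ids=child_ids)
    kid_pos = _positions(m_matrix.columns, design.child_ids,
                         "children missing from M-matrix")
    mom_pos = dad_pos = None
    if design.mother_ids is not None:
        mom_pos = _positions(m_matrix.columns, design.mother_ids,
                             "mothers missing from M-matrix")
    if design.father_ids is not None:
        dad_pos = _positions(m_matrix.columns, design.father_ids,
                             "fathers missing from M-matrix")

    if probes is None:
        probes = m_matrix.index
    vals = m_matrix.to_numpy(dtype=float)
    probe_pos = _positions(m_matrix.index, probes, "probes missing from M-matrix")

    records = []
    for pid, ppos in zip(probes, probe_pos):
        y = vals[ppos, kid_pos]
        X = design.X
        columns = design.columns
        if mom_pos is not None:
            mm = vals[ppos, mom_pos]
            X = np.column_stack([X, mm])
            columns = columns + ["maternal_m"]
        if dad_pos is not None:
            dm = vals[ppos, dad_pos]
            X = np.column_stack([X, dm])
            columns = columns + ["paternal_m"]
        # complete-case over response and any parental covariates
        keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
        try:
            eff, se, z, p, n_used = fit_cpg(y[keep], X[keep], columns,
                                            design.plate_ids[keep])
        except (ValidationError, np.linalg.LinAlgError):
            eff = se = z = p = np.nan
            n_used = int(keep.sum())
        records.append((pid, model_id, sex, eff, se, z, p, n_used))
    return pd.DataFrame(records, columns=[
        "probe_id", "model_id", "sex", "effect", "se", "z_raw", "p_raw", "n_used"])


def _positions(index: pd.Index, wanted, what: str) -> np.ndarray:
    indexer = index.get_indexer(pd.Index(wanted))
    if (indexer < 0).any():
        missing = [w for w, i in zip(list(wanted), indexer) if i < 0]
        raise ValidationError(f"{what}: {missing[:5]}")
    return indexer
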