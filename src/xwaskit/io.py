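"""Readers and writers for the tabular formats the pipeline consumes.

Matrices and sheets travel as delimited text (TSV by default, CSV by file
extension), DMRs additionally as BED, and every result table written through
:func:`write_table` gets a JSON sidecar recording run metadata (seed, model,
thresholds) so that any output file is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DmrResult,
    MethylationMatrix,
    ProbeManifest,
    SampleSheet,
    ValidationError,
)

MISSING_TOKEN = "NA"

_MANIFEST_BOOL_COLS = ("cross_reactive", "snp_overlap_last3", "par_region")


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_matrix_file(path, missing_token: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=[missing_token],
                     keep_default_na=False)
    df.index.name = "probe_id"
    df.index = df.index.astype(str)
    df.columns = pd.Index([str(c) for c in df.columns], name="sample_id")
    return df.astype(float)


def read_methylation(beta_path, detection_path=None,
                     missing_token: str = MISSING_TOKEN) -> MethylationMatrix:
    """Read a probe x sample beta matrix (and optional detection-p matrix).

    First column must be the probe id, the header row the sample ids.  Values
    are validated against [0, 1]; the missing token becomes NaN.
    """
    beta = _read_matrix_file(beta_path, missing_token)
    detp = None
    if detection_path is not None:
        detp = _read_matrix_file(detection_path, missing_token)
        if not (detp.index.equals(beta.index) and detp.columns.equals(beta.columns)):
            raise ValidationError(
                f"detection matrix {detection_path} does not share axes with {beta_path}"
            )
    return MethylationMatrix(beta, detp)


def write_methylation(matrix: MethylationMatrix, beta_path, detection_path=None,
                      missing_token: str = MISSING_TOKEN) -> None:
    matrix.beta.to_csv(beta_path, sep=_sep_for(beta_path), na_rep=missing_token)
    if detection_path is not None:
        if matrix.detection_p is None:
            raise ValidationError("matrix has no detection p-values to write")
        matrix.detection_p.to_csv(detection_path, sep=_sep_for(detection_path),
                                  na_rep=missing_token)


def read_manifest(path, missing_token: str = MISSING_TOKEN) -> ProbeManifest:
    df = pd.read_csv(path, sep=_sep_for(path), na_values=[missing_token],
                     keep_default_na=False)
    if "probe_id" not in df.columns:
        raise ValidationError("manifest file is missing required column 'probe_id'")
    df["probe_id"] = df["probe_id"].astype(str)
    df = df.set_index("probe_id")
    if "position" in df.columns:
        df["position"] = df["position"].astype(int)
    for col in _MANIFEST_BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].map(_parse_bool)
    return ProbeManifest(df)


def _parse_bool(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float)):
        return bool(int(v))
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no", ""):
        return False
    raise ValidationError(f"cannot parse boolean flag value {v!r}")


def write_manifest(manifest: ProbeManifest, path,
                   missing_token: str = MISSING_TOKEN) -> None:
    manifest.table.to_csv(path, sep=_sep_for(path), na_rep=missing_token)


def read_samplesheet(path, missing_token: str = MISSING_TOKEN) -> SampleSheet:
    df = pd.read_csv(path, sep=_sep_for(path), na_values=[missing_token],
                     keep_default_na=False)
    for col in ("sample_id", "trio_id", "role"):
        if col not in df.columns:
            raise ValidationError(f"sample sheet file is missing required column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id values: {dups[:5]}")
    df = df.set_index("sample_id")
    for col in ("art", "primiparity"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return SampleSheet(df)


def write_samplesheet(sheet: SampleSheet, path,
                      missing_token: str = MISSING_TOKEN) -> None:
    sheet.table.to_csv(path, sep=_sep_for(path), na_rep=missing_token)


def write_dmr_bed(dmrs: list[DmrResult], path) -> None:
    """Write DMRs as BED lines (0-based half-open; score = -log10 p, name =
    member count).  Internal coordinates are 1-based inclusive, so bed_start =
    start - 1 and bed_end = end."""
    lines = ["# chrom\tstart\tend\tn_cpgs\tneg_log10_p"]
    for d in dmrs:
        if d.start > d.end:
            raise ValidationError(f"DMR start {d.start} > end {d.end}")
        score = -np.log10(max(d.p, 1e-300))
        chrom = d.chromosome if str(d.chromosome).startswith("chr") else f"chr{d.chromosome}"
        lines.append(f"{chrom}\t{d.start - 1}\t{d.end}\t{d.n_cpgs}\t{score:.4g}")
    Path(path).write_text("\n".join(lines) + "\n")


def dmrs_to_frame(dmrs: list[DmrResult]) -> pd.DataFrame:
    rows = []
    for d in dmrs:
        rows.append({
            "chromosome": d.chromosome, "start": d.start, "end": d.end,
            "n_cpgs": d.n_cpgs, "members": ";".join(d.member_probe_ids),
            "effect_B": d.effect_B, "se_B": d.se_B, "z": d.z, "p": d.p,
            "q": d.q, "significant": d.significant,
        })
    cols = ["chromosome", "start", "end", "n_cpgs", "members", "effect_B",
            "se_B", "z", "p", "q", "significant"]
    return pd.DataFrame(rows, columns=cols)


def write_table(df: pd.DataFrame, path, metadata: dict | None = None,
                missing_token: str = MISSING_TOKEN, index: bool = False) -> None:
    """Write a result table plus a ``<path>.meta.json`` sidecar with run
    metadata (seed, model id, thresholds, ...)."""
    df.to_csv(path, sep=_sep_for(path), na_rep=missing_token, index=index)
    sidecar = Path(str(path) + ".meta.json")
    sidecar.write_text(json.dumps(metadata or {}, indent=2, default=str) + "\n")


def read_table(path, missing_token: str = MISSING_TOKEN) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), na_values=[missing_token],
                       keep_default_na=False)
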