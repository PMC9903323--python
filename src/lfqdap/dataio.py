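"""Readers and writers for peptide reports, sample metadata and result tables.

Three input dialects are supported and mapped onto one canonical long
schema (sample_id, protein_id, peptide_id, intensity, qvalue):

* ``generic_long`` — canonical column names, qvalue optional;
* ``maxquant_wide`` — simplified MaxQuant ``peptides.txt``: one row per
  peptide ("Sequence", "Leading razor protein") with one
  ``Intensity <sample>`` column per sample, zero meaning missing;
* ``diann_long`` — simplified DIA-NN report: "Run", "Protein.Group",
  "Modified.Sequence", "Precursor.Quantity", "Q.Value".

All files are UTF-8, tab-separated, "." decimal.  Intensities that are
absent, non-positive or NaN are recorded as missing; a peptide observation
is "detected" when its q-value is at or below the threshold (for inputs
without q-values, detection follows intensity presence).
"""

from __future__ import annotations

import json
import logging
import os
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    AbundanceMatrix,
    ConsistencyError,
    FormatError,
    InputError,
    PeptideTable,
    SampleMetadata,
)

logger = logging.getLogger(__name__)

DIALECTS = ("generic_long", "maxquant_wide", "diann_long")

_DIANN_COLUMNS = {
    "Run": "sample_id",
    "Protein.Group": "protein_id",
    "Modified.Sequence": "peptide_id",
    "Precursor.Quantity": "intensity",
    "Q.Value": "qvalue",
}


def read_peptide_table(
    path, dialect: str = "generic_long", qvalue_threshold: float = 0.01
) -> PeptideTable:
    """Parse a peptide-level report into the canonical long format.

    Parameters
    ----------
    path : str or path-like
        TSV file to read.
    dialect : str
        One of ``generic_long``, ``maxquant_wide``, ``diann_long``.
    qvalue_threshold : float
        Observations with qvalue <= threshold are flagged ``detected``.
        For rows without a q-value the flag falls back to intensity
        presence (generic and MaxQuant dialects; DIA-NN rows lacking a
        q-value are not detected).
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not (0 < qvalue_threshold <= 1):
        raise FormatError("qvalue_threshold must be in (0, 1]")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if len(raw) == 0:
        raise InputError(f"{path}: empty peptide report")

    if dialect == "generic_long":
        frame, qv_fallback = _parse_generic(raw, path)
    elif dialect == "diann_long":
        frame, qv_fallback = _parse_diann(raw, path)
    else:
        frame, qv_fallback = _parse_maxquant_wide(raw, path)

    frame["intensity"] = pd.to_numeric(frame["intensity"], errors="coerce")
    frame.loc[frame["intensity"] <= 0, "intensity"] = np.nan
    frame["qvalue"] = pd.to_numeric(frame["qvalue"], errors="coerce")

    malformed = (
        frame["sample_id"].isna()
        | frame["protein_id"].isna()
        | frame["peptide_id"].isna()
        | (frame["sample_id"].astype(str).str.strip() == "")
        | (frame["peptide_id"].astype(str).str.strip() == "")
    )
    n_malformed = int(malformed.sum())
    if n_malformed:
        logger.warning("%s: dropped %d malformed rows", path, n_malformed)
        frame = frame[~malformed]
    frame = frame[frame["intensity"].notna()].reset_index(drop=True)
    if len(frame) == 0:
        raise InputError(f"{path}: no usable observations after parsing")

    detected = frame["qvalue"] <= qvalue_threshold
    if qv_fallback:
        detected = detected | (frame["qvalue"].isna() & frame["intensity"].notna())
    frame = frame.assign(detected=detected.to_numpy(dtype=bool))
    return PeptideTable(frame, n_malformed=n_malformed)


def _parse_generic(raw: pd.DataFrame, path) -> tuple[pd.DataFrame, bool]:
    for col in ("sample_id", "protein_id", "peptide_id", "intensity"):
        if col not in raw.columns:
            raise FormatError(f"{path}: generic_long input lacks column {col!r}")
    frame = raw.copy()
    if "qvalue" not in frame.columns:
        frame["qvalue"] = np.nan
    cols = ["sample_id", "protein_id", "peptide_id", "intensity", "qvalue"]
    return frame[cols], True


def _parse_diann(raw: pd.DataFrame, path) -> tuple[pd.DataFrame, bool]:
    missing = [c for c in _DIANN_COLUMNS if c not in raw.columns and c != "Q.Value"]
    if missing:
        raise FormatError(f"{path}: diann_long input lacks column {missing[0]!r}")
    frame = raw.rename(columns=_DIANN_COLUMNS)
    if "qvalue" not in frame.columns:
        frame["qvalue"] = np.nan
    cols = ["sample_id", "protein_id", "peptide_id", "intensity", "qvalue"]
    return frame[cols], False


def _parse_maxquant_wide(raw: pd.DataFrame, path) -> tuple[pd.DataFrame, bool]:
    for col in ("Sequence", "Leading razor protein"):
        if col not in raw.columns:
            raise FormatError(f"{path}: maxquant_wide input lacks column {col!r}")
    intensity_cols = [c for c in raw.columns if c.startswith("Intensity ")]
    if not intensity_cols:
        raise FormatError(f"{path}: maxquant_wide input has no 'Intensity <sample>' columns")
    long = raw.melt(
        id_vars=["Sequence", "Leading razor protein"],
        value_vars=intensity_cols,
        var_name="sample_id",
        value_name="intensity",
    )
    long["sample_id"] = long["sample_id"].str.removeprefix("Intensity ")
    long = long.rename(
        columns={"Sequence": "peptide_id", "Leading razor protein": "protein_id"}
    )
    long["qvalue"] = np.nan
    cols = ["sample_id", "protein_id", "peptide_id", "intensity", "qvalue"]
    return long[cols], True


def read_sample_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    if len(frame) == 0:
        raise InputError(f"{path}: empty sample metadata")
    return SampleMetadata(frame)


def build_matrix(
    table: PeptideTable, metadata: SampleMetadata, include_excluded: bool = False
) -> AbundanceMatrix:
    """Pivot a peptide table into a log2 feature-by-sample matrix.

    Rows are ordered by (protein_id, peptide_id); columns follow metadata
    order, restricted to samples present in the table.  Excluded samples
    are dropped unless ``include_excluded``.  The aligned ``detected``
    boolean matrix is attached.
    """
    meta = metadata if include_excluded else metadata.included()
    known = set(meta.frame["sample_id"])
    table_samples = set(table.frame["sample_id"])
    unknown = table_samples - set(metadata.frame["sample_id"])
    if unknown:
        raise ConsistencyError(
            f"samples present in peptide table but not in metadata: {sorted(unknown)[:5]}"
        )
    sample_ids = [s for s in meta.frame["sample_id"] if s in table_samples]
    if not sample_ids:
        raise InputError("no samples remain after applying metadata")

    f = table.frame[table.frame["sample_id"].isin(known)]
    wide = f.pivot(index="peptide_id", columns="sample_id", values="intensity")
    det = (
        f.pivot(index="peptide_id", columns="sample_id", values="detected")
        .astype("boolean")
        .fillna(False)
        .astype(bool)
    )
    pep_to_prot = dict(zip(f["peptide_id"], f["protein_id"]))
    order = sorted(wide.index, key=lambda p: (pep_to_prot[p], p))
    wide = wide.loc[order, sample_ids]
    det = det.loc[order, sample_ids]

    values = np.log2(wide.to_numpy(dtype=float))
    groups = meta.frame.set_index("sample_id").loc[sample_ids, "group"].to_numpy(object)
    return AbundanceMatrix(
        values=values,
        feature_ids=np.asarray(order, dtype=object),
        sample_ids=np.asarray(sample_ids, dtype=object),
        groups=groups,
        feature_to_protein=np.asarray([pep_to_prot[p] for p in order], dtype=object),
        detected=det.to_numpy(),
    )


def matrix_to_frame(matrix) -> pd.DataFrame:
    """Flatten an AbundanceMatrix or ProteinMatrix to a writable table."""
    if hasattr(matrix, "feature_ids"):
        ids = {"feature_id": matrix.feature_ids, "protein_id": matrix.feature_to_protein}
    else:
        ids = {"protein_id": matrix.protein_ids}
    out = pd.DataFrame(ids)
    for j, s in enumerate(matrix.sample_ids):
        out[str(s)] = matrix.values[:, j]
    return out


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> dict[str, str]:
    """Write result tables as TSV with missing values as empty strings.

    Returns a mapping of table name to written path; also drops a
    ``run_log.json`` with row counts next to the tables.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")
    paths: dict[str, str] = {}
    counts: dict[str, int] = {}
    for name, frame in tables.items():
        path = os.path.join(out_dir, f"{name}.tsv")
        frame.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.12g")
        paths[name] = path
        counts[name] = len(frame)
    log_path = os.path.join(out_dir, "run_log.json")
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump({"tables": counts}, fh, indent=2)
    paths["run_log"] = log_path
    return paths


def read_result_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results` (empty cell -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=[""], keep_default_na=True)
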