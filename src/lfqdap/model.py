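"""Core data model shared by all pipeline stages.

The pipeline operates on three matrix-shaped objects:

* :class:`AbundanceMatrix` — log2 peptide intensities, one row per peptide
  feature, one column per sample, ``NaN`` marking missing cells.  Missing
  cells are never imputed anywhere in this package.
* :class:`ProteinMatrix` — the protein-level analog produced by rollup.
* Long-form observation tables wrapped in :class:`PeptideTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


class LfqDapError(Exception):
    """Base class for all package errors."""


class FormatError(LfqDapError):
    """A file does not conform to its declared dialect."""


class InputError(LfqDapError):
    """Input is structurally valid but unusable (e.g. empty)."""


class ConsistencyError(LfqDapError):
    """Cross-table references do not line up."""


class ConfigurationError(LfqDapError):
    """Bad parameter combination or unknown method name."""


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison; effects are reported as B minus A."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ConfigurationError(
                f"contrast {self.name!r}: group_a and group_b are both {self.group_a!r}"
            )

    @property
    def groups(self) -> tuple[str, str]:
        return (self.group_a, self.group_b)


REQUIRED_PEPTIDE_COLUMNS = ("sample_id", "protein_id", "peptide_id", "intensity")


@dataclass
class PeptideTable:
    """Long-form peptide-level observations.

    ``frame`` columns: sample_id, protein_id, peptide_id, intensity (raw,
    linear scale, > 0), qvalue (may be NaN), detected (bool).  One row per
    (peptide_id, sample_id); each peptide maps to exactly one protein.
    """

    frame: pd.DataFrame
    n_malformed: int = 0

    def __post_init__(self) -> None:
        f = self.frame
        for col in REQUIRED_PEPTIDE_COLUMNS:
            if col not in f.columns:
                raise FormatError(f"peptide table lacks mandatory column {col!r}")
        if len(f) == 0:
            raise InputError("peptide table is empty")
        if "qvalue" not in f.columns:
            f = f.assign(qvalue=np.nan)
        if "detected" not in f.columns:
            f = f.assign(detected=f["intensity"].notna())
        dup = f.duplicated(subset=["peptide_id", "sample_id"])
        if dup.any():
            raise ConsistencyError(
                f"{int(dup.sum())} duplicate (peptide_id, sample_id) observations"
            )
        nprot = f.groupby("peptide_id", sort=False)["protein_id"].nunique()
        bad = nprot[nprot > 1]
        if len(bad):
            raise ConsistencyError(
                f"peptides mapped to multiple proteins: {list(bad.index[:5])}"
            )
        self.frame = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.frame["sample_id"]))

    @property
    def n_observations(self) -> int:
        return int(self.frame["intensity"].notna().sum())


@dataclass
class SampleMetadata:
    """Sample annotation: sample_id, group, exclude + free covariate columns.

    Excluded samples stay visible to QC but never enter filtering for DEA,
    normalization for DEA, or DEA itself.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("sample_id", "group"):
            if col not in f.columns:
                raise FormatError(f"sample metadata lacks mandatory column {col!r}")
        if "exclude" not in f.columns:
            f = f.assign(exclude=False)
        f = f.copy()
        f["exclude"] = f["exclude"].map(_parse_bool)
        if f["sample_id"].duplicated().any():
            raise ConsistencyError("duplicate sample_id in metadata")
        self.frame = f.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.frame["group"]))

    def group_of(self) -> Mapping[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["group"]))

    def included(self) -> "SampleMetadata":
        return SampleMetadata(self.frame[~self.frame["exclude"]].reset_index(drop=True))

    @property
    def extra_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("sample_id", "group", "exclude")]


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer, float, np.floating)):
        return bool(x) and not (isinstance(x, float) and np.isnan(x))
    s = str(x).strip().lower()
    return s in ("true", "t", "yes", "y", "1")


@dataclass
class AbundanceMatrix:
    """log2 feature-by-sample intensity matrix with explicit missingness.

    ``values[i, j]`` is the log2 intensity of feature ``feature_ids[i]`` in
    sample ``sample_ids[j]``; NaN means missing.  ``groups[j]`` is the group
    of column j.  ``feature_to_protein[i]`` maps row i to its protein.
    ``detected`` (optional) is the aligned boolean identification matrix.
    """

    values: np.ndarray
    feature_ids: np.ndarray
    sample_ids: np.ndarray
    groups: np.ndarray
    feature_to_protein: np.ndarray
    detected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.feature_to_protein = np.asarray(self.feature_to_protein, dtype=object)
        n, m = self.values.shape
        if not (len(self.feature_ids) == len(self.feature_to_protein) == n):
            raise ConsistencyError("row annotation length mismatch")
        if not (len(self.sample_ids) == len(self.groups) == m):
            raise ConsistencyError("column annotation length mismatch")
        if self.detected is not None:
            self.detected = np.asarray(self.detected, dtype=bool)
            if self.detected.shape != self.values.shape:
                raise ConsistencyError("detected matrix shape mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(),
            self.feature_ids.copy(),
            self.sample_ids.copy(),
            self.groups.copy(),
            self.feature_to_protein.copy(),
            None if self.detected is None else self.detected.copy(),
        )

    def subset_rows(self, idx) -> "AbundanceMatrix":
        idx = np.asarray(idx)
        return AbundanceMatrix(
            self.values[idx],
            self.feature_ids[idx],
            self.sample_ids,
            self.groups,
            self.feature_to_protein[idx],
            None if self.detected is None else self.detected[idx],
        )

    def subset_columns(self, idx) -> "AbundanceMatrix":
        idx = np.asarray(idx)
        return AbundanceMatrix(
            self.values[:, idx],
            self.feature_ids,
            self.sample_ids[idx],
            self.groups[idx],
            self.feature_to_protein,
            None if self.detected is None else self.detected[:, idx],
        )

    def columns_for_group(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.groups == group)


@dataclass
class ProteinMatrix:
    """log2 protein abundance after rollup.

    ``n_peptides[i]`` counts peptides of protein i with at least one
    non-missing cell in the input matrix (the count DEqMS-style moderation
    conditions on).
    """

    values: np.ndarray
    protein_ids: np.ndarray
    sample_ids: np.ndarray
    groups: np.ndarray
    n_peptides: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.n_peptides = np.asarray(self.n_peptides, dtype=int)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def columns_for_group(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.groups == group)


@dataclass
class NormOffsets:
    """Per-sample additive log2 offsets produced by a normalization step."""

    per_sample_offset: np.ndarray
    method: str
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        self.per_sample_offset = np.asarray(self.per_sample_offset, dtype=float)


@dataclass
class PairwiseModeMatrix:
    """Mode of between-group log2 foldchanges for every ordered group pair.

    ``m[g, h]`` is the mode of (mean-in-h minus mean-in-g) over shared
    features; antisymmetric up to mode-estimation tolerance; NaN marks pairs
    dropped for insufficient shared features.
    """

    groups: list
    m: np.ndarray
    n_shared: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.n_shared = np.asarray(self.n_shared, dtype=int)


@dataclass
class Dataset:
    """A peptide table together with its sample metadata."""

    table: PeptideTable
    metadata: SampleMetadata


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator.

    ``regulated`` maps each regulated protein_id to its direction (+1 up in
    group B, -1 down); ``true_fc`` holds the per-protein log2 foldchange
    (0 for background); ``true_loading_offsets`` the injected per-sample
    log2 loading offsets; ``complete`` the pre-missingness log2 matrix.
    """

    regulated: dict
    true_fc: dict
    true_loading_offsets: dict
    complete: AbundanceMatrix | None = None
    config: dict = field(default_factory=dict)

    @property
    def background(self) -> set:
        return {p for p, fc in self.true_fc.items() if fc == 0.0}
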