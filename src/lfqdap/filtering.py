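"""Feature selection: detection-rate filtering, protein-level minimums and
top-M peptide selection, dataset-wide or restricted to one contrast.

Rules are applied in a fixed order: (1) a peptide survives only if its
detected count (or fraction of replicates) meets the threshold in every
group in scope; (2) proteins with fewer surviving peptides than
``min_peptides_per_protein`` are dropped; (3) at most ``topn_peptides``
peptides are kept per protein, ranked by descending detected count, then
descending mean log2 intensity over in-scope samples, then peptide_id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AbundanceMatrix, ConfigurationError, Contrast


@dataclass(frozen=True)
class FilterParams:
    min_detect: int = 0
    min_detect_fraction: float | None = None
    min_peptides_per_protein: int = 1
    topn_peptides: int | None = None
    by_contrast: bool = False

    def __post_init__(self) -> None:
        if self.min_detect < 0:
            raise ConfigurationError("min_detect must be >= 0")
        if self.min_detect_fraction is not None:
            if not (0 <= self.min_detect_fraction <= 1):
                raise ConfigurationError("min_detect_fraction must be in [0, 1]")
            if self.min_detect > 0:
                raise ConfigurationError(
                    "set only one of min_detect / min_detect_fraction"
                )
        if self.min_peptides_per_protein < 1:
            raise ConfigurationError("min_peptides_per_protein must be >= 1")
        if self.topn_peptides is not None:
            if self.topn_peptides < 1:
                raise ConfigurationError("topn_peptides must be >= 1")
            if self.topn_peptides < self.min_peptides_per_protein:
                raise ConfigurationError(
                    "topn_peptides must be >= min_peptides_per_protein"
                )


def filter_peptides(
    matrix: AbundanceMatrix,
    detected: np.ndarray,
    params: FilterParams,
    groups_in_scope=None,
) -> AbundanceMatrix:
    """Apply the three selection rules; returns a row-subset of ``matrix``.

    ``groups_in_scope`` defaults to all groups present in the matrix.
    Row order of the input is preserved.
    """
    detected = np.asarray(detected, dtype=bool)
    if detected.shape != matrix.values.shape:
        raise ConfigurationError("detected matrix not aligned with abundance matrix")
    if groups_in_scope is None:
        groups_in_scope = list(dict.fromkeys(matrix.groups))
    groups_in_scope = list(groups_in_scope)

    scope_cols = np.zeros(matrix.n_samples, dtype=bool)
    keep = np.ones(matrix.n_features, dtype=bool)
    for g in groups_in_scope:
        cols = matrix.columns_for_group(g)
        if len(cols) == 0:
            raise ConfigurationError(f"group {g!r} has no samples in scope")
        scope_cols[cols] = True
        n_det = detected[:, cols].sum(axis=1)
        if params.min_detect_fraction is not None:
            threshold = math.ceil(params.min_detect_fraction * len(cols))
        else:
            threshold = params.min_detect
        keep &= n_det >= threshold

    keep = _apply_protein_rules(matrix, detected, keep, scope_cols, params)
    return matrix.subset_rows(np.flatnonzero(keep))


def _apply_protein_rules(
    matrix: AbundanceMatrix,
    detected: np.ndarray,
    keep: np.ndarray,
    scope_cols: np.ndarray,
    params: FilterParams,
) -> np.ndarray:
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        return keep
    prot = matrix.feature_to_protein[idx]
    counts = pd.Series(prot).value_counts()
    ok_prot = set(counts[counts >= params.min_peptides_per_protein].index)
    keep = keep.copy()
    for i in idx:
        if matrix.feature_to_protein[i] not in ok_prot:
            keep[i] = False

    if params.topn_peptides is None:
        return keep

    idx = np.flatnonzero(keep)
    det_count = detected[np.ix_(idx, np.flatnonzero(scope_cols))].sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_int = np.nanmean(
            np.where(
                np.isnan(matrix.values[np.ix_(idx, np.flatnonzero(scope_cols))]),
                np.nan,
                matrix.values[np.ix_(idx, np.flatnonzero(scope_cols))],
            ),
            axis=1,
        )
    mean_int = np.where(np.isnan(mean_int), -np.inf, mean_int)
    ranking = pd.DataFrame(
        {
            "row": idx,
            "protein": matrix.feature_to_protein[idx],
            "det": det_count,
            "mean": mean_int,
            "pep": matrix.feature_ids[idx],
        }
    )
    ranking = ranking.sort_values(
        ["protein", "det", "mean", "pep"], ascending=[True, False, False, True]
    )
    top = ranking.groupby("protein", sort=False).head(params.topn_peptides)
    keep_rows = set(top["row"])
    for i in idx:
        if i not in keep_rows:
            keep[i] = False
    return keep


def filter_for_contrast(
    matrix: AbundanceMatrix,
    detected: np.ndarray,
    params: FilterParams,
    contrast: Contrast,
) -> AbundanceMatrix:
    """By-contrast feature selection: filter on the contrast's two groups
    only, and drop samples outside the contrast from the result."""
    col_idx = np.flatnonzero(np.isin(matrix.groups, list(contrast.groups)))
    if len(col_idx) == 0:
        raise ConfigurationError(
            f"contrast {contrast.name!r}: no samples for groups {contrast.groups}"
        )
    sub = matrix.subset_columns(col_idx)
    det = np.asarray(detected, dtype=bool)[:, col_idx]
    return filter_peptides(sub, det, params, groups_in_scope=list(contrast.groups))
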