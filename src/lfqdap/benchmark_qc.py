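"""Ground-truth scoring for spike-in benchmarks plus dataset QC metrics.

Scoring: ROC curves over per-protein significance scores (smaller = more
significant), partial AUC at 95% specificity (trapezoid over
FPR in [0, 0.05]), distance-to-best within (contrast, DEA) cells of a
benchmark grid, background-foldchange centering and confusion counts at
q-value cutoffs.

QC: per-sample detected peptide counts, per-group coefficient-of-variation
summaries (linear scale), leave-one-out impact on within-group variation,
PCA coordinates of samples (complete-case rows) and per-contrast
foldchange-distribution summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import build_matrix
from .model import Dataset, InputError
from .normalization import estimate_mode


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    pauc95: float
    auc: float
    n_pos: int
    n_neg: int


def roc_pauc(scores, labels, specificity_floor: float = 0.95) -> RocResult:
    """ROC sweep over unique score thresholds; smaller score wins.

    ``pauc95`` integrates TPR over FPR in [0, 1 - specificity_floor] by
    the trapezoid rule; tied scores form a single threshold step.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ok = np.isfinite(scores)
    scores, labels = scores[ok], labels[ok]
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("roc_pauc requires both positive and negative labels")

    order = np.argsort(scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # block boundaries: last index of each tied-score run
    last = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    tp = np.cumsum(y)[last]
    fp = np.cumsum(~y)[last]
    fpr = np.r_[0.0, fp / n_neg]
    tpr = np.r_[0.0, tp / n_pos]
    thresholds = np.r_[-np.inf, s[last]]

    fpr_max = 1.0 - specificity_floor
    pauc = _partial_trapezoid(fpr, tpr, fpr_max)
    auc = _partial_trapezoid(fpr, tpr, 1.0)
    return RocResult(fpr, tpr, thresholds, pauc, auc, n_pos, n_neg)


def _partial_trapezoid(fpr: np.ndarray, tpr: np.ndarray, fpr_max: float) -> float:
    total = 0.0
    for i in range(1, len(fpr)):
        x0, x1 = fpr[i - 1], fpr[i]
        y0, y1 = tpr[i - 1], tpr[i]
        if x0 >= fpr_max:
            break
        if x1 > fpr_max:
            # linear interpolation at the integration boundary
            y1 = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0) if x1 > x0 else y0
            x1 = fpr_max
        total += 0.5 * (y0 + y1) * (x1 - x0)
    return float(total)


def distance_to_best(grid: pd.DataFrame, by=("contrast", "dea"), metric: str = "pauc95") -> pd.DataFrame:
    """Add ``distance_to_best`` = best metric within each group minus own."""
    out = grid.copy()
    best = out.groupby(list(by))[metric].transform("max")
    out["distance_to_best"] = best - out[metric]
    return out


def background_fc_median(dea_results: pd.DataFrame, background_set) -> float:
    """Median protein-level log2 foldchange over background proteins."""
    background_set = set(background_set)
    sub = dea_results[dea_results["protein_id"].isin(background_set)]
    fcs = sub["log2fc"].to_numpy(dtype=float)
    fcs = fcs[np.isfinite(fcs)]
    if fcs.size == 0:
        raise InputError("no background proteins among scored results")
    return float(np.median(fcs))


def confusion_counts(
    dea_results: pd.DataFrame,
    truth_positive,
    q_cutoffs=(0.01, 0.05),
    fc_threshold: float | None = None,
    min_peptides: int | None = None,
) -> pd.DataFrame:
    """TP/FP/TN/FN per q-value cutoff, with optional |fc| and peptide-count
    restrictions on what may count as significant."""
    truth_positive = set(truth_positive)
    sub = dea_results[np.isfinite(dea_results["qvalue"].to_numpy(dtype=float))].copy()
    if min_peptides is not None:
        sub = sub[sub["n_peptides"] >= min_peptides]
    is_pos = sub["protein_id"].isin(truth_positive).to_numpy()
    q = sub["qvalue"].to_numpy(dtype=float)
    fc_ok = (
        np.abs(sub["log2fc"].to_numpy(dtype=float)) >= fc_threshold
        if fc_threshold is not None
        else np.ones(len(sub), dtype=bool)
    )
    rows = []
    for cutoff in q_cutoffs:
        sig = (q <= cutoff) & fc_ok
        rows.append(
            {
                "q_cutoff": cutoff,
                "tp": int((sig & is_pos).sum()),
                "fp": int((sig & ~is_pos).sum()),
                "tn": int((~sig & ~is_pos).sum()),
                "fn": int((~sig & is_pos).sum()),
            }
        )
    return pd.DataFrame(rows)


def qc_metrics(dataset: Dataset, contrasts=None) -> dict[str, pd.DataFrame]:
    """Dataset-level QC tables (excluded samples included throughout).

    Returns tables: ``detect_counts``, ``cv`` (per-group median CV and the
    leave-one-out delta per sample), ``pca`` (first two components with
    metadata attached) and, when contrasts are given, ``fc_summary``.
    """
    meta = dataset.metadata
    matrix = build_matrix(dataset.table, meta, include_excluded=True)

    detect_counts = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "group": matrix.groups,
            "n_detected": matrix.detected.sum(axis=0) if matrix.detected is not None else np.nan,
            "n_quantified": np.isfinite(matrix.values).sum(axis=0),
        }
    )

    linear = np.power(2.0, matrix.values)
    cv_rows = []
    for g in dict.fromkeys(matrix.groups):
        cols = matrix.columns_for_group(g)
        full_cv = _median_cv(linear[:, cols])
        cv_rows.append({"group": g, "sample_id": "", "median_cv": full_cv, "loo_delta": np.nan})
        if len(cols) < 2:
            cv_rows[-1]["median_cv"] = np.nan
            continue
        for j in cols:
            rest = [c for c in cols if c != j]
            loo = _median_cv(linear[:, rest]) if len(rest) >= 2 else np.nan
            cv_rows.append(
                {
                    "group": g,
                    "sample_id": matrix.sample_ids[j],
                    "median_cv": loo,
                    "loo_delta": loo - full_cv if np.isfinite(loo) else np.nan,
                }
            )
    cv = pd.DataFrame(cv_rows)

    pca = _pca_coordinates(matrix)
    pca = pca.merge(meta.frame, on="sample_id", how="left")

    tables = {"detect_counts": detect_counts, "cv": cv, "pca": pca}
    if contrasts:
        fc_rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for c in contrasts:
                ma = np.nanmean(matrix.values[:, matrix.columns_for_group(c.group_a)], axis=1)
                mb = np.nanmean(matrix.values[:, matrix.columns_for_group(c.group_b)], axis=1)
                fc = (mb - ma)[np.isfinite(mb - ma)]
                fc_rows.append(
                    {
                        "contrast": c.name,
                        "n_features": fc.size,
                        "fc_median": float(np.median(fc)) if fc.size else np.nan,
                        "fc_mode": estimate_mode(fc) if fc.size else np.nan,
                    }
                )
        tables["fc_summary"] = pd.DataFrame(fc_rows)
    return tables


def _median_cv(linear: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(linear, axis=1)
        sd = np.nanstd(linear, axis=1, ddof=1)
        cv = sd / mean
    cv = cv[np.isfinite(cv)]
    return float(np.median(cv)) if cv.size else np.nan


def _pca_coordinates(matrix) -> pd.DataFrame:
    complete = ~np.isnan(matrix.values).any(axis=1)
    x = matrix.values[complete].T  # samples x features
    if x.shape[1] == 0:
        return pd.DataFrame(
            {"sample_id": matrix.sample_ids, "pc1": np.nan, "pc2": np.nan}
        )
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :2] * s[:2]
    if coords.shape[1] < 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    var = s**2 / max(1, len(x) - 1)
    frac = var[:2] / var.sum() if var.sum() > 0 else np.zeros(2)
    return pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "pc1": coords[:, 0],
            "pc2": coords[:, 1],
            "pc1_varfrac": frac[0],
            "pc2_varfrac": frac[1] if len(frac) > 1 else 0.0,
        }
    )
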