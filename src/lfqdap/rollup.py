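"""Peptide-to-protein rollup: sum, Tukey median polish, MaxLFQ-style
pairwise-ratio reconstruction.

All methods consume a log2 peptide matrix and return a log2
:class:`~lfqdap.model.ProteinMatrix`.  Proteins whose peptides are missing
everywhere are dropped; ``n_peptides`` counts peptides with at least one
observed cell.  Filtering (minimum peptides per protein, top-M) is owned
by the filtering module, not here.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np

from .model import AbundanceMatrix, ConfigurationError, ProteinMatrix

# tight enough that the profile matches an any-length run of the same
# sweeps to 1e-6; some missing-data patterns need well over 20 sweeps
TMP_TOL = 1e-9
TMP_MAX_SWEEPS = 100


def rollup(matrix: AbundanceMatrix, method: str = "maxlfq") -> ProteinMatrix:
    try:
        fn = {"sum": rollup_sum, "tmp": rollup_tmp, "maxlfq": rollup_maxlfq}[method]
    except KeyError:
        raise ConfigurationError(
            f"unknown rollup method {method!r}; expected sum, tmp or maxlfq"
        ) from None
    return fn(matrix)


def _protein_blocks(matrix: AbundanceMatrix):
    """Yield (protein_id, row indices) in sorted protein order."""
    order = np.argsort(matrix.feature_to_protein, kind="stable")
    prot_sorted = matrix.feature_to_protein[order]
    boundaries = np.flatnonzero(prot_sorted[1:] != prot_sorted[:-1]) + 1
    for block in np.split(order, boundaries):
        yield prot_sorted[0] if False else matrix.feature_to_protein[block[0]], block


def _assemble(matrix: AbundanceMatrix, rows, method: str) -> ProteinMatrix:
    ids, values, n_pep = [], [], []
    for pid, profile, n in rows:
        if np.all(np.isnan(profile)):
            continue
        ids.append(pid)
        values.append(profile)
        n_pep.append(n)
    return ProteinMatrix(
        values=np.vstack(values) if values else np.empty((0, matrix.n_samples)),
        protein_ids=np.asarray(ids, dtype=object),
        sample_ids=matrix.sample_ids.copy(),
        groups=matrix.groups.copy(),
        n_peptides=np.asarray(n_pep, dtype=int),
        method=method,
    )


def _n_observed_peptides(sub: np.ndarray) -> int:
    return int(np.any(np.isfinite(sub), axis=1).sum())


def rollup_sum(matrix: AbundanceMatrix) -> ProteinMatrix:
    """Protein abundance = log2 of the sum of linear peptide intensities."""
    rows = []
    linear = np.power(2.0, matrix.values)
    for pid, block in _protein_blocks(matrix):
        sub = linear[block]
        observed = np.isfinite(sub)
        total = np.where(observed, sub, 0.0).sum(axis=0)
        profile = np.where(observed.any(axis=0), np.log2(np.where(total > 0, total, 1.0)), np.nan)
        rows.append((pid, profile, _n_observed_peptides(matrix.values[block])))
    return _assemble(matrix, rows, "sum")


def median_polish(x: np.ndarray, tol: float = TMP_TOL, max_sweeps: int = TMP_MAX_SWEEPS) -> np.ndarray:
    """Tukey median polish; returns the per-column profile (overall + column
    effect).  Starts with a row sweep; missing cells contribute nothing."""
    resid = np.array(x, dtype=float)
    row_eff = np.zeros(resid.shape[0])
    col_eff = np.zeros(resid.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(max_sweeps):
            rm = np.nanmedian(resid, axis=1)
            rm = np.where(np.isfinite(rm), rm, 0.0)
            resid -= rm[:, None]
            row_eff += rm
            cm = np.nanmedian(resid, axis=0)
            cm = np.where(np.isfinite(cm), cm, 0.0)
            resid -= cm[None, :]
            col_eff += cm
            if max(np.max(np.abs(rm)), np.max(np.abs(cm))) < tol:
                break
    overall = float(np.median(row_eff))
    profile = overall + col_eff
    profile[~np.any(np.isfinite(x), axis=0)] = np.nan
    return profile


def rollup_tmp(matrix: AbundanceMatrix) -> ProteinMatrix:
    """Protein profile from Tukey median polish of each peptide block."""
    rows = []
    for pid, block in _protein_blocks(matrix):
        sub = matrix.values[block]
        rows.append((pid, median_polish(sub), _n_observed_peptides(sub)))
    return _assemble(matrix, rows, "tmp")


def maxlfq_profile(x: np.ndarray) -> np.ndarray:
    """MaxLFQ-style profile of one protein's peptide-by-sample log2 block.

    Pairwise sample ratios are medians over peptides observed in both
    samples; the per-sample profile solves the pairwise system in least
    squares, anchored so its mean equals the mean of all observed cells.
    Samples outside every valid pair are missing; if no pair is valid the
    per-sample mean of observed peptide cells is returned.
    """
    x = np.asarray(x, dtype=float)
    n_samples = x.shape[1]
    observed = np.isfinite(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        # r[j, k] = median over shared peptides of x[:, k] - x[:, j]
        diff = x[:, None, :] - x[:, :, None]
        r = np.nanmedian(diff, axis=0)
    pairs = [
        (j, k)
        for j, k in itertools.combinations(range(n_samples), 2)
        if np.isfinite(r[j, k])
    ]
    if not pairs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(x, axis=0)
    design = np.zeros((len(pairs) + 1, n_samples))
    target = np.zeros(len(pairs) + 1)
    in_pair = np.zeros(n_samples, dtype=bool)
    for i, (j, k) in enumerate(pairs):
        design[i, j] = -1.0
        design[i, k] = 1.0
        target[i] = r[j, k]
        in_pair[j] = in_pair[k] = True
    # soft anchor row keeps the system full rank; the exact anchor follows
    design[-1, in_pair] = 1.0 / in_pair.sum()
    p, *_ = np.linalg.lstsq(design, target, rcond=None)
    profile = np.full(n_samples, np.nan)
    profile[in_pair] = p[in_pair]
    anchor = np.nanmean(x[:, in_pair][observed[:, in_pair]]) if in_pair.any() else 0.0
    profile[in_pair] += anchor - np.nanmean(profile[in_pair])
    return profile


def rollup_maxlfq(matrix: AbundanceMatrix) -> ProteinMatrix:
    rows = []
    for pid, block in _protein_blocks(matrix):
        sub = matrix.values[block]
        rows.append((pid, maxlfq_profile(sub), _n_observed_peptides(sub)))
    return _assemble(matrix, rows, "maxlfq")
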