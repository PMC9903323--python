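"""Protein-level differential expression for two-group contrasts.

Implements empirical-Bayes moderated t-statistics (variance shrinkage
toward a constant prior estimated across proteins) and a peptide-count
aware variant where the prior variance follows a fitted trend on the
number of quantified peptides per protein.  Also provides BH adjustment,
a permutation-based foldchange threshold, and the ``run_dea``
orchestrator wiring filtering -> normalization -> rollup -> testing.

Result tables have one row per protein with columns: protein_id,
contrast, log2fc (group_b minus group_a), se, t, df, pvalue, qvalue,
n_peptides, algorithm, signif, reason (empty when tested; otherwise why
the protein was skipped).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .dataio import build_matrix
from .filtering import FilterParams, filter_for_contrast, filter_peptides
from .model import (
    ConfigurationError,
    Contrast,
    Dataset,
    InputError,
    ProteinMatrix,
)
from .normalization import normalize
from .rollup import rollup

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "protein_id", "contrast", "log2fc", "se", "t", "df",
    "pvalue", "qvalue", "n_peptides", "algorithm", "signif", "reason",
]

_D0_CAP = 1e6


@dataclass
class EBayesPrior:
    """Moderation hyperparameters: prior df d0 and prior variance s0sq.

    For the peptide-count-aware variant ``s0sq`` is a per-protein array
    following the fitted trend on n_peptides.
    """

    d0: float
    s0sq: np.ndarray

    def __post_init__(self) -> None:
        self.s0sq = np.atleast_1d(np.asarray(self.s0sq, dtype=float))
        if self.d0 <= 0:
            raise ConfigurationError("prior df d0 must be > 0")
        if np.any(self.s0sq <= 0):
            raise ConfigurationError("prior variance s0sq must be > 0")


def _trigamma_inverse(t: float) -> float:
    """Solve trigamma(y) = t by Newton iteration."""
    if t > 1e7:
        return 1.0 / math.sqrt(t)
    if t < 1e-6:
        return 1.0 / t
    y = 0.5 + 1.0 / t
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / t) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def _two_group_stats(pm: ProteinMatrix, contrast: Contrast):
    """Per-protein group means, residual variance and counts."""
    for g in contrast.groups:
        if len(pm.columns_for_group(g)) == 0:
            raise ConfigurationError(f"contrast {contrast.name!r}: group {g!r} absent")
    xa = pm.values[:, pm.columns_for_group(contrast.group_a)]
    xb = pm.values[:, pm.columns_for_group(contrast.group_b)]
    na = np.isfinite(xa).sum(axis=1)
    nb = np.isfinite(xb).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(xa, axis=1)
        mb = np.nanmean(xb, axis=1)
        ssa = np.nansum((xa - ma[:, None]) ** 2, axis=1)
        ssb = np.nansum((xb - mb[:, None]) ** 2, axis=1)
    df = na + nb - 2
    valid = (na >= 2) & (nb >= 2)
    s2 = np.full(len(pm.protein_ids), np.nan)
    s2[valid] = (ssa[valid] + ssb[valid]) / df[valid]
    fc = mb - ma
    return fc, s2, df.astype(float), na, nb, valid


def fit_variance_prior(s2: np.ndarray, df: np.ndarray, covariate_basis: np.ndarray | None = None) -> EBayesPrior:
    """Method-of-moments fit of the scaled inverse chi-square prior.

    Matches the mean and spread of log residual variances through
    digamma/trigamma identities.  With a ``covariate_basis`` the prior
    mean follows the fitted linear trend instead of a constant; the prior
    df is then estimated from the residual spread around the trend.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise InputError("fewer than 2 proteins with a valid residual variance; "
                         "moderation prior cannot be estimated (use a plain t-test)")
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    if covariate_basis is None:
        e_fit = np.full(ok.sum(), e.mean())
        resid = e - e_fit
        ddof = 1
    else:
        basis = covariate_basis[ok]
        design = np.column_stack([np.ones(len(basis)), basis])
        beta, *_ = np.linalg.lstsq(design, e, rcond=None)
        e_fit = design @ beta
        resid = e - e_fit
        ddof = design.shape[1]
    evar = resid.var(ddof=min(ddof, len(resid) - 1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, _D0_CAP)
        corr = special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    else:
        d0 = _D0_CAP
        corr = 0.0

    s0 = np.full(len(s2), np.nan)
    if covariate_basis is None:
        if evar > 0:
            s0[:] = float(np.exp(e.mean() + corr))
        else:
            # no excess spread: the best common variance is the plain average
            s0[:] = float(np.mean(s2[ok]))
    else:
        design_all = np.column_stack([np.ones(len(s2)), covariate_basis])
        s0 = np.exp(design_all @ beta + corr)
    return EBayesPrior(d0=d0, s0sq=s0)


def _moderated_table(
    pm: ProteinMatrix,
    contrast: Contrast,
    prior: EBayesPrior,
    algorithm: str,
    d0_override: float | None = None,
    alpha: float = 0.05,
    fc_threshold: float | None = None,
) -> pd.DataFrame:
    fc, s2, df, na, nb, valid = _two_group_stats(pm, contrast)
    n = len(pm.protein_ids)
    d0 = prior.d0 if d0_override is None else d0_override
    s0 = prior.s0sq if len(prior.s0sq) == n else np.full(n, prior.s0sq[0])

    with np.errstate(invalid="ignore", divide="ignore"):
        if d0 == 0:
            post = s2
            df_total = df
        else:
            post = (d0 * s0 + df * s2) / (d0 + df)
            df_total = np.minimum(d0 + df, _D0_CAP)
        se = np.sqrt(post * (1.0 / na + 1.0 / nb))
        t = fc / se
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    p = np.where(valid, p, np.nan)
    q = adjust_bh(p)
    signif = (q <= alpha) & (
        np.abs(fc) >= fc_threshold if fc_threshold is not None else True
    )
    reason = np.where(valid, "", "insufficient_replicates")
    return pd.DataFrame(
        {
            "protein_id": pm.protein_ids,
            "contrast": contrast.name,
            "log2fc": np.where(valid, fc, np.nan),
            "se": np.where(valid, se, np.nan),
            "t": np.where(valid, t, np.nan),
            "df": np.where(valid, df_total, np.nan),
            "pvalue": p,
            "qvalue": q,
            "n_peptides": pm.n_peptides,
            "algorithm": algorithm,
            "signif": np.where(valid, signif, False).astype(bool),
            "reason": reason,
        },
        columns=RESULT_COLUMNS,
    )


def fit_ebayes(
    pm: ProteinMatrix,
    contrast: Contrast,
    d0_override: float | None = None,
    alpha: float = 0.05,
    fc_threshold: float | None = None,
) -> pd.DataFrame:
    """Moderated two-group t-test with a constant variance prior.

    Per protein: log2fc = mean(B) - mean(A); the residual variance is
    shrunk toward the across-protein prior; t uses d0 + d degrees of
    freedom.  Proteins with fewer than 2 observed values in either group
    are reported with reason ``insufficient_replicates``.
    ``d0_override=0`` disables moderation (plain pooled t).
    """
    _, s2, df, *_ = _two_group_stats(pm, contrast)
    prior = fit_variance_prior(s2, df)
    return _moderated_table(pm, contrast, prior, "ebayes", d0_override, alpha, fc_threshold)


def _natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray | None:
    """Natural cubic spline basis (boundary + interior knots at quantiles).

    Returns None when x has too few distinct values for a spline."""
    ux = np.unique(x)
    if len(ux) < 4:
        if len(ux) < 2:
            return None
        return x[:, None]
    probs = np.linspace(0, 1, df + 1)
    knots = np.unique(np.quantile(x, probs))
    if len(knots) < 4:
        return x[:, None]
    k_max = knots[-1]
    k_pen = knots[-2]

    def d(knot, v):
        num = np.maximum(v - knot, 0) ** 3 - np.maximum(v - k_max, 0) ** 3
        return num / (k_max - knot)

    cols = [x]
    for knot in knots[:-2]:
        cols.append(d(knot, x) - d(k_pen, x))
    return np.column_stack(cols)


def fit_deqms(
    pm: ProteinMatrix,
    contrast: Contrast,
    d0_override: float | None = None,
    alpha: float = 0.05,
    fc_threshold: float | None = None,
) -> pd.DataFrame:
    """Moderated t with a peptide-count-dependent variance prior.

    The prior log-variance follows a natural cubic spline (3 df) fit on
    log n_peptides; the prior df is re-estimated from the spread around
    that trend.  Falls back to the constant prior when every protein has
    the same peptide count.
    """
    _, s2, df, *_ = _two_group_stats(pm, contrast)
    x = np.log(pm.n_peptides.astype(float))
    basis = _natural_spline_basis(x, df=3)
    if basis is None:
        logger.warning("fit_deqms: constant n_peptides; falling back to constant prior")
        out = fit_ebayes(pm, contrast, d0_override, alpha, fc_threshold)
        return out.assign(algorithm="deqms")
    prior = fit_variance_prior(s2, df, covariate_basis=basis)
    return _moderated_table(pm, contrast, prior, "deqms", d0_override, alpha, fc_threshold)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN p-values stay NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return q
    ps = p[ok]
    m = ps.size
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def estimate_fc_threshold(
    pm: ProteinMatrix,
    contrast: Contrast,
    n_permutations: int = 1000,
    quantile: float = 0.95,
    seed: int = 0,
) -> float:
    """Foldchange threshold from a group-label permutation test.

    Group labels of the contrast's samples are permuted (distinct
    assignments only); per-protein |log2fc| values from all permutations
    are pooled and the requested quantile returned.
    """
    cols_a = pm.columns_for_group(contrast.group_a)
    cols_b = pm.columns_for_group(contrast.group_b)
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise ConfigurationError("permutation threshold needs >= 3 samples per group")
    cols = np.concatenate([cols_a, cols_b])
    n_a = len(cols_a)
    all_assignments = list(itertools.combinations(range(len(cols)), n_a))
    if len(all_assignments) <= n_permutations:
        if len(all_assignments) < n_permutations:
            logger.warning(
                "only %d distinct permutations exist (requested %d); using all",
                len(all_assignments), n_permutations,
            )
        chosen = all_assignments
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(all_assignments), size=n_permutations, replace=False)
        chosen = [all_assignments[i] for i in idx]

    x = pm.values[:, cols]
    pooled = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for assign in chosen:
            mask = np.zeros(len(cols), dtype=bool)
            mask[list(assign)] = True
            fc = np.nanmean(x[:, ~mask], axis=1) - np.nanmean(x[:, mask], axis=1)
            pooled.append(np.abs(fc[np.isfinite(fc)]))
    pooled = np.concatenate(pooled)
    if pooled.size == 0:
        return 0.0
    return float(np.quantile(pooled, quantile))


_DEA_METHODS = {"ebayes": fit_ebayes, "deqms": fit_deqms}
_DEA_PLUGINS: dict = {}


def register_dea(name: str, fn) -> None:
    """Register a DEA plugin: ``fn(peptide_matrix, protein_matrix, contrast)
    -> result DataFrame`` with the standard columns."""
    _DEA_PLUGINS[name] = fn


@dataclass
class DeaConfig:
    algorithms: list[str] = field(default_factory=lambda: ["ebayes"])
    filter_params: FilterParams = field(default_factory=FilterParams)
    norm_chain: list[str] = field(default_factory=lambda: ["vwmb", "modebetween_protein"])
    rollup_method: str = "maxlfq"
    alpha: float = 0.05
    fc_threshold: float | str | None = None  # number, "permute", or None
    n_permutations: int = 1000
    permute_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ConfigurationError("at least one DEA algorithm is required")
        for a in self.algorithms:
            if a not in _DEA_METHODS and a not in _DEA_PLUGINS:
                raise ConfigurationError(
                    f"unknown DEA algorithm {a!r}; known: "
                    f"{sorted(set(_DEA_METHODS) | set(_DEA_PLUGINS))}"
                )


def run_dea(dataset: Dataset, contrasts, config: DeaConfig) -> pd.DataFrame:
    """Full per-contrast pipeline: filter -> normalize -> rollup -> test.

    Excluded samples never enter any stage.  Returns the concatenation of
    per-contrast, per-algorithm result tables.
    """
    matrix = build_matrix(dataset.table, dataset.metadata, include_excluded=False)
    results = []
    for ci, contrast in enumerate(contrasts):
        for g in contrast.groups:
            if not np.any(matrix.groups == g):
                raise ConfigurationError(
                    f"contrast {contrast.name!r}: group {g!r} has no usable samples"
                )
        if config.filter_params.by_contrast:
            sub = filter_for_contrast(matrix, matrix.detected, config.filter_params, contrast)
        else:
            sub = filter_peptides(matrix, matrix.detected, config.filter_params)
            cols = np.flatnonzero(np.isin(sub.groups, list(contrast.groups)))
            sub = sub.subset_columns(cols)
        normed, _ = normalize(sub, config.norm_chain)
        prot = rollup(normed, method=config.rollup_method)

        if config.fc_threshold == "permute":
            child_seed = int(np.random.SeedSequence([config.seed, ci]).generate_state(1)[0])
            threshold = estimate_fc_threshold(
                prot, contrast, config.n_permutations, config.permute_quantile, child_seed
            )
        else:
            threshold = config.fc_threshold

        for algo in config.algorithms:
            if algo in _DEA_METHODS:
                res = _DEA_METHODS[algo](
                    prot, contrast, alpha=config.alpha, fc_threshold=threshold
                )
            else:
                res = _DEA_PLUGINS[algo](normed, prot, contrast)
                res = res.assign(algorithm=algo, contrast=contrast.name)
            results.append(res)
    return pd.concat(results, ignore_index=True)
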