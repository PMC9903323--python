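"""Sample scaling by within-group variation and between-group foldchange modes.

All methods return a single additive log2 offset per sample; applying a
method adds that constant to every non-missing cell of the column and
leaves missing cells missing.  Available methods:

* ``median`` — per-column median centering to the global median (baseline);
* ``var_overall`` — within-group variation minimization with all samples
  treated as one group;
* ``vwmb`` — within-group variation minimization (VW) followed by
  between-group foldchange-mode alignment (MB);
* ``mwmb`` — within-group pairwise foldchange-mode alignment (MW)
  followed by MB;
* ``modebetween`` — MB alone;
* ``modebetween_protein`` — MB computed on the protein-rolled matrix and
  applied to the peptide matrix (chainable after any other method).

The MB step estimates, for every pair of sample groups, the mode of the
per-feature log2 foldchange of group means, then chooses zero-sum
per-group offsets minimizing the summed absolute residual modes.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
from scipy import stats

from .model import (
    AbundanceMatrix,
    ConfigurationError,
    NormOffsets,
    PairwiseModeMatrix,
)

logger = logging.getLogger(__name__)

MODE_MIN_COUNT = 10
VW_TOL = 1e-6
VW_MAX_ITER = 100
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 200
IRLS_EPS = 1e-6


def estimate_mode(values, bandwidth_rule: str = "silverman", min_count: int = MODE_MIN_COUNT) -> float:
    """Mode of a sample: argmax of a Gaussian KDE on a 512-point grid.

    The grid spans [min, max] padded by three bandwidths.  With fewer than
    ``min_count`` finite values the median is returned with a warning.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("estimate_mode: no finite values")
    if v.size < min_count:
        logger.warning("estimate_mode: only %d finite values, falling back to median", v.size)
        return float(np.median(v))
    if np.ptp(v) < 1e-12:
        return float(v[0])
    kde = stats.gaussian_kde(v, bw_method=bandwidth_rule)
    bw = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(v.min() - 3 * bw, v.max() + 3 * bw, 512)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def _median_row_variance(x: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rv = np.nanvar(x, axis=1, ddof=1)
    rv = rv[np.isfinite(rv)]
    return float(np.median(rv)) if rv.size else 0.0


def vw_offsets(values: np.ndarray, groups, tol: float = VW_TOL, max_iter: int = VW_MAX_ITER) -> NormOffsets:
    """Within-group variation minimization.

    For each group independently, each column's offset is iteratively set
    to the median over rows of (within-group row mean minus cell) until the
    largest offset update falls below ``tol``.  Offsets are centered to
    zero mean per group; single-sample groups keep offset zero.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    offsets = np.zeros(values.shape[1])
    converged = True
    iterations = 0
    for g in dict.fromkeys(groups):
        cols = np.flatnonzero(groups == g)
        if len(cols) < 2:
            continue
        x = values[:, cols]
        off = np.zeros(len(cols))
        it = 0
        for it in range(1, max_iter + 1):
            adj = x + off
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rowmean = np.nanmean(adj, axis=1)
                delta = np.nanmedian(rowmean[:, None] - adj, axis=0)
            delta = np.where(np.isfinite(delta), delta, 0.0)
            off += delta
            if np.max(np.abs(delta)) < tol:
                break
        else:
            converged = False
        iterations = max(iterations, it)
        offsets[cols] = off - off.mean()
    return NormOffsets(offsets, "vw", converged=converged, iterations=iterations)


def mw_offsets(values: np.ndarray, groups, min_shared: int = MODE_MIN_COUNT) -> NormOffsets:
    """Within-group pairwise foldchange-mode alignment.

    For each group, the mode of pairwise column differences (over rows
    non-missing in both samples) defines a pairwise system solved for
    zero-sum per-sample offsets within the group.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    offsets = np.zeros(values.shape[1])
    converged = True
    iterations = 0
    for g in dict.fromkeys(groups):
        cols = np.flatnonzero(groups == g)
        k = len(cols)
        if k < 2:
            continue
        m = np.zeros((k, k))
        n_shared = np.zeros((k, k), dtype=int)
        for a, b in itertools.combinations(range(k), 2):
            diff = values[:, cols[b]] - values[:, cols[a]]
            diff = diff[np.isfinite(diff)]
            n_shared[a, b] = n_shared[b, a] = diff.size
            if diff.size < min_shared:
                logger.warning(
                    "mw_offsets: samples %s/%s share only %d features; pair dropped",
                    cols[a], cols[b], diff.size,
                )
                m[a, b] = m[b, a] = np.nan
                continue
            mode = estimate_mode(diff)
            m[a, b] = mode
            m[b, a] = -mode
        pm = PairwiseModeMatrix(groups=list(cols), m=m, n_shared=n_shared)
        off = solve_offsets_from_pairwise_modes(pm)
        # the solver reproduces the mode differences; the correction is their negation
        offsets[cols] = -off.per_sample_offset
        converged &= off.converged
        iterations = max(iterations, off.iterations)
    return NormOffsets(offsets, "mw", converged=converged, iterations=iterations)


def pairwise_group_modes(values: np.ndarray, groups, min_shared: int = MODE_MIN_COUNT) -> PairwiseModeMatrix:
    """Mode of between-group log2 foldchanges for every group pair.

    Group means are taken over non-missing cells; features missing entirely
    in either group are skipped for that pair.  Pairs sharing fewer than
    ``min_shared`` features are marked NaN (dropped from the objective).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    names = list(dict.fromkeys(groups))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.column_stack(
            [np.nanmean(values[:, np.flatnonzero(groups == g)], axis=1) for g in names]
        )
    k = len(names)
    m = np.zeros((k, k))
    n_shared = np.zeros((k, k), dtype=int)
    for a, b in itertools.combinations(range(k), 2):
        fc = means[:, b] - means[:, a]
        fc = fc[np.isfinite(fc)]
        n_shared[a, b] = n_shared[b, a] = fc.size
        if fc.size < min_shared:
            logger.warning(
                "pairwise_group_modes: groups %r/%r share only %d features; pair dropped",
                names[a], names[b], fc.size,
            )
            m[a, b] = m[b, a] = np.nan
            continue
        mode = estimate_mode(fc)
        m[a, b] = mode
        m[b, a] = -mode
    return PairwiseModeMatrix(groups=names, m=m, n_shared=n_shared)


def solve_offsets_from_pairwise_modes(pm: PairwiseModeMatrix) -> NormOffsets:
    """Zero-sum offsets minimizing sum over pairs of |m[g,h] - (o_h - o_g)|.

    Solved by iteratively reweighted least squares on the pair-difference
    design (weights 1/max(|residual|, 1e-6)), initialized from ordinary
    least squares.  Raises if the pair graph is disconnected.
    """
    k = len(pm.groups)
    pairs = [
        (a, b, pm.m[a, b])
        for a, b in itertools.combinations(range(k), 2)
        if np.isfinite(pm.m[a, b])
    ]
    if k == 1:
        return NormOffsets(np.zeros(1), "mb-solver", converged=True, iterations=0)
    _check_connected(k, pairs, pm.groups)

    design = np.zeros((len(pairs), k))
    target = np.zeros(len(pairs))
    for i, (a, b, mode) in enumerate(pairs):
        design[i, a] = -1.0
        design[i, b] = 1.0
        target[i] = mode
    o, *_ = np.linalg.lstsq(design, target, rcond=None)
    o -= o.mean()
    converged = False
    it = 0
    for it in range(1, IRLS_MAX_ITER + 1):
        resid = target - design @ o
        w = 1.0 / np.maximum(np.abs(resid), IRLS_EPS)
        sw = np.sqrt(w)
        o_new, *_ = np.linalg.lstsq(design * sw[:, None], target * sw, rcond=None)
        o_new -= o_new.mean()
        change = float(np.max(np.abs(o_new - o)))
        o = o_new
        if change < IRLS_TOL:
            converged = True
            break
    return NormOffsets(o, "mb-solver", converged=converged, iterations=it)


def _check_connected(k: int, pairs, names) -> None:
    adj: dict[int, set[int]] = {i: set() for i in range(k)}
    for a, b, _ in pairs:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[int] = set()
    components = []
    for start in range(k):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt in adj[node] - comp:
                comp.add(nxt)
                stack.append(nxt)
        seen |= comp
        components.append(sorted(names[i] for i in comp))
    if len(components) > 1:
        raise ConfigurationError(
            f"pairwise mode graph is disconnected; components: {components}"
        )


def mb_offsets(values: np.ndarray, groups, min_shared: int = MODE_MIN_COUNT) -> NormOffsets:
    """Between-group foldchange-mode alignment.

    Every sample of group g receives the group offset o_g from
    :func:`solve_offsets_from_pairwise_modes` applied to the pairwise mode
    matrix of group-mean foldchanges.  Requires at least two groups.
    """
    groups = np.asarray(groups, dtype=object)
    names = list(dict.fromkeys(groups))
    if len(names) < 2:
        raise ConfigurationError("mb_offsets requires at least two groups")
    pm = pairwise_group_modes(values, groups, min_shared=min_shared)
    sol = solve_offsets_from_pairwise_modes(pm)
    # the solver reproduces the mode differences; the correction is their negation
    per_group = dict(zip(pm.groups, -sol.per_sample_offset))
    offsets = np.array([per_group[g] for g in groups])
    return NormOffsets(offsets, "mb", converged=sol.converged, iterations=sol.iterations)


def mb_objective(pm: PairwiseModeMatrix, offsets) -> float:
    """Sum over retained pairs of |m[g,h] - (o_h - o_g)| (diagnostic)."""
    offsets = np.asarray(offsets, dtype=float)
    total = 0.0
    for a, b in itertools.combinations(range(len(pm.groups)), 2):
        if np.isfinite(pm.m[a, b]):
            total += abs(pm.m[a, b] - (offsets[b] - offsets[a]))
    return total


def median_offsets(values: np.ndarray, groups=None) -> NormOffsets:
    """Per-column median centering to the global median of all cells."""
    values = np.asarray(values, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_med = np.nanmedian(values, axis=0)
    finite = values[np.isfinite(values)]
    global_med = float(np.median(finite)) if finite.size else 0.0
    offsets = np.where(np.isfinite(col_med), global_med - col_med, 0.0)
    return NormOffsets(offsets, "median")


def var_overall_offsets(values: np.ndarray, groups=None) -> NormOffsets:
    """Variation minimization over the whole matrix (one-group VW)."""
    values = np.asarray(values, dtype=float)
    one_group = np.asarray(["__all__"] * values.shape[1], dtype=object)
    off = vw_offsets(values, one_group)
    return NormOffsets(off.per_sample_offset, "var_overall", off.converged, off.iterations)


def modebetween_protein(
    matrix: AbundanceMatrix, groups=None, rollup_method: str = "maxlfq"
) -> NormOffsets:
    """Between-group mode alignment computed at protein level.

    The peptide matrix is rolled up to proteins (default MaxLFQ-style),
    MB offsets are computed on the protein matrix and applied per sample
    of the peptide matrix (within-group scaling disabled).
    """
    from .rollup import rollup

    groups = matrix.groups if groups is None else np.asarray(groups, dtype=object)
    prot = rollup(matrix, method=rollup_method)
    off = mb_offsets(prot.values, prot.groups)
    per_group = {g: off.per_sample_offset[np.flatnonzero(prot.groups == g)[0]]
                 for g in dict.fromkeys(prot.groups)}
    offsets = np.array([per_group[g] for g in groups])
    return NormOffsets(offsets, "modebetween_protein", off.converged, off.iterations)


def _vwmb(matrix: AbundanceMatrix) -> NormOffsets:
    vw = vw_offsets(matrix.values, matrix.groups)
    mb = mb_offsets(matrix.values + vw.per_sample_offset, matrix.groups)
    return NormOffsets(
        vw.per_sample_offset + mb.per_sample_offset,
        "vwmb",
        vw.converged and mb.converged,
        vw.iterations + mb.iterations,
    )


def _mwmb(matrix: AbundanceMatrix) -> NormOffsets:
    mw = mw_offsets(matrix.values, matrix.groups)
    mb = mb_offsets(matrix.values + mw.per_sample_offset, matrix.groups)
    return NormOffsets(
        mw.per_sample_offset + mb.per_sample_offset,
        "mwmb",
        mw.converged and mb.converged,
        mw.iterations + mb.iterations,
    )


_METHODS = {
    "median": lambda m: median_offsets(m.values),
    "var_overall": lambda m: var_overall_offsets(m.values),
    "vwmb": _vwmb,
    "mwmb": _mwmb,
    "modebetween": lambda m: mb_offsets(m.values, m.groups),
    "modebetween_protein": modebetween_protein,
}

_PLUGINS: dict = {}


def register_normalizer(name: str, fn) -> None:
    """Register a plugin: ``fn(log2_values, groups) -> per-sample offsets``."""
    _PLUGINS[name] = fn


def registered_methods() -> list[str]:
    return sorted(set(_METHODS) | set(_PLUGINS))


def normalize(matrix: AbundanceMatrix, chain, groups=None) -> tuple[AbundanceMatrix, list[NormOffsets]]:
    """Apply a chain of normalization methods left to right.

    Returns the normalized matrix (missing mask untouched) and one
    :class:`NormOffsets` per chain element.
    """
    if isinstance(chain, str):
        chain = [s for s in chain.split(",") if s]
    if not chain:
        raise ConfigurationError("normalization chain is empty")
    out = matrix.copy()
    if groups is not None:
        out.groups = np.asarray(groups, dtype=object)
    all_offsets: list[NormOffsets] = []
    for name in chain:
        if name in _METHODS:
            off = _METHODS[name](out)
        elif name in _PLUGINS:
            raw = np.asarray(_PLUGINS[name](out.values, out.groups), dtype=float)
            off = NormOffsets(raw, name)
        else:
            raise ConfigurationError(
                f"unknown normalization {name!r}; registered: {registered_methods()}"
            )
        out.values = out.values + off.per_sample_offset
        all_offsets.append(off)
    return out, all_offsets
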