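"""A weighted-correlation-network (WGCNA-style) hub comparator.

The classic alternative to outdegree-based hub ranking: build a soft
correlation adjacency, transform it to a topological overlap matrix
(TOM), cluster genes into co-expression modules, summarize each module by
its eigengene (first principal component), and rank regulators by module
membership kME — the absolute correlation of a regulator's profile with
its module's eigengene.

Module detection uses average-linkage hierarchical clustering on
1 - TOM with a static height cut plus a minimum-size filter.  This is a
simplified, parameterized stand-in for the dynamic tree-cut algorithm:
the comparator only needs representative module structure, not the full
adaptive cut.  Modules whose eigengenes correlate above
``1 - merge_threshold`` are merged iteratively until stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DegenerateDataError, ValidationError
from .io import ExpressionMatrix, RegulatorSet

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleAssignment",
    "pick_soft_power",
    "adjacency",
    "topological_overlap",
    "module_eigengene",
    "detect_modules",
    "kme_hub_ranking",
    "wgcna_hub_pipeline",
]

DEFAULT_POWERS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


@dataclass(frozen=True)
class ModuleAssignment:
    """Gene → module labels (0 = unassigned) with per-module eigengenes
    (unit-variance sample profiles) and the soft power used."""

    labels: dict[str, int]
    eigengenes: dict[int, np.ndarray]
    power: int


def _correlation_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gene-gene Pearson correlations; zero-variance genes get zero
    rows/columns (flag mask returned)."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat] = 0.0
    corr = (z @ z.T) / values.shape[1]
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr, flat


def adjacency(expr: ExpressionMatrix, power: int) -> np.ndarray:
    """Unsigned soft adjacency a_ij = |cor(i, j)|^power with unit diagonal.

    Zero-variance genes get zero off-diagonal entries (correlation is
    undefined there) with a logged warning.
    """
    if power < 1:
        raise ValidationError("power must be >= 1")
    corr, flat = _correlation_matrix(expr.values)
    if flat.any():
        logger.warning(
            "%d zero-variance gene(s); adjacency rows set to 0", int(flat.sum())
        )
    a = np.abs(corr) ** power
    np.fill_diagonal(a, 1.0)
    return a


def pick_soft_power(
    expr: ExpressionMatrix,
    powers: tuple[int, ...] = DEFAULT_POWERS,
    fit_target: float = 0.8,
    n_bins: int = 10,
) -> int:
    """Smallest candidate power whose scale-free topology fit reaches
    ``fit_target``; if none qualifies, the power with the best fit (logged).

    The fit index is the signed R² of the log10(frequency) on
    log10(connectivity) regression over occupied connectivity bins, made
    negative when the slope is positive (scale-free topology requires a
    decreasing degree distribution).
    """
    if not powers:
        raise ValidationError("candidate power list is empty")
    best_power, best_fit = None, -np.inf
    for power in sorted(powers):
        a = adjacency(expr, power)
        k = a.sum(axis=1) - 1.0  # exclude the unit diagonal
        fit = _scale_free_fit(k, n_bins)
        if fit >= fit_target:
            return power
        if fit > best_fit:
            best_fit, best_power = fit, power
    logger.info(
        "no candidate reached fit %.2f; using power %d (fit %.3f)",
        fit_target,
        best_power,
        best_fit,
    )
    return int(best_power)


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the log-log frequency-vs-connectivity regression."""
    k = connectivity[connectivity > 0]
    if k.size == 0 or k.max() == k.min():
        raise DegenerateDataError("degenerate connectivity; cannot assess fit")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occupied = counts > 0
    if occupied.sum() < 3:
        raise DegenerateDataError(
            f"only {int(occupied.sum())} occupied connectivity bins (need >= 3)"
        )
    x = np.log10(centers[occupied])
    y = np.log10(counts[occupied])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency in [0, 1] with unit
    diagonal:

        TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij)
                 / (min(k_i, k_j) + 1 - a_ij),   TOM_ii = 1,

    where k_i is node i's connectivity (row sum excluding the diagonal).
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0, atol=1e-12):
        raise ValidationError("adjacency diagonal must be 1")
    k = a.sum(axis=1) - 1.0
    # shared-neighbor term: (A^2)_ij minus the two diagonal contributions
    shared = a @ a - 2.0 * a  # = sum_{u != i,j} a_iu a_uj when a_ii = a_jj = 1
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    return tom


def module_eigengene(expr: ExpressionMatrix, member_ids: list[str]) -> np.ndarray:
    """First principal component of the standardized member submatrix,
    scaled to unit variance, sign-oriented so the mean correlation with
    the member genes is non-negative."""
    if len(member_ids) < 2:
        raise ValidationError("a module needs >= 2 member genes")
    rows = np.array([expr.gene_index(g) for g in member_ids])
    sub = expr.values[rows]
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    if np.all(sd == 0):
        raise DegenerateDataError("module submatrix has rank 0")
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    # first right singular vector = PC1 sample profile
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0:
        raise DegenerateDataError("module submatrix has rank 0")
    pc = vt[0]
    sd_pc = pc.std()
    if sd_pc == 0:
        raise DegenerateDataError("eigengene is constant")
    eig = (pc - pc.mean()) / sd_pc
    corr_mean = float(np.mean(z @ eig) / expr.n_samples)
    if corr_mean < 0:
        eig = -eig
    return eig


def _eigengene_for(expr: ExpressionMatrix, labels: dict[str, int], module: int) -> np.ndarray:
    members = sorted(g for g, m in labels.items() if m == module)
    return module_eigengene(expr, members)


def detect_modules(
    tom: np.ndarray,
    min_module_size: int,
    cut_height: float,
    merge_threshold: float,
    expr: ExpressionMatrix,
) -> ModuleAssignment:
    """Cluster genes into modules from a TOM.

    Average-linkage hierarchical clustering on 1 - TOM, cut statically at
    ``cut_height`` × (maximum merge height); clusters below
    ``min_module_size`` are unassigned (label 0).  Module pairs whose
    eigengenes correlate above ``1 - merge_threshold`` are merged
    iteratively (recomputing eigengenes) until stable.  Labels are
    renumbered 1..M by decreasing module size (ties by smallest member
    id), independent of gene input order.
    """
    if min_module_size < 2:
        raise ValidationError("min_module_size must be >= 2")
    if not 0.0 < cut_height < 1.0:
        raise ValidationError("cut_height must be in (0, 1)")
    if not 0.0 < merge_threshold < 1.0:
        raise ValidationError("merge_threshold must be in (0, 1)")
    genes = list(expr.gene_ids)
    if tom.shape != (len(genes), len(genes)):
        raise ValidationError("TOM shape does not match the expression matrix")
    # order-independence: cluster in sorted-gene order
    order = sorted(range(len(genes)), key=lambda i: genes[i])
    tom_sorted = tom[np.ix_(order, order)]
    dissim = 1.0 - tom_sorted
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    Z = linkage(condensed, method="average")
    max_h = float(Z[:, 2].max()) if len(Z) else 0.0
    if max_h <= 0:
        raise DegenerateDataError("all genes identical; no module structure")
    flat = fcluster(Z, t=cut_height * max_h, criterion="distance")
    labels: dict[str, int] = {}
    for pos, idx in enumerate(order):
        labels[genes[idx]] = int(flat[pos])
    # drop undersized clusters
    sizes: dict[int, int] = {}
    for m in labels.values():
        sizes[m] = sizes.get(m, 0) + 1
    for g, m in labels.items():
        if sizes[m] < min_module_size:
            labels[g] = 0
    if all(m == 0 for m in labels.values()):
        raise DegenerateDataError(
            "no module passed the minimum size filter; lower min_module_size "
            "or raise cut_height"
        )
    labels = _renumber(labels)
    eigengenes = {
        m: _eigengene_for(expr, labels, m) for m in sorted(set(labels.values())) if m
    }
    # iterative merging of similar modules
    while True:
        mods = sorted(eigengenes)
        best: tuple[float, int, int] | None = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                e1, e2 = eigengenes[mods[i]], eigengenes[mods[j]]
                r = float(np.mean(e1 * e2))  # both unit-variance, zero-mean
                if r > 1.0 - merge_threshold and (best is None or r > best[0]):
                    best = (r, mods[i], mods[j])
        if best is None:
            break
        _, keep, absorb = best
        for g, m in labels.items():
            if m == absorb:
                labels[g] = keep
        labels = _renumber(labels)
        eigengenes = {
            m: _eigengene_for(expr, labels, m)
            for m in sorted(set(labels.values()))
            if m
        }
    power = 0  # caller records the power actually used
    return ModuleAssignment(labels, eigengenes, power)


def _renumber(labels: dict[str, int]) -> dict[str, int]:
    """Renumber modules 1..M by decreasing size, ties by smallest member
    gene id; label 0 is preserved."""
    members: dict[int, list[str]] = {}
    for g, m in labels.items():
        if m:
            members.setdefault(m, []).append(g)
    ordered = sorted(members.items(), key=lambda kv: (-len(kv[1]), min(kv[1])))
    remap = {old: new for new, (old, _) in enumerate(ordered, start=1)}
    return {g: (remap[m] if m else 0) for g, m in labels.items()}


def kme_hub_ranking(
    expr: ExpressionMatrix,
    modules: ModuleAssignment,
    regs: RegulatorSet,
) -> list[tuple[str, float]]:
    """Rank regulators by module membership kME.

    kME is the absolute correlation of the regulator's profile with its
    own module's eigengene; regulators left unassigned (label 0) fall
    back to their maximum |kME| over all modules so every regulator is
    rankable.  Descending score, ties by id.
    """
    if not modules.eigengenes:
        raise ValidationError("module assignment has no modules")
    n = expr.n_samples
    scored: list[tuple[str, float]] = []
    for reg in regs.sorted_ids:
        profile = expr.profile(reg)
        sd = profile.std()
        if sd == 0:
            scored.append((reg, 0.0))
            continue
        z = (profile - profile.mean()) / sd
        kmes = {
            m: abs(float(np.mean(z * eig))) for m, eig in modules.eigengenes.items()
        }
        module = modules.labels.get(reg, 0)
        score = kmes[module] if module in kmes else max(kmes.values())
        scored.append((reg, min(1.0, score)))
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return scored


def wgcna_hub_pipeline(
    expr: ExpressionMatrix,
    regs: RegulatorSet,
    power: int | None = None,
    min_module_size: int = 20,
    cut_height: float = 0.99,
    merge_threshold: float = 0.25,
    fit_target: float = 0.8,
) -> tuple[list[tuple[str, float]], ModuleAssignment]:
    """End-to-end comparator: adjacency → TOM → modules → eigengenes →
    kME ranking.  ``power=None`` selects the soft power automatically."""
    if power is None:
        power = pick_soft_power(expr, fit_target=fit_target)
        logger.info("selected soft power %d", power)
    a = adjacency(expr, power)
    tom = topological_overlap(a)
    modules = detect_modules(tom, min_module_size, cut_height, merge_threshold, expr)
    modules = ModuleAssignment(modules.labels, modules.eigengenes, power)
    ranking = kme_hub_ranking(expr, modules, regs)
    return ranking, modules
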