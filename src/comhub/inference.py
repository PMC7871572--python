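"""The six gene-regulatory-network inference engines.

Each engine maps an (:class:`~comhub.io.ExpressionMatrix`,
:class:`~comhub.io.RegulatorSet`) pair to a
:class:`~comhub.io.RankedEdgeList` of directed regulator→target edges
with a method-specific confidence.  The compendium covers the main
families of expression-based inference:

======================  =================================================
engine                  confidence
======================  =================================================
``pcc``                 absolute Pearson correlation of the two profiles
``clr``                 background-corrected mutual-information z-score
``aracne``              mutual information after data-processing-
                        inequality triangle pruning
``genie3``              per-target random-forest importance (variance
                        reduction, normalized to sum 1 per target)
``elasticnet``          bootstrap selection frequency of an elastic-net
                        coefficient
``tigress``             stability-selection area score over a randomized
                        least-angle regression path
======================  =================================================

All engines are deterministic given ``random_seed``.  Correlation and
mutual-information engines use raw profiles (equal-frequency binning is
already invariant to monotone transforms); the regression engines
standardize each profile to zero mean and unit variance internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, lars_path
from sklearn.model_selection import KFold

from .errors import ValidationError
from .io import ExpressionMatrix, RankedEdgeList, RegulatorSet

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceConfig",
    "pcc_network",
    "mutual_information_matrix",
    "clr",
    "clr_from_mi",
    "aracne",
    "genie3",
    "elasticnet_bootstrap",
    "tigress",
    "run_engine",
    "ENGINES",
]


@dataclass(frozen=True)
class InferenceConfig:
    """Engine hyperparameters with package defaults.

    ``n_bootstrap`` defaults to 1000 bootstrap resamples for the
    elastic-net engine; ``n_trees`` to 1000 trees considering *all*
    regulator features at each split, which keeps the importances
    conditional on the other regulators — with small regulator panels a
    "sqrt" fraction makes the importances nearly marginal and leaks
    credit to correlated proxy regulators ("sqrt" remains available for
    large panels where it is the usual speed/accuracy trade).  TIGRESS
    uses its published defaults (1000 resamples, 5 LARS steps,
    perturbation 0.2).
    """

    mi_bins: int = 10
    dpi_tolerance: float = 0.0
    n_trees: int = 1000
    tree_feature_fraction: str | float = "all"
    n_bootstrap: int = 1000
    l1_ratio: float = 0.5
    n_resample: int = 1000
    lars_steps: int = 5
    perturbation_alpha: float = 0.2
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.mi_bins < 2:
            raise ValidationError("mi_bins must be >= 2")
        if not 0.0 <= self.dpi_tolerance <= 1.0:
            raise ValidationError("dpi_tolerance must be in [0, 1]")
        for name in ("n_trees", "n_bootstrap", "n_resample", "lars_steps"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if not 0.0 < self.l1_ratio <= 1.0:
            raise ValidationError("l1_ratio must be in (0, 1]")
        if not 0.0 < self.perturbation_alpha <= 1.0:
            raise ValidationError("perturbation_alpha must be in (0, 1]")
        if isinstance(self.tree_feature_fraction, str):
            if self.tree_feature_fraction not in ("sqrt", "all"):
                raise ValidationError(
                    "tree_feature_fraction must be 'sqrt', 'all' or a fraction"
                )
        elif not 0.0 < float(self.tree_feature_fraction) <= 1.0:
            raise ValidationError("tree_feature_fraction fraction must be in (0, 1]")


def _check_inputs(
    expr: ExpressionMatrix, regs: RegulatorSet, min_samples: int = 3
) -> tuple[list[str], np.ndarray]:
    """Validate regulators against the matrix; return sorted regulator ids
    and their row indices."""
    missing = sorted(r for r in regs.ids if r not in expr.gene_ids)
    if missing:
        raise ValidationError(
            f"regulator(s) not in expression matrix: {', '.join(missing[:5])}"
        )
    if expr.n_samples < min_samples:
        raise ValidationError(
            f"need at least {min_samples} samples, got {expr.n_samples}"
        )
    reg_ids = sorted(regs.ids)
    idx = np.array([expr.gene_index(r) for r in reg_ids])
    return reg_ids, idx


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize; zero-variance rows are returned as zeros together
    with a boolean mask marking them."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (values - mean) / sd
    z[flat] = 0.0
    return z, flat


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def pcc_network(expr: ExpressionMatrix, regs: RegulatorSet) -> RankedEdgeList:
    """Rank edges by the absolute Pearson correlation of the regulator and
    target profiles.  Zero-variance genes yield confidence 0 (correlation
    is undefined there) with a logged warning."""
    reg_ids, reg_idx = _check_inputs(expr, regs)
    z, flat = _standardize_rows(expr.values)
    if flat.any():
        logger.warning(
            "%d zero-variance gene(s); their edges get confidence 0",
            int(flat.sum()),
        )
    corr = np.abs(z[reg_idx] @ z.T) / expr.n_samples
    np.clip(corr, 0.0, 1.0, out=corr)
    scored = []
    for i, reg in enumerate(reg_ids):
        for j, gene in enumerate(expr.gene_ids):
            if gene == reg:
                continue
            scored.append((reg, gene, float(corr[i, j])))
    return RankedEdgeList.from_scores(scored, method_name="pcc")


# ---------------------------------------------------------------------------
# mutual information (shared kernel for CLR and ARACNE)
# ---------------------------------------------------------------------------


def _discretize_equal_frequency(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency (rank-based) discretization of each row into
    ``bins`` levels.  Invariant to monotone transforms of the profiles."""
    n = values.shape[1]
    out = np.empty(values.shape, dtype=np.int64)
    positions = (np.arange(n) * bins) // n
    for i, row in enumerate(values):
        order = np.argsort(row, kind="stable")
        out[i, order] = positions
    return out


def _plugin_mi(joint: np.ndarray) -> float:
    """Maximum-likelihood plug-in mutual information (nats) of a 2-D
    contingency table of counts."""
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def mutual_information_matrix(
    expr: ExpressionMatrix, regs: RegulatorSet, mi_bins: int = 10
) -> tuple[np.ndarray, list[str], list[str]]:
    """Plug-in mutual information between every regulator and every gene.

    Profiles are discretized by equal-frequency binning into ``mi_bins``
    levels and MI is the maximum-likelihood estimate on the 2-D
    contingency table, in nats.  The diagonal entries MI(x, x) equal the
    discretized entropy of x.

    Returns the (regulators × genes) matrix together with the regulator
    (sorted) and gene (matrix-order) index labels.
    """
    if mi_bins < 2:
        raise ValidationError("mi_bins must be >= 2")
    if expr.n_samples < mi_bins:
        raise ValidationError(
            f"need at least mi_bins={mi_bins} samples, got {expr.n_samples}"
        )
    reg_ids, reg_idx = _check_inputs(expr, regs, min_samples=mi_bins)
    disc = _discretize_equal_frequency(expr.values, mi_bins)
    genes = list(expr.gene_ids)
    mi = np.zeros((len(reg_ids), len(genes)))
    for i, ri in enumerate(reg_idx):
        di = disc[ri] * mi_bins
        for j in range(len(genes)):
            joint = np.bincount(di + disc[j], minlength=mi_bins * mi_bins)
            mi[i, j] = _plugin_mi(joint.reshape(mi_bins, mi_bins).astype(float))
    return mi, reg_ids, genes


def clr_from_mi(
    mi: np.ndarray, reg_ids: Sequence[str], gene_ids: Sequence[str]
) -> RankedEdgeList:
    """Context-likelihood-of-relatedness scores from a precomputed
    (regulators × genes) MI matrix.

    For the edge (i, j): z_i is the positive part of the z-score of
    MI_ij against row i, z_j likewise against column j, and the
    confidence is sqrt(z_i² + z_j²).  Zero-spread rows or columns give
    z = 0 rather than an undefined score.
    """
    row_mean = mi.mean(axis=1, keepdims=True)
    row_sd = mi.std(axis=1, keepdims=True)
    col_mean = mi.mean(axis=0, keepdims=True)
    col_sd = mi.std(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        zr = np.where(row_sd > 0, (mi - row_mean) / row_sd, 0.0)
        zc = np.where(col_sd > 0, (mi - col_mean) / col_sd, 0.0)
    zr = np.maximum(zr, 0.0)
    zc = np.maximum(zc, 0.0)
    conf = np.sqrt(zr**2 + zc**2)
    scored = []
    for i, reg in enumerate(reg_ids):
        for j, gene in enumerate(gene_ids):
            if gene == reg:
                continue
            scored.append((reg, gene, float(conf[i, j])))
    return RankedEdgeList.from_scores(scored, method_name="clr")


def clr(
    expr: ExpressionMatrix, regs: RegulatorSet, mi_bins: int = 10
) -> RankedEdgeList:
    """CLR: mutual information with per-row/column z-score background
    correction."""
    mi, reg_ids, gene_ids = mutual_information_matrix(expr, regs, mi_bins)
    return clr_from_mi(mi, reg_ids, gene_ids)


def _aracne_prune(
    mi: np.ndarray,
    reg_ids: Sequence[str],
    gene_ids: Sequence[str],
    dpi_tolerance: float,
) -> dict[tuple[str, str], float]:
    """Data-processing-inequality pruning on the undirected MI pair set.

    MI is only defined for pairs with at least one regulator endpoint, so
    the triangles examined are exactly those with >= 2 regulator
    vertices.  All removals are decided on the original MI values, then
    applied at once (the classic ARACNE convention)."""
    reg_pos = {r: i for i, r in enumerate(reg_ids)}
    gene_pos = {g: j for j, g in enumerate(gene_ids)}

    def pair_mi(a: str, b: str) -> float:
        if a in reg_pos:
            return mi[reg_pos[a], gene_pos[b]]
        return mi[reg_pos[b], gene_pos[a]]

    pairs: dict[tuple[str, str], float] = {}
    for reg in reg_ids:
        for gene in gene_ids:
            if gene == reg:
                continue
            key = (reg, gene) if reg <= gene else (gene, reg)
            pairs[key] = pair_mi(*key)

    removed: set[tuple[str, str]] = set()
    keep = 1.0 - dpi_tolerance
    reg_list = list(reg_ids)
    non_regs = [g for g in gene_ids if g not in reg_pos]
    # triples with exactly 2 regulators, plus triples of 3 regulators
    triples = []
    for a_i in range(len(reg_list)):
        for b_i in range(a_i + 1, len(reg_list)):
            for g in non_regs:
                triples.append((reg_list[a_i], reg_list[b_i], g))
            for c_i in range(b_i + 1, len(reg_list)):
                triples.append((reg_list[a_i], reg_list[b_i], reg_list[c_i]))
    for a, b, c in triples:
        e_ab = (a, b) if a <= b else (b, a)
        e_ac = (a, c) if a <= c else (c, a)
        e_bc = (b, c) if b <= c else (c, b)
        vals = [(pairs[e_ab], e_ab), (pairs[e_ac], e_ac), (pairs[e_bc], e_bc)]
        vals.sort(key=lambda v: v[0])
        if vals[0][0] < keep * vals[1][0]:
            removed.add(vals[0][1])
    return {k: v for k, v in pairs.items() if k not in removed}


def aracne(
    expr: ExpressionMatrix,
    regs: RegulatorSet,
    mi_bins: int = 10,
    dpi_tolerance: float = 0.0,
) -> RankedEdgeList:
    """ARACNE: MI edges pruned by the data-processing inequality.

    In every triangle the weakest edge is removed when its MI is strictly
    below ``(1 - dpi_tolerance)`` times the smaller of the other two;
    tolerance 1 disables pruning entirely.  Surviving edges are ranked by
    MI.  The output edge set is always a subset of the MI pair set.
    """
    if not 0.0 <= dpi_tolerance <= 1.0:
        raise ValidationError("dpi_tolerance must be in [0, 1]")
    mi, reg_ids, gene_ids = mutual_information_matrix(expr, regs, mi_bins)
    surviving = _aracne_prune(mi, reg_ids, gene_ids, dpi_tolerance)
    reg_set = set(reg_ids)
    scored = []
    for (a, b), value in surviving.items():
        if a in reg_set:
            scored.append((a, b, float(value)))
        if b in reg_set and b != a:
            scored.append((b, a, float(value)))
    return RankedEdgeList.from_scores(scored, method_name="aracne")


# ---------------------------------------------------------------------------
# regression / tree ensembles
# ---------------------------------------------------------------------------


def _target_seed(random_seed: int, target_index: int) -> int:
    """A per-target seed stream independent of the other targets."""
    ss = np.random.SeedSequence(entropy=random_seed, spawn_key=(target_index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def genie3(
    expr: ExpressionMatrix,
    regs: RegulatorSet,
    n_trees: int = 1000,
    tree_feature_fraction: str | float = "all",
    random_seed: int = 0,
) -> RankedEdgeList:
    """GENIE3: per-target random-forest regression on the regulator
    profiles; the confidence of (regulator, target) is the regulator's
    total variance-reduction importance, normalized per target to sum 1
    (0 for constant targets, which are logged)."""
    reg_ids, reg_idx = _check_inputs(expr, regs)
    if len(reg_ids) < 2:
        raise ValidationError("genie3 requires at least 2 regulators")
    if isinstance(tree_feature_fraction, str):
        if tree_feature_fraction == "sqrt":
            max_features: str | float = "sqrt"
        elif tree_feature_fraction == "all":
            max_features = 1.0
        else:
            raise ValidationError(
                "tree_feature_fraction must be 'sqrt', 'all' or a fraction"
            )
    else:
        max_features = float(tree_feature_fraction)
    X_all = expr.values[reg_idx].T  # samples x regulators
    scored = []
    for t, gene in enumerate(expr.gene_ids):
        y = expr.values[expr.gene_index(gene)]
        feat = [k for k, r in enumerate(reg_ids) if r != gene]
        if not feat:
            continue
        if np.std(y) == 0:
            logger.warning("constant target %r: importances set to 0", gene)
            importances = np.zeros(len(feat))
        else:
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=max_features,
                random_state=_target_seed(random_seed, t),
                n_jobs=1,
            )
            forest.fit(X_all[:, feat], y)
            importances = forest.feature_importances_
        for k, imp in zip(feat, importances):
            scored.append((reg_ids[k], gene, float(imp)))
    return RankedEdgeList.from_scores(scored, method_name="genie3")


def _select_alpha(
    X: np.ndarray, y: np.ndarray, l1_ratio: float, random_seed: int
) -> float:
    """Pick the elastic-net regularization strength on the full data by a
    fixed small-grid cross-validated MSE; held fixed across bootstrap
    resamples so the confidence stays a pure selection frequency."""
    alphas = np.logspace(-3, 0, 7)
    n = len(y)
    n_splits = min(3, n)
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=random_seed)
    best_alpha, best_mse = alphas[0], np.inf
    for alpha in alphas:
        mse = 0.0
        for train, test in kf.split(X):
            model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=2000)
            model.fit(X[train], y[train])
            resid = y[test] - model.predict(X[test])
            mse += float(resid @ resid)
        if mse < best_mse - 1e-12:
            best_mse, best_alpha = mse, alpha
    return float(best_alpha)


def elasticnet_bootstrap(
    expr: ExpressionMatrix,
    regs: RegulatorSet,
    n_bootstrap: int = 1000,
    l1_ratio: float = 0.5,
    random_seed: int = 0,
) -> RankedEdgeList:
    """Bootstrap elastic net: for each target the confidence of a
    regulator is the fraction of bootstrap resamples in which its
    coefficient is nonzero (so confidences live in [0, 1])."""
    if n_bootstrap < 1:
        raise ValidationError("n_bootstrap must be >= 1")
    reg_ids, reg_idx = _check_inputs(expr, regs)
    z, _ = _standardize_rows(expr.values)
    X_all = z[reg_idx].T
    n = expr.n_samples
    scored = []
    for t, gene in enumerate(expr.gene_ids):
        y = z[expr.gene_index(gene)]
        feat = [k for k, r in enumerate(reg_ids) if r != gene]
        if not feat:
            continue
        if np.std(y) == 0:
            logger.warning("constant target %r: confidences set to 0", gene)
            freq = np.zeros(len(feat))
        else:
            X = X_all[:, feat]
            seed = _target_seed(random_seed, t)
            alpha = _select_alpha(X, y, l1_ratio, seed)
            rng = np.random.default_rng(seed)
            counts = np.zeros(len(feat))
            model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=2000)
            for _ in range(n_bootstrap):
                idx = rng.integers(0, n, n)
                model.fit(X[idx], y[idx])
                counts += model.coef_ != 0
            freq = counts / n_bootstrap
        for k, f in zip(feat, freq):
            scored.append((reg_ids[k], gene, float(f)))
    return RankedEdgeList.from_scores(scored, method_name="elasticnet")


def tigress(
    expr: ExpressionMatrix,
    regs: RegulatorSet,
    n_resample: int = 1000,
    lars_steps: int = 5,
    perturbation_alpha: float = 0.2,
    random_seed: int = 0,
) -> RankedEdgeList:
    """TIGRESS stability selection.

    Each resample takes one half of a random split of the samples and
    multiplies every regulator profile by an independent weight drawn
    uniformly from [perturbation_alpha, 1]; a least-angle regression path
    is run for ``lars_steps`` steps.  The confidence is the area score
    (1/L) * sum over s = 1..L of the frequency with which the regulator
    was selected within the first s steps, which lies in [0, 1].
    """
    if n_resample < 2 or n_resample % 2:
        raise ValidationError("n_resample must be an even integer >= 2")
    reg_ids, reg_idx = _check_inputs(expr, regs)
    if lars_steps >= len(reg_ids):
        raise ValidationError(
            f"lars_steps ({lars_steps}) must be smaller than the number of "
            f"regulators ({len(reg_ids)})"
        )
    z, _ = _standardize_rows(expr.values)
    X_all = z[reg_idx].T
    n = expr.n_samples
    half = n // 2
    if half < 2:
        raise ValidationError("tigress needs at least 4 samples")
    scored = []
    for t, gene in enumerate(expr.gene_ids):
        y = z[expr.gene_index(gene)]
        feat = [k for k, r in enumerate(reg_ids) if r != gene]
        if not feat:
            continue
        p = len(feat)
        steps = min(lars_steps, p)
        area = np.zeros(p)
        if np.std(y) == 0:
            logger.warning("constant target %r: confidences set to 0", gene)
        else:
            X = X_all[:, feat]
            rng = np.random.default_rng(_target_seed(random_seed, t))
            for _ in range(n_resample // 2):
                perm = rng.permutation(n)
                for part in (perm[:half], perm[half : 2 * half]):
                    w = rng.uniform(perturbation_alpha, 1.0, p)
                    _, active, _ = lars_path(
                        X[part] * w, y[part], method="lar", max_iter=steps
                    )
                    # entry at step s contributes (L - s + 1)/L to the area
                    for s, k in enumerate(active[:steps], start=1):
                        area[k] += (steps - s + 1) / steps
            area /= n_resample
        for k, a in zip(feat, area):
            scored.append((reg_ids[k], gene, float(a)))
    return RankedEdgeList.from_scores(scored, method_name="tigress")


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def run_engine(
    name: str,
    expr: ExpressionMatrix,
    regs: RegulatorSet,
    config: InferenceConfig | None = None,
) -> RankedEdgeList:
    """Run one engine by name with parameters taken from ``config``."""
    cfg = config or InferenceConfig()
    if name not in ENGINES:
        raise ValidationError(
            f"unknown engine {name!r}; available: {', '.join(sorted(ENGINES))}"
        )
    return ENGINES[name](expr, regs, cfg)


ENGINES: dict[str, Callable[..., RankedEdgeList]] = {
    "pcc": lambda expr, regs, cfg: pcc_network(expr, regs),
    "clr": lambda expr, regs, cfg: clr(expr, regs, cfg.mi_bins),
    "aracne": lambda expr, regs, cfg: aracne(
        expr, regs, cfg.mi_bins, cfg.dpi_tolerance
    ),
    "genie3": lambda expr, regs, cfg: genie3(
        expr, regs, cfg.n_trees, cfg.tree_feature_fraction, cfg.random_seed
    ),
    "elasticnet": lambda expr, regs, cfg: elasticnet_bootstrap(
        expr, regs, cfg.n_bootstrap, cfg.l1_ratio, cfg.random_seed
    ),
    "tigress": lambda expr, regs, cfg: tigress(
        expr,
        regs,
        cfg.n_resample,
        cfg.lars_steps,
        cfg.perturbation_alpha,
        cfg.random_seed,
    ),
}
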