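"""The community hub-prediction core.

Given N ranked edge-list predictions for the same regulator set, the
community prediction proceeds in three steps:

1. at an edge-inclusion threshold T, count each regulator's *outdegree*
   (its number of targets among the top-T edges of each prediction);
2. pick T by maximizing the mean pairwise Pearson correlation of the
   regulator-outdegree vectors across predictions — the threshold where
   the methods agree most about who the hubs are;
3. average the outdegrees over the N predictions,

       score_k = (1/N) * sum_{l=1..N} outdegree_{kl},

   and rank regulators by descending score.

The edge-rank community (averaging each edge's rank across methods,
absent edges contributing rank |list|+1) is provided as the classic
per-edge consensus comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateDataError, ValidationError
from .inference import InferenceConfig, run_engine
from .io import ExpressionMatrix, RankedEdgeList, RegulatorSet

logger = logging.getLogger(__name__)

__all__ = [
    "OutdegreeVector",
    "HubScore",
    "ThresholdScan",
    "DEFAULT_THRESHOLDS",
    "ENGINE_SEED_OFFSETS",
    "compute_outdegree",
    "pairwise_similarity",
    "select_threshold",
    "average_outdegree",
    "rank_hubs",
    "edge_rank_community",
    "run_comhub",
]

#: Log-spaced default candidate grid, intersected with [1, max |edges|] at
#: run time.  Covers optima from a few hundred edges up to the 1e5 scale
#: typical of genome-wide predictions.
DEFAULT_THRESHOLDS: tuple[int, ...] = (
    100, 200, 500, 1000, 2000, 5000, 10000, 20000, 50000, 100000,
)

#: Fixed per-engine offsets fanned out from the one global seed, so adding
#: an engine never shifts another engine's random stream.
ENGINE_SEED_OFFSETS: dict[str, int] = {
    "pcc": 0,
    "clr": 1,
    "aracne": 2,
    "genie3": 3,
    "elasticnet": 4,
    "tigress": 5,
}


@dataclass(frozen=True)
class OutdegreeVector:
    """Per-regulator target counts among the top-T edges of one prediction.

    Every regulator of the bound set appears; regulators absent from the
    prediction count 0.  The counts always sum to min(T, |edges|).
    """

    counts: dict[str, int]
    threshold: int
    method_name: str = ""

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.counts[r] for r in order], dtype=float)


@dataclass(frozen=True)
class HubScore:
    """The community hub score: per-regulator mean outdegree over the N
    ingoing predictions at the selected threshold.  Scores lie in [0, T]."""

    scores: dict[str, float]
    n_methods: int
    threshold: int

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.scores[r] for r in order], dtype=float)


@dataclass(frozen=True)
class ThresholdScan:
    """The inter-method agreement profile over candidate thresholds.

    ``mean_similarity`` maps each candidate to the mean pairwise Pearson
    correlation of outdegree vectors, or ``None`` where every pair was
    degenerate (constant vectors).  ``selected`` maximizes the similarity,
    with ties broken toward the smallest threshold.
    """

    candidate_thresholds: tuple[int, ...]
    mean_similarity: dict[int, float | None]
    selected: int


def compute_outdegree(
    edges: RankedEdgeList, threshold: int, regs: RegulatorSet
) -> OutdegreeVector:
    """Count each regulator's targets among the top-``threshold`` edges.

    Confidence ties at the cut boundary are resolved by the stored edge
    order (loaders and engines sort stably, so file order is the ultimate
    tie-break).
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    extra = edges.sources() - regs.ids
    if extra:
        raise ValidationError(
            f"edge source(s) not in regulator set: {', '.join(sorted(extra)[:5])}"
        )
    counts = {r: 0 for r in regs.sorted_ids}
    for reg, _tgt, _conf in edges.top(threshold):
        counts[reg] += 1
    return OutdegreeVector(counts, threshold, edges.method_name)


def pairwise_similarity(vectors: Sequence[OutdegreeVector]) -> float | None:
    """Mean pairwise Pearson correlation of outdegree vectors.

    Pairs in which either vector is constant (zero variance) are excluded
    — a constant vector carries no ranking information.  Returns ``None``
    when every pair is excluded.
    """
    if len(vectors) < 2:
        raise ValidationError("pairwise similarity requires >= 2 vectors")
    keys = sorted(vectors[0].counts)
    for v in vectors[1:]:
        if sorted(v.counts) != keys or v.threshold != vectors[0].threshold:
            raise ValidationError(
                "outdegree vectors must share the regulator set and threshold"
            )
    arrays = [v.as_array(keys) for v in vectors]
    centered = [a - a.mean() for a in arrays]
    ssq = [float(c @ c) for c in centered]
    sims = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            if ssq[i] == 0 or ssq[j] == 0:
                continue
            # dot-product form: identical vectors give exactly 1.0, which
            # keeps the smallest-threshold tie-break well defined
            r = float(centered[i] @ centered[j]) / np.sqrt(ssq[i] * ssq[j])
            sims.append(min(1.0, max(-1.0, r)))
    if not sims:
        return None
    return float(np.mean(sims))


def select_threshold(
    predictions: Sequence[RankedEdgeList],
    regs: RegulatorSet,
    candidate_thresholds: Sequence[int],
) -> ThresholdScan:
    """Scan candidate thresholds and select the one maximizing the mean
    pairwise outdegree correlation between predictions (smallest wins on
    ties; thresholds where the similarity is undefined are skipped)."""
    if len(predictions) < 2:
        raise ValidationError("community requires >= 2 methods")
    if not candidate_thresholds:
        raise ValidationError("candidate threshold grid is empty")
    candidates = tuple(sorted(set(int(t) for t in candidate_thresholds)))
    if candidates[0] < 1:
        raise ValidationError("candidate thresholds must be >= 1")
    similarity: dict[int, float | None] = {}
    best_t: int | None = None
    best_sim = -np.inf
    for t in candidates:
        vectors = [compute_outdegree(p, t, regs) for p in predictions]
        sim = pairwise_similarity(vectors)
        similarity[t] = sim
        if sim is not None and sim > best_sim:
            best_sim, best_t = sim, t
    if best_t is None:
        raise DegenerateDataError(
            "similarity undefined at every candidate threshold "
            "(all outdegree vectors constant)"
        )
    return ThresholdScan(candidates, similarity, best_t)


def average_outdegree(
    predictions: Sequence[RankedEdgeList],
    regs: RegulatorSet,
    threshold: int,
) -> HubScore:
    """score_k: the arithmetic mean over the N predictions of regulator
    k's outdegree at the given threshold.  Regulators absent from a
    prediction contribute 0 for that prediction."""
    if not predictions:
        raise ValidationError("average_outdegree requires >= 1 prediction")
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    n = len(predictions)
    totals = {r: 0.0 for r in regs.sorted_ids}
    for p in predictions:
        od = compute_outdegree(p, threshold, regs)
        for r, c in od.counts.items():
            totals[r] += c
    return HubScore({r: v / n for r, v in totals.items()}, n, threshold)


def rank_hubs(scores: HubScore) -> list[str]:
    """Regulators ordered by descending community score; ties broken
    lexicographically by id (deterministic)."""
    return [r for r, _ in sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))]


def edge_rank_community(predictions: Sequence[RankedEdgeList]) -> RankedEdgeList:
    """Per-edge consensus: average each edge's rank position across the
    methods, an edge absent from method m contributing rank |list_m| + 1;
    the confidence is the negative mean rank so ascending mean rank sorts
    as descending confidence."""
    if len(predictions) < 2:
        raise ValidationError("edge-rank community requires >= 2 predictions")
    rank_maps = []
    absent_ranks = []
    universe: set[tuple[str, str]] = set()
    for p in predictions:
        ranks = {(r, t): i for i, (r, t, _c) in enumerate(p.edges, start=1)}
        rank_maps.append(ranks)
        absent_ranks.append(len(p.edges) + 1)
        universe.update(ranks)
    scored = []
    for reg, tgt in universe:
        total = 0.0
        for ranks, absent in zip(rank_maps, absent_ranks):
            total += ranks.get((reg, tgt), absent)
        scored.append((reg, tgt, -total / len(predictions)))
    return RankedEdgeList.from_scores(scored, method_name="edge_rank_community")


def run_comhub(
    expr: ExpressionMatrix | None,
    regs: RegulatorSet,
    engines: Sequence[str] = (),
    networks: Sequence[RankedEdgeList] = (),
    candidate_thresholds: Sequence[int] | None = None,
    config: InferenceConfig | None = None,
    random_seed: int = 0,
) -> tuple[HubScore, ThresholdScan, list[RankedEdgeList]]:
    """Full pipeline: run the requested engines (and/or take predefined
    networks), select the agreement-maximizing threshold, and average the
    outdegrees into the community hub score.

    The global seed fans out to the stochastic engines through fixed
    per-engine offsets (see :data:`ENGINE_SEED_OFFSETS`).
    """
    cfg = config or InferenceConfig()
    predictions: list[RankedEdgeList] = list(networks)
    for name in engines:
        if expr is None:
            raise ValidationError("engines requested but no expression matrix given")
        offset = ENGINE_SEED_OFFSETS.get(name, 99)
        engine_cfg = InferenceConfig(
            mi_bins=cfg.mi_bins,
            dpi_tolerance=cfg.dpi_tolerance,
            n_trees=cfg.n_trees,
            tree_feature_fraction=cfg.tree_feature_fraction,
            n_bootstrap=cfg.n_bootstrap,
            l1_ratio=cfg.l1_ratio,
            n_resample=cfg.n_resample,
            lars_steps=cfg.lars_steps,
            perturbation_alpha=cfg.perturbation_alpha,
            random_seed=random_seed + 1000 * offset,
        )
        logger.info("running engine %s", name)
        predictions.append(run_engine(name, expr, regs, engine_cfg))
    if len(predictions) < 2:
        raise ValidationError(
            "community requires >= 2 methods (engines and/or predefined networks)"
        )
    if candidate_thresholds is None:
        max_edges = max(len(p) for p in predictions)
        grid = [t for t in DEFAULT_THRESHOLDS if 1 <= t <= max_edges]
        if not grid:
            grid = [max_edges]
            logger.info(
                "default grid exceeds the largest prediction; using T=%d", max_edges
            )
        candidate_thresholds = grid
    scan = select_threshold(predictions, regs, candidate_thresholds)
    logger.info(
        "selected threshold T=%d (mean pairwise correlation %.4f)",
        scan.selected,
        scan.mean_similarity[scan.selected],
    )
    scores = average_outdegree(predictions, regs, scan.selected)
    return scores, scan, predictions
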