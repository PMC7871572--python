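"""Scoring hub predictions against a gold standard.

Performance is the Pearson correlation between predicted and
gold-standard regulator outdegrees (Spearman as the rank-based
alternative), computed over the *full* regulator set including
zero-outdegree regulators — this is deterministic and punishes falsely
predicted hubs.  Two further diagnostics are provided: a normalized mean
absolute error on degree fractions, and the HITS hub score of the
thresholded prediction graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .community import HubScore, OutdegreeVector
from .errors import DegenerateDataError, ValidationError
from .io import GoldStandard, RankedEdgeList, RegulatorSet

logger = logging.getLogger(__name__)

__all__ = [
    "PerformanceReport",
    "gold_outdegree",
    "performance_pcc",
    "performance_spearman",
    "absolute_error",
    "hits_hub_scores",
    "evaluate_all",
]


@dataclass(frozen=True)
class PerformanceReport:
    """Summary of one hub prediction against one gold standard."""

    pcc: float
    scc: float
    mean_absolute_error: float
    n_regulators_scored: int

    def to_row(self) -> str:
        return (
            "pcc\tscc\tmean_absolute_error\tn_regulators\n"
            f"{self.pcc:.6f}\t{self.scc:.6f}\t"
            f"{self.mean_absolute_error:.6g}\t{self.n_regulators_scored}\n"
        )


def gold_outdegree(gs: GoldStandard, regs: RegulatorSet) -> OutdegreeVector:
    """Regulator outdegrees in the gold standard.

    Directed standards count distinct targets; undirected (PPI-proxy)
    standards count distinct partners — degree stands in for regulatory
    outdegree.  Regulators with no edges get 0.
    """
    counts = {r: 0 for r in regs.sorted_ids}
    for a, b in gs.edges:
        if a in counts:
            counts[a] += 1
        if not gs.directed and b in counts:
            counts[b] += 1
    return OutdegreeVector(counts, threshold=len(gs.edges), method_name="gold_standard")


def _aligned(
    predicted: HubScore | OutdegreeVector | Mapping[str, float],
    gold: OutdegreeVector,
) -> tuple[np.ndarray, np.ndarray]:
    """Align the two score vectors over the gold vector's regulator
    universe; regulators missing from the prediction score 0."""
    if isinstance(predicted, (HubScore, OutdegreeVector)):
        pred_map: Mapping[str, float] = (
            predicted.scores if isinstance(predicted, HubScore) else predicted.counts
        )
    else:
        pred_map = predicted
    keys = sorted(gold.counts)
    p = np.array([float(pred_map.get(r, 0.0)) for r in keys])
    g = np.array([float(gold.counts[r]) for r in keys])
    return p, g


def performance_pcc(
    predicted: HubScore | OutdegreeVector | Mapping[str, float],
    gold: OutdegreeVector,
) -> float:
    """Pearson correlation between predicted hub scores and gold
    outdegrees over all regulators (zeros included)."""
    p, g = _aligned(predicted, gold)
    if p.std() == 0:
        raise DegenerateDataError("predicted scores are constant; PCC undefined")
    if g.std() == 0:
        raise DegenerateDataError("gold outdegrees are constant; PCC undefined")
    return float(stats.pearsonr(p, g).statistic)


def performance_spearman(
    predicted: HubScore | OutdegreeVector | Mapping[str, float],
    gold: OutdegreeVector,
) -> float:
    """Spearman correlation (average ranks for ties) between predicted
    scores and gold outdegrees."""
    p, g = _aligned(predicted, gold)
    if p.std() == 0:
        raise DegenerateDataError("predicted scores are constant; SCC undefined")
    if g.std() == 0:
        raise DegenerateDataError("gold outdegrees are constant; SCC undefined")
    return float(stats.spearmanr(p, g).statistic)


def absolute_error(
    predicted: HubScore | OutdegreeVector | Mapping[str, float],
    gold: OutdegreeVector,
) -> float:
    """Mean absolute difference of degree *fractions*.

    Both vectors are normalized to sum 1 before differencing, because
    predicted scores (means) and gold outdegrees (counts) live on
    different scales; the result is 0 iff the two are proportional.
    """
    p, g = _aligned(predicted, gold)
    if p.sum() <= 0:
        raise DegenerateDataError("predicted scores sum to 0; fractions undefined")
    if g.sum() <= 0:
        raise DegenerateDataError("gold outdegrees sum to 0; fractions undefined")
    return float(np.mean(np.abs(p / p.sum() - g / g.sum())))


def hits_hub_scores(
    edges: RankedEdgeList,
    threshold: int,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> dict[str, float]:
    """HITS hub scores of the top-``threshold`` edges.

    Power iteration of the mutual-reinforcement recurrence (hub <- sum of
    target authorities; authority <- sum of source hubs), normalizing both
    vectors to unit Euclidean norm each iteration, until the maximum
    componentwise change of the hub vector drops below ``tol``.  Returns
    non-negative hub values for every node of the thresholded graph.
    """
    if threshold < 1:
        raise ValidationError("threshold must be >= 1")
    top = edges.top(threshold)
    if not top:
        raise DegenerateDataError("thresholded edge set is empty")
    nodes = sorted({n for r, t, _ in top for n in (r, t)})
    index = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for r, t, _ in top:
        A[index[r], index[t]] = 1.0
    h = np.ones(len(nodes))
    h /= np.linalg.norm(h)
    for _ in range(max_iter):
        a = A.T @ h
        norm_a = np.linalg.norm(a)
        if norm_a > 0:
            a /= norm_a
        h_new = A @ a
        norm_h = np.linalg.norm(h_new)
        if norm_h > 0:
            h_new /= norm_h
        delta = float(np.max(np.abs(h_new - h)))
        h = h_new
        if delta < tol:
            break
    return {n: float(max(h[i], 0.0)) for n, i in index.items()}


def evaluate_all(
    predicted: HubScore | OutdegreeVector | Mapping[str, float],
    gs: GoldStandard,
    regs: RegulatorSet,
) -> PerformanceReport:
    """Compose gold outdegree extraction with the three metrics."""
    if len(gs) == 0:
        raise DegenerateDataError("gold standard has no edges")
    gold = gold_outdegree(gs, regs)
    report = PerformanceReport(
        pcc=performance_pcc(predicted, gold),
        scc=performance_spearman(predicted, gold),
        mean_absolute_error=absolute_error(predicted, gold),
        n_regulators_scored=len(gold.counts),
    )
    logger.info("evaluated %d regulators", report.n_regulators_scored)
    return report
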