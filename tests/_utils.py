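"""Independent brute-force oracles and random-instance generators shared
by the test modules.

Everything here is deliberately written in plain Python (loops, sums,
explicit formulas) so it stays independent of the library code paths it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from comhub.io import ExpressionMatrix, RankedEdgeList, RegulatorSet

# ---------------------------------------------------------------------------
# brute-force statistics
# ---------------------------------------------------------------------------


def brute_pearson(x, y) -> float:
    """Sum-of-products Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / math.sqrt(sxx * syy)


def brute_average_ranks(x) -> list[float]:
    """Average ranks (ties share the mean of their positions)."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_plugin_mi(x_levels, y_levels, n_bins: int) -> float:
    """Plug-in MI (nats) from two discrete level sequences."""
    n = len(x_levels)
    joint = {}
    for a, b in zip(x_levels, y_levels):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    px = {}
    py = {}
    for (a, b), c in joint.items():
        px[a] = px.get(a, 0) + c
        py[b] = py.get(b, 0) + c
    mi = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        mi += p_ab * math.log(p_ab / ((px[a] / n) * (py[b] / n)))
    return mi


def brute_equal_frequency_levels(values, n_bins: int) -> list[int]:
    """Rank-based equal-frequency bin levels (stable ties)."""
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], i))
    levels = [0] * n
    for pos, i in enumerate(order):
        levels[i] = (pos * n_bins) // n
    return levels


# ---------------------------------------------------------------------------
# brute-force community core
# ---------------------------------------------------------------------------


def brute_outdegree(edges: RankedEdgeList, threshold: int, reg_ids) -> dict[str, int]:
    counts = {r: 0 for r in reg_ids}
    for reg, _t, _c in edges.edges[: min(threshold, len(edges.edges))]:
        counts[reg] += 1
    return counts


def brute_mean_pairwise_pearson(count_maps, reg_ids) -> float | None:
    vectors = [[float(m[r]) for r in sorted(reg_ids)] for m in count_maps]
    sims = []
    for a, b in itertools.combinations(vectors, 2):
        if len(set(a)) == 1 or len(set(b)) == 1:
            continue
        sims.append(brute_pearson(a, b))
    if not sims:
        return None
    return sum(sims) / len(sims)


def brute_select_threshold(predictions, reg_ids, candidates):
    """(selected, {t: sim-or-None}) by exhaustive recomputation."""
    sims = {}
    best_t, best = None, -math.inf
    for t in sorted(set(candidates)):
        maps = [brute_outdegree(p, t, reg_ids) for p in predictions]
        sim = brute_mean_pairwise_pearson(maps, reg_ids)
        sims[t] = sim
        if sim is not None and sim > best:
            best, best_t = sim, t
    return best_t, sims


def brute_average_outdegree(predictions, reg_ids, threshold):
    totals = {r: 0.0 for r in reg_ids}
    for p in predictions:
        counts = brute_outdegree(p, threshold, reg_ids)
        for r in reg_ids:
            totals[r] += counts[r]
    return {r: v / len(predictions) for r, v in totals.items()}


def brute_edge_rank_community(predictions):
    """Mean-rank table: {(reg, tgt): -mean_rank} with absence = len+1."""
    table = {}
    universe = set()
    rank_maps = []
    for p in predictions:
        ranks = {}
        for i, (r, t, _c) in enumerate(p.edges, start=1):
            ranks[(r, t)] = i
        rank_maps.append(ranks)
        universe.update(ranks)
    for key in universe:
        total = 0.0
        for p, ranks in zip(predictions, rank_maps):
            total += ranks.get(key, len(p.edges) + 1)
        table[key] = -total / len(predictions)
    return table


# ---------------------------------------------------------------------------
# random instances
# ---------------------------------------------------------------------------


def random_prediction_set(rng: np.random.Generator):
    """A random small community instance: 2-6 ranked edge lists over a
    shared regulator set (<= 20 regulators, <= 200 edges each, occasional
    confidence ties)."""
    n_regs = int(rng.integers(2, 21))
    reg_ids = [f"R{i:02d}" for i in range(n_regs)]
    targets = reg_ids + [f"T{i:02d}" for i in range(30)]
    max_possible = n_regs * (len(targets) - 1)
    n_methods = int(rng.integers(2, 7))
    predictions = []
    for m in range(n_methods):
        n_edges = int(rng.integers(1, min(200, max_possible) + 1))
        pairs = set()
        while len(pairs) < n_edges:
            reg = reg_ids[rng.integers(0, n_regs)]
            tgt = targets[rng.integers(0, len(targets))]
            if tgt != reg:
                pairs.add((reg, tgt))
        tie_prone = rng.random() < 0.3
        scored = []
        for reg, tgt in sorted(pairs):
            conf = float(rng.random())
            if tie_prone:
                conf = round(conf, 1)
            scored.append((reg, tgt, conf))
        predictions.append(
            RankedEdgeList.from_scores(scored, method_name=f"m{m}")
        )
    regs = RegulatorSet.from_iterable(reg_ids)
    n_cand = int(rng.integers(2, 7))
    candidates = sorted(set(int(c) for c in rng.integers(1, 251, n_cand)))
    return predictions, regs, candidates


def random_expression(
    rng: np.random.Generator, n_genes: int, n_samples: int, n_regs: int
):
    """A small random expression matrix with the first n_regs genes as
    regulators."""
    gene_ids = tuple(f"g{i}" for i in range(n_genes))
    values = rng.standard_normal((n_genes, n_samples))
    expr = ExpressionMatrix(gene_ids, tuple(f"s{j}" for j in range(n_samples)), values)
    regs = RegulatorSet.from_iterable(gene_ids[:n_regs])
    return expr, regs
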