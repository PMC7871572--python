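"""Synthetic gold-standard networks with planted hubs and matching
linear-Gaussian expression data.

The generator emulates the structure the community predictor targets: a
directed regulator→target network whose regulator outdegrees are
heavy-tailed (a few planted hubs regulate many genes), and an expression
matrix in which each regulated gene is a noisy linear combination of its
regulators' profiles.  A linear-Gaussian model (rather than kinetic ODE
simulation) keeps noiseless limits exactly checkable while preserving the
hub-detectability structure that matters for benchmarking.

The regulator→regulator subgraph is restricted to a DAG (edges only run
from earlier to later regulators in a fixed topological order), so
expression can be simulated in a single topological pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import ExpressionMatrix, GoldStandard, RegulatorSet

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "generate_grn",
    "simulate_expression",
    "default_fixture",
    "make_fixture",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic benchmark.

    ``outdegree_exponent`` is the power-law weighting of regulator
    sampling: regulator at rank r of a random permutation is drawn with
    probability proportional to r^(-outdegree_exponent), so larger
    exponents concentrate edges on fewer hubs.  ``effect_sd`` scales the
    per-edge regulatory weights; ``noise_sd`` the additive Gaussian noise
    on regulated genes (both in standardized expression units).
    """

    n_genes: int = 300
    n_regulators: int = 20
    n_edges: int = 600
    outdegree_exponent: float = 2.0
    n_samples: int = 200
    effect_sd: float = 1.0
    noise_sd: float = 0.5
    random_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if not 1 <= self.n_regulators <= self.n_genes:
            raise ValidationError("n_regulators must be in [1, n_genes]")
        if self.n_edges < 1:
            raise ValidationError("n_edges must be >= 1")
        if self.n_edges > self.n_regulators * (self.n_genes - 1):
            raise ValidationError(
                "n_edges exceeds n_regulators * (n_genes - 1) possible edges"
            )
        if self.outdegree_exponent <= 1.0:
            raise ValidationError("outdegree_exponent must be > 1")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.effect_sd <= 0:
            raise ValidationError("effect_sd must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        width = len(str(self.n_genes - 1))
        return tuple(f"G{i:0{width}d}" for i in range(self.n_genes))

    @property
    def regulator_ids(self) -> tuple[str, ...]:
        return self.gene_ids[: self.n_regulators]


def generate_grn(cfg: SyntheticConfig) -> GoldStandard:
    """Draw a directed gold-standard network with planted hubs.

    Regulators receive sampling weights proportional to
    rank^(-outdegree_exponent) over a random permutation; ``n_edges``
    distinct (regulator, target) pairs are drawn with the regulator by
    weight and the target uniform over the other genes.  Edges between
    regulators are only kept when they run from earlier to later in a
    fixed topological order, keeping the regulator subgraph acyclic.

    The topological order is drawn independently of the outdegree
    weighting: a regulator's position in the regulatory hierarchy and its
    number of targets are separate properties, and tying the biggest hub
    to the top of the hierarchy would let its entire regulon be inherited
    by every downstream regulator.
    """
    rng = np.random.default_rng(cfg.random_seed)
    genes = cfg.gene_ids
    regulators = list(cfg.regulator_ids)
    perm = rng.permutation(len(regulators))
    weight_order = [regulators[i] for i in perm]  # rank 1 = heaviest hub
    topo_order = list(regulators)
    rng.shuffle(topo_order)  # fixed topological order, independent of weights
    topo_pos = {r: i for i, r in enumerate(topo_order)}
    ranks = np.arange(1, len(regulators) + 1, dtype=float)
    weights = ranks ** (-cfg.outdegree_exponent)
    weights /= weights.sum()

    edges: set[tuple[str, str]] = set()
    budget = 200 * cfg.n_edges + 10000
    attempts = 0
    while len(edges) < cfg.n_edges:
        attempts += 1
        if attempts > budget:
            raise ValidationError(
                "edge sampling exceeded its retry budget; lower n_edges or "
                "outdegree_exponent"
            )
        reg = weight_order[rng.choice(len(weight_order), p=weights)]
        tgt = genes[rng.integers(0, len(genes))]
        if tgt == reg:
            continue
        if tgt in topo_pos and topo_pos[tgt] <= topo_pos[reg]:
            continue  # would break the regulator DAG
        edges.add((reg, tgt))
    return GoldStandard(frozenset(edges), directed=True)


def simulate_expression(gs: GoldStandard, cfg: SyntheticConfig) -> ExpressionMatrix:
    """Linear-Gaussian expression for a (regulator-acyclic) network.

    Unregulated genes are standard-normal sources; every regulated gene is
    the weighted sum of its regulators' profiles (weights drawn once per
    edge from N(0, effect_sd^2)) plus N(0, noise_sd^2) sample noise,
    evaluated in topological order.
    """
    rng = np.random.default_rng(cfg.random_seed + 1)
    genes = cfg.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    parents: dict[str, list[str]] = {g: [] for g in genes}
    for reg, tgt in sorted(gs.edges):
        if reg not in gene_pos or tgt not in gene_pos:
            raise ValidationError(f"edge ({reg}, {tgt}) references unknown genes")
        parents[tgt].append(reg)
    # topological order over genes: regulators first, ordered so that every
    # regulator precedes the regulators it targets; then all other genes.
    reg_set = set(cfg.regulator_ids)
    order = _topological_order(genes, parents, reg_set)
    weights = {
        edge: float(rng.normal(0.0, cfg.effect_sd)) for edge in sorted(gs.edges)
    }
    values = np.zeros((len(genes), cfg.n_samples))
    for g in order:
        i = gene_pos[g]
        if not parents[g]:
            values[i] = rng.standard_normal(cfg.n_samples)
        else:
            profile = np.zeros(cfg.n_samples)
            for reg in parents[g]:
                profile += weights[(reg, g)] * values[gene_pos[reg]]
            if cfg.noise_sd > 0:
                profile = profile + rng.normal(0.0, cfg.noise_sd, cfg.n_samples)
            values[i] = profile
    return ExpressionMatrix(genes, tuple(f"S{j}" for j in range(cfg.n_samples)), values)


def _topological_order(
    genes: tuple[str, ...],
    parents: dict[str, list[str]],
    reg_set: set[str],
) -> list[str]:
    """Kahn's algorithm over the regulator subgraph (non-regulators never
    regulate, so they can all come last); raises on cycles."""
    regs = [g for g in genes if g in reg_set]
    indeg = {r: 0 for r in regs}
    children: dict[str, list[str]] = {r: [] for r in regs}
    for tgt in regs:
        for reg in parents[tgt]:
            if reg in indeg:
                indeg[tgt] += 1
                children[reg].append(tgt)
    ready = sorted(r for r, d in indeg.items() if d == 0)
    order: list[str] = []
    while ready:
        node = ready.pop(0)
        order.append(node)
        added = False
        for child in children[node]:
            indeg[child] -= 1
            if indeg[child] == 0:
                ready.append(child)
                added = True
        if added:
            ready.sort()
    if len(order) != len(regs):
        raise ValidationError("regulator subgraph contains a cycle")
    order.extend(g for g in genes if g not in reg_set)
    return order


def make_fixture(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, RegulatorSet, GoldStandard]:
    """Matched (expression, regulators, gold standard) triple for one
    configuration."""
    gs = generate_grn(cfg)
    expr = simulate_expression(gs, cfg)
    regs = RegulatorSet.from_iterable(cfg.regulator_ids)
    return expr, regs, gs


def default_fixture() -> tuple[ExpressionMatrix, RegulatorSet, GoldStandard]:
    """The package's standard benchmark: 300 genes (20 regulators), 600
    gold edges with outdegree exponent 2.0, 200 samples, effect sd 1.0,
    noise sd 0.5, seed 42."""
    return make_fixture(SyntheticConfig())
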