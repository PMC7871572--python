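"""Model/results interface for the community hub predictor.

:class:`ComHub` is constructed from data (an expression matrix and a
regulator set, and/or predefined ranked edge lists); :meth:`ComHub.fit`
runs the requested inference engines, selects the agreement-maximizing
edge threshold and averages regulator outdegrees, returning a
:class:`ComHubResults` that carries the hub scores, the threshold scan,
the per-method predictions, and evaluation/summary helpers.

Example
-------
>>> from comhub import ComHub
>>> from comhub.synthetic import default_fixture
>>> expr, regs, gold = default_fixture()
>>> res = ComHub(expr, regs, methods=("pcc", "clr")).fit()
>>> res.ranking[:3]                          # top hub candidates
[...]
>>> report = res.evaluate(gold)
>>> round(report.pcc, 2) <= 1.0
True
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from .community import (
    HubScore,
    ThresholdScan,
    edge_rank_community,
    rank_hubs,
    run_comhub,
)
from .errors import ValidationError
from .evaluation import PerformanceReport, evaluate_all
from .inference import InferenceConfig
from .io import (
    ExpressionMatrix,
    GoldStandard,
    RankedEdgeList,
    RegulatorSet,
    read_edge_list,
    read_expression,
    read_regulators,
    write_edge_list,
    write_hub_table,
)

logger = logging.getLogger(__name__)

__all__ = ["ComHub", "ComHubResults"]


class ComHub:
    """Community predictor of hub regulators.

    Parameters
    ----------
    expression :
        Genes × samples expression matrix, or ``None`` when only
        predefined networks are supplied.
    regulators :
        The candidate regulators (e.g. transcription factors).
    methods :
        Names of the built-in inference engines to run
        (``pcc``, ``clr``, ``aracne``, ``genie3``, ``elasticnet``,
        ``tigress``).
    networks :
        Predefined ranked edge lists from external methods; combined with
        the engine outputs.  At least two predictions are required in
        total.
    thresholds :
        Candidate edge-inclusion grid; defaults to a log-spaced grid
        clipped to the largest prediction.
    config :
        Engine hyperparameters (see :class:`~comhub.inference.InferenceConfig`).
    seed :
        Global random seed, fanned out to the stochastic engines by fixed
        per-engine offsets.
    """

    def __init__(
        self,
        expression: ExpressionMatrix | None,
        regulators: RegulatorSet,
        methods: Sequence[str] = ("pcc", "clr", "aracne"),
        networks: Sequence[RankedEdgeList] = (),
        thresholds: Sequence[int] | None = None,
        config: InferenceConfig | None = None,
        seed: int = 0,
    ) -> None:
        if expression is None and methods:
            methods = ()
        if len(tuple(methods)) + len(tuple(networks)) < 2:
            raise ValidationError(
                "community requires >= 2 methods (engines and/or networks)"
            )
        self.expression = expression
        self.regulators = regulators
        self.methods = tuple(methods)
        self.networks = tuple(networks)
        self.thresholds = tuple(thresholds) if thresholds is not None else None
        self.config = config or InferenceConfig()
        self.seed = int(seed)

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path | None,
        regulators_path: str | Path,
        network_paths: Sequence[str | Path] = (),
        **kwargs,
    ) -> "ComHub":
        """Build the model from the standard tab-separated files."""
        expr = read_expression(expression_path) if expression_path else None
        regs = read_regulators(regulators_path)
        networks = tuple(read_edge_list(p) for p in network_paths)
        if networks:
            kwargs.setdefault("methods", ())
        return cls(expr, regs, networks=networks, **kwargs)

    def fit(self) -> "ComHubResults":
        """Run inference, select the threshold, average outdegrees."""
        scores, scan, predictions = run_comhub(
            self.expression,
            self.regulators,
            engines=self.methods,
            networks=self.networks,
            candidate_thresholds=self.thresholds,
            config=self.config,
            random_seed=self.seed,
        )
        return ComHubResults(self, scores, scan, predictions)


class ComHubResults:
    """Fitted community hub prediction.

    Attributes
    ----------
    hub_scores : HubScore
        Per-regulator mean outdegree at the selected threshold.
    scan : ThresholdScan
        Mean pairwise outdegree correlation per candidate threshold and
        the selected threshold.
    predictions : list[RankedEdgeList]
        The per-method ranked edge lists that entered the community.
    """

    def __init__(
        self,
        model: ComHub,
        hub_scores: HubScore,
        scan: ThresholdScan,
        predictions: Sequence[RankedEdgeList],
    ) -> None:
        self.model = model
        self.hub_scores = hub_scores
        self.scan = scan
        self.predictions = list(predictions)

    @property
    def threshold(self) -> int:
        """The selected edge-inclusion threshold T."""
        return self.scan.selected

    @property
    def ranking(self) -> list[str]:
        """Regulators by descending community score (ties by id)."""
        return rank_hubs(self.hub_scores)

    @property
    def scores(self) -> pd.Series:
        """Community scores as a descending pandas Series."""
        order = self.ranking
        return pd.Series(
            [self.hub_scores.scores[r] for r in order], index=order, name="score"
        )

    def to_frame(self) -> pd.DataFrame:
        """Hub table: regulator, score, rank."""
        s = self.scores
        return pd.DataFrame(
            {"regulator": s.index, "score": s.to_numpy(), "rank": range(1, len(s) + 1)}
        ).set_index("regulator")

    def edge_rank_consensus(self) -> RankedEdgeList:
        """The per-edge (rank-averaging) consensus of the same predictions,
        for comparison with the outdegree-averaging community score."""
        return edge_rank_community(self.predictions)

    def evaluate(self, gold: GoldStandard) -> PerformanceReport:
        """Score the community prediction against a gold standard."""
        return evaluate_all(self.hub_scores, gold, self.model.regulators)

    def scan_frame(self) -> pd.DataFrame:
        """The threshold scan as a DataFrame (NaN where undefined)."""
        rows = [
            (t, self.scan.mean_similarity[t])
            for t in self.scan.candidate_thresholds
        ]
        frame = pd.DataFrame(rows, columns=["threshold", "mean_pairwise_pcc"])
        frame["selected"] = frame["threshold"] == self.scan.selected
        return frame

    def summary(self, top: int = 10) -> str:
        """Human-readable summary of the fit."""
        lines = [
            "Community hub prediction",
            "========================",
            f"methods combined (N): {self.hub_scores.n_methods}",
            f"  {', '.join(p.method_name or '<unnamed>' for p in self.predictions)}",
            f"selected edge threshold (T): {self.threshold}",
            "",
            "threshold scan (mean pairwise outdegree PCC):",
        ]
        for t in self.scan.candidate_thresholds:
            sim = self.scan.mean_similarity[t]
            mark = "  <- selected" if t == self.scan.selected else ""
            sim_s = f"{sim:.4f}" if sim is not None else "undefined"
            lines.append(f"  T={t:>8d}  {sim_s}{mark}")
        lines += ["", f"top {min(top, len(self.ranking))} hub candidates (score_k):"]
        for rank, reg in enumerate(self.ranking[:top], start=1):
            lines.append(f"  {rank:>3d}. {reg}  {self.hub_scores.scores[reg]:.3f}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write the hub table, the threshold scan, and the per-method
        edge lists into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_hub_table(self.hub_scores.scores, outdir / "hubs.tsv")
        self.scan_frame().to_csv(outdir / "threshold_scan.tsv", sep="\t", index=False)
        for p in self.predictions:
            name = p.method_name or "network"
            write_edge_list(p, outdir / f"edges_{name}.tsv")
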