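"""Typed containers and tab-separated readers/writers.

All file formats are plain tab-separated text:

* expression matrix — header row of sample ids, first column gene ids;
* regulator list — one gene id per line;
* edge list — ``regulator<TAB>target[<TAB>confidence]``, no header; a
  missing confidence column means the file order *is* the ranking;
* gold standard — two or three columns; a numeric third column equal to
  zero marks an explicit non-interaction and the line is skipped (with a
  logged count), matching the DREAM5 gold-standard dialect.

Identifiers are opaque, case-sensitive strings; no symbol mapping is
attempted.  Missing expression values are a hard error — silent imputation
would change every downstream confidence score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "RegulatorSet",
    "RankedEdgeList",
    "GoldStandard",
    "read_expression",
    "write_expression",
    "read_regulators",
    "write_regulators",
    "read_edge_list",
    "write_edge_list",
    "read_gold_standard",
    "write_gold_standard",
    "read_hub_table",
    "write_hub_table",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes × samples real-valued expression matrix.

    The tool is scale-agnostic: values are passed through unchanged in
    whatever units the upstream pipeline produced (counts, log-intensity,
    TPM, ...).  Engines that need scale invariance standardize internally.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValidationError("expression matrix has no genes")
        if len(self.sample_ids) == 0:
            raise ValidationError("expression matrix has no samples")
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if not i:
                    raise ValidationError(f"empty {label} identifier")
                if i in seen:
                    raise ValidationError(f"duplicate {label} id {i!r}")
                seen.add(i)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"missing or non-finite expression value at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "_gene_index", {g: i for i, g in enumerate(self.gene_ids)}
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            sample_ids=tuple(str(s) for s in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_index[gene_id]  # type: ignore[attr-defined]
        except KeyError:
            raise ValidationError(f"gene {gene_id!r} not in expression matrix") from None

    def profile(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]


@dataclass(frozen=True)
class RegulatorSet:
    """The candidate regulators (e.g. transcription factors).

    Membership in an expression matrix is checked at the point of use, not
    at construction: gold standards may legitimately reference regulators
    absent from the measured genes.
    """

    ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValidationError("regulator set is empty")
        object.__setattr__(self, "ids", frozenset(self.ids))

    @classmethod
    def from_iterable(cls, ids: Iterable[str]) -> "RegulatorSet":
        return cls(frozenset(str(i) for i in ids))

    @property
    def sorted_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.ids))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.ids

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class RankedEdgeList:
    """One method's GRN prediction: directed regulator→target edges,
    ordered by non-increasing confidence (ties keep stored order)."""

    edges: tuple[tuple[str, str, float], ...]
    method_name: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        prev = np.inf
        for reg, tgt, conf in self.edges:
            if reg == tgt:
                raise ValidationError(f"self-edge {reg!r} -> {tgt!r}")
            if (reg, tgt) in seen:
                raise ValidationError(f"duplicate edge {reg!r} -> {tgt!r}")
            seen.add((reg, tgt))
            if conf > prev:
                raise ValidationError(
                    f"edges not sorted by non-increasing confidence at "
                    f"{reg!r} -> {tgt!r} ({conf} > {prev})"
                )
            prev = conf

    @classmethod
    def from_scores(
        cls,
        scored: Iterable[tuple[str, str, float]],
        method_name: str = "",
    ) -> "RankedEdgeList":
        """Build a ranked list from unordered scores.

        Sorting is deterministic: descending confidence, ties broken by
        (regulator, target) id so reruns are bitwise reproducible.
        """
        ordered = sorted(scored, key=lambda e: (-e[2], e[0], e[1]))
        return cls(tuple((r, t, float(c)) for r, t, c in ordered), method_name)

    def __len__(self) -> int:
        return len(self.edges)

    def top(self, threshold: int) -> tuple[tuple[str, str, float], ...]:
        """The first min(threshold, len) edges; boundary ties resolve by
        stored order."""
        if threshold < 0:
            raise ValidationError("threshold must be >= 0")
        return self.edges[: min(threshold, len(self.edges))]

    def sources(self) -> frozenset[str]:
        return frozenset(e[0] for e in self.edges)


@dataclass(frozen=True)
class GoldStandard:
    """A reference network used only for evaluation.

    ``directed`` is True for regulatory standards; False for
    protein–protein-interaction proxies, where (a, b) and (b, a) are the
    same edge and are stored canonically with a <= b.
    """

    edges: frozenset[tuple[str, str]]
    directed: bool = True

    def __post_init__(self) -> None:
        canon: set[tuple[str, str]] = set()
        for a, b in self.edges:
            if a == b:
                raise ValidationError(f"self-edge {a!r} in gold standard")
            if not self.directed:
                a, b = (a, b) if a <= b else (b, a)
            canon.add((a, b))
        object.__setattr__(self, "edges", frozenset(canon))

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (header = sample ids,
    first column = gene ids).  Row and column order are preserved."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene id {dup[0]!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    missing = frame.isna()
    if missing.to_numpy().any():
        g, s = np.argwhere(missing.to_numpy())[0]
        raise ValidationError(
            f"{path}: missing expression value at gene {frame.index[g]!r}, "
            f"sample {frame.columns[s]!r} (values are never imputed)"
        )
    bad = numeric.isna() & ~missing
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {frame.iat[g, s]!r} at gene "
            f"{frame.index[g]!r}, sample {frame.columns[s]!r}"
        )
    # numpy's parser is correctly rounded, so repr() round-trips bitwise
    values = frame.to_numpy(dtype="U32").astype(float)
    return ExpressionMatrix(
        tuple(str(g) for g in frame.index),
        tuple(str(s) for s in frame.columns),
        values,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    # repr() keeps full float precision so write/read round-trips bitwise
    with open(Path(path), "w") as fh:
        fh.write("\t" + "\t".join(expr.sample_ids) + "\n")
        for gene, row in zip(expr.gene_ids, expr.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_regulators(path: str | Path) -> RegulatorSet:
    path = Path(path)
    ids: list[str] = []
    for line in path.read_text().splitlines():
        token = line.strip()
        if token:
            ids.append(token)
    if not ids:
        raise ValidationError(f"{path}: regulator file is empty")
    n_dup = len(ids) - len(set(ids))
    if n_dup:
        logger.warning("%s: %d duplicate regulator line(s) collapsed", path, n_dup)
    return RegulatorSet.from_iterable(ids)


def write_regulators(regs: RegulatorSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{r}\n" for r in regs.sorted_ids))


def read_edge_list(path: str | Path, name: str | None = None) -> RankedEdgeList:
    """Read a ranked edge list.

    With a confidence column the edges are stably sorted by descending
    confidence (file order breaks ties).  Without one, synthetic
    confidences ``n_lines - line_index`` preserve the file order as the
    ranking.
    """
    path = Path(path)
    rows: list[tuple[str, str, float | None]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (2, 3):
            raise ParseError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
        reg, tgt = parts[0].strip(), parts[1].strip()
        if not reg or not tgt:
            raise ParseError(f"{path}:{lineno}: empty identifier")
        if reg == tgt:
            raise ValidationError(f"{path}:{lineno}: self-edge {reg!r} -> {tgt!r}")
        conf: float | None = None
        if len(parts) == 3:
            try:
                conf = float(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric confidence {parts[2]!r}"
                ) from None
        rows.append((reg, tgt, conf))
    seen: dict[tuple[str, str], int] = {}
    for i, (reg, tgt, _) in enumerate(rows, start=1):
        if (reg, tgt) in seen:
            raise ValidationError(
                f"{path}:{i}: duplicate edge {reg!r} -> {tgt!r} "
                f"(first seen at line {seen[(reg, tgt)]})"
            )
        seen[(reg, tgt)] = i
    n = len(rows)
    has_conf = [c is not None for _, _, c in rows]
    if any(has_conf) and not all(has_conf):
        raise ParseError(f"{path}: mixed lines with and without a confidence column")
    if not all(has_conf):
        edges = [(r, t, float(n - i)) for i, (r, t, _) in enumerate(rows)]
    else:
        # stable sort: file order is the ultimate tie-break
        edges = sorted(
            ((r, t, float(c)) for r, t, c in rows),  # type: ignore[arg-type]
            key=lambda e: -e[2],
        )
    return RankedEdgeList(tuple(edges), method_name=name or path.stem)


def write_edge_list(edges: RankedEdgeList, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for reg, tgt, conf in edges.edges:
            fh.write(f"{reg}\t{tgt}\t{conf!r}\n")


def read_gold_standard(path: str | Path, directed: bool = True) -> GoldStandard:
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    n_nonedges = 0
    n_dup = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) not in (2, 3):
            raise ParseError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields")
        a, b = parts[0].strip(), parts[1].strip()
        if a == b:
            raise ValidationError(f"{path}:{lineno}: self-edge {a!r}")
        if len(parts) == 3:
            try:
                label = float(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric label {parts[2]!r}"
                ) from None
            if label == 0:
                n_nonedges += 1
                continue
        if not directed:
            a, b = (a, b) if a <= b else (b, a)
        if (a, b) in pairs:
            n_dup += 1
        pairs.add((a, b))
    if n_nonedges:
        logger.info("%s: skipped %d explicit non-edge line(s)", path, n_nonedges)
    if n_dup:
        logger.info("%s: collapsed %d duplicate edge line(s)", path, n_dup)
    return GoldStandard(frozenset(pairs), directed=directed)


def write_gold_standard(gs: GoldStandard, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for a, b in sorted(gs.edges):
            fh.write(f"{a}\t{b}\n")


def read_hub_table(path: str | Path) -> dict[str, float]:
    """Read a hub table written by :func:`write_hub_table` back into a
    regulator → score mapping."""
    path = Path(path)
    scores: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("regulator\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields")
        reg = parts[0]
        if reg in scores:
            raise ValidationError(f"{path}:{lineno}: duplicate regulator {reg!r}")
        scores[reg] = float(parts[1])
    if not scores:
        raise ValidationError(f"{path}: hub table is empty")
    return scores


def write_hub_table(scores: Mapping[str, float], path: str | Path) -> None:
    """Write ``regulator<TAB>score<TAB>rank`` sorted by descending score
    (ties broken by id)."""
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(Path(path), "w") as fh:
        fh.write("regulator\tscore\trank\n")
        for rank, (reg, score) in enumerate(ordered, start=1):
            fh.write(f"{reg}\t{score!r}\t{rank}\n")
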