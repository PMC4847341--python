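"""Benchmark matching and the six standard complex-prediction metrics.

A predicted and a benchmark complex match when their neighborhood
affinity (squared overlap over the size product) exceeds a threshold,
0.2 by default. Precision/recall/F count matched complexes on each
side; Sn/PPV/Acc are computed from the full protein-overlap matrix.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

logger = logging.getLogger(__name__)


def neighborhood_affinity(p: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """``|P ∩ B|^2 / (|P| * |B|)``; 1 for identical sets, 0 for disjoint."""
    if not p or not b:
        raise ValueError("neighborhood affinity undefined for empty sets")
    overlap = len(set(p) & set(b))
    return overlap * overlap / (len(p) * len(b))


@dataclass(frozen=True)
class BenchmarkComplexSet:
    """Reference complexes with normalized protein IDs."""

    complexes: tuple[frozenset[str], ...]
    name: str = "benchmark"

    def __post_init__(self) -> None:
        if any(not c for c in self.complexes):
            raise ValueError("benchmark contains an empty complex")

    def __len__(self) -> int:
        return len(self.complexes)

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "BenchmarkComplexSet":
        """One complex per line, whitespace-separated IDs, '#' comments."""
        seen: set[frozenset[str]] = set()
        ordered: list[frozenset[str]] = []
        with open(path, encoding="utf-8") as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                members = frozenset(tok.upper() for tok in line.split())
                if members and members not in seen:
                    seen.add(members)
                    ordered.append(members)
        if not ordered:
            raise ValueError(f"{path}: no benchmark complexes")
        return cls(tuple(ordered), name or Path(path).stem)


@dataclass(frozen=True)
class EvaluationReport:
    precision: float
    recall: float
    f_score: float
    sn: float
    ppv: float
    accuracy: float
    n_cp: int
    n_cb: int
    match_pairs: tuple[tuple[int, int, float], ...] = field(repr=False, default=())

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "sn": self.sn,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "n_cp": self.n_cp,
            "n_cb": self.n_cb,
            "match_pairs": [list(p) for p in self.match_pairs],
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)
            fh.write("\n")

    def format_table(self) -> str:
        header = f"{'P':>8} {'R':>8} {'F':>8} {'Sn':>8} {'PPV':>8} {'Acc':>8}"
        row = (
            f"{self.precision:8.3f} {self.recall:8.3f} {self.f_score:8.3f} "
            f"{self.sn:8.3f} {self.ppv:8.3f} {self.accuracy:8.3f}"
        )
        return header + "\n" + row


def match_and_score(
    predicted: Sequence[frozenset[str] | set[str]],
    benchmark: BenchmarkComplexSet,
    na_thresh: float = 0.2,
) -> EvaluationReport:
    """Match predictions against the benchmark and compute all metrics.

    Matching is many-to-many: every (predicted, benchmark) pair with
    affinity strictly above ``na_thresh`` counts. With no predictions,
    precision/recall are reported as 0 with a warning; with no protein
    overlap at all, PPV is defined as 0.
    """
    if len(benchmark) == 0:
        raise ValueError("empty benchmark set")
    pred = [frozenset(p) for p in predicted]
    if any(not p for p in pred):
        raise ValueError("empty predicted complex")
    if not pred:
        logger.warning("no predicted complexes: precision/recall reported as 0")
        return EvaluationReport(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 0)

    bench = benchmark.complexes
    pairs: list[tuple[int, int, float]] = []
    matched_pred: set[int] = set()
    matched_bench: set[int] = set()
    # T[i][j] = overlap between benchmark i and predicted j
    overlap = [[0] * len(pred) for _ in bench]
    for i, b in enumerate(bench):
        for j, p in enumerate(pred):
            t_ij = len(b & p)
            overlap[i][j] = t_ij
            if t_ij == 0:
                continue
            na = t_ij * t_ij / (len(p) * len(b))
            if na > na_thresh:
                pairs.append((j, i, na))
                matched_pred.add(j)
                matched_bench.add(i)

    n_cp = len(matched_pred)
    n_cb = len(matched_bench)
    precision = n_cp / len(pred)
    recall = n_cb / len(bench)
    f_score = (
        2.0 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )

    sn_num = sum(max(row) for row in overlap)
    sn_den = sum(len(b) for b in bench)
    sn = sn_num / sn_den

    ppv_num = sum(max(overlap[i][j] for i in range(len(bench))) for j in range(len(pred)))
    ppv_den = sum(sum(row) for row in overlap)
    ppv = ppv_num / ppv_den if ppv_den > 0 else 0.0

    accuracy = math.sqrt(sn * ppv)
    pairs.sort()
    return EvaluationReport(
        precision=precision,
        recall=recall,
        f_score=f_score,
        sn=sn,
        ppv=ppv,
        accuracy=accuracy,
        n_cp=n_cp,
        n_cb=n_cb,
        match_pairs=tuple(pairs),
    )
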