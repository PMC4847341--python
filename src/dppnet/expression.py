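"""Per-gene activity calling from time-course expression data.

Each gene is scored against its own expression distribution: the sample
mean and standard deviation define three variance-damped k-sigma
thresholds, and each time point is assigned one of four activity
probability levels (0.99 / 0.95 / 0.68 / 0) depending on which threshold
the expression value clears.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Activity probability levels, highest confidence first.
PROB_HIGH = 0.99
PROB_MID = 0.95
PROB_LOW = 0.68
PROB_LEVELS = (PROB_HIGH, PROB_MID, PROB_LOW)

#: Two-sided normal masses within k sigma of the mean, k = 1, 2, 3.
#: The three activity levels above are these masses truncated to two
#: decimal places.
SIGMA_MASSES = (0.6827, 0.9545, 0.9973)


@dataclass(frozen=True)
class ExpressionProfile:
    """Expression values for one gene across ordered time points."""

    gene_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError(
                f"gene {self.gene_id!r}: need at least 2 time points, "
                f"got {len(self.values)}"
            )
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError(f"gene {self.gene_id!r}: non-finite expression value")

    @property
    def n_timepoints(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GeneStats:
    """Per-gene summary statistics and k-sigma activity thresholds.

    ``thresholds`` holds the k = 1, 2, 3 thresholds in nondecreasing
    order; each equals ``mean + k * sd * (1 - 1/(1 + sd**2))``.
    """

    gene_id: str
    mean: float
    sd: float
    thresholds: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        t1, t2, t3 = self.thresholds
        if not (t1 <= t2 <= t3):
            raise ValueError("thresholds must be nondecreasing")


def sigma_thresholds(mean: float, sd: float) -> tuple[float, float, float]:
    """k-sigma thresholds with the variance damping factor.

    The damping term ``1 - 1/(1 + sd**2)`` pulls the thresholds toward
    the mean for low-variance genes, so flat expression curves do not
    produce spurious actives from tiny fluctuations.
    """
    damp = 1.0 - 1.0 / (1.0 + sd * sd)
    return tuple(mean + k * sd * damp for k in (1, 2, 3))  # type: ignore[return-value]


def gene_stats(profile: ExpressionProfile) -> GeneStats:
    """Sample mean, sample SD (divisor n-1) and the three thresholds."""
    arr = np.asarray(profile.values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return GeneStats(profile.gene_id, mean, sd, sigma_thresholds(mean, sd))


def active_probability(stats: GeneStats, value: float) -> float:
    """Activity probability level of one expression value.

    Tiers are half-open from above: a value equal to a threshold clears
    it. Returns one of 0.99, 0.95, 0.68 or 0.
    """
    t1, t2, t3 = stats.thresholds
    if value >= t3:
        return PROB_HIGH
    if value >= t2:
        return PROB_MID
    if value >= t1:
        return PROB_LOW
    return 0.0


class ActivityTable:
    """Per-protein activity levels at each time point.

    Only nonzero levels are stored; every queried (protein, time point)
    pair resolves to 0.0 when inactive. A protein's active set is the
    set of 1-based time points with a nonzero level.
    """

    def __init__(
        self,
        levels: Mapping[str, Mapping[int, float]],
        n_timepoints: int,
    ) -> None:
        if n_timepoints < 1:
            raise ValueError("n_timepoints must be positive")
        allowed = set(PROB_LEVELS)
        self._levels: dict[str, dict[int, float]] = {}
        for protein, row in levels.items():
            kept = {}
            for t, level in row.items():
                if level == 0.0:
                    continue
                if level not in allowed:
                    raise ValueError(
                        f"protein {protein!r}, T{t}: invalid level {level!r}"
                    )
                if not 1 <= t <= n_timepoints:
                    raise ValueError(f"protein {protein!r}: time point {t} out of range")
                kept[int(t)] = float(level)
            self._levels[protein] = kept
        self.n_timepoints = n_timepoints

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self._levels)

    def level(self, protein: str, timepoint: int) -> float:
        return self._levels.get(protein, {}).get(timepoint, 0.0)

    def active_set(self, protein: str) -> frozenset[int]:
        return frozenset(self._levels.get(protein, {}))

    def levels_of(self, protein: str) -> dict[int, float]:
        return dict(self._levels.get(protein, {}))

    def __contains__(self, protein: str) -> bool:
        return protein in self._levels

    def __len__(self) -> int:
        return len(self._levels)

    def write_tsv(self, path: str | Path) -> None:
        """Write nonzero entries as protein_id / time_point / level rows."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["protein_id", "time_point", "probability_level"])
            for protein in sorted(self._levels):
                for t in sorted(self._levels[protein]):
                    writer.writerow([protein, f"T{t}", f"{self._levels[protein][t]:.2f}"])

    @classmethod
    def read_tsv(cls, path: str | Path, n_timepoints: int) -> "ActivityTable":
        levels: dict[str, dict[int, float]] = {}
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None:
                raise ValueError(f"{path}: empty activity file")
            for row in reader:
                protein, t_label, level = row[0], row[1], float(row[2])
                t = int(t_label.lstrip("T"))
                levels.setdefault(protein, {})[t] = level
        return cls(levels, n_timepoints)


def _parse_rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) skipping blanks and '!' comments."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("!"):
                continue
            yield lineno, line.split("\t")


def load_expression_matrix(path: str | Path) -> list[ExpressionProfile]:
    """Parse a TSV expression matrix into one profile per gene.

    Expects a header row of time-point labels and gene IDs in the first
    column. Lines starting with ``!`` (GEO series-matrix comments) and
    blank lines are skipped. Gene IDs are uppercased; duplicate rows for
    the same gene are averaged element-wise with a warning.
    """
    rows = _parse_rows(path)
    try:
        _, header = next(rows)
    except StopIteration:
        raise ValueError(f"{path}: no expression records") from None

    by_gene: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    width: int | None = None
    for lineno, fields in rows:
        if len(fields) < 2:
            raise ValueError(f"{path}, line {lineno}: expected >= 2 columns")
        gene = fields[0].strip().upper()
        if width is None:
            width = len(fields)
            if len(header) not in (width, width - 1):
                logger.warning(
                    "%s: header has %d fields but data rows have %d columns",
                    path, len(header), width,
                )
        elif len(fields) != width:
            raise ValueError(
                f"{path}, line {lineno}: expected {width} columns, got {len(fields)}"
            )
        try:
            values = np.array([float(v) for v in fields[1:]], dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: non-numeric cell ({exc})") from None
        if gene not in by_gene:
            order.append(gene)
        by_gene.setdefault(gene, []).append(values)

    if not by_gene:
        raise ValueError(f"{path}: no expression records")

    profiles = []
    n_dup = 0
    for gene in order:
        stack = by_gene[gene]
        if len(stack) > 1:
            n_dup += 1
            values = np.mean(stack, axis=0)
        else:
            values = stack[0]
        profiles.append(ExpressionProfile(gene, tuple(float(v) for v in values)))
    if n_dup:
        logger.warning("%s: averaged duplicate rows for %d gene(s)", path, n_dup)
    return profiles


def collapse_cycles(
    profiles: Iterable[ExpressionProfile],
    cycles: int,
    points_per_cycle: int,
    method: str = "mean",
) -> list[ExpressionProfile]:
    """Reduce a multi-cycle time course to one representative cycle.

    ``method`` is ``"mean"`` (per-position average across cycles, the
    default), ``"first"`` (keep the first cycle), or ``"none"`` (no
    reduction; profile lengths are still validated).
    """
    if method not in ("mean", "first", "none"):
        raise ValueError(f"unknown collapse method {method!r}")
    expected = cycles * points_per_cycle
    out = []
    for profile in profiles:
        if profile.n_timepoints != expected:
            raise ValueError(
                f"gene {profile.gene_id!r}: expected {expected} time points "
                f"({cycles} cycles x {points_per_cycle}), got {profile.n_timepoints}"
            )
        if method == "none" or cycles == 1:
            out.append(profile)
            continue
        arr = np.asarray(profile.values, dtype=float).reshape(cycles, points_per_cycle)
        collapsed = arr[0] if method == "first" else arr.mean(axis=0)
        out.append(ExpressionProfile(profile.gene_id, tuple(float(v) for v in collapsed)))
    return out


def build_activity_table(profiles: Sequence[ExpressionProfile]) -> ActivityTable:
    """Apply the tiered thresholds to every (gene, time point) pair.

    Zero-variance genes score 0.99 everywhere (all thresholds collapse
    to the mean); they carry no temporal signal and are counted in a
    warning.
    """
    if not profiles:
        raise ValueError("no expression profiles")
    n = profiles[0].n_timepoints
    levels: dict[str, dict[int, float]] = {}
    n_flat = 0
    for profile in profiles:
        if profile.n_timepoints != n:
            raise ValueError(
                f"gene {profile.gene_id!r}: inconsistent profile length "
                f"{profile.n_timepoints} != {n}"
            )
        stats = gene_stats(profile)
        if stats.sd == 0.0:
            n_flat += 1
        levels[profile.gene_id] = {
            t: level
            for t, value in enumerate(profile.values, start=1)
            if (level := active_probability(stats, value)) > 0.0
        }
    if n_flat:
        logger.warning(
            "%d zero-variance gene(s): active at level 0.99 everywhere", n_flat
        )
    return ActivityTable(levels, n)
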