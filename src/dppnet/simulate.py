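"""Synthetic PPI + expression + benchmark generation with known truth.

Planted complexes are cliques whose member genes receive a strong
expression pulse at a chosen time point in every cycle, sized so the
pulse clears the gene's own three-sigma threshold; background genes get
periodic-plus-noise expression and sparse random edges. Also implements
the row-wise expression shuffling control.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .expression import _parse_rows


@dataclass(frozen=True)
class PlantedComplex:
    size: int
    time: int  # 1-based active time point
    density: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("planted complex size must be >= 2")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``amplitude`` is the pulse height in units of ``noise_sd`` above the
    gene's baseline mean; >= 3 keeps planted members above their own
    top threshold at the planted time.
    """

    n_proteins: int
    planted: tuple[PlantedComplex, ...] = ()
    n_timepoints: int = 12
    n_cycles: int = 3
    background_edge_prob: float = 0.01
    noise_sd: float = 1.0
    amplitude: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ValueError("background_edge_prob must be in [0, 1]")
        total = sum(c.size for c in self.planted)
        if total > self.n_proteins:
            raise ValueError(
                f"planted complexes need {total} proteins but spec has {self.n_proteins}"
            )
        for c in self.planted:
            if not 1 <= c.time <= self.n_timepoints:
                raise ValueError(f"planted time {c.time} outside 1..{self.n_timepoints}")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = json.load(fh)
        planted = tuple(PlantedComplex(**c) for c in raw.pop("planted", []))
        return cls(planted=planted, **raw)


@dataclass(frozen=True)
class SyntheticDataset:
    """File paths of one generated dataset."""

    ppi_path: Path
    expression_path: Path
    benchmark_path: Path
    truth_path: Path


def _protein_name(i: int) -> str:
    return f"P{i + 1:04d}"


def generate(spec: SyntheticSpec, out_dir: str | Path) -> SyntheticDataset:
    """Write ppi.tsv, expression.tsv, benchmark.tsv and truth.json.

    Fully determined by ``spec`` (including its seed): the same spec
    always produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    names = [_protein_name(i) for i in range(n)]

    # planted complexes occupy disjoint leading blocks of proteins
    complexes: list[list[int]] = []
    cursor = 0
    for planted in spec.planted:
        complexes.append(list(range(cursor, cursor + planted.size)))
        cursor += planted.size

    edges: set[tuple[int, int]] = set()
    for planted, members in zip(spec.planted, complexes):
        for i, j in combinations(members, 2):
            if planted.density >= 1.0 or rng.random() < planted.density:
                edges.add((i, j))
    for i, j in combinations(range(n), 2):
        if (i, j) not in edges and rng.random() < spec.background_edge_prob:
            edges.add((i, j))

    # expression: baseline + (background: sinusoid) + noise; planted
    # members instead get a pulse at their complex's time in every cycle
    n_cols = spec.n_cycles * spec.n_timepoints
    pulse_time = {}
    for planted, members in zip(spec.planted, complexes):
        for m in members:
            pulse_time[m] = planted.time
    values = np.empty((n, n_cols))
    for g in range(n):
        mu = rng.uniform(4.0, 8.0)
        row = mu + rng.normal(0.0, spec.noise_sd, size=n_cols)
        if g in pulse_time:
            for c in range(spec.n_cycles):
                row[c * spec.n_timepoints + pulse_time[g] - 1] += (
                    spec.amplitude * spec.noise_sd
                )
        else:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            t = np.arange(n_cols) % spec.n_timepoints
            row = row + 2.0 * spec.noise_sd * np.sin(
                2.0 * np.pi * t / spec.n_timepoints + phase
            )
        values[g] = row

    ppi_path = out_dir / "ppi.tsv"
    with open(ppi_path, "w") as fh:
        for i, j in sorted(edges):
            fh.write(f"{names[i]}\t{names[j]}\n")

    expression_path = out_dir / "expression.tsv"
    with open(expression_path, "w") as fh:
        labels = "\t".join(f"T{k + 1}" for k in range(n_cols))
        fh.write(f"gene_id\t{labels}\n")
        for g in range(n):
            row = "\t".join(f"{v:.6f}" for v in values[g])
            fh.write(f"{names[g]}\t{row}\n")

    benchmark_path = out_dir / "benchmark.tsv"
    with open(benchmark_path, "w") as fh:
        for members in complexes:
            fh.write("\t".join(names[m] for m in members) + "\n")

    truth_path = out_dir / "truth.json"
    truth = {
        "spec": asdict(spec),
        "complexes": [
            {
                "members": [names[m] for m in members],
                "time": planted.time,
                "density": planted.density,
            }
            for planted, members in zip(spec.planted, complexes)
        ],
    }
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return SyntheticDataset(ppi_path, expression_path, benchmark_path, truth_path)


def shuffle_expression(
    in_path: str | Path, out_path: str | Path, seed: int
) -> None:
    """Permute each gene's values across time columns, independently.

    The multiset of values per gene is preserved; only their temporal
    order changes. Gene order and numeric formatting are kept.
    """
    rng = np.random.default_rng(seed)
    rows = list(_parse_rows(in_path))
    if not rows:
        raise ValueError(f"{in_path}: empty expression file")
    with open(out_path, "w") as fh:
        _, header = rows[0]
        fh.write("\t".join(header) + "\n")
        for _, fields in rows[1:]:
            gene, cells = fields[0], fields[1:]
            perm = rng.permutation(len(cells))
            fh.write(gene + "\t" + "\t".join(cells[i] for i in perm) + "\n")
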