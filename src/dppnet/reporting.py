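"""Writers/readers for pipeline artifacts and experiment reports."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

from .detect import DetectorConfig, PredictedComplex, identify_complexes
from .evaluate import BenchmarkComplexSet, EvaluationReport, match_and_score
from .network import DPPN


def write_complexes_tsv(complexes: Sequence[PredictedComplex], path: str | Path) -> None:
    """One complex per line: id, assigned time, score, then member IDs."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for idx, pc in enumerate(complexes, start=1):
            writer.writerow(
                [f"C{idx:04d}", f"T{pc.assigned_time}", f"{pc.score:.6f}"]
                + sorted(pc.members)
            )


def write_complexes_json(complexes: Sequence[PredictedComplex], path: str | Path) -> None:
    payload = [
        {
            "id": f"C{idx:04d}",
            "assigned_time": pc.assigned_time,
            "score": pc.score,
            "core": sorted(pc.core.members),
            "core_origin": pc.core.origin,
            "attachments": sorted(pc.attachments),
            "members": sorted(pc.members),
        }
        for idx, pc in enumerate(complexes, start=1)
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_complexes_tsv(path: str | Path) -> list[frozenset[str]]:
    """Member sets from a complexes TSV (id/time/score columns skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                continue
            out.append(frozenset(fields[3:]))
    return out


def write_active_distribution(dppn: DPPN, path: str | Path) -> list[int]:
    """Per-time-point counts of proteins with level >= 0.68, as TSV."""
    counts = dppn.active_protein_counts()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["time_point", "n_active_proteins"])
        for t, count in enumerate(counts, start=1):
            writer.writerow([f"T{t}", count])
    return counts


def sweep(
    dppn: DPPN,
    benchmark: BenchmarkComplexSet,
    grid: Sequence[tuple[float, float]],
    na_thresh: float = 0.2,
    base_config: DetectorConfig | None = None,
) -> list[tuple[float, float, EvaluationReport]]:
    """Evaluate the detector over a (core_thresh, extend_thresh) grid."""
    if not grid:
        raise ValueError("empty parameter grid")
    base = base_config or DetectorConfig()
    rows = []
    for core_thresh, extend_thresh in grid:
        config = DetectorConfig(
            core_thresh=core_thresh,
            extend_thresh=extend_thresh,
            min_clique_size=base.min_clique_size,
            overlap_thresh=base.overlap_thresh,
        )
        predicted = [pc.members for pc in identify_complexes(dppn, config)]
        report = match_and_score(predicted, benchmark, na_thresh)
        rows.append((core_thresh, extend_thresh, report))
    return rows


def write_sweep_table(
    rows: Sequence[tuple[float, float, EvaluationReport]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["core_thresh", "extend_thresh", "P", "R", "F", "Sn", "PPV", "Acc"]
        )
        for core_thresh, extend_thresh, report in rows:
            writer.writerow(
                [
                    f"{core_thresh:g}",
                    f"{extend_thresh:g}",
                    f"{report.precision:.6f}",
                    f"{report.recall:.6f}",
                    f"{report.f_score:.6f}",
                    f"{report.sn:.6f}",
                    f"{report.ppv:.6f}",
                    f"{report.accuracy:.6f}",
                ]
            )
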