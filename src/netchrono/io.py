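"""Edge-list and result file formats, plus run configuration.

Edge lists are plain text, one edge per line:

    u<TAB>v[<TAB>arrival[<TAB>snapshot]]

Lines starting with ``#`` are comments; node ids are opaque strings; arrival
positions and snapshot labels are 1-based.  Restored sequences are written as
``u<TAB>v<TAB>alpha_hat<TAB>borda`` with the same conventions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import yaml

from .network import Edge, TemporalNetwork, canonical_edge
from .ordermodel import RestoredSequence
from .theory import ErrorReport

PathLike = Union[str, Path]


@dataclasses.dataclass
class RunConfig:
    """Reproducible run settings; every seed is explicit."""

    input_path: str = ""
    output_dir: str = "."
    dim: int = 64
    train_fraction: float = 0.05
    seed: int = 0
    n_snapshots: Optional[int] = None
    verbosity: int = 1

    def to_yaml(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def read_temporal_edgelist(path: PathLike) -> TemporalNetwork:
    """Parse an edge-list file into a TemporalNetwork.

    Edges carrying an arrival column are sorted into arrival order; the
    arrival values must form a bijection onto 1..E.  Malformed lines,
    self-loops and duplicates are rejected with their line number.
    """
    rows: List[tuple] = []
    has_arrival = None
    has_snapshot = None
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2 or len(parts) > 4:
            raise ValueError(f"{path}:{ln}: expected 2-4 columns, got {len(parts)}")
        u, v = parts[0], parts[1]
        if u == v:
            raise ValueError(f"{path}:{ln}: self-loop {u!r}")
        arrival = snapshot = None
        try:
            if len(parts) >= 3:
                arrival = int(parts[2])
            if len(parts) == 4:
                snapshot = int(parts[3])
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-integer arrival/snapshot column") from None
        if (has_arrival is not None and (arrival is not None) != has_arrival) or \
           (has_snapshot is not None and (snapshot is not None) != has_snapshot):
            raise ValueError(f"{path}:{ln}: inconsistent column count")
        has_arrival = arrival is not None
        has_snapshot = snapshot is not None
        rows.append((ln, u, v, arrival, snapshot))
    if not rows:
        raise ValueError(f"{path}: no edge lines found")
    seen: Dict[Edge, int] = {}
    for ln, u, v, *_ in rows:
        e = canonical_edge(u, v)
        if e in seen:
            raise ValueError(f"{path}:{ln}: duplicate edge {e!r} (first at line {seen[e]})")
        seen[e] = ln
    if has_arrival:
        arrivals = [r[3] for r in rows]
        if sorted(arrivals) != list(range(1, len(rows) + 1)):
            raise ValueError(f"{path}: arrival positions are not a bijection onto 1..E")
        rows.sort(key=lambda r: r[3])
    edges = [(r[1], r[2]) for r in rows]
    snapshots = [r[4] for r in rows] if has_snapshot else None
    return TemporalNetwork(edges, snapshots=snapshots)


def write_temporal_edgelist(net: TemporalNetwork, path: PathLike) -> None:
    lines = ["# u\tv\tarrival" + ("\tsnapshot" if net.snapshots is not None else "")]
    for k, (u, v) in enumerate(net.edges):
        row = f"{u}\t{v}\t{k + 1}"
        if net.snapshots is not None:
            row += f"\t{net.snapshots[k]}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def write_sequence(restored: RestoredSequence, path: PathLike,
                   report: Optional[ErrorReport] = None,
                   report_path: Optional[PathLike] = None) -> None:
    """Write a restored sequence (TSV) and optionally its error report (JSON)."""
    lines = ["# u\tv\talpha_hat\tborda"]
    for (u, v), pos, cnt in zip(restored.edges, restored.positions, restored.borda):
        lines.append(f"{u}\t{v}\t{int(pos)}\t{int(cnt)}")
    Path(path).write_text("\n".join(lines) + "\n")
    if report is not None:
        payload = {
            "overall_error": report.overall_error,
            "kendall_tau": report.kendall_tau,
            "spearman_rho": report.spearman_rho,
            "theory_error": report.theory_error,
        }
        out = Path(report_path) if report_path is not None else Path(path).with_suffix(".report.json")
        out.write_text(json.dumps(payload, indent=2) + "\n")


def read_sequence(path: PathLike) -> RestoredSequence:
    import numpy as np
    edges: List[Edge] = []
    positions: List[int] = []
    borda: List[int] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 columns")
        edges.append((parts[0], parts[1]))
        positions.append(int(parts[2]))
        borda.append(int(parts[3]))
    return RestoredSequence(edges=edges, positions=np.array(positions),
                            borda=np.array(borda), source=str(path))


def read_node_labels(path: PathLike) -> Dict[str, str]:
    """Two-column file: node<TAB>label."""
    labels: Dict[str, str] = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 columns")
        labels[parts[0]] = parts[1]
    return labels
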