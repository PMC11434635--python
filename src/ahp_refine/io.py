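"""Reading and writing judgment matrices, reports and run configuration.

Matrix CSV dialect: first row is a header whose cells after the corner are
the item labels; each following row is a label and n numeric cells.  Cells
may be decimals or exact fraction strings like ``1/6``.  The JSON alternative
is ``{"labels": [...], "entries": [[...]]}``.  Reports are JSON with a
versioned schema.
"""

from __future__ import annotations

import csv
import json
from fractions import Fraction
from pathlib import Path

import yaml

from .matrices import PairwiseComparisonMatrix, validate_matrix
from .optimizers import AnnealConfig, SwarmConfig

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_report",
    "load_run_config",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = 1


def _parse_cell(text: str) -> float:
    text = text.strip()
    if not text:
        raise ValueError("empty numeric cell")
    if "/" in text:
        return float(Fraction(text))
    return float(text)


def read_matrix(
    path, fmt: str | None = None, mode: str = "strict"
) -> PairwiseComparisonMatrix:
    """Load a pairwise-comparison matrix from CSV or JSON.

    ``fmt`` is inferred from the file suffix when omitted.  ``mode`` is
    passed to validation; use ``"repair_reciprocal"`` for files whose lower
    triangle holds rounded decimals (e.g. 0.33 for 1/3).
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        data = json.loads(path.read_text())
        labels = data["labels"]
        grid = data["entries"]
        return validate_matrix(grid, labels=labels, mode=mode)
    if fmt != "csv":
        raise ValueError(f"unknown matrix format {fmt!r}")

    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if len(rows) < 3:
        raise ValueError(f"{path}: too few rows for a comparison matrix")
    labels = [c.strip() for c in rows[0][1:] if c.strip()]
    n = len(labels)
    grid = []
    for r in rows[1:]:
        cells = [c for c in r if c.strip()]
        if len(cells) != n + 1:
            raise ValueError(
                f"{path}: ragged row {r!r}; expected label plus {n} cells"
            )
        grid.append([_parse_cell(c) for c in cells[1:]])
    if len(grid) != n:
        raise ValueError(f"{path}: expected {n} data rows, found {len(grid)}")
    return validate_matrix(grid, labels=labels, mode=mode)


def write_matrix(M: PairwiseComparisonMatrix, path, fmt: str | None = None) -> None:
    """Write a matrix as CSV (default) or JSON; round-trips to 12+ digits."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "json":
        path.write_text(
            json.dumps(
                {"labels": list(M.labels), "entries": M.entries.tolist()}, indent=2
            )
            + "\n"
        )
        return
    if fmt != "csv":
        raise ValueError(f"unknown matrix format {fmt!r}")
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["", *M.labels])
        for label, row in zip(M.labels, M.entries):
            w.writerow([label, *(repr(float(x)) for x in row)])


def write_report(payload: dict, path=None) -> str:
    """Serialize a result payload as versioned JSON; write it if a path is given."""
    doc = {"schema": REPORT_SCHEMA_VERSION, **payload}
    text = json.dumps(doc, indent=2, default=_jsonify) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _jsonify(obj):
    try:
        import numpy as np

        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"cannot serialize {type(obj)!r}")


_SWARM_KEYS = {
    "swarm_size", "inertia", "c1", "c2", "vmax",
    "max_iterations", "error_threshold", "seed",
}
_ANNEAL_KEYS = {"t0", "gamma", "neighborhood_size", "radius0", "radius_decay"}


def load_run_config(path=None, seed: int | None = None):
    """Build (SwarmConfig, AnnealConfig) from a YAML key-value file.

    Keys may be flat or grouped under ``swarm:`` / ``anneal:`` blocks; any
    missing key keeps its default.  ``seed`` overrides the file's seed.
    """
    swarm_kw: dict = {}
    anneal_kw: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a key-value mapping")
        flat = dict(data)
        for block, kw, keys in (
            ("swarm", swarm_kw, _SWARM_KEYS),
            ("anneal", anneal_kw, _ANNEAL_KEYS),
        ):
            sub = flat.pop(block, {}) or {}
            for k, v in sub.items():
                if k not in keys:
                    raise ValueError(f"unknown {block} parameter {k!r}")
                kw[k] = v
        for k, v in flat.items():
            if k in _SWARM_KEYS:
                swarm_kw[k] = v
            elif k in _ANNEAL_KEYS:
                anneal_kw[k] = v
            else:
                raise ValueError(f"unknown config parameter {k!r}")
    if seed is not None:
        swarm_kw["seed"] = seed
    return SwarmConfig(**swarm_kw), AnnealConfig(**anneal_kw)
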