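"""Graph document I/O: JSON, edge-list TSV and dense CSV.

The JSON document stores the family, its parameters, the vertex labels and
the row-major weight matrix.  Numbers are serialised as exact fraction
strings (``"2/3"``) when the value has a small exact representation, else
as 17-significant-digit decimal strings, so a write -> read round trip
reproduces the weight matrix to full precision.  Edge lists use 1-based
vertex ids to match the v1..vN labelling convention.
"""

from __future__ import annotations

import csv
import json
from fractions import Fraction
from pathlib import Path

from .graphs import WeightedDigraph, as_fraction

__all__ = [
    "GraphDocumentError",
    "write_graph",
    "read_graph",
    "write_edge_list",
    "read_edge_list",
    "write_matrix_csv",
]

SCHEMA_VERSION = 1


class GraphDocumentError(ValueError):
    pass


def _encode_number(x: Fraction) -> str:
    if x.denominator == 1:
        return str(x.numerator)
    if x.denominator < 10**12:
        return f"{x.numerator}/{x.denominator}"
    return repr(float(x))


def _encode_param(v):
    if isinstance(v, Fraction):
        return _encode_number(v)
    if isinstance(v, (tuple, list)):
        return [_encode_param(x) for x in v]
    return v


def write_graph(path, graph: WeightedDigraph, provenance: dict | None = None) -> None:
    doc = {
        "schema": SCHEMA_VERSION,
        "family": graph.family,
        "params": {k: _encode_param(v) for k, v in graph.params.items()},
        "N": graph.N,
        "vertex_labels": graph.vertex_labels,
        "W": [[_encode_number(x) for x in row] for row in graph.W_exact],
    }
    if provenance:
        doc["provenance"] = provenance
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_graph(path) -> WeightedDigraph:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise GraphDocumentError(f"malformed graph JSON {path}: {err}") from None
    for key in ("family", "N", "W"):
        if key not in doc:
            raise GraphDocumentError(f"graph document missing field {key!r}")
    W = doc["W"]
    if len(W) != doc["N"] or any(len(r) != doc["N"] for r in W):
        raise GraphDocumentError(
            f"W must be {doc['N']}x{doc['N']} row-major"
        )
    try:
        rows = [[as_fraction(x) for x in row] for row in W]
    except (ValueError, ZeroDivisionError) as err:
        raise GraphDocumentError(f"unparseable weight: {err}") from None
    return WeightedDigraph(
        rows,
        family=doc["family"],
        params=doc.get("params", {}),
        vertex_labels=doc.get("vertex_labels"),
    )


def write_edge_list(path, graph: WeightedDigraph) -> None:
    """TSV of (i, j, w_ij) with 1-based ids; zero-weight edges omitted."""
    with open(path, "w", newline="") as fh:
        out = csv.writer(fh, delimiter="\t")
        for i, row in enumerate(graph.W_exact):
            for j, w in enumerate(row):
                if w != 0:
                    out.writerow([i + 1, j + 1, _encode_number(w)])


def read_edge_list(path, N: int | None = None) -> WeightedDigraph:
    """Read a 1-based (i, j, w) TSV into a validated WeightedDigraph."""
    entries = []
    with open(path, newline="") as fh:
        for lineno, parts in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 3:
                raise GraphDocumentError(
                    f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            try:
                entries.append((int(parts[0]), int(parts[1]), as_fraction(parts[2])))
            except ValueError as err:
                raise GraphDocumentError(f"line {lineno}: {err}") from None
    if not entries:
        raise GraphDocumentError("empty edge list")
    size = N or max(max(i, j) for i, j, _ in entries)
    rows = [[Fraction(0)] * size for _ in range(size)]
    for i, j, w in entries:
        if not (1 <= i <= size and 1 <= j <= size):
            raise GraphDocumentError(f"vertex id out of range in edge ({i}, {j})")
        rows[i - 1][j - 1] += w
    try:
        return WeightedDigraph(rows)
    except ValueError as err:
        raise GraphDocumentError(str(err)) from None


def write_matrix_csv(path, graph: WeightedDigraph, exact: bool = False) -> None:
    """Dense CSV export (decimal floats, or exact fraction strings)."""
    with open(path, "w", newline="") as fh:
        out = csv.writer(fh)
        out.writerow(graph.vertex_labels)
        for row in graph.W_exact:
            if exact:
                out.writerow([_encode_number(x) for x in row])
            else:
                out.writerow([repr(float(x)) for x in row])
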