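"""Degree-based hub-gene screening on a protein-protein interaction network.

The PPI network is supplied as a STRING-export-style edge list (two symbol
columns, optionally a combined score).  Hubs are the k nodes of highest
degree, with alphabetical tie-break; hub lists can be intersected with a
curated reference list (e.g. GenAge human aging genes) case-insensitively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .io_data import read_gene_list

logger = logging.getLogger(__name__)

__all__ = ["HubResult", "read_edge_list", "degree_hubs", "intersect_gene_list"]

_HEADER_TOKENS = {
    "protein1", "protein2", "node1", "node2", "gene1", "gene2",
    "source", "target", "combined_score", "score",
}


@dataclass
class HubResult:
    """Degree ranking and the top-k hub set of a PPI graph."""

    ranking: list[tuple[str, int]]  # (gene, degree), non-increasing degree
    hubs: list[str]
    k: int
    n_nodes: int
    n_edges: int


def read_edge_list(
    path: str | Path,
    score_column: int | None = None,
    min_score: float | None = None,
    delimiter: str | None = None,
) -> nx.Graph:
    """Read an undirected simple graph from a delimited edge list.

    Reversed duplicate edges collapse; self-loops are dropped (logged);
    ``min_score`` filters on the score column (default: third column when a
    filter is requested).  A recognizable header row is skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if min_score is not None and score_column is None:
        score_column = 2

    g = nx.Graph()
    n_self_loops = 0
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tokens = line.split(delimiter) if delimiter else line.split()
        if lineno == 1 and any(t.lower() in _HEADER_TOKENS for t in tokens):
            continue
        if len(tokens) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least two columns")
        a, b = tokens[0], tokens[1]
        if score_column is not None:
            if len(tokens) <= score_column:
                raise ValueError(f"{path}:{lineno}: missing score column")
            try:
                score = float(tokens[score_column])
            except ValueError as err:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {tokens[score_column]!r}"
                ) from err
            if min_score is not None and score < min_score:
                continue
        else:
            score = None
        if a == b:
            n_self_loops += 1
            continue
        if score is not None:
            g.add_edge(a, b, score=score)
        else:
            g.add_edge(a, b)
    if n_self_loops:
        logger.info("dropped %d self-loop(s) from %s", n_self_loops, path)
    if g.number_of_nodes() == 0:
        logger.warning("edge list %s produced an empty graph", path)
    return g


def degree_hubs(g: nx.Graph, k: int) -> HubResult:
    """Top-k nodes by degree, ties broken alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > g.number_of_nodes():
        raise ValueError(
            f"k={k} exceeds node count {g.number_of_nodes()}"
        )
    ranking = sorted(g.degree(), key=lambda t: (-t[1], t[0]))
    return HubResult(
        ranking=[(str(n), int(d)) for n, d in ranking],
        hubs=[str(n) for n, _ in ranking[:k]],
        k=k,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
    )


def intersect_gene_list(
    genes: Sequence[str], reference_path: str | Path
) -> list[str]:
    """Members of ``genes`` present in the reference list (case-insensitive).

    Preserves the rank order of ``genes``; duplicates (in either input)
    yield no duplicate outputs.  An empty reference file is an error; an
    empty intersection is not.
    """
    if not genes:
        raise ValueError("empty gene list")
    reference = {g.lower() for g in read_gene_list(reference_path)}
    if not reference:
        raise ValueError(f"reference list {reference_path} is empty")
    seen: set[str] = set()
    out = []
    for g in genes:
        if g.lower() in reference and g.lower() not in seen:
            seen.add(g.lower())
            out.append(g)
    return out
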