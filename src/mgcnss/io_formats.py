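"""File formats and validated in-memory containers.

All dense matrices travel as TSV/CSV with the first row holding column
identifiers and the first column holding row identifiers (UTF-8, '.'
decimal separator).  Disease hierarchies travel as two-column
``child<TAB>parent`` edge lists.  Ranked prediction tables are written
long-format, one (miRNA, disease, score, rank) row per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DiseaseDAG",
    "FormatError",
    "read_association_matrix",
    "write_association_matrix",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_disease_dag",
    "write_score_table",
]

SYMMETRY_TOL = 1e-9


class FormatError(ValueError):
    """Raised when an input file or matrix violates a format contract."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


@dataclass
class AssociationMatrix:
    """Binary miRNA-disease association matrix A (Nm x Nd) with identifiers.

    ``values[i, j] == 1`` asserts an experimentally supported association
    between miRNA ``mirna_ids[i]`` and disease ``disease_ids[j]``.
    """

    values: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("association matrix must be 2-D")
        nm, nd = self.values.shape
        if nm < 2 or nd < 2:
            raise FormatError(f"need at least 2 miRNAs and 2 diseases, got {nm}x{nd}")
        bad = np.argwhere(~np.isin(self.values, (0.0, 1.0)))
        if bad.size:
            i, j = bad[0]
            raise FormatError(
                f"non-binary entry {self.values[i, j]!r} at row {i} "
                f"({self.mirna_ids[i]!r}), column {j} ({self.disease_ids[j]!r})"
            )
        self.mirna_ids = _check_unique(self.mirna_ids, "miRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        if len(self.mirna_ids) != nm or len(self.disease_ids) != nd:
            raise FormatError("identifier list lengths do not match matrix shape")

    @property
    def n_mirna(self) -> int:
        return self.values.shape[0]

    @property
    def n_disease(self) -> int:
        return self.values.shape[1]

    def positives(self) -> list[tuple[int, int]]:
        """Index pairs (i, j) with A[i, j] == 1, row-major order."""
        return [tuple(p) for p in np.argwhere(self.values == 1)]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal."""

    values: np.ndarray
    ids: list[str]
    kind: str = "integrated"

    _KINDS = ("functional", "semantic", "gip", "lncrna", "integrated")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self._KINDS:
            raise FormatError(f"unknown similarity kind {self.kind!r}")
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise FormatError("similarity matrix must be square")
        self.ids = _check_unique(self.ids, "similarity")
        if len(self.ids) != n:
            raise FormatError("identifier count does not match matrix size")
        if not np.allclose(self.values, self.values.T, atol=SYMMETRY_TOL, rtol=0):
            raise FormatError("similarity matrix is not symmetric within 1e-9")
        if not np.allclose(np.diag(self.values), 1.0, atol=SYMMETRY_TOL, rtol=0):
            raise FormatError("similarity matrix diagonal must be 1")
        if self.values.min() < -SYMMETRY_TOL or self.values.max() > 1 + SYMMETRY_TOL:
            raise FormatError("similarity entries must lie in [0, 1]")


@dataclass
class DiseaseDAG:
    """Disease hierarchy: nodes plus child->parent edges, guaranteed acyclic.

    Mirrors a MeSH-style hierarchy where each disease term points at its
    broader parent terms.  ``ancestors(d)`` returns the ancestor closure
    T(d) *including d itself*, the set the semantic-similarity recursion
    sums over.
    """

    nodes: list[str]
    parent_edges: list[tuple[str, str]]
    _graph: nx.DiGraph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.nodes = _check_unique(self.nodes, "DAG node")
        node_set = set(self.nodes)
        for c, p in self.parent_edges:
            if c not in node_set or p not in node_set:
                raise FormatError(f"edge ({c!r}, {p!r}) references undeclared node")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.parent_edges)  # edge child -> parent
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle is not None:
            path = " -> ".join(str(e[0]) for e in cycle) + f" -> {cycle[-1][1]}"
            raise FormatError(f"disease hierarchy contains a cycle: {path}")
        self._graph = g

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def parents(self, node: str) -> list[str]:
        return sorted(self._graph.successors(node))

    def children(self, node: str) -> list[str]:
        return sorted(self._graph.predecessors(node))

    def ancestors(self, node: str) -> set[str]:
        """T(node): all ancestors of ``node`` plus ``node`` itself."""
        if node not in self._graph:
            raise KeyError(f"unknown disease {node!r}")
        return nx.descendants(self._graph, node) | {node}


# ---------------------------------------------------------------------------
# readers / writers


def _read_frame(path: str | Path, dialect: str) -> pd.DataFrame:
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    return pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})


def read_association_matrix(path: str | Path, dialect: str = "tsv") -> AssociationMatrix:
    """Read a binary association matrix; header = disease ids, first column = miRNA ids."""
    df = _read_frame(path, dialect)
    return AssociationMatrix(
        values=df.to_numpy(dtype=float),
        mirna_ids=[str(i) for i in df.index],
        disease_ids=[str(c) for c in df.columns],
    )


def write_association_matrix(
    mat: AssociationMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    sep = "\t" if dialect == "tsv" else ","
    df = pd.DataFrame(
        mat.values.astype(int), index=mat.mirna_ids, columns=mat.disease_ids
    )
    df.to_csv(path, sep=sep)


def read_similarity_matrix(
    path: str | Path, kind: str = "integrated", dialect: str = "tsv"
) -> SimilarityMatrix:
    df = _read_frame(path, dialect)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise FormatError("similarity matrix row and column identifiers differ")
    return SimilarityMatrix(values=df.to_numpy(dtype=float), ids=ids, kind=kind)


def write_similarity_matrix(
    mat: SimilarityMatrix, path: str | Path, dialect: str = "tsv"
) -> None:
    sep = "\t" if dialect == "tsv" else ","
    pd.DataFrame(mat.values, index=mat.ids, columns=mat.ids).to_csv(
        path, sep=sep, float_format="%.17g"
    )


def read_disease_dag(path: str | Path) -> DiseaseDAG:
    """Read a ``child<TAB>parent`` edge list into a validated DAG."""
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # isolated node declaration
                parts = [parts[0], ""]
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'child<TAB>parent'")
            child, parent = parts[0].strip(), parts[1].strip()
            for n in (child, parent):
                if n and n not in seen:
                    seen.add(n)
                    nodes.append(n)
            if parent:
                edges.append((child, parent))
    return DiseaseDAG(nodes=nodes, parent_edges=edges)


def write_disease_dag(dag: DiseaseDAG, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        with_edge = {c for c, _ in dag.parent_edges}
        for c, p in dag.parent_edges:
            fh.write(f"{c}\t{p}\n")
        for n in dag.nodes:
            if n not in with_edge and not any(p == n for _, p in dag.parent_edges):
                fh.write(f"{n}\n")


def write_score_table(
    scores: np.ndarray,
    mirna_ids: Sequence[str],
    disease_ids: Sequence[str],
    path: str | Path,
) -> pd.DataFrame:
    """Write a long-format TSV of pair scores with within-disease ranks.

    Rank 1 is the highest score for that disease; ties are broken by
    miRNA identifier in lexicographic order so output is deterministic.
    Returns the frame that was written.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores contain NaN or infinite values")
    nm, nd = scores.shape
    if nm != len(mirna_ids) or nd != len(disease_ids):
        raise FormatError("score matrix shape does not match identifier lists")
    rows = []
    for j, dis in enumerate(disease_ids):
        order = sorted(range(nm), key=lambda i: (-scores[i, j], str(mirna_ids[i])))
        for rank, i in enumerate(order, 1):
            rows.append((str(mirna_ids[i]), str(dis), scores[i, j], rank))
    df = pd.DataFrame(rows, columns=["mirna", "disease", "score", "rank"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return df
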