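"""Regional adjacency structures and the intrinsic-CAR precision matrix.

Regions are identified by string labels; the order in which labels are
declared (in a ``.gra`` file or at construction) is the canonical index
order for every matrix built from the graph.  Nothing is ever re-sorted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RegionGraph",
    "PrecisionMatrix",
    "GraphParseError",
    "GraphValidationError",
    "read_gra",
    "write_gra",
    "read_edge_list",
    "icar_precision",
    "connected_components",
    "senegal_graph_2005",
    "senegal_graph_2010",
]


class GraphParseError(ValueError):
    """Raised when an adjacency file cannot be parsed."""


class GraphValidationError(ValueError):
    """Raised when an adjacency structure violates a graph invariant."""


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class RegionGraph:
    """An undirected region adjacency graph.

    Parameters
    ----------
    labels:
        Ordered, unique region identifiers.  This order is the canonical
        index order for all derived matrices.
    adjacency:
        Set of unordered label pairs (stored canonically sorted within
        each pair).  Symmetric by construction; no self-pairs.
    """

    labels: tuple[str, ...]
    adjacency: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise GraphValidationError(f"duplicate region labels: {dupes}")
        known = set(self.labels)
        canon = set()
        for a, b in self.adjacency:
            if a == b:
                raise GraphValidationError(f"self-pair ({a},{b}) not allowed")
            for lab in (a, b):
                if lab not in known:
                    raise GraphValidationError(f"adjacency references unknown label {lab!r}")
            canon.add(_canonical_pair(a, b))
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "adjacency", frozenset(canon))

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def neighbors(self, label: str) -> list[str]:
        """Neighbours of ``label`` in canonical label order."""
        nb = set()
        for a, b in self.adjacency:
            if a == label:
                nb.add(b)
            elif b == label:
                nb.add(a)
        return [l for l in self.labels if l in nb]

    def degree(self, label: str) -> int:
        return len(self.neighbors(label))

    def adjacency_matrix(self) -> np.ndarray:
        """Symmetric 0/1 adjacency matrix in canonical label order."""
        n = self.n_regions
        pos = {lab: i for i, lab in enumerate(self.labels)}
        A = np.zeros((n, n), dtype=np.int64)
        for a, b in self.adjacency:
            i, j = pos[a], pos[b]
            A[i, j] = A[j, i] = 1
        return A


@dataclass(frozen=True)
class PrecisionMatrix:
    """Intrinsic-CAR (graph Laplacian) precision matrix.

    ``entries`` holds degree on the diagonal, -1 for adjacent pairs and 0
    otherwise; ``rank`` equals ``order`` minus the number of connected
    components of the underlying graph.
    """

    order: int
    entries: np.ndarray
    rank: int

    def __post_init__(self) -> None:
        E = np.asarray(self.entries)
        if E.shape != (self.order, self.order):
            raise ValueError("entries shape inconsistent with order")
        if not np.array_equal(E, E.T):
            raise ValueError("precision matrix must be symmetric")


def connected_components(graph: RegionGraph) -> list[set[str]]:
    """Partition of the graph's labels into connected components.

    Components are returned in order of their first label's appearance in
    ``graph.labels``.
    """
    nb: dict[str, set[str]] = {lab: set() for lab in graph.labels}
    for a, b in graph.adjacency:
        nb[a].add(b)
        nb[b].add(a)
    seen: set[str] = set()
    comps: list[set[str]] = []
    for lab in graph.labels:
        if lab in seen:
            continue
        comp = {lab}
        stack = [lab]
        while stack:
            cur = stack.pop()
            for other in nb[cur]:
                if other not in comp:
                    comp.add(other)
                    stack.append(other)
        seen |= comp
        comps.append(comp)
    return comps


def icar_precision(graph: RegionGraph) -> PrecisionMatrix:
    """Degree-minus-adjacency precision matrix of the structured prior.

    Row sums are exactly zero (integer arithmetic).  Isolated regions are
    permitted: they contribute an all-zero row/column and are flagged via
    a warning because their structured effect is only identified through
    the per-component sum-to-zero constraint (degenerate: pinned to 0).
    """
    if graph.n_regions < 2:
        raise GraphValidationError("icar_precision requires at least 2 regions")
    A = graph.adjacency_matrix()
    deg = A.sum(axis=1)
    if np.any(deg == 0):
        isolated = [graph.labels[i] for i in np.flatnonzero(deg == 0)]
        warnings.warn(
            f"isolated regions {isolated}: structured effect pinned to 0 by "
            "its per-component sum-to-zero constraint",
            stacklevel=2,
        )
    Q = np.diag(deg) - A
    rank = graph.n_regions - len(connected_components(graph))
    return PrecisionMatrix(order=graph.n_regions, entries=Q, rank=rank)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_gra(path: str | Path) -> RegionGraph:
    """Read a BayesX-style ``.gra`` adjacency file.

    Layout: first non-comment token is the region count; then one block
    per region consisting of the region label line, the neighbour count
    line, and one line listing the neighbours.  Neighbour references may
    be labels or 1-based indices into declaration order; labels are
    canonical on write.  Symmetry is checked, not assumed.
    """
    path = Path(path)
    lines: list[tuple[int, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if stripped and not stripped.startswith("#"):
                lines.append((lineno, stripped))
    if not lines:
        raise GraphParseError(f"{path}: empty adjacency file")
    pos = 0

    def take(what: str) -> tuple[int, str]:
        nonlocal pos
        if pos >= len(lines):
            raise GraphParseError(f"{path}: unexpected end of file, expected {what}")
        line = lines[pos]
        pos += 1
        return line

    first_no, first = take("region count")
    try:
        n = int(first)
    except ValueError as exc:
        raise GraphParseError(
            f"{path}:{first_no}: first token must be the region count"
        ) from exc

    labels: list[str] = []
    blocks: list[list[tuple[int, str]]] = []
    for r in range(n):
        _, label = take("region label")
        cnt_no, cnt_tok = take(f"neighbour count for {label!r}")
        try:
            cnt = int(cnt_tok)
        except ValueError as exc:
            raise GraphParseError(
                f"{path}:{cnt_no}: neighbour count for {label!r} is not an integer"
            ) from exc
        if cnt < 0:
            raise GraphParseError(
                f"{path}:{cnt_no}: negative neighbour count for {label!r}")
        if cnt == 0:
            nbs: list[tuple[int, str]] = []
        else:
            nb_no, nb_line = take(f"neighbour line for {label!r}")
            toks = nb_line.split()
            if len(toks) != cnt:
                raise GraphParseError(
                    f"{path}:{nb_no}: region {label!r} declares {cnt} neighbours "
                    f"but lists {len(toks)}")
            nbs = [(nb_no, t) for t in toks]
        labels.append(label)
        blocks.append(nbs)
    if pos != len(lines):
        extra_no, extra = lines[pos]
        raise GraphParseError(f"{path}:{extra_no}: trailing content {extra!r}")
    if len(set(labels)) != len(labels):
        raise GraphParseError(f"{path}: duplicate region labels")

    directed: dict[str, set[str]] = {lab: set() for lab in labels}
    for label, nbs in zip(labels, blocks):
        for nb_no, tok in nbs:
            if tok in directed:
                ref = tok
            else:
                try:
                    idx = int(tok)
                except ValueError:
                    raise GraphParseError(
                        f"{path}:{nb_no}: unknown neighbour label {tok!r} for region {label!r}"
                    ) from None
                if not 1 <= idx <= len(labels):
                    raise GraphParseError(
                        f"{path}:{nb_no}: neighbour index {idx} out of range for region {label!r}"
                    )
                ref = labels[idx - 1]
            if ref == label:
                raise GraphParseError(f"{path}:{nb_no}: region {label!r} lists itself")
            directed[label].add(ref)

    for a in labels:
        for b in directed[a]:
            if a not in directed[b]:
                raise GraphValidationError(f"asymmetric pair ({a},{b})")
    adjacency = {_canonical_pair(a, b) for a in labels for b in directed[a]}
    return RegionGraph(labels=tuple(labels), adjacency=frozenset(adjacency))


def write_gra(graph: RegionGraph, path: str | Path) -> None:
    """Write ``graph`` as a ``.gra`` file re-readable by :func:`read_gra`."""
    path = Path(path)
    out = [str(graph.n_regions)]
    for lab in graph.labels:
        nbs = graph.neighbors(lab)
        out.append(lab)
        out.append(str(len(nbs)))
        if nbs:
            out.append(" ".join(nbs))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


def read_edge_list(path: str | Path, labels: list[str] | None = None) -> RegionGraph:
    """Read a two-column TSV edge list (one undirected edge per line).

    ``labels`` fixes the canonical region order (and may add isolated
    regions); otherwise labels appear in order of first mention.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(parts) != 2:
                raise GraphParseError(f"{path}:{lineno}: expected two columns")
            a, b = parts
            for lab in (a, b):
                if lab not in seen:
                    seen.append(lab)
            edges.append((a, b))
    use = tuple(labels) if labels is not None else tuple(seen)
    missing = [l for l in seen if l not in use]
    if missing:
        raise GraphValidationError(f"edge list references labels not in `labels`: {missing}")
    return RegionGraph(labels=use, adjacency=frozenset(_canonical_pair(a, b) for a, b in edges))


# ---------------------------------------------------------------------------
# Shipped fixture graphs (stylized adjacency, not authoritative geography)
# ---------------------------------------------------------------------------

_SENEGAL11_LABELS = (
    "Dakar", "Diourbel", "Fatick", "Kaolack", "Kolda", "Louga",
    "Matam", "SaintLouis", "Tambacounda", "Thies", "Ziguinchor",
)

_SENEGAL11_EDGES = (
    ("Dakar", "Thies"),
    ("Thies", "Diourbel"),
    ("Thies", "Louga"),
    ("Thies", "Fatick"),
    ("Diourbel", "Louga"),
    ("Diourbel", "Fatick"),
    ("Fatick", "Kaolack"),
    ("Kaolack", "Tambacounda"),
    ("Kaolack", "Kolda"),
    ("Louga", "SaintLouis"),
    ("Louga", "Matam"),
    ("Louga", "Tambacounda"),
    ("SaintLouis", "Matam"),
    ("Matam", "Tambacounda"),
    ("Tambacounda", "Kolda"),
    ("Kolda", "Ziguinchor"),
)


def senegal_graph_2005() -> RegionGraph:
    """Stylized 11-region wave-1 fixture graph (connected)."""
    return RegionGraph(
        labels=_SENEGAL11_LABELS,
        adjacency=frozenset(_canonical_pair(a, b) for a, b in _SENEGAL11_EDGES),
    )


#: wave-1 region -> wave-2 subdivisions, applied by ``split_region_map``
SENEGAL_SPLITS_2008 = {
    "Kaolack": ["Kaolack", "Kaffrine"],
    "Tambacounda": ["Tambacounda", "Kedougou"],
    "Kolda": ["Kolda", "Sedhiou"],
}


def senegal_graph_2010() -> RegionGraph:
    """Stylized 14-region wave-2 fixture graph (three two-way splits)."""
    from .synthetic import split_region_map

    graph2, _ = split_region_map(senegal_graph_2005(), SENEGAL_SPLITS_2008)
    return graph2
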