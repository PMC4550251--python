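"""Regular interaction graphs and per-vertex trait assignments.

The population lives on a simple, connected, k-regular graph on N vertices
(N·k even, k ≥ 3).  Vertices may carry baseline traits: a benefit ``b_i`` and
cost ``c_i`` of cooperating, and optionally an immutable genotype label
``u(i) ∈ {1, …, ℓ}``.  Graphs are generated with the uniform pairing model
(via :func:`networkx.random_regular_graph`) and regenerated until connected,
since the analytic layer assumes a single large component.

Vertices are indexed 0..N−1 internally; 1-based labels on input files are
accepted and preserved on output only insofar as the edge list is written
0-based (a header comment records the convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RegularGraph",
    "VertexTraits",
    "GaussianTraits",
    "TwoValuedCosts",
    "ConstantTraits",
    "ExplicitTraits",
    "GenotypeLabels",
    "random_regular_graph",
    "assign_traits",
]


class InvalidParameterError(ValueError):
    """A graph or trait parameter violates a structural constraint."""


@dataclass(frozen=True)
class RegularGraph:
    """A simple k-regular graph stored as an (N, k) neighbor table.

    ``neighbors[i]`` lists the k neighbors of vertex ``i`` in increasing
    order.  ``neighbor_pos[i, l]`` gives the slot of ``i`` in the neighbor
    list of ``neighbors[i, l]`` (used by the incremental payoff updates in
    the simulation kernels).
    """

    n_vertices: int
    degree: int
    neighbors: np.ndarray  # (N, k) int64

    def __post_init__(self) -> None:
        nbrs = np.asarray(self.neighbors, dtype=np.int64)
        object.__setattr__(self, "neighbors", nbrs)
        n, k = self.n_vertices, self.degree
        if nbrs.shape != (n, k):
            raise InvalidParameterError(
                f"neighbor table has shape {nbrs.shape}, expected {(n, k)}"
            )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(cls, n_vertices: int, edges: Sequence[tuple[int, int]]) -> "RegularGraph":
        adj: list[list[int]] = [[] for _ in range(n_vertices)]
        seen = set()
        for i, j in edges:
            if i == j:
                raise InvalidParameterError(f"self-loop at vertex {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise InvalidParameterError(f"multi-edge {key}")
            seen.add(key)
            adj[i].append(j)
            adj[j].append(i)
        degrees = {len(a) for a in adj}
        if len(degrees) != 1:
            raise InvalidParameterError(f"graph is not regular: degrees {sorted(degrees)}")
        k = degrees.pop()
        nbrs = np.array([sorted(a) for a in adj], dtype=np.int64)
        return cls(n_vertices, k, nbrs)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "RegularGraph":
        n = g.number_of_nodes()
        return cls.from_edges(n, list(g.edges()))

    # -- views -------------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_vertices))
        g.add_edges_from(self.edges())
        return g

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edges, each listed once with i < j."""
        out = []
        for i in range(self.n_vertices):
            for j in self.neighbors[i]:
                if i < j:
                    out.append((i, int(j)))
        return out

    def directed_edges(self) -> np.ndarray:
        """(N·k, 2) array of ordered pairs (i, j) with an edge i—j."""
        n, k = self.n_vertices, self.degree
        src = np.repeat(np.arange(n), k)
        return np.column_stack([src, self.neighbors.ravel()])

    def adjacency(self) -> np.ndarray:
        """Dense N×N 0/1 adjacency matrix w_ij."""
        w = np.zeros((self.n_vertices, self.n_vertices), dtype=np.int8)
        rows = np.repeat(np.arange(self.n_vertices), self.degree)
        w[rows, self.neighbors.ravel()] = 1
        return w

    @property
    def neighbor_pos(self) -> np.ndarray:
        pos = getattr(self, "_neighbor_pos", None)
        if pos is None:
            n, k = self.n_vertices, self.degree
            pos = np.empty((n, k), dtype=np.int64)
            for i in range(n):
                for l in range(k):
                    j = self.neighbors[i, l]
                    pos[i, l] = int(np.searchsorted(self.neighbors[j], i))
            object.__setattr__(self, "_neighbor_pos", pos)
        return pos

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def validate(self) -> None:
        """Assert symmetry, zero diagonal and exact regularity."""
        w = self.adjacency()
        if not np.array_equal(w, w.T):
            raise InvalidParameterError("adjacency is not symmetric")
        if np.any(np.diag(w) != 0):
            raise InvalidParameterError("adjacency has self-loops")
        if not np.all(w.sum(axis=1) == self.degree):
            raise InvalidParameterError("graph is not regular")

    # -- text I/O ----------------------------------------------------------

    def write_edgelist(self, path: Union[str, Path]) -> None:
        lines = [f"{i} {j}" for i, j in self.edges()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_edgelist(cls, path: Union[str, Path]) -> "RegularGraph":
        pairs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()
            pairs.append((int(a), int(b)))
        labels = sorted({v for e in pairs for v in e})
        # accept 1-based vertex labels on input
        offset = 1 if labels and labels[0] == 1 and len(labels) == labels[-1] else 0
        if offset:
            pairs = [(i - 1, j - 1) for i, j in pairs]
            labels = [v - 1 for v in labels]
        n = labels[-1] + 1 if labels else 0
        return cls.from_edges(n, pairs)


@dataclass(frozen=True)
class VertexTraits:
    """Per-vertex benefit/cost values and optional genotype labels.

    ``genotype`` uses 1-based labels forming a contiguous set {1, …, ℓ}.
    """

    benefit: Optional[np.ndarray] = None
    cost: Optional[np.ndarray] = None
    genotype: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        lengths = set()
        for name in ("benefit", "cost"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                object.__setattr__(self, name, arr)
                lengths.add(arr.shape[0])
        if self.genotype is not None:
            g = np.asarray(self.genotype, dtype=np.int64)
            object.__setattr__(self, "genotype", g)
            lengths.add(g.shape[0])
            labels = np.unique(g)
            if not np.array_equal(labels, np.arange(1, labels.size + 1)):
                raise InvalidParameterError(
                    f"genotype labels {labels.tolist()} are not a contiguous set 1..l"
                )
        if len(lengths) > 1:
            raise InvalidParameterError(f"trait arrays have mismatched lengths {sorted(lengths)}")

    @property
    def n_vertices(self) -> int:
        for arr in (self.benefit, self.cost, self.genotype):
            if arr is not None:
                return int(arr.shape[0])
        return 0

    @property
    def n_genotypes(self) -> int:
        if self.genotype is None:
            return 0
        return int(self.genotype.max())

    def write_tsv(self, path: Union[str, Path]) -> None:
        cols = ["vertex"]
        if self.benefit is not None:
            cols.append("b")
        if self.cost is not None:
            cols.append("c")
        if self.genotype is not None:
            cols.append("genotype")
        lines = ["\t".join(cols)]
        for i in range(self.n_vertices):
            row = [str(i)]
            if self.benefit is not None:
                row.append(repr(float(self.benefit[i])))
            if self.cost is not None:
                row.append(repr(float(self.cost[i])))
            if self.genotype is not None:
                row.append(str(int(self.genotype[i])))
            lines.append("\t".join(row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "VertexTraits":
        lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
        header = lines[0].split("\t")
        if header[0] != "vertex":
            raise InvalidParameterError("trait table must start with a 'vertex' column")
        rows = [l.split("\t") for l in lines[1:]]
        idx = np.array([int(r[0]) for r in rows])
        order = np.argsort(idx)
        if idx.min() == 1:  # 1-based labels accepted
            idx = idx - 1
        data: dict[str, np.ndarray] = {}
        for col, name in (("b", "benefit"), ("c", "cost"), ("genotype", "genotype")):
            if col in header:
                pos = header.index(col)
                vals = np.array([float(r[pos]) for r in rows])[order]
                data[name] = vals.astype(np.int64) if col == "genotype" else vals
        return cls(**data)


# ---------------------------------------------------------------------------
# trait-assignment schemes


@dataclass(frozen=True)
class GaussianTraits:
    """Independent normal draws for benefits and costs (no truncation)."""

    mean_b: float
    var_b: float
    mean_c: float
    var_c: float

    def __post_init__(self) -> None:
        if self.var_b < 0 or self.var_c < 0:
            raise InvalidParameterError("variance must be non-negative")

    def sample(self, n: int, rng: np.random.Generator) -> VertexTraits:
        b = rng.normal(self.mean_b, np.sqrt(self.var_b), size=n)
        c = rng.normal(self.mean_c, np.sqrt(self.var_c), size=n)
        if np.any(c < 0):
            logger.warning("Gaussian trait draw produced %d negative cost(s)", int((c < 0).sum()))
        if np.any(b < 0):
            logger.warning("Gaussian trait draw produced %d negative benefit(s)", int((b < 0).sum()))
        return VertexTraits(benefit=b, cost=c)


@dataclass(frozen=True)
class TwoValuedCosts:
    """Cost c1 on a uniformly chosen fraction q of vertices, c2 on the rest."""

    c1: float
    c2: float
    q: float = 0.5
    b: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise InvalidParameterError(f"fraction q={self.q} outside [0, 1]")

    def sample(self, n: int, rng: np.random.Generator) -> VertexTraits:
        n1 = int(round(self.q * n))
        c = np.full(n, self.c2, dtype=float)
        chosen = rng.choice(n, size=n1, replace=False)
        c[chosen] = self.c1
        return VertexTraits(benefit=np.full(n, self.b, dtype=float), cost=c)


@dataclass(frozen=True)
class ConstantTraits:
    b: float
    c: float

    def sample(self, n: int, rng: np.random.Generator) -> VertexTraits:
        return VertexTraits(
            benefit=np.full(n, self.b, dtype=float), cost=np.full(n, self.c, dtype=float)
        )


@dataclass(frozen=True)
class ExplicitTraits:
    """User-supplied arrays, validated against N at assignment time."""

    benefit: Optional[Sequence[float]] = None
    cost: Optional[Sequence[float]] = None
    genotype: Optional[Sequence[int]] = None

    def sample(self, n: int, rng: np.random.Generator) -> VertexTraits:
        traits = VertexTraits(
            benefit=None if self.benefit is None else np.asarray(self.benefit, dtype=float),
            cost=None if self.cost is None else np.asarray(self.cost, dtype=float),
            genotype=None if self.genotype is None else np.asarray(self.genotype, dtype=np.int64),
        )
        if traits.n_vertices != n:
            raise InvalidParameterError(
                f"explicit trait arrays have length {traits.n_vertices}, expected {n}"
            )
        return traits


@dataclass(frozen=True)
class GenotypeLabels:
    """Random genotype labels 1..l with the given proportions (rounded)."""

    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.proportions)
        if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise InvalidParameterError("genotype proportions must be non-negative and sum to 1")
        object.__setattr__(self, "proportions", p)

    def sample(self, n: int, rng: np.random.Generator) -> VertexTraits:
        counts = [int(round(q * n)) for q in self.proportions]
        counts[-1] = n - sum(counts[:-1])
        labels = np.concatenate(
            [np.full(m, u + 1, dtype=np.int64) for u, m in enumerate(counts)]
        )
        rng.shuffle(labels)
        return VertexTraits(genotype=labels)


TraitScheme = Union[GaussianTraits, TwoValuedCosts, ConstantTraits, ExplicitTraits, GenotypeLabels]


# ---------------------------------------------------------------------------
# operations


def random_regular_graph(n_vertices: int, degree: int, seed: int) -> RegularGraph:
    """Draw a simple connected k-regular graph on ``n_vertices`` vertices.

    Uses the uniform pairing model and regenerates (advancing the same seeded
    stream) until the draw is connected.  Identical arguments give identical
    graphs.
    """
    if degree < 3:
        raise InvalidParameterError(f"degree k={degree} < 3 (cycles are not supported)")
    if degree >= n_vertices:
        raise InvalidParameterError(f"degree k={degree} must be smaller than N={n_vertices}")
    if (n_vertices * degree) % 2 != 0:
        raise InvalidParameterError(
            f"N*k = {n_vertices}*{degree} is odd; a k-regular graph requires N*k even"
        )
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        child = int(rng.integers(0, 2**31 - 1))
        g = nx.random_regular_graph(degree, n_vertices, seed=child)
        if nx.is_connected(g):
            return RegularGraph.from_networkx(g)
    raise RuntimeError("failed to draw a connected regular graph in 1000 attempts")


def assign_traits(graph: RegularGraph, scheme: TraitScheme, seed: int) -> VertexTraits:
    """Assign per-vertex traits according to ``scheme``, deterministically in seed."""
    rng = np.random.default_rng(seed)
    return scheme.sample(graph.n_vertices, rng)
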