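"""Asymmetric payoff structures: per-edge bimatrix fields and their averages.

An *ecological field* assigns to every ordered pair of adjacent vertices
(i, j) an n×n payoff matrix a^{ij}: entry a^{ij}_{rs} is the payoff to the
player at vertex i using strategy r against the neighbor at vertex j using
strategy s.  Under weak selection the dynamics of the asymmetric process
reduce to those of the symmetric game with the edge-averaged payoff matrix

    ā_st = (1/kN) Σ_ij w_ij a^{ij}_st,

so this module provides the field constructors for the worked social
dilemmas (Donation and Snowdrift games), exact edge-averaging, a spatial
additivity test (a^{ij}_rs = x^i_rs + y^j_rs, which makes the average
independent of the network wiring), and the genotype-to-composite-strategy
expansion used with genetic update rules.

Strategy order for the two-strategy social dilemmas is always (C, D); the
row index is the focal player's strategy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr

from .networks import InvalidParameterError, RegularGraph, VertexTraits

logger = logging.getLogger(__name__)

__all__ = [
    "EcologicalField",
    "DenseField",
    "ConstantField",
    "DonationField",
    "SnowdriftField",
    "GenotypeField",
    "GenotypeGame",
    "MeanMatrix",
    "CompositeMatrix",
    "AdditiveDecomposition",
    "donation_field",
    "snowdrift_field",
    "mean_matrix",
    "additive_decomposition",
    "composite_matrix",
    "field_from_genotypes",
    "donation_genotype_game",
]


# ---------------------------------------------------------------------------
# fields


class EcologicalField:
    """Base class: ordered-pair payoff map over the edges of a graph."""

    n_strategies: int
    strategies: tuple[str, ...]

    def payoff_matrix(self, i: int, j: int) -> np.ndarray:
        """The n×n matrix a^{ij} for the ordered pair (i, j)."""
        raise NotImplementedError

    def payoff(self, i: int, j: int, r: int, s: int) -> float:
        return float(self.payoff_matrix(i, j)[r, s])

    def payoff_tensor(self, graph: RegularGraph) -> np.ndarray:
        """(N, k, n, n) array: entry [i, l] is a^{i, nbr(i, l)}.

        This dense materialization backs the simulation kernels and exact
        edge sums; re-querying it reproduces ``payoff`` exactly.
        """
        n, k, m = graph.n_vertices, graph.degree, self.n_strategies
        out = np.empty((n, k, m, m), dtype=np.float64)
        for i in range(n):
            for l in range(k):
                out[i, l] = self.payoff_matrix(i, int(graph.neighbors[i, l]))
        return out

    def materialize(self, graph: RegularGraph) -> "DenseField":
        return DenseField(graph, self.payoff_tensor(graph), self.strategies)

    def write_tsv(self, graph: RegularGraph, path: Union[str, Path]) -> None:
        """Directed-edge dump: columns i, j, r, s, payoff."""
        lines = ["i\tj\tr\ts\tpayoff"]
        for i in range(graph.n_vertices):
            for j in graph.neighbors[i]:
                m = self.payoff_matrix(i, int(j))
                for r in range(self.n_strategies):
                    for s in range(self.n_strategies):
                        lines.append(f"{i}\t{j}\t{r}\t{s}\t{float(m[r, s])!r}")
        Path(path).write_text("\n".join(lines) + "\n")


class DenseField(EcologicalField):
    """Field backed by an explicit (N, k, n, n) payoff tensor."""

    def __init__(
        self,
        graph: RegularGraph,
        tensor: np.ndarray,
        strategies: Sequence[str] | None = None,
    ) -> None:
        tensor = np.asarray(tensor, dtype=np.float64)
        n, k = graph.n_vertices, graph.degree
        if tensor.shape[:2] != (n, k) or tensor.shape[2] != tensor.shape[3]:
            raise InvalidParameterError(f"payoff tensor has shape {tensor.shape}")
        self._graph = graph
        self._tensor = tensor
        self.n_strategies = int(tensor.shape[2])
        self.strategies = tuple(strategies) if strategies else tuple(
            f"A{r + 1}" for r in range(self.n_strategies)
        )

    def payoff_matrix(self, i: int, j: int) -> np.ndarray:
        slots = np.flatnonzero(self._graph.neighbors[i] == j)
        if slots.size == 0:
            raise InvalidParameterError(f"({i}, {j}) is not an edge")
        return self._tensor[i, slots[0]]

    def payoff_tensor(self, graph: RegularGraph) -> np.ndarray:
        if graph is not self._graph and not np.array_equal(
            graph.neighbors, self._graph.neighbors
        ):
            raise InvalidParameterError("dense field queried on a different graph")
        return self._tensor


class ConstantField(EcologicalField):
    """The same matrix on every ordered pair (a symmetric game)."""

    def __init__(self, matrix: np.ndarray, strategies: Sequence[str] | None = None) -> None:
        self.matrix = np.asarray(matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise InvalidParameterError("constant field requires a square matrix")
        self.n_strategies = int(self.matrix.shape[0])
        self.strategies = tuple(strategies) if strategies else tuple(
            f"A{r + 1}" for r in range(self.n_strategies)
        )

    def payoff_matrix(self, i: int, j: int) -> np.ndarray:
        return self.matrix

    def payoff_tensor(self, graph: RegularGraph) -> np.ndarray:
        n, k = graph.n_vertices, graph.degree
        return np.broadcast_to(
            self.matrix, (n, k, self.n_strategies, self.n_strategies)
        ).copy()


class DonationField(EcologicalField):
    """Donation Game with per-vertex benefits and costs.

    A cooperator at vertex i pays c_i and donates b_i, so against vertex j:
    a_CC = b_j − c_i, a_CD = −c_i, a_DC = b_j, a_DD = 0.
    """

    strategies = ("C", "D")
    n_strategies = 2

    def __init__(self, benefit: np.ndarray, cost: np.ndarray) -> None:
        self.benefit = np.asarray(benefit, dtype=float)
        self.cost = np.asarray(cost, dtype=float)
        if self.benefit.shape != self.cost.shape:
            raise InvalidParameterError("benefit and cost arrays must have equal length")

    def payoff_matrix(self, i: int, j: int) -> np.ndarray:
        b_j, c_i = self.benefit[j], self.cost[i]
        return np.array([[b_j - c_i, -c_i], [b_j, 0.0]])

    def payoff_tensor(self, graph: RegularGraph) -> np.ndarray:
        n, k = graph.n_vertices, graph.degree
        if self.benefit.shape[0] != n:
            raise InvalidParameterError("field and graph vertex counts differ")
        bj = self.benefit[graph.neighbors]  # (N, k)
        ci = np.broadcast_to(self.cost[:, None], (n, k))
        out = np.zeros((n, k, 2, 2))
        out[..., 0, 0] = bj - ci
        out[..., 0, 1] = -ci
        out[..., 1, 0] = bj
        return out


class SnowdriftField(EcologicalField):
    """Snowdrift Game with location-dependent costs and a cost-sharing rule.

    Two cooperators split the cost of clearing the drift: the cooperator at
    i clears a fraction α_ij (α_ij + α_ji = 1), so a_CC^{ij} = b − α_ij c_i,
    a_CD = b − c_i, a_DC = b, a_DD = 0.  ``alpha_mode``:

    - ``"fair"``  — α_ij = c_j / (c_i + c_j), equalizing the shared burden
      (α_ij c_i = α_ji c_j); spatially non-additive when two adjacent
      vertices have distinct costs.
    - ``"half"``  — α_ij ≡ 1/2; spatially additive.
    - an (N, N) array of custom α values satisfying the complement rule.
    """

    strategies = ("C", "D")
    n_strategies = 2

    def __init__(
        self,
        benefit: Union[float, np.ndarray],
        cost: np.ndarray,
        alpha_mode: Union[str, np.ndarray] = "fair",
    ) -> None:
        self.cost = np.asarray(cost, dtype=float)
        n = self.cost.shape[0]
        b = np.asarray(benefit, dtype=float)
        if b.ndim == 0:
            b = np.full(n, float(b))
        if b.shape != (n,):
            raise InvalidParameterError("benefit must be scalar or length-N")
        if not np.allclose(b, b[0]):
            logger.warning(
                "snowdrift field with heterogeneous benefits; the standard model "
                "assumes a common benefit of passing"
            )
        self.benefit = b
        if isinstance(alpha_mode, str):
            if alpha_mode not in ("fair", "half"):
                raise InvalidParameterError(f"unknown alpha_mode {alpha_mode!r}")
            self.alpha_mode = alpha_mode
            self._alpha_table = None
        else:
            table = np.asarray(alpha_mode, dtype=float)
            if table.shape != (n, n):
                raise InvalidParameterError("custom alpha table must be N x N")
            if np.any(table < 0) or np.any(table > 1):
                raise InvalidParameterError("alpha values must lie in [0, 1]")
            if not np.allclose(table + table.T, 1.0, atol=1e-12):
                raise InvalidParameterError("custom alpha table must satisfy a_ij + a_ji = 1")
            self.alpha_mode = "custom"
            self._alpha_table = table

    def alpha(self, i: int, j: int) -> float:
        if self.alpha_mode == "half":
            return 0.5
        if self.alpha_mode == "custom":
            return float(self._alpha_table[i, j])
        denom = self.cost[i] + self.cost[j]
        if denom == 0:
            raise InvalidParameterError(
                f"fair cost sharing undefined on edge ({i}, {j}): c_i + c_j = 0"
            )
        return float(self.cost[j] / denom)

    def payoff_matrix(self, i: int, j: int) -> np.ndarray:
        b, c_i = self.benefit[i], self.cost[i]
        return np.array([[b - self.alpha(i, j) * c_i, b - c_i], [b, 0.0]])

    def payoff_tensor(self, graph: RegularGraph) -> np.ndarray:
        if self.cost.shape[0] != graph.n_vertices:
            raise InvalidParameterError("field and graph vertex counts differ")
        return super().payoff_tensor(graph)


class GenotypeField(EcologicalField):
    """Ecological field induced by immutable genotypes: a^{ij} = M^{u(i)u(j)}.

    Only meaningful with cultural update rules, under which the genotype at
    each vertex never changes.
    """

    def __init__(self, game: "GenotypeGame", genotype: np.ndarray) -> None:
        self.game = game
        self.genotype = np.asarray(genotype, dtype=np.int64)
        if self.genotype.min() < 1 or self.genotype.max() > game.n_genotypes:
            raise InvalidParameterError(
                f"genotype labels must lie in 1..{game.n_genotypes}"
            )
        self.n_strategies = game.n_strategies
        self.strategies = game.strategies

    def payoff_matrix(self, i: int, j: int) -> np.ndarray:
        return self.game.matrix(int(self.genotype[i]), int(self.genotype[j]))


# ---------------------------------------------------------------------------
# genotype games and composite matrices


@dataclass(frozen=True)
class GenotypeGame:
    """Payoff matrices M^{uv} indexed by ordered genotype pairs.

    ``payoffs[u-1, v-1, r, s]`` is the payoff to a genotype-u player using
    strategy r against a genotype-v player using strategy s.
    """

    payoffs: np.ndarray  # (l, l, n, n)
    strategies: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.payoffs, dtype=np.float64)
        if p.ndim != 4 or p.shape[0] != p.shape[1] or p.shape[2] != p.shape[3]:
            raise InvalidParameterError(f"genotype payoff array has shape {p.shape}")
        object.__setattr__(self, "payoffs", p)
        if not self.strategies:
            object.__setattr__(
                self, "strategies", tuple(f"A{r + 1}" for r in range(p.shape[2]))
            )

    @property
    def n_genotypes(self) -> int:
        return int(self.payoffs.shape[0])

    @property
    def n_strategies(self) -> int:
        return int(self.payoffs.shape[2])

    def matrix(self, u: int, v: int) -> np.ndarray:
        return self.payoffs[u - 1, v - 1]


def donation_genotype_game(benefit: Sequence[float], cost: Sequence[float]) -> GenotypeGame:
    """Donation Game where a genotype-u cooperator donates b_u at cost c_u."""
    b = np.asarray(benefit, dtype=float)
    c = np.asarray(cost, dtype=float)
    if b.shape != c.shape:
        raise InvalidParameterError("benefit and cost must have one value per genotype")
    l = b.shape[0]
    p = np.zeros((l, l, 2, 2))
    for u in range(l):
        for v in range(l):
            p[u, v] = [[b[v] - c[u], -c[u]], [b[v], 0.0]]
    return GenotypeGame(p, strategies=("C", "D"))


@dataclass(frozen=True)
class CompositeMatrix:
    """Symmetric-game matrix over composite (genotype, strategy) pairs."""

    values: np.ndarray
    labels: tuple[str, ...]
    groups: tuple[tuple[tuple[int, int], ...], ...]  # merged (u, r) members per row

    def write_tsv(self, path: Union[str, Path]) -> None:
        _write_matrix_tsv(path, self.values, self.labels)

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "CompositeMatrix":
        values, labels = _read_matrix_tsv(path)
        groups = tuple((() if "," in l else ((0, i),)) for i, l in enumerate(labels))
        return cls(values, labels, groups)


def composite_matrix(g: GenotypeGame, merge_duplicates: bool = False) -> CompositeMatrix:
    """Expand genotype asymmetry into a larger symmetric game.

    Composite strategy (u, A_r) plays against (v, A_s) for a^{uv}_{rs}.
    With ``merge_duplicates``, composite strategies whose payoff row and
    column patterns are exactly identical are collapsed (for the Donation
    Game all (u, D) collapse into a single D, leaving ℓ+1 strategies).
    """
    l, n = g.n_genotypes, g.n_strategies
    pairs = [(u, r) for u in range(1, l + 1) for r in range(n)]
    m = len(pairs)
    full = np.empty((m, m))
    for a, (u, r) in enumerate(pairs):
        for bb, (v, s) in enumerate(pairs):
            full[a, bb] = g.payoffs[u - 1, v - 1, r, s]

    def label_of(pair: tuple[int, int]) -> str:
        return f"({pair[0]},{g.strategies[pair[1]]})"

    if not merge_duplicates:
        return CompositeMatrix(
            full, tuple(label_of(p) for p in pairs), tuple((p,) for p in pairs)
        )

    # group indices by exact (row, column) payoff pattern
    groups: list[list[int]] = []
    for a in range(m):
        for grp in groups:
            b0 = grp[0]
            if np.array_equal(full[a], full[b0]) and np.array_equal(full[:, a], full[:, b0]):
                grp.append(a)
                break
        else:
            groups.append([a])
    reps = [grp[0] for grp in groups]
    merged = full[np.ix_(reps, reps)]
    labels = []
    for grp in groups:
        members = [pairs[a] for a in grp]
        strategies_in = {r for _, r in members}
        if len(grp) == 1:
            labels.append(label_of(members[0]))
        elif len(strategies_in) == 1:
            labels.append(g.strategies[strategies_in.pop()])
        else:
            labels.append("|".join(label_of(p) for p in members))
    return CompositeMatrix(
        merged, tuple(labels), tuple(tuple(pairs[a] for a in grp) for grp in groups)
    )


# ---------------------------------------------------------------------------
# mean matrix


@dataclass(frozen=True)
class MeanMatrix:
    """Edge-averaged symmetric payoff matrix ā_st with provenance (k, N)."""

    values: np.ndarray
    strategies: tuple[str, ...]
    degree: int
    n_vertices: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    @property
    def n_strategies(self) -> int:
        return int(self.values.shape[0])

    def write_tsv(self, path: Union[str, Path]) -> None:
        _write_matrix_tsv(path, self.values, self.strategies,
                          comment=f"k={self.degree} N={self.n_vertices}")

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "MeanMatrix":
        values, labels, meta = _read_matrix_tsv(path, with_meta=True)
        return cls(values, labels, int(meta.get("k", 0)), int(meta.get("N", 0)))


def _write_matrix_tsv(path, values, labels, comment: str | None = None) -> None:
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append("\t".join(labels))
    for row in values:
        lines.append("\t".join(repr(float(x)) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _read_matrix_tsv(path, with_meta: bool = False):
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    meta = {}
    if lines[0].startswith("#"):
        for tok in lines[0][1:].split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                meta[key] = val
        lines = lines[1:]
    labels = tuple(lines[0].split("\t"))
    values = np.array([[float(x) for x in l.split("\t")] for l in lines[1:]])
    if with_meta:
        return values, labels, meta
    return values, labels


def mean_matrix(field: EcologicalField, graph: RegularGraph) -> MeanMatrix:
    """Exact edge average ā_st = (1/kN) Σ_ij w_ij a^{ij}_st (direct summation)."""
    tensor = field.payoff_tensor(graph)
    if tensor.shape[0] != graph.n_vertices:
        raise InvalidParameterError("field and graph vertex counts differ")
    values = tensor.sum(axis=(0, 1)) / (graph.degree * graph.n_vertices)
    return MeanMatrix(values, field.strategies, graph.degree, graph.n_vertices)


# ---------------------------------------------------------------------------
# spatial additivity


@dataclass(frozen=True)
class AdditiveDecomposition:
    """Per-vertex decomposition a^{ij}_rs ≈ x^i_rs + y^j_rs.

    The split is identifiable only up to a constant per entry (r, s); the
    gauge Σ_j y^j_rs = 0 makes it unique.  ``residual`` is the maximum
    absolute reconstruction error over directed edges and entries.
    """

    x: np.ndarray  # (N, n, n)
    y: np.ndarray  # (N, n, n)
    residual: float
    tolerance: float

    @property
    def is_additive(self) -> bool:
        return self.residual <= self.tolerance


def additive_decomposition(
    field: EcologicalField, graph: RegularGraph, tolerance: float = 1e-9
) -> AdditiveDecomposition:
    """Least-squares fit of the spatially additive model on each entry (r, s)."""
    n, k, m = graph.n_vertices, graph.degree, field.n_strategies
    tensor = field.payoff_tensor(graph)
    edges = graph.directed_edges()  # (N*k, 2)
    n_edges = edges.shape[0]

    # design matrix: one row per directed edge selecting x_i and y_j,
    # plus a gauge row sum_j y_j = 0 (appended with weight 1)
    rows = np.repeat(np.arange(n_edges), 2)
    cols = np.empty(2 * n_edges, dtype=np.int64)
    cols[0::2] = edges[:, 0]
    cols[1::2] = n + edges[:, 1]
    data = np.ones(2 * n_edges)
    gauge_rows = np.full(n, n_edges)
    gauge_cols = n + np.arange(n)
    design = sp.csr_matrix(
        (
            np.concatenate([data, np.ones(n)]),
            (np.concatenate([rows, gauge_rows]), np.concatenate([cols, gauge_cols])),
        ),
        shape=(n_edges + 1, 2 * n),
    )

    x = np.zeros((n, m, m))
    y = np.zeros((n, m, m))
    residual = 0.0
    flat = tensor.reshape(n_edges, m, m)
    for r in range(m):
        for s in range(m):
            rhs = np.concatenate([flat[:, r, s], [0.0]])
            sol = lsqr(design, rhs, atol=1e-14, btol=1e-14, iter_lim=10000)[0]
            x[:, r, s] = sol[:n]
            y[:, r, s] = sol[n:]
            recon = sol[edges[:, 0]] + sol[n + edges[:, 1]]
            residual = max(residual, float(np.max(np.abs(recon - flat[:, r, s]))))
    return AdditiveDecomposition(x, y, residual, tolerance)


# ---------------------------------------------------------------------------
# constructors from traits


def donation_field(traits: VertexTraits, graph: RegularGraph) -> DonationField:
    """Per-edge Donation Game from vertex benefit/cost traits."""
    if traits.benefit is None or traits.cost is None:
        raise InvalidParameterError("donation field requires benefit and cost traits")
    if traits.n_vertices != graph.n_vertices:
        raise InvalidParameterError("trait arrays do not match the graph size")
    return DonationField(traits.benefit, traits.cost)


def snowdrift_field(
    traits: VertexTraits,
    graph: RegularGraph,
    alpha_mode: Union[str, np.ndarray] = "fair",
) -> SnowdriftField:
    """Per-edge Snowdrift Game from vertex costs and a cost-sharing rule."""
    if traits.benefit is None or traits.cost is None:
        raise InvalidParameterError("snowdrift field requires benefit and cost traits")
    if traits.n_vertices != graph.n_vertices:
        raise InvalidParameterError("trait arrays do not match the graph size")
    fld = SnowdriftField(traits.benefit, traits.cost, alpha_mode)
    if fld.alpha_mode == "fair":
        for i, j in graph.edges():
            if traits.cost[i] + traits.cost[j] == 0:
                raise InvalidParameterError(
                    f"fair cost sharing undefined on edge ({i}, {j}): c_i + c_j = 0"
                )
    return fld


def field_from_genotypes(
    g: GenotypeGame, traits: VertexTraits, graph: RegularGraph
) -> GenotypeField:
    """Ecological field M^{ij} = M^{u(i)u(j)} (cultural update rules only)."""
    if traits.genotype is None:
        raise InvalidParameterError("traits carry no genotype labels")
    if traits.n_vertices != graph.n_vertices:
        raise InvalidParameterError("trait arrays do not match the graph size")
    return GenotypeField(g, traits.genotype)
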