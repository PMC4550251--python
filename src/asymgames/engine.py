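"""Stochastic simulation of the four update processes on a graph.

Each elementary update selects players according to one of four rules and
changes at most one vertex's strategy:

- death-birth (DB): a uniformly chosen player dies; its neighbors compete
  to fill the vacancy with probability proportional to fitness.
- birth-death (BD): a player reproduces with probability proportional to
  fitness over the whole population; the offspring replaces a uniformly
  chosen neighbor.
- imitation (IM): a uniformly chosen player either keeps its strategy or
  adopts a neighbor's, with probabilities proportional to fitness over the
  k+1 candidates.
- pairwise comparison (PC): a uniform focal player compares itself with a
  uniform neighbor and adopts the neighbor's strategy with the Fermi
  probability 1/(1 + e^{β(π_f − π_m)}).

Payoff π is the realized sum over actual neighbors, and fitness is
f_β(π) = e^{βπ}.  DB and BD are *genetic* rules (offspring inherit the
parent's genotype along with its strategy); IM and PC are *cultural*
(genotypes are immutable, only strategies change).

Besides sampling, the module provides an exact one-step expectation by
exhaustive enumeration of all focal/replacement outcomes, fixation runs,
and the profile protocol that records per-sweep changes in cooperator
frequency binned by the starting frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import _kernels
from .games import EcologicalField
from .networks import InvalidParameterError, RegularGraph

__all__ = [
    "UpdateRule",
    "DEATH_BIRTH",
    "BIRTH_DEATH",
    "IMITATION",
    "PAIRWISE_COMPARISON",
    "PopulationState",
    "DeltaProfile",
    "FixationResult",
    "fitness",
    "total_payoff",
    "step",
    "exact_step_expectation",
    "sample_step_deltas",
    "run_to_fixation",
    "delta_profile",
]


@dataclass(frozen=True)
class UpdateRule:
    """One of the four update processes; the transmission class is fixed by name."""

    name: str

    _CANONICAL = {
        "death-birth": "death-birth", "db": "death-birth",
        "birth-death": "birth-death", "bd": "birth-death",
        "imitation": "imitation", "im": "imitation",
        "pairwise-comparison": "pairwise-comparison", "pc": "pairwise-comparison",
    }
    _KERNEL_ID = {
        "death-birth": _kernels.DEATH_BIRTH,
        "birth-death": _kernels.BIRTH_DEATH,
        "imitation": _kernels.IMITATION,
        "pairwise-comparison": _kernels.PAIRWISE_COMPARISON,
    }

    def __post_init__(self) -> None:
        canon = self._CANONICAL.get(self.name.lower())
        if canon is None:
            raise InvalidParameterError(f"unknown update rule {self.name!r}")
        object.__setattr__(self, "name", canon)

    @property
    def transmission(self) -> str:
        return "genetic" if self.name in ("death-birth", "birth-death") else "cultural"

    @property
    def kernel_id(self) -> int:
        return self._KERNEL_ID[self.name]


DEATH_BIRTH = UpdateRule("death-birth")
BIRTH_DEATH = UpdateRule("birth-death")
IMITATION = UpdateRule("imitation")
PAIRWISE_COMPARISON = UpdateRule("pairwise-comparison")


@dataclass(frozen=True)
class PopulationState:
    """Per-vertex strategies (and optional genotypes) with state statistics."""

    strategies: np.ndarray
    n_strategies: int
    genotype: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        s = np.asarray(self.strategies, dtype=np.int64)
        object.__setattr__(self, "strategies", s)
        if s.min(initial=0) < 0 or s.max(initial=0) >= self.n_strategies:
            raise InvalidParameterError("strategy index out of range")
        if self.genotype is not None:
            g = np.asarray(self.genotype, dtype=np.int64)
            if g.shape != s.shape:
                raise InvalidParameterError("genotype array does not match strategies")
            object.__setattr__(self, "genotype", g)

    @property
    def n_vertices(self) -> int:
        return int(self.strategies.shape[0])

    def frequencies(self) -> np.ndarray:
        """Strategy frequencies p_r."""
        return np.bincount(self.strategies, minlength=self.n_strategies) / self.n_vertices

    def pair_frequencies(self, graph: RegularGraph) -> np.ndarray:
        """p_rs over directed edges; symmetric on undirected graphs."""
        n = self.n_strategies
        sr = self.strategies[:, None].repeat(graph.degree, axis=1)
        ss = self.strategies[graph.neighbors]
        out = np.zeros((n, n))
        np.add.at(out, (sr.ravel(), ss.ravel()), 1.0)
        return out / (graph.degree * graph.n_vertices)

    def conditional_frequencies(self, graph: RegularGraph) -> np.ndarray:
        """q_{s|r} = p_rs / p_r, rows r; rows with p_r = 0 are zero."""
        p = self.frequencies()
        prs = self.pair_frequencies(graph)
        q = np.zeros_like(prs)
        mask = p > 0
        q[mask] = prs[mask] / p[mask, None]
        return q

    def is_monomorphic(self) -> bool:
        return bool(np.all(self.strategies == self.strategies[0]))


def fitness(payoff: Union[float, np.ndarray], beta: float) -> Union[float, np.ndarray]:
    """Exponential payoff-to-fitness map f_β(π) = e^{βπ} (strictly positive)."""
    return np.exp(beta * np.asarray(payoff, dtype=float))


def total_payoff(
    state: PopulationState, field: EcologicalField, graph: RegularGraph, vertex: int
) -> float:
    """Realized payoff of ``vertex``: Σ_{j ~ i} a^{ij}(s_i, s_j)."""
    s = state.strategies
    acc = 0.0
    for j in graph.neighbors[vertex]:
        acc += field.payoff(vertex, int(j), int(s[vertex]), int(s[j]))
    return acc


def _all_payoffs(state: PopulationState, tensor: np.ndarray, graph: RegularGraph) -> np.ndarray:
    s = state.strategies
    sj = s[graph.neighbors]  # (N, k)
    n, k = graph.n_vertices, graph.degree
    rows = np.repeat(np.arange(n), k)
    slots = np.tile(np.arange(k), n)
    return tensor[rows, slots, s[rows], sj.ravel()].reshape(n, k).sum(axis=1)


# ---------------------------------------------------------------------------
# single steps


def step(
    state: PopulationState,
    rule: UpdateRule,
    field: EcologicalField,
    graph: RegularGraph,
    beta: float,
    rng: np.random.Generator,
) -> PopulationState:
    """One elementary update (pure-python reference implementation).

    Genetic rules copy the parent's genotype and strategy onto the replaced
    vertex; cultural rules copy the strategy only.
    """
    tensor = field.payoff_tensor(graph)
    pi = _all_payoffs(state, tensor, graph)
    s = state.strategies.copy()
    g = None if state.genotype is None else state.genotype.copy()
    n, k = graph.n_vertices, graph.degree

    def weighted_choice(indices: np.ndarray) -> int:
        w = np.exp(beta * pi[indices])
        return int(indices[np.searchsorted(np.cumsum(w), rng.random() * w.sum())])

    if rule.name == "death-birth":
        i = int(rng.integers(n))
        parent = weighted_choice(graph.neighbors[i])
        target = i
    elif rule.name == "birth-death":
        parent = weighted_choice(np.arange(n))
        target = int(graph.neighbors[parent, rng.integers(k)])
    elif rule.name == "imitation":
        i = int(rng.integers(n))
        candidates = np.concatenate([[i], graph.neighbors[i]])
        parent = weighted_choice(candidates)
        target = i
    else:  # pairwise comparison
        i = int(rng.integers(n))
        parent = int(graph.neighbors[i, rng.integers(k)])
        p_adopt = 1.0 / (1.0 + np.exp(beta * (pi[i] - pi[parent])))
        target = i
        if rng.random() >= p_adopt:
            parent = i

    s[target] = s[parent]
    if g is not None and rule.transmission == "genetic":
        g[target] = g[parent]
    return PopulationState(s, state.n_strategies, genotype=g)


def exact_step_expectation(
    state: PopulationState,
    rule: UpdateRule,
    field: EcologicalField,
    graph: RegularGraph,
    beta: float,
) -> np.ndarray:
    """Exact E[Δp_r] for one elementary update, by exhaustive enumeration.

    Sums over every focal choice and every replacement/adoption outcome with
    its exact probability; no sampling.
    """
    tensor = field.payoff_tensor(graph)
    pi = _all_payoffs(state, tensor, graph)
    s = state.strategies
    n, k = graph.n_vertices, graph.degree
    m = state.n_strategies
    out = np.zeros(m)

    def onehot(idx: int) -> np.ndarray:
        v = np.zeros(m)
        v[s[idx]] = 1.0
        return v

    if rule.name == "death-birth":
        for i in range(n):
            w = np.exp(beta * pi[graph.neighbors[i]])
            w /= w.sum()
            for l in range(k):
                j = int(graph.neighbors[i, l])
                out += (1.0 / n) * w[l] * (onehot(j) - onehot(i)) / n
    elif rule.name == "birth-death":
        f = np.exp(beta * pi)
        f /= f.sum()
        for i in range(n):
            for l in range(k):
                j = int(graph.neighbors[i, l])
                out += f[i] * (1.0 / k) * (onehot(i) - onehot(j)) / n
    elif rule.name == "imitation":
        for i in range(n):
            cand = np.concatenate([[i], graph.neighbors[i]])
            w = np.exp(beta * pi[cand])
            w /= w.sum()
            for l, j in enumerate(cand):
                out += (1.0 / n) * w[l] * (onehot(int(j)) - onehot(i)) / n
    else:  # pairwise comparison
        for i in range(n):
            for l in range(k):
                j = int(graph.neighbors[i, l])
                p_adopt = 1.0 / (1.0 + np.exp(beta * (pi[i] - pi[j])))
                out += (1.0 / n) * (1.0 / k) * p_adopt * (onehot(j) - onehot(i)) / n
    return out


def sample_step_deltas(
    state: PopulationState,
    rule: UpdateRule,
    field: EcologicalField,
    graph: RegularGraph,
    beta: float,
    n_samples: int,
    seed: int,
    strategy: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo (mean, standard error) of the one-step change in p_strategy."""
    tensor = field.payoff_tensor(graph)
    pi = _all_payoffs(state, tensor, graph)
    total, total_sq = _kernels.sample_step_deltas(
        state.strategies, pi, graph.neighbors, graph.neighbor_pos, tensor,
        rule.kernel_id, float(beta), int(strategy), int(n_samples), int(seed) % (2**31),
    )
    mean = total / n_samples
    var = max(total_sq / n_samples - mean**2, 0.0)
    return mean, float(np.sqrt(var / n_samples))


# ---------------------------------------------------------------------------
# fixation runs


@dataclass(frozen=True)
class FixationResult:
    absorbed: Optional[int]  # fixated strategy index, or None
    n_updates: int
    status: str  # "fixated" | "max_updates"
    trajectory: Optional[np.ndarray] = None  # p_C once per sweep, if recorded

    def write_trajectory_tsv(self, path: Union[str, Path]) -> None:
        if self.trajectory is None:
            raise InvalidParameterError("no trajectory was recorded")
        lines = ["sweep\tp_C"] + [
            f"{t}\t{float(p)!r}" for t, p in enumerate(self.trajectory)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def run_to_fixation(
    initial: PopulationState,
    rule: UpdateRule,
    field: EcologicalField,
    graph: RegularGraph,
    beta: float,
    rng: Union[np.random.Generator, int],
    max_updates: Optional[int] = None,
    record_trajectory: bool = False,
) -> FixationResult:
    """Run until the population is monomorphic or ``max_updates`` is reached.

    Reaching the cap is reported via ``status="max_updates"``, not raised.
    The fast path does not track genotype labels; they do not influence the
    payoffs of an ecological field.
    """
    if max_updates is None:
        max_updates = 10_000 * graph.n_vertices
    gen = np.random.default_rng(rng) if isinstance(rng, int) else rng
    seed = int(gen.integers(2**31))
    tensor = field.payoff_tensor(graph)
    s = initial.strategies.copy()
    n_sweeps = max_updates // graph.n_vertices + 2
    traj = np.full(min(n_sweeps, 1_000_000), np.nan) if record_trajectory else np.empty(0)
    absorbed, n_updates = _kernels.run_to_fixation(
        s, graph.neighbors, graph.neighbor_pos, tensor,
        rule.kernel_id, float(beta), int(max_updates), seed, traj, record_trajectory,
    )
    trajectory = None
    if record_trajectory:
        trajectory = traj[~np.isnan(traj)]
    if absorbed < 0:
        return FixationResult(None, n_updates, "max_updates", trajectory)
    return FixationResult(int(absorbed), n_updates, "fixated", trajectory)


# ---------------------------------------------------------------------------
# profile protocol


@dataclass(frozen=True)
class DeltaProfile:
    """Mean per-sweep change in cooperator frequency, binned by p_C.

    ``p`` runs over the achievable frequencies {0, 1/N, …, 1}; the boundary
    bins are absorbing and identically zero.
    """

    p: np.ndarray
    mean_delta: np.ndarray
    stderr: np.ndarray
    count: np.ndarray
    status: str = "ok"  # "ok" | "partial"
    n_cycles: int = 0
    n_absorbed_c: int = 0
    n_absorbed_d: int = 0

    @property
    def n_vertices(self) -> int:
        return int(self.p.shape[0]) - 1

    def write_tsv(self, path: Union[str, Path]) -> None:
        lines = ["p_C\tmean_delta\tstderr\tn_samples"]
        for p, md, se, c in zip(self.p, self.mean_delta, self.stderr, self.count):
            lines.append(f"{float(p)!r}\t{float(md)!r}\t{float(se)!r}\t{int(c)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "DeltaProfile":
        lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
        rows = [l.split("\t") for l in lines[1:]]
        return cls(
            p=np.array([float(r[0]) for r in rows]),
            mean_delta=np.array([float(r[1]) for r in rows]),
            stderr=np.array([float(r[2]) for r in rows]),
            count=np.array([int(r[3]) for r in rows]),
        )


def delta_profile(
    field: EcologicalField,
    graph: RegularGraph,
    rule: UpdateRule,
    beta: float,
    min_samples_per_bin: int,
    rng: Union[np.random.Generator, int],
    cycle_budget: int = 1_000_000,
    max_updates_per_cycle: Optional[int] = None,
    target_bins: Optional[np.ndarray] = None,
) -> DeltaProfile:
    """The figure protocol: repeated fixation cycles from random densities.

    Each cycle draws a density d ~ U[0, 1], seeds every vertex with strategy
    C (index 0) independently with probability d, runs the process to
    fixation, and records the change in p_C over every sweep of N updates,
    keyed by the starting frequency.  Cycles stop once every target interior
    bin has at least ``min_samples_per_bin`` samples; if the cycle budget
    runs out first, a partial profile (status="partial") is returned.
    """
    if field.n_strategies != 2:
        raise InvalidParameterError("the profile protocol requires a 2-strategy game")
    if max_updates_per_cycle is None:
        max_updates_per_cycle = 10_000 * graph.n_vertices
    gen = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n = graph.n_vertices
    tensor = field.payoff_tensor(graph)
    if target_bins is None:
        target_bins = np.arange(1, n)
    sum_d = np.zeros(n + 1)
    sumsq_d = np.zeros(n + 1)
    count_d = np.zeros(n + 1, dtype=np.int64)
    n_cycles = 0
    absorbed_c = absorbed_d = 0
    status = "partial"
    while n_cycles < cycle_budget:
        d = gen.random()
        s = (gen.random(n) >= d).astype(np.int64)  # strategy 0 = C w.p. d
        seed = int(gen.integers(2**31))
        absorbed, _ = _kernels.run_cycle(
            s, graph.neighbors, graph.neighbor_pos, tensor,
            rule.kernel_id, float(beta), int(max_updates_per_cycle), seed,
            sum_d, sumsq_d, count_d,
        )
        n_cycles += 1
        if absorbed == 0:
            absorbed_c += 1
        elif absorbed == 1:
            absorbed_d += 1
        if n_cycles % 32 == 0 or n_cycles == cycle_budget:
            if count_d[target_bins].min() >= min_samples_per_bin:
                status = "ok"
                break
    else:
        pass
    if count_d[target_bins].min() >= min_samples_per_bin:
        status = "ok"

    mean = np.zeros(n + 1)
    stderr = np.zeros(n + 1)
    pos = count_d > 0
    mean[pos] = sum_d[pos] / count_d[pos]
    var = np.zeros(n + 1)
    var[pos] = np.maximum(sumsq_d[pos] / count_d[pos] - mean[pos] ** 2, 0.0)
    multi = count_d > 1
    stderr[multi] = np.sqrt(var[multi] / count_d[multi])
    # absorbing boundaries are identically zero
    mean[[0, n]] = 0.0
    stderr[[0, n]] = 0.0
    return DeltaProfile(
        p=np.arange(n + 1) / n,
        mean_delta=mean,
        stderr=stderr,
        count=count_d,
        status=status,
        n_cycles=n_cycles,
        n_absorbed_c=absorbed_c,
        n_absorbed_d=absorbed_d,
    )
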