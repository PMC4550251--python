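"""Numba kernels for the elementary update processes.

These implement the hot loops of the stochastic engine: one elementary
update of the death-birth (0), birth-death (1), imitation (2) or pairwise
comparison (3) process, whole fixation runs, whole profile cycles, and
repeated single-step sampling from a fixed state.

State layout: ``s`` holds per-vertex strategy indices; ``nbrs`` is the
(N, k) neighbor table; ``pos[i, l]`` is the slot of i in the neighbor list
of ``nbrs[i, l]``; ``tensor[i, l, r, s]`` is the payoff to vertex i playing
r against its l-th neighbor playing s.  Realized payoffs ``pi`` are
maintained incrementally: a flip at v touches only v and its neighbors.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEATH_BIRTH = 0
BIRTH_DEATH = 1
IMITATION = 2
PAIRWISE_COMPARISON = 3


@njit(cache=True)
def recompute_payoffs(s, nbrs, tensor):
    n, k = nbrs.shape
    pi = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for l in range(k):
            acc += tensor[i, l, s[i], s[nbrs[i, l]]]
        pi[i] = acc
    return pi


@njit(cache=True)
def _flip(v, new_s, s, pi, nbrs, pos, tensor):
    old = s[v]
    if new_s == old:
        return False
    k = nbrs.shape[1]
    for l in range(k):
        u = nbrs[v, l]
        pl = pos[v, l]
        pi[u] += tensor[u, pl, s[u], new_s] - tensor[u, pl, s[u], old]
    s[v] = new_s
    acc = 0.0
    for l in range(k):
        acc += tensor[v, l, new_s, s[nbrs[v, l]]]
    pi[v] = acc
    return True


@njit(cache=True)
def elementary_update(rule, s, pi, nbrs, pos, tensor, beta, counts):
    """One elementary update in place; maintains per-strategy counts."""
    n, k = nbrs.shape
    if rule == DEATH_BIRTH:
        i = np.random.randint(0, n)
        total = 0.0
        for l in range(k):
            total += np.exp(beta * pi[nbrs[i, l]])
        u = np.random.random() * total
        acc = 0.0
        j = nbrs[i, k - 1]
        for l in range(k):
            acc += np.exp(beta * pi[nbrs[i, l]])
            if u < acc:
                j = nbrs[i, l]
                break
        new_s = s[j]
        target = i
    elif rule == BIRTH_DEATH:
        total = 0.0
        for v in range(n):
            total += np.exp(beta * pi[v])
        u = np.random.random() * total
        acc = 0.0
        i = n - 1
        for v in range(n):
            acc += np.exp(beta * pi[v])
            if u < acc:
                i = v
                break
        j = nbrs[i, np.random.randint(0, k)]
        new_s = s[i]
        target = j
    elif rule == IMITATION:
        i = np.random.randint(0, n)
        total = np.exp(beta * pi[i])
        for l in range(k):
            total += np.exp(beta * pi[nbrs[i, l]])
        u = np.random.random() * total
        acc = np.exp(beta * pi[i])
        cand = i
        if u >= acc:
            for l in range(k):
                acc += np.exp(beta * pi[nbrs[i, l]])
                if u < acc:
                    cand = nbrs[i, l]
                    break
        new_s = s[cand]
        target = i
    else:  # pairwise comparison
        i = np.random.randint(0, n)
        j = nbrs[i, np.random.randint(0, k)]
        p_adopt = 1.0 / (1.0 + np.exp(beta * (pi[i] - pi[j])))
        if np.random.random() < p_adopt:
            new_s = s[j]
        else:
            new_s = s[i]
        target = i
    old = s[target]
    if _flip(target, new_s, s, pi, nbrs, pos, tensor):
        counts[old] -= 1
        counts[new_s] += 1


@njit(cache=True)
def run_to_fixation(s, nbrs, pos, tensor, rule, beta, max_updates, seed, traj, record):
    """Run until monomorphic or max_updates; returns (absorbed, n_updates).

    ``absorbed`` is the fixated strategy index, or -1 if the cap was hit.
    If ``record``, ``traj`` is filled with the strategy-0 frequency once per
    sweep of N updates (including the initial state), up to its length.
    """
    np.random.seed(seed)
    n = s.shape[0]
    m = tensor.shape[2]
    pi = recompute_payoffs(s, nbrs, tensor)
    counts = np.zeros(m, dtype=np.int64)
    for i in range(n):
        counts[s[i]] += 1
    n_traj = 0
    if record and traj.shape[0] > 0:
        traj[0] = counts[0] / n
        n_traj = 1
    for r in range(m):
        if counts[r] == n:
            return r, 0
    updates = 0
    while updates < max_updates:
        for _ in range(n):
            elementary_update(rule, s, pi, nbrs, pos, tensor, beta, counts)
            updates += 1
            for r in range(m):
                if counts[r] == n:
                    if record and n_traj < traj.shape[0]:
                        traj[n_traj] = counts[0] / n
                    return r, updates
            if updates >= max_updates:
                break
        if record and n_traj < traj.shape[0]:
            traj[n_traj] = counts[0] / n
            n_traj += 1
    return -1, updates


@njit(cache=True)
def run_cycle(s, nbrs, pos, tensor, rule, beta, max_updates, seed,
              sum_d, sumsq_d, count_d):
    """One profile cycle: run to fixation, recording per-sweep changes.

    After every sweep of N elementary updates the change in the frequency of
    strategy 0 is accumulated into the bin of the starting frequency
    (bin index = starting count of strategy 0).  Returns (absorbed, updates).
    """
    np.random.seed(seed)
    n = s.shape[0]
    m = tensor.shape[2]
    pi = recompute_payoffs(s, nbrs, tensor)
    counts = np.zeros(m, dtype=np.int64)
    for i in range(n):
        counts[s[i]] += 1
    for r in range(m):
        if counts[r] == n:
            return r, 0
    updates = 0
    absorbed = -1
    while updates < max_updates and absorbed == -1:
        start = counts[0]
        for _ in range(n):
            elementary_update(rule, s, pi, nbrs, pos, tensor, beta, counts)
            updates += 1
            for r in range(m):
                if counts[r] == n:
                    absorbed = r
                    break
            if absorbed != -1:
                break
        # once absorbed, the remainder of the sweep cannot change frequencies
        delta = (counts[0] - start) / n
        sum_d[start] += delta
        sumsq_d[start] += delta * delta
        count_d[start] += 1
    return absorbed, updates


@njit(cache=True)
def sample_step_deltas(s, pi, nbrs, pos, tensor, rule, beta, r_strat, n_samples, seed):
    """Monte-Carlo draws of the one-step change in the frequency of r_strat.

    The state is never mutated; each sample simulates one elementary update's
    outcome.  Returns (sum of deltas, sum of squared deltas).
    """
    np.random.seed(seed)
    n, k = nbrs.shape
    total_pop = 0.0
    if rule == BIRTH_DEATH:
        for v in range(n):
            total_pop += np.exp(beta * pi[v])
    acc_sum = 0.0
    acc_sq = 0.0
    for _ in range(n_samples):
        if rule == DEATH_BIRTH:
            i = np.random.randint(0, n)
            total = 0.0
            for l in range(k):
                total += np.exp(beta * pi[nbrs[i, l]])
            u = np.random.random() * total
            acc = 0.0
            j = nbrs[i, k - 1]
            for l in range(k):
                acc += np.exp(beta * pi[nbrs[i, l]])
                if u < acc:
                    j = nbrs[i, l]
                    break
            delta = ((1.0 if s[j] == r_strat else 0.0) -
                     (1.0 if s[i] == r_strat else 0.0)) / n
        elif rule == BIRTH_DEATH:
            u = np.random.random() * total_pop
            acc = 0.0
            i = n - 1
            for v in range(n):
                acc += np.exp(beta * pi[v])
                if u < acc:
                    i = v
                    break
            j = nbrs[i, np.random.randint(0, k)]
            delta = ((1.0 if s[i] == r_strat else 0.0) -
                     (1.0 if s[j] == r_strat else 0.0)) / n
        elif rule == IMITATION:
            i = np.random.randint(0, n)
            total = np.exp(beta * pi[i])
            for l in range(k):
                total += np.exp(beta * pi[nbrs[i, l]])
            u = np.random.random() * total
            acc = np.exp(beta * pi[i])
            cand = i
            if u >= acc:
                for l in range(k):
                    acc += np.exp(beta * pi[nbrs[i, l]])
                    if u < acc:
                        cand = nbrs[i, l]
                        break
            delta = ((1.0 if s[cand] == r_strat else 0.0) -
                     (1.0 if s[i] == r_strat else 0.0)) / n
        else:
            i = np.random.randint(0, n)
            j = nbrs[i, np.random.randint(0, k)]
            p_adopt = 1.0 / (1.0 + np.exp(beta * (pi[i] - pi[j])))
            if np.random.random() < p_adopt:
                delta = ((1.0 if s[j] == r_strat else 0.0) -
                         (1.0 if s[i] == r_strat else 0.0)) / n
            else:
                delta = 0.0
        acc_sum += delta
        acc_sq += delta * delta
    return acc_sum, acc_sq
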