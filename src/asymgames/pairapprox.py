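"""Pair-approximation analytics for weak selection on regular graphs.

Closing the dynamics on strategy-pair frequencies and letting the fast pair
variables equilibrate gives, to first order in the selection intensity β,
an expected per-update change in each strategy frequency that depends on
the asymmetric payoff field only through its edge average ā.  On the slow
time scale the dynamics are the classical replicator equation with the
payoffs transformed by a rule- and degree-dependent correction b̄_rs:

    ṗ_r = p_r ( Σ_s p_s (ā_rs + b̄_rs) − φ ),   φ = Σ_st p_s p_t ā_st.

The corrections are

    death-birth:          b̄_rs = ((k+1)ā_rr + ā_rs − ā_sr − (k+1)ā_ss) / ((k−2)(k+1))
    birth-death, pairwise: b̄_rs = (ā_rr + ā_rs − ā_sr − ā_ss) / (k−2)
    imitation:            b̄_rs = ((k+3)ā_rr + 3ā_rs − 3ā_sr − (k+3)ā_ss) / ((k−2)(k+3))

so birth-death and pairwise comparison share one correction.  (For the
Donation Game these recover the classical thresholds: cooperation is
favored under death-birth iff b̄/c̄ > k, under imitation iff b̄/c̄ > k+2,
and never under birth-death.)

For birth-death updating the positive prefactor involves the total
population fitness, for which no closed form is available; birth-death
expectations are therefore returned with a unit constant and flagged
"proportional-only" — signs and shapes are exact, the scale is not.

All formulas require k ≥ 3; degree-2 graphs (cycles) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.integrate import solve_ivp

from .engine import DeltaProfile, UpdateRule
from .games import MeanMatrix
from .networks import InvalidParameterError

__all__ = [
    "PairPrediction",
    "pair_equilibrium",
    "on_transform",
    "expected_change_weak",
    "replicator_rhs",
    "integrate_replicator",
    "genotypic_increase_condition",
    "predicted_profile",
]


def _check_k(k: int) -> None:
    if k < 3:
        raise InvalidParameterError(f"degree k={k} < 3: cycles are not treated")


def _check_simplex(p: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < -tol) or abs(p.sum() - 1.0) > tol:
        raise InvalidParameterError("frequency vector is not on the simplex")
    return p


def pair_equilibrium(p: np.ndarray, k: int) -> np.ndarray:
    """Equilibrium conditional neighbor frequencies q_{r|s}.

    Returns the matrix q with rows indexed by the focal strategy s and
    entries q[s, r] = p_r + (δ_sr − p_r)/(k−1); every row sums to 1.
    """
    _check_k(k)
    p = _check_simplex(p)
    n = p.shape[0]
    return p[None, :] + (np.eye(n) - p[None, :]) / (k - 1)


def on_transform(mean: Union[MeanMatrix, np.ndarray], k: int, rule: UpdateRule) -> np.ndarray:
    """Rule- and degree-dependent payoff correction b̄_rs (zero diagonal)."""
    _check_k(k)
    a = mean.values if isinstance(mean, MeanMatrix) else np.asarray(mean, dtype=float)
    d = np.diag(a)
    if rule.name == "death-birth":
        w = k + 1
        denom = (k - 2) * (k + 1)
    elif rule.name in ("birth-death", "pairwise-comparison"):
        w = 1
        denom = k - 2
    elif rule.name == "imitation":
        w = k + 3
        denom = (k - 2) * (k + 3)
    else:  # pragma: no cover
        raise InvalidParameterError(f"unknown rule {rule.name}")
    if rule.name == "imitation":
        off = 3.0
    else:
        off = 1.0
    return (w * d[:, None] + off * a - off * a.T - w * d[None, :]) / denom


def _bracket(a: np.ndarray, p: np.ndarray, rule: UpdateRule, k: int) -> np.ndarray:
    """The rule's first-order bracket, per strategy (vectorized over r)."""
    phi = float(p @ a @ p)
    S = a @ p          # Σ_s ā_rs p_s
    T = a.T @ p        # Σ_s ā_sr p_s
    U = float(np.diag(a) @ p)
    d = np.diag(a)
    if rule.name == "death-birth":
        return (-(k - 2) * (k + 1) * phi + (k * k - k - 1) * S - T
                - (k + 1) * U + (k + 1) * d)
    if rule.name in ("birth-death", "pairwise-comparison"):
        return -(k - 2) * phi + (k - 1) * S - T - U + d
    # imitation
    return (-(k - 2) * (k + 3) * phi + (k * k + k - 3) * S - 3 * T
            - (k + 3) * U + (k + 3) * d)


def prefactor(rule: UpdateRule, k: int, beta: float, n_vertices: int) -> Optional[float]:
    """Positive constant multiplying the bracket; None for birth-death
    (proportional-only: the constant involves the total population fitness)."""
    _check_k(k)
    if rule.name == "death-birth":
        return beta * (k - 2) / (k * (k - 1) * n_vertices)
    if rule.name == "imitation":
        return beta * k * (k - 2) / ((k - 1) * (k + 1) ** 2 * n_vertices)
    if rule.name == "pairwise-comparison":
        return beta * (k - 2) / (2 * (k - 1) * n_vertices)
    return None


def expected_change_weak(
    p: np.ndarray,
    mean: Union[MeanMatrix, np.ndarray],
    k: int,
    rule: UpdateRule,
    beta: float,
    n_vertices: int,
    per_sweep: bool = False,
    bd_constant: Optional[float] = None,
) -> np.ndarray:
    """First-order-in-β expected change in each strategy frequency per update.

    For birth-death the result carries a unit constant (proportional-only)
    unless ``bd_constant`` supplies a scale.  ``per_sweep`` multiplies by N
    (the expected change over one sweep of N elementary updates).
    """
    _check_k(k)
    p = _check_simplex(p)
    a = mean.values if isinstance(mean, MeanMatrix) else np.asarray(mean, dtype=float)
    pref = prefactor(rule, k, beta, n_vertices)
    if pref is None:
        pref = beta * (1.0 if bd_constant is None else bd_constant)
    out = pref * p * _bracket(a, p, rule, k)
    if per_sweep:
        out = out * n_vertices
    return out


def replicator_rhs(
    p: np.ndarray, mean: Union[MeanMatrix, np.ndarray], k: int, rule: UpdateRule
) -> np.ndarray:
    """ṗ_r = p_r(Σ_s p_s(ā_rs + b̄_rs) − φ) — the replicator equation on graphs."""
    p = _check_simplex(p)
    a = mean.values if isinstance(mean, MeanMatrix) else np.asarray(mean, dtype=float)
    b = on_transform(a, k, rule)
    phi = float(p @ a @ p)
    return p * ((a + b) @ p - phi)


def integrate_replicator(
    p0: np.ndarray,
    mean: Union[MeanMatrix, np.ndarray],
    k: int,
    rule: UpdateRule,
    t_span: tuple[float, float],
    n_points: int = 200,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the replicator equation; returns (t, p(t)) with p rows on the simplex."""
    p0 = _check_simplex(p0)
    a = mean.values if isinstance(mean, MeanMatrix) else np.asarray(mean, dtype=float)
    b = on_transform(a, k, rule)

    def rhs(_t, p):
        phi = float(p @ a @ p)
        return p * ((a + b) @ p - phi)

    t_eval = np.linspace(t_span[0], t_span[1], n_points)
    sol = solve_ivp(rhs, t_span, p0, t_eval=t_eval, rtol=rtol, atol=atol)
    traj = sol.y.T
    drift = np.abs(traj.sum(axis=1) - 1.0).max()
    if drift > 1e-8:
        raise RuntimeError(f"simplex drift {drift:.2e} exceeds guard")
    traj = traj / traj.sum(axis=1, keepdims=True)
    return sol.t, traj


@dataclass(frozen=True)
class PairPrediction:
    """Bundle of the weak-selection prediction for one (game, rule, k)."""

    mean_matrix: MeanMatrix
    rule: UpdateRule
    correction: np.ndarray
    proportional_only: bool

    @classmethod
    def build(cls, mean: MeanMatrix, rule: UpdateRule) -> "PairPrediction":
        return cls(
            mean_matrix=mean,
            rule=rule,
            correction=on_transform(mean, mean.degree, rule),
            proportional_only=rule.name == "birth-death",
        )

    def phi(self, p: np.ndarray) -> float:
        p = _check_simplex(p)
        return float(p @ self.mean_matrix.values @ p)

    def expected_change(self, p: np.ndarray, beta: float, per_sweep: bool = False) -> np.ndarray:
        return expected_change_weak(
            p, self.mean_matrix, self.mean_matrix.degree, self.rule, beta,
            self.mean_matrix.n_vertices, per_sweep=per_sweep,
        )


def genotypic_increase_condition(
    rule: UpdateRule,
    genotype: int,
    benefits: np.ndarray,
    costs: np.ndarray,
    cooperator_frequencies: np.ndarray,
    k: int,
) -> tuple[bool, float, float]:
    """Increase condition for genotype-u cooperators under a genetic rule.

    Death-birth: k(c_u − Σ_v c_v p_v) < b_u − Σ_v b_v p_v (the benefit/cost
    premiums replace b and c in the b/c > k rule).  Birth-death:
    c_u < Σ_v c_v p_v.  Returns (condition holds, lhs, rhs).
    """
    _check_k(k)
    if rule.transmission != "genetic":
        raise InvalidParameterError(
            f"genotypic increase conditions apply to genetic rules, not {rule.name}"
        )
    b = np.asarray(benefits, dtype=float)
    c = np.asarray(costs, dtype=float)
    p = np.asarray(cooperator_frequencies, dtype=float)
    if np.any(p < 0) or p.sum() > 1 + 1e-12:
        raise InvalidParameterError("cooperator frequencies must be >= 0 and sum to <= 1")
    u = genotype - 1
    if rule.name == "death-birth":
        lhs = k * (c[u] - float(c @ p))
        rhs = b[u] - float(b @ p)
    else:
        lhs = float(c[u])
        rhs = float(c @ p)
    return lhs < rhs, lhs, rhs


def predicted_profile(
    mean: MeanMatrix,
    k: int,
    rule: UpdateRule,
    beta: float,
    n_vertices: int,
    bd_constant: Optional[float] = None,
) -> DeltaProfile:
    """Per-sweep weak-selection prediction on the achievable bins {0, 1/N, …, 1}.

    This is the analytic overlay for the simulation profile.  Birth-death is
    refused unless a proportionality constant is supplied.
    """
    if mean.n_strategies != 2:
        raise InvalidParameterError("predicted profile requires a 2-strategy mean matrix")
    if rule.name == "birth-death" and bd_constant is None:
        raise InvalidParameterError(
            "birth-death predictions are proportional-only; supply bd_constant"
        )
    n = n_vertices
    grid = np.arange(n + 1) / n
    values = np.zeros(n + 1)
    for idx in range(1, n):
        p = np.array([grid[idx], 1.0 - grid[idx]])
        values[idx] = expected_change_weak(
            p, mean, k, rule, beta, n, per_sweep=True, bd_constant=bd_constant
        )[0]
    return DeltaProfile(
        p=grid,
        mean_delta=values,
        stderr=np.zeros(n + 1),
        count=np.zeros(n + 1, dtype=np.int64),
        status="ok",
    )
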