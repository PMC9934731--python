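"""Exact Markov-chain oracle for small models.

The random-order asynchronous process is a Markov chain on the 2^n joint
states.  Its one-iteration kernel is the average over all n! node
permutations of the ordered product of per-node single-site kernels, where
each single-site kernel encodes the propensity-gated update of one node.
Cost is 2^n x n! matrix algebra, so the oracle refuses models with more
than MAX_ORACLE_NODES nodes; it exists to validate the Monte-Carlo engine,
not to analyze the full network.

State-index convention (matching the simulator's packed states): index
s = sum_i x_i * 2^(n-1-i) over nodes in model order — the first node is the
most significant bit, i.e. states are ordered lexicographically as tuples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .engine import Scenario, effective_model, initial_condition_kinds
from .expr import eval_expr
from .model import LogicModel, validate_model
from . import _kernels

__all__ = [
    "TransitionMatrix",
    "OracleSizeError",
    "MAX_ORACLE_NODES",
    "exact_transition_matrix",
    "initial_distribution",
    "distribution_at",
    "stationary_distribution",
    "marginals",
    "total_variation",
    "empirical_joint",
]

MAX_ORACLE_NODES = 6


class OracleSizeError(ValueError):
    pass


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic one-iteration kernel over lexicographic states."""

    kernel: np.ndarray
    nodes: tuple[str, ...]
    ordering: str = "lexicographic, first node = most significant bit"

    @property
    def n_states(self) -> int:
        return self.kernel.shape[0]

    def state_index(self, state: dict[str, int]) -> int:
        idx = 0
        for name in self.nodes:
            idx = (idx << 1) | (1 if state[name] else 0)
        return idx

    def state_tuple(self, index: int) -> tuple[int, ...]:
        n = len(self.nodes)
        return tuple((index >> (n - 1 - i)) & 1 for i in range(n))


def _single_site_kernel(model: LogicModel, node_idx: int) -> np.ndarray:
    """Kernel of updating one node against every joint state."""
    n = len(model.nodes)
    spec = model.nodes[node_idx]
    names = model.node_names
    size = 1 << n
    bit = 1 << (n - 1 - node_idx)
    kern = np.zeros((size, size))
    for s in range(size):
        state = {names[i]: (s >> (n - 1 - i)) & 1 for i in range(n)}
        f = eval_expr(spec.rule, state)
        x = state[spec.name]
        if f == 1 and x == 0:
            kern[s, s | bit] += spec.p_a
            kern[s, s] += 1.0 - spec.p_a
        elif f == 0 and x == 1:
            kern[s, s & ~bit] += spec.p_d
            kern[s, s] += 1.0 - spec.p_d
        else:
            kern[s, s] = 1.0
    return kern


def exact_transition_matrix(model: LogicModel) -> TransitionMatrix:
    """Permutation-averaged one-iteration kernel of the update process.

    kernel = (1/n!) * sum over permutations sigma of
    A[sigma_1] @ A[sigma_2] @ ... @ A[sigma_n], with A[j] the single-site
    kernel of node j.  Raises :class:`OracleSizeError` for models larger
    than MAX_ORACLE_NODES nodes.
    """
    validate_model(model)
    n = len(model.nodes)
    if n > MAX_ORACLE_NODES:
        raise OracleSizeError(
            f"exact kernel supports at most {MAX_ORACLE_NODES} nodes "
            f"(2^n states x n! permutations); got n={n}"
        )
    site = [_single_site_kernel(model, j) for j in range(n)]
    size = 1 << n
    total = np.zeros((size, size))
    for sigma in itertools.permutations(range(n)):
        k = site[sigma[0]].copy()
        for j in sigma[1:]:
            k = k @ site[j]
        total += k
    total /= math.factorial(n)
    return TransitionMatrix(kernel=total, nodes=tuple(model.node_names))


def initial_distribution(model: LogicModel, scenario: Scenario) -> np.ndarray:
    """Exact product distribution of the scenario's initial condition."""
    kinds = initial_condition_kinds(model, scenario)
    n = len(model.nodes)
    dist = np.ones(1)
    for i in range(n):
        if kinds[i] == _kernels.INIT_ONE:
            p1 = 1.0
        elif kinds[i] == _kernels.INIT_COIN:
            p1 = 0.5
        else:
            p1 = 0.0
        dist = np.kron(dist, np.array([1.0 - p1, p1]))
    return dist


def distribution_at(
    model: LogicModel, scenario: Scenario, t: int
) -> tuple[np.ndarray, TransitionMatrix]:
    """Exact joint distribution after t iterations under the scenario."""
    eff = effective_model(model, scenario)
    tm = exact_transition_matrix(eff)
    dist = initial_distribution(eff, scenario)
    step_kernel = np.linalg.matrix_power(tm.kernel, t)
    return dist @ step_kernel, tm


def stationary_distribution(tm: TransitionMatrix, tol: float = 1e-12) -> np.ndarray:
    """Left eigenvector of the kernel for eigenvalue 1, normalized.

    For reducible chains (several absorbing classes) this returns one
    stationary vector; the chain's long-run behavior then depends on the
    initial distribution and :func:`distribution_at` should be used
    instead.
    """
    w, v = np.linalg.eig(tm.kernel.T)
    idx = np.argmin(np.abs(w - 1.0))
    if abs(w[idx] - 1.0) > 1e-8:
        raise ValueError("kernel has no eigenvalue 1; not row-stochastic?")
    pi = np.real(v[:, idx])
    pi[np.abs(pi) < tol] = 0.0
    pi = np.abs(pi)
    return pi / pi.sum()


def marginals(dist: np.ndarray, tm: TransitionMatrix) -> dict[str, float]:
    """Per-node P(ON) under a joint distribution over packed states."""
    n = len(tm.nodes)
    out = {}
    idx = np.arange(dist.size)
    for i, name in enumerate(tm.nodes):
        mask = (idx >> (n - 1 - i)) & 1
        out[name] = float(dist[mask == 1].sum())
    return out


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())


def empirical_joint(joint_column: np.ndarray, n_nodes: int) -> np.ndarray:
    """Empirical distribution over packed states from one ensemble column."""
    counts = np.bincount(joint_column.astype(np.int64), minlength=1 << n_nodes)
    return counts / counts.sum()
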