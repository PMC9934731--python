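"""Compiled Monte-Carlo kernels for the stochastic update process.

Rules are flattened to a postfix bytecode (push-variable / push-constant /
NOT / binary AND / binary OR) and interpreted inside a numba-jitted loop, so
ensembles of 10,000 replicates over ~60 nodes run in seconds.  Replicate r
is seeded from entry r of a seed array derived from the scenario's base
seed, so replicates are independent streams and each one is individually
reproducible.

State packing (for joint-distribution checks against the exact chain):
state index = sum_i state[i] << (n-1-i), i.e. the first node in model order
is the most significant bit, matching lexicographic ordering of state
tuples.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .expr import BoolExpr, Kind

# opcodes (codes >= 0 push the value of that node index)
_PUSH0 = -1
_PUSH1 = -2
_NOT = -3
_AND = -4
_OR = -5

# initial-condition kinds
INIT_ZERO = 0
INIT_ONE = 1
INIT_COIN = 2

UPDATE_RANDOM_ASYNC = 0
UPDATE_SYNCHRONOUS = 1


def _emit(expr: BoolExpr, index: dict[str, int], out: list[int]) -> int:
    """Append postfix codes; returns max stack depth used."""
    if expr.kind is Kind.CONST:
        out.append(_PUSH1 if expr.value else _PUSH0)
        return 1
    if expr.kind is Kind.VAR:
        out.append(index[expr.name])  # type: ignore[index]
        return 1
    if expr.kind is Kind.NOT:
        d = _emit(expr.children[0], index, out)
        out.append(_NOT)
        return d
    op = _AND if expr.kind is Kind.AND else _OR
    depth = _emit(expr.children[0], index, out)
    for child in expr.children[1:]:
        depth = max(depth, 1 + _emit(child, index, out))
        out.append(op)
    return depth


def compile_rules(rules: list[BoolExpr], names: list[str]):
    """Flatten rules into (codes, offsets, lengths, stack_size) arrays."""
    index = {name: i for i, name in enumerate(names)}
    codes: list[int] = []
    offsets = np.zeros(len(rules), dtype=np.int64)
    lengths = np.zeros(len(rules), dtype=np.int64)
    stack_size = 1
    for i, rule in enumerate(rules):
        offsets[i] = len(codes)
        stack_size = max(stack_size, _emit(rule, index, codes))
        lengths[i] = len(codes) - offsets[i]
    return np.asarray(codes, dtype=np.int64), offsets, lengths, stack_size


@njit(cache=True)
def _eval_rule(codes, off, length, state, stack):
    sp = 0
    for idx in range(off, off + length):
        c = codes[idx]
        if c >= 0:
            stack[sp] = state[c]
            sp += 1
        elif c == _PUSH0:
            stack[sp] = 0
            sp += 1
        elif c == _PUSH1:
            stack[sp] = 1
            sp += 1
        elif c == _NOT:
            stack[sp - 1] = 1 - stack[sp - 1]
        elif c == _AND:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] & stack[sp]
        else:
            sp -= 1
            stack[sp - 1] = stack[sp - 1] | stack[sp]
    return stack[0]


@njit(cache=True)
def run_ensemble(
    codes,
    offsets,
    lengths,
    stack_size,
    p_a,
    p_d,
    init_kind,
    replicates,
    horizon,
    window,
    seeds,
    record_joint,
    update_mode,
):
    """Simulate the ensemble; returns (on_counts, window_counts, joint).

    on_counts[t, i]  — replicates with node i ON at iteration t (row 0 is
                       the initial condition).
    window_counts[r, i] — iterations among the last `window` with node i ON
                       in replicate r (for replicate-level standard errors).
    joint[r, t]      — packed state index per replicate (only filled when
                       record_joint; requires n <= 63).

    Each iteration draws a fresh Fisher-Yates permutation of the nodes and
    applies single-node updates in that order against the evolving state;
    one uniform draw is consumed per node per iteration whether or not a
    switching event is possible.
    """
    n = len(offsets)
    counts = np.zeros((horizon + 1, n), dtype=np.int64)
    wcounts = np.zeros((replicates, n), dtype=np.int32)
    if record_joint:
        joint = np.zeros((replicates, horizon + 1), dtype=np.uint64)
    else:
        joint = np.zeros((1, 1), dtype=np.uint64)

    state = np.zeros(n, dtype=np.int8)
    fvals = np.zeros(n, dtype=np.int8)
    perm = np.zeros(n, dtype=np.int64)
    stack = np.zeros(stack_size, dtype=np.int8)

    for r in range(replicates):
        np.random.seed(seeds[r])
        for i in range(n):
            k = init_kind[i]
            if k == INIT_ONE:
                state[i] = 1
            elif k == INIT_COIN:
                state[i] = 1 if np.random.random() < 0.5 else 0
            else:
                state[i] = 0
        for i in range(n):
            counts[0, i] += state[i]
        if record_joint:
            packed = np.uint64(0)
            for i in range(n):
                packed = (packed << np.uint64(1)) | np.uint64(state[i])
            joint[r, 0] = packed

        for t in range(1, horizon + 1):
            if update_mode == UPDATE_SYNCHRONOUS:
                for i in range(n):
                    fvals[i] = _eval_rule(codes, offsets[i], lengths[i], state, stack)
                for i in range(n):
                    draw = np.random.random()
                    if fvals[i] == 1 and state[i] == 0:
                        if draw < p_a[i]:
                            state[i] = 1
                    elif fvals[i] == 0 and state[i] == 1:
                        if draw < p_d[i]:
                            state[i] = 0
            else:
                for i in range(n):
                    perm[i] = i
                for i in range(n - 1, 0, -1):
                    j = np.random.randint(0, i + 1)
                    tmp = perm[i]
                    perm[i] = perm[j]
                    perm[j] = tmp
                for k in range(n):
                    node = perm[k]
                    f = _eval_rule(codes, offsets[node], lengths[node], state, stack)
                    draw = np.random.random()
                    if f == 1 and state[node] == 0:
                        if draw < p_a[node]:
                            state[node] = 1
                    elif f == 0 and state[node] == 1:
                        if draw < p_d[node]:
                            state[node] = 0

            for i in range(n):
                counts[t, i] += state[i]
            if t > horizon - window:
                for i in range(n):
                    wcounts[r, i] += state[i]
            if record_joint:
                packed = np.uint64(0)
                for i in range(n):
                    packed = (packed << np.uint64(1)) | np.uint64(state[i])
                joint[r, t] = packed

    return counts, wcounts, joint
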