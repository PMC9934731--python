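"""Random logic-model generation for property tests and oracle
cross-validation sweeps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expr import AND, CONST, NOT, OR, VAR, BoolExpr
from .model import LogicModel, NodeSpec, validate_model

__all__ = ["RandomModelSpec", "generate_random_model", "random_expression"]


@dataclass(frozen=True)
class RandomModelSpec:
    """Recipe for a reproducible random model."""

    n_nodes: int = 4
    max_depth: int = 3
    p_a_range: tuple[float, float] = (0.2, 1.0)
    p_d_range: tuple[float, float] = (0.0, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        for lo, hi in (self.p_a_range, self.p_d_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("propensity ranges must satisfy 0 <= lo <= hi <= 1")


def random_expression(
    names: list[str], max_depth: int, rng: np.random.Generator
) -> BoolExpr:
    """Random expression over ``names`` with nesting depth <= max_depth."""
    if max_depth <= 1:
        r = rng.random()
        if r < 0.8:
            return VAR(names[rng.integers(len(names))])
        return CONST(int(rng.integers(2)))
    r = rng.random()
    if r < 0.35:
        return random_expression(names, max_depth - 1, rng)
    if r < 0.55:
        return NOT(random_expression(names, max_depth - 1, rng))
    k = int(rng.integers(2, 4))
    children = tuple(random_expression(names, max_depth - 1, rng) for _ in range(k))
    op = AND if rng.random() < 0.5 else OR
    expr = op(*children)
    # n-ary flattening can collapse to a single child; keep it as-is
    return expr


def generate_random_model(spec: RandomModelSpec) -> LogicModel:
    """Syntactically valid random model, reproducible from the seed.

    Every rule references only defined nodes, so the model always passes
    validation; propensities are drawn uniformly from the spec's ranges.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"N{i+1}" for i in range(spec.n_nodes)]
    nodes = []
    for name in names:
        rule = random_expression(names, spec.max_depth, rng)
        nodes.append(
            NodeSpec(
                name=name,
                rule=rule,
                p_a=float(rng.uniform(*spec.p_a_range)),
                p_d=float(rng.uniform(*spec.p_d_range)),
            )
        )
    model = LogicModel(
        nodes=tuple(nodes),
        name=f"random-{spec.n_nodes}n-seed{spec.seed}",
        metadata={"generator": "cartsim.randmodel", "seed": str(spec.seed)},
    )
    validate_model(model)
    return model
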