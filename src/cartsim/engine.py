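"""Stochastic propensity-driven execution of logic models.

The update process: each iteration visits every node once, in a freshly
drawn uniformly random permutation, and each visit sees the evolving state
(true asynchrony — later nodes in the permutation observe earlier nodes'
new values).  A visit to node ``v`` with rule value ``f`` and current state
``x`` switches ON with probability ``p_a`` when ``f=1, x=0``, switches OFF
with probability ``p_d`` when ``f=0, x=1``, and otherwise leaves the node
unchanged.

Scenario semantics: active input nodes are rewired to constant-TRUE rules
(they re-engage through ``p_a`` and never satisfy the degradation
condition); inactive inputs are constant-FALSE and, starting from 0, stay
0.  Initial states are all-zero except LCK (basally active in T cells),
active inputs (independent fair coins) and any perturbation-forced values.

Knockout = forced initial 0 with ``p_a = 0``; overexpression = forced
initial 1 with ``p_a = 1`` (``p_d`` untouched, so an overexpressed node can
still transiently degrade; a strict clamp with ``p_d = 0`` is available but
not the default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .expr import CONST, eval_expr
from .model import LogicModel, NodeSpec, validate_model

__all__ = [
    "PerturbationSpec",
    "Scenario",
    "EnsembleResult",
    "knockout",
    "overexpress",
    "update_node",
    "step",
    "make_initial_state",
    "effective_model",
    "initial_condition_kinds",
    "simulate_ensemble",
    "steady_state_summary",
]

State = dict[str, int]


@dataclass(frozen=True)
class PerturbationSpec:
    """Forced initial state and/or propensity overrides for one node."""

    node: str
    forced_initial: int | None = None
    p_a_override: float | None = None
    p_d_override: float | None = None

    def __post_init__(self) -> None:
        if self.forced_initial not in (None, 0, 1):
            raise ValueError(f"forced_initial must be 0/1/None, got {self.forced_initial!r}")
        for label, v in (("p_a", self.p_a_override), ("p_d", self.p_d_override)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{label}_override={v} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "node": self.node,
            "forced_initial": self.forced_initial,
            "pa": self.p_a_override,
            "pd": self.p_d_override,
        }


def knockout(node: str) -> PerturbationSpec:
    """Constitutively-OFF perturbation: initial 0, activation propensity 0."""
    return PerturbationSpec(node, forced_initial=0, p_a_override=0.0)


def overexpress(node: str, strict: bool = False) -> PerturbationSpec:
    """Constitutively-ON perturbation: initial 1, activation propensity 1.

    With ``strict=True`` degradation is also disabled, clamping the node ON
    for all time.
    """
    return PerturbationSpec(
        node, forced_initial=1, p_a_override=1.0, p_d_override=0.0 if strict else None
    )


@dataclass(frozen=True)
class Scenario:
    """Inputs, perturbations and run parameters for one ensemble."""

    active_inputs: frozenset[str] = frozenset()
    perturbations: tuple[PerturbationSpec, ...] = ()
    horizon: int = 100
    replicates: int = 10_000
    seed: int = 0
    steady_window: int = 20
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "active_inputs", frozenset(self.active_inputs))
        object.__setattr__(self, "perturbations", tuple(self.perturbations))
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (1 <= self.steady_window <= self.horizon):
            raise ValueError("steady_window must satisfy 1 <= W <= horizon")

    def validate_against(self, model: LogicModel) -> None:
        inputs = set(model.input_names)
        stray = sorted(self.active_inputs - inputs)
        if stray:
            raise ValueError(f"active_inputs not input nodes of the model: {stray}")
        for p in self.perturbations:
            if p.node not in model:
                raise ValueError(f"perturbation targets unknown node {p.node!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "active_inputs": sorted(self.active_inputs),
            "perturbations": [p.to_dict() for p in self.perturbations],
            "horizon": self.horizon,
            "replicates": self.replicates,
            "seed": self.seed,
            "steady_window": self.steady_window,
        }


def scenario_from_dict(d: Mapping, **overrides) -> Scenario:
    """Build a Scenario from a configuration mapping (e.g. parsed YAML)."""
    perts = []
    for p in d.get("perturbations", []) or []:
        perts.append(
            PerturbationSpec(
                node=p["node"],
                forced_initial=p.get("forced_initial"),
                p_a_override=p.get("pa"),
                p_d_override=p.get("pd"),
            )
        )
    kwargs = {
        "active_inputs": frozenset(d.get("active_inputs", []) or []),
        "perturbations": tuple(perts),
        "horizon": int(d.get("horizon", 100)),
        "replicates": int(d.get("replicates", 10_000)),
        "seed": int(d.get("seed", 0)),
        "steady_window": int(d.get("steady_window", 20)),
        "name": str(d.get("name", "")),
    }
    kwargs.update(overrides)
    return Scenario(**kwargs)


# ---------------------------------------------------------------------------
# Reference (single-state) semantics


def update_node(state: Mapping[str, int], spec: NodeSpec, draw: float) -> int:
    """Single-node update given one uniform draw in [0, 1)."""
    f = eval_expr(spec.rule, state)
    x = 1 if state[spec.name] else 0
    if f == 1 and x == 0:
        return 1 if draw < spec.p_a else 0
    if f == 0 and x == 1:
        return 0 if draw < spec.p_d else 1
    return x


def step(state: Mapping[str, int], model: LogicModel, rng: np.random.Generator) -> State:
    """One random-order asynchronous iteration over all nodes.

    Draws a uniform permutation of the node list; each node's update sees
    the partially updated state.  One uniform draw is consumed per node.
    """
    new: State = dict(state)
    order = rng.permutation(len(model.nodes))
    for idx in order:
        spec = model.nodes[idx]
        new[spec.name] = update_node(new, spec, rng.random())
    return new


def make_initial_state(
    model: LogicModel, scenario: Scenario, rng: np.random.Generator
) -> State:
    """Draw one initial state: zeros except LCK, coins on active inputs,
    and perturbation-forced values (which take precedence)."""
    scenario.validate_against(model)
    forced = {p.node: p.forced_initial for p in scenario.perturbations if p.forced_initial is not None}
    state: State = {}
    for spec in model.nodes:
        if spec.name in forced:
            state[spec.name] = forced[spec.name]
        elif spec.name in scenario.active_inputs:
            state[spec.name] = 1 if rng.random() < 0.5 else 0
        elif spec.name == "LCK":
            state[spec.name] = 1
        else:
            state[spec.name] = 0
    return state


# ---------------------------------------------------------------------------
# Scenario application


def effective_model(model: LogicModel, scenario: Scenario) -> LogicModel:
    """Model with input rules rewired and perturbation overrides applied."""
    scenario.validate_against(model)
    overrides = {p.node: p for p in scenario.perturbations}
    nodes = []
    for spec in model.nodes:
        if spec.role == "input":
            spec = replace(spec, rule=CONST(1 if spec.name in scenario.active_inputs else 0))
        p = overrides.get(spec.name)
        if p is not None:
            if p.p_a_override is not None:
                spec = replace(spec, p_a=p.p_a_override)
            if p.p_d_override is not None:
                spec = replace(spec, p_d=p.p_d_override)
        nodes.append(spec)
    return model.with_nodes(nodes)


def initial_condition_kinds(model: LogicModel, scenario: Scenario) -> np.ndarray:
    """Per-node initial-condition code: 0 start-OFF, 1 start-ON, 2 fair coin."""
    forced = {p.node: p.forced_initial for p in scenario.perturbations if p.forced_initial is not None}
    kinds = np.zeros(len(model.nodes), dtype=np.int8)
    for i, spec in enumerate(model.nodes):
        if spec.name in forced:
            kinds[i] = _kernels.INIT_ONE if forced[spec.name] else _kernels.INIT_ZERO
        elif spec.name in scenario.active_inputs:
            kinds[i] = _kernels.INIT_COIN
        elif spec.name == "LCK":
            kinds[i] = _kernels.INIT_ONE
    return kinds


@dataclass
class EnsembleResult:
    """Mean ON-fraction trajectories over a replicate ensemble.

    ``activity[t, i]`` is the fraction of replicates in which node i is ON
    at iteration t (row 0 = initial condition).  ``window_counts[r, i]``
    counts ON iterations of node i among the last ``window`` iterations of
    replicate r, retained for replicate-level standard errors.
    """

    activity: np.ndarray
    nodes: list[str]
    scenario: Scenario
    seed: int
    replicates: int
    window: int
    window_counts: np.ndarray
    joint: np.ndarray | None = None

    @property
    def horizon(self) -> int:
        return self.activity.shape[0] - 1

    def node_activity(self, name: str) -> np.ndarray:
        return self.activity[:, self.nodes.index(name)]

    def steady_state(self) -> pd.Series:
        """Per-node mean activity over the last ``window`` iterations."""
        return pd.Series(
            self.activity[self.horizon - self.window + 1 :].mean(axis=0),
            index=self.nodes,
            name="steady",
        )

    def steady_se(self) -> pd.Series:
        """Standard error of the steady fraction from replicate variance."""
        means = self.window_counts / self.window
        return pd.Series(
            means.std(axis=0, ddof=1) / np.sqrt(self.replicates),
            index=self.nodes,
            name="se",
        )

    def to_tidy(self, nodes: Sequence[str] | None = None) -> pd.DataFrame:
        """Long-format (iteration, node, activity) table."""
        names = list(nodes) if nodes is not None else list(self.nodes)
        unknown = [n for n in names if n not in self.nodes]
        if unknown:
            raise KeyError(f"unknown node(s): {unknown}")
        t = np.arange(self.activity.shape[0])
        frames = [
            pd.DataFrame(
                {"iteration": t, "node": name, "activity": self.node_activity(name)}
            )
            for name in names
        ]
        return pd.concat(frames, ignore_index=True)

    def summary_dict(self) -> dict:
        steady = self.steady_state()
        se = self.steady_se()
        return {
            "scenario": self.scenario.to_dict(),
            "seed": self.seed,
            "replicates": self.replicates,
            "horizon": self.horizon,
            "steady_window": self.window,
            "steady": {n: float(steady[n]) for n in self.nodes},
            "steady_se": {n: float(se[n]) for n in self.nodes},
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary_dict(), indent=2, sort_keys=True)


def _replicate_seeds(base_seed: int, replicates: int) -> np.ndarray:
    ss = np.random.SeedSequence(base_seed)
    return ss.generate_state(replicates, dtype=np.uint32).astype(np.int64)


def simulate_ensemble(
    model: LogicModel,
    scenario: Scenario,
    record_joint: bool = False,
    update_mode: str = "random_async",
) -> EnsembleResult:
    """Run R independent replicates of T iterations and aggregate.

    Fully reproducible for fixed (model, scenario, seed).  ``record_joint``
    additionally stores each replicate's packed state index per iteration
    (models with <= 63 nodes) for joint-distribution validation against the
    exact Markov kernel.  ``update_mode="synchronous"`` applies all rule
    evaluations against the frozen state of the previous iteration — an
    explicitly flagged comparison variant, not the default semantics.
    """
    validate_model(model)
    eff = effective_model(model, scenario)
    names = eff.node_names
    if record_joint and len(names) > 63:
        raise ValueError("record_joint requires at most 63 nodes")
    modes = {
        "random_async": _kernels.UPDATE_RANDOM_ASYNC,
        "synchronous": _kernels.UPDATE_SYNCHRONOUS,
    }
    if update_mode not in modes:
        raise ValueError(f"unknown update_mode {update_mode!r}")
    codes, offsets, lengths, stack_size = _kernels.compile_rules(
        [n.rule for n in eff.nodes], names
    )
    p_a = np.array([n.p_a for n in eff.nodes])
    p_d = np.array([n.p_d for n in eff.nodes])
    kinds = initial_condition_kinds(eff, scenario)
    seeds = _replicate_seeds(scenario.seed, scenario.replicates)
    counts, wcounts, joint = _kernels.run_ensemble(
        codes,
        offsets,
        lengths,
        stack_size,
        p_a,
        p_d,
        kinds,
        scenario.replicates,
        scenario.horizon,
        scenario.steady_window,
        seeds,
        record_joint,
        modes[update_mode],
    )
    return EnsembleResult(
        activity=counts / scenario.replicates,
        nodes=names,
        scenario=scenario,
        seed=scenario.seed,
        replicates=scenario.replicates,
        window=scenario.steady_window,
        window_counts=wcounts,
        joint=joint if record_joint else None,
    )


def steady_state_summary(result: EnsembleResult, window: int | None = None) -> pd.DataFrame:
    """Per-node steady fraction (mean activity over the last ``window``
    iterations) with replicate-level standard errors.

    The standard error column is only defined for the window the ensemble
    was run with; for any other window it is NaN.
    """
    w = result.window if window is None else window
    if w < 1:
        raise ValueError("window must be >= 1")
    if w > result.horizon:
        raise ValueError("window exceeds horizon")
    steady = result.activity[result.horizon - w + 1 :].mean(axis=0)
    if w == result.window:
        se = result.steady_se().to_numpy()
    else:
        se = np.full(len(result.nodes), np.nan)
    return pd.DataFrame({"steady": steady, "se": se}, index=result.nodes)
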