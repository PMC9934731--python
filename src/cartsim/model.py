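"""Logic models: named Boolean nodes with update rules and propensities.

A :class:`LogicModel` is an ordered collection of :class:`NodeSpec` entries.
Each node carries an update rule (a Boolean formula over node names), an
activation propensity ``p_a`` (probability an OFF node whose rule is
satisfied switches ON in an iteration) and a degradation propensity ``p_d``
(probability an ON node whose rule is unsatisfied switches OFF), plus a
``role`` (input / internal / readout) and a ``compartment`` tag used to
select perturbation-scan targets.

The on-disk format is line-oriented UTF-8 text::

    @model <name>                      # optional header
    # comment
    NAME = EXPR [, pa=<float>] [, pd=<float>] [, role=<role>] [, compartment=<c>]

Omitted propensities take the model-level defaults (0.5 / 0.05).
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .expr import BoolExpr, Kind, ParseError, eval_expr, parse_expression

__all__ = [
    "NodeSpec",
    "LogicModel",
    "ModelValidationError",
    "ROLES",
    "COMPARTMENTS",
    "DEFAULT_PA",
    "DEFAULT_PD",
    "load_model",
    "loads_model",
    "save_model",
    "dumps_model",
    "dependency_graph",
    "edge_sign_by_flipping",
    "activatable_closure",
    "export_boolnet",
]

ROLES = ("input", "internal", "readout")
COMPARTMENTS = ("cart", "tumor", "interface")

DEFAULT_PA = 0.5
DEFAULT_PD = 0.05


class ModelValidationError(ValueError):
    """Aggregates every defect found while validating a model."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "model validation failed:\n" + "\n".join(f"  - {p}" for p in problems)
        )


@dataclass(frozen=True)
class NodeSpec:
    """One node: rule, propensities, role and compartment."""

    name: str
    rule: BoolExpr
    p_a: float = DEFAULT_PA
    p_d: float = DEFAULT_PD
    role: str = "internal"
    compartment: str = "cart"

    def problems(self) -> list[str]:
        out = []
        if not (0.0 <= self.p_a <= 1.0):
            out.append(f"node {self.name}: pa={self.p_a} outside [0, 1]")
        if not (0.0 <= self.p_d <= 1.0):
            out.append(f"node {self.name}: pd={self.p_d} outside [0, 1]")
        if self.role not in ROLES:
            out.append(f"node {self.name}: unknown role {self.role!r}")
        if self.compartment not in COMPARTMENTS:
            out.append(f"node {self.name}: unknown compartment {self.compartment!r}")
        if self.role == "input" and not self.rule.is_const():
            out.append(
                f"node {self.name}: role=input requires a constant rule "
                f"(got {self.rule.unparse()!r})"
            )
        return out


@dataclass(frozen=True)
class LogicModel:
    """Validated, ordered collection of nodes."""

    nodes: tuple[NodeSpec, ...]
    name: str = ""
    metadata: Mapping[str, str] = field(default_factory=dict)

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def input_names(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == "input"]

    @property
    def readout_names(self) -> list[str]:
        return [n.name for n in self.nodes if n.role == "readout"]

    def __len__(self) -> int:
        return len(self.nodes)

    def __getitem__(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(n.name == name for n in self.nodes)

    def index(self, name: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.name == name:
                return i
        raise KeyError(name)

    def with_nodes(self, nodes: Iterable[NodeSpec]) -> "LogicModel":
        return replace(self, nodes=tuple(nodes))

    def content_hash(self) -> str:
        """SHA-256 of the canonical serialization (for run manifests)."""
        return hashlib.sha256(dumps_model(self).encode()).hexdigest()


def validate_model(model: LogicModel) -> None:
    """Raise :class:`ModelValidationError` listing every problem found."""
    problems: list[str] = []
    if not model.nodes:
        problems.append("model has no nodes")
    seen: set[str] = set()
    for n in model.nodes:
        if n.name in seen:
            problems.append(f"duplicate node name {n.name!r}")
        seen.add(n.name)
        problems.extend(n.problems())
    defined = {n.name for n in model.nodes}
    for n in model.nodes:
        unresolved = sorted(n.rule.variables() - defined)
        if unresolved:
            problems.append(
                f"node {n.name}: rule references undefined node(s) "
                + ", ".join(unresolved)
            )
    if problems:
        raise ModelValidationError(problems)


# ---------------------------------------------------------------------------
# Serialization


def _parse_line(line: str, lineno: int, problems: list[str]) -> NodeSpec | None:
    if "=" not in line:
        problems.append(f"line {lineno}: expected 'NAME = EXPR', got {line!r}")
        return None
    name, rhs = line.split("=", 1)
    name = name.strip()
    fields = rhs.split(",")
    rule_text = fields[0].strip()
    kwargs: dict[str, object] = {}
    for f in fields[1:]:
        f = f.strip()
        if "=" not in f:
            problems.append(f"line {lineno}: malformed attribute {f!r}")
            continue
        key, val = (s.strip() for s in f.split("=", 1))
        if key in ("pa", "pd"):
            try:
                kwargs["p_a" if key == "pa" else "p_d"] = float(val)
            except ValueError:
                problems.append(f"line {lineno}: malformed propensity {f!r}")
        elif key in ("role", "compartment"):
            kwargs[key] = val
        else:
            problems.append(f"line {lineno}: unknown attribute {key!r}")
    try:
        rule = parse_expression(rule_text)
    except ParseError as e:
        problems.append(f"line {lineno}: {e}")
        return None
    try:
        return NodeSpec(name=name, rule=rule, **kwargs)  # type: ignore[arg-type]
    except ValueError as e:
        problems.append(f"line {lineno}: {e}")
        return None


def loads_model(text: str, name: str = "") -> LogicModel:
    """Parse model text; validates before returning."""
    problems: list[str] = []
    nodes: list[NodeSpec] = []
    model_name = name
    metadata: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("@model"):
            model_name = line[len("@model"):].strip()
            continue
        if line.startswith("@meta"):
            body = line[len("@meta"):].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                metadata[k.strip()] = v.strip()
            continue
        spec = _parse_line(line, lineno, problems)
        if spec is not None:
            nodes.append(spec)
    if problems:
        raise ModelValidationError(problems)
    model = LogicModel(nodes=tuple(nodes), name=model_name, metadata=metadata)
    validate_model(model)
    return model


def load_model(path: str | Path) -> LogicModel:
    p = Path(path)
    return loads_model(p.read_text(encoding="utf-8"), name=p.stem)


def dumps_model(model: LogicModel) -> str:
    lines = []
    if model.name:
        lines.append(f"@model {model.name}")
    for k, v in model.metadata.items():
        lines.append(f"@meta {k} = {v}")
    for n in model.nodes:
        lines.append(
            f"{n.name} = {n.rule.unparse()}, pa={n.p_a!r}, pd={n.p_d!r}, "
            f"role={n.role}, compartment={n.compartment}"
        )
    return "\n".join(lines) + "\n"


def save_model(model: LogicModel, path: str | Path) -> None:
    Path(path).write_text(dumps_model(model), encoding="utf-8")


def export_boolnet(model: LogicModel) -> str:
    """BoolNet-style ``targets, factors`` CSV of the rule set.

    Lossy: propensities, roles and compartments are dropped; constant rules
    are written as literals.  Intended for interoperability with
    attractor-analysis tools that consume deterministic Boolean networks.
    """
    lines = ["targets, factors"]
    for n in model.nodes:
        lines.append(f"{n.name}, {n.rule.unparse()}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Structure


def _sign_occurrences(expr: BoolExpr, negated: bool, out: dict[str, set[bool]]) -> None:
    if expr.kind is Kind.VAR:
        out.setdefault(expr.name, set()).add(negated)  # type: ignore[arg-type]
    elif expr.kind is Kind.NOT:
        _sign_occurrences(expr.children[0], not negated, out)
    else:
        for c in expr.children:
            _sign_occurrences(c, negated, out)


def dependency_graph(model: LogicModel) -> nx.DiGraph:
    """Directed regulator -> target graph with a ``sign`` edge attribute.

    Edge (u, v) exists iff u appears in v's rule.  ``sign`` is "activating"
    when every occurrence of u sits under an even number of NOTs,
    "inhibitory" when every occurrence is under an odd number, and "dual"
    for mixed parity.
    """
    g = nx.DiGraph()
    g.add_nodes_from(model.node_names)
    for n in model.nodes:
        occ: dict[str, set[bool]] = {}
        _sign_occurrences(n.rule, False, occ)
        for reg, parities in occ.items():
            if parities == {False}:
                sign = "activating"
            elif parities == {True}:
                sign = "inhibitory"
            else:
                sign = "dual"
            g.add_edge(reg, n.name, sign=sign)
    return g


def edge_sign_by_flipping(rule: BoolExpr, regulator: str) -> str:
    """Sign of a regulator determined by brute force over all contexts.

    Flips ``regulator`` in every assignment of the rule's variables: if the
    rule output only ever increases with the regulator the edge is
    activating, if it only decreases it is inhibitory, if both occur it is
    dual.  Exponential in the variable count; intended for small rules as an
    independent check on :func:`dependency_graph` labels.
    """
    variables = sorted(rule.variables())
    others = [v for v in variables if v != regulator]
    up = down = False
    for bits in itertools.product((0, 1), repeat=len(others)):
        ctx = dict(zip(others, bits))
        lo = eval_expr(rule, {**ctx, regulator: 0})
        hi = eval_expr(rule, {**ctx, regulator: 1})
        if hi > lo:
            up = True
        elif hi < lo:
            down = True
    if up and down:
        return "dual"
    if down:
        return "inhibitory"
    if up:
        return "activating"
    return "none"


def _satisfiable_given(rule: BoolExpr, free: set[str]) -> bool:
    """Can the rule be true when variables outside ``free`` are fixed 0?"""
    vs = sorted(rule.variables())
    free_vs = [v for v in vs if v in free]
    base = {v: 0 for v in vs}
    for bits in itertools.product((0, 1), repeat=len(free_vs)):
        base.update(zip(free_vs, bits))
        if eval_expr(rule, base):
            return True
    return False


def activatable_closure(
    model: LogicModel,
    initially_on: Iterable[str] = (),
    never_on: Iterable[str] = (),
) -> set[str]:
    """Least fixed point of "this node can ever be ON".

    A node is activatable if it starts ON, or if its rule can evaluate true
    in some assignment where all non-activatable nodes are 0.  Nodes in
    ``never_on`` (knockouts: initial 0 with zero activation propensity) are
    excluded outright and pinned to 0 inside every rule.  Any node outside
    the returned set is a structural zero: its ensemble activity is exactly
    0 at every iteration, not merely statistically small.
    """
    never = set(never_on)
    closure = set(initially_on) - never
    rules = {n.name: n.rule for n in model.nodes}
    changed = True
    while changed:
        changed = False
        for name, rule in rules.items():
            if name in closure or name in never:
                continue
            if _satisfiable_given(rule, closure - never):
                closure.add(name)
                changed = True
    return closure
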