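import pytest

from cartsim import build_cart_model
from cartsim.expr import parse_expression
from cartsim.model import DEFAULT_PA, DEFAULT_PD, LogicModel, NodeSpec


@pytest.fixture(scope="session")
def cart_model():
    return build_cart_model()


def make_model(rules: dict[str, str], pa=DEFAULT_PA, pd=DEFAULT_PD, **per_node):
    """Small-model helper: rules maps name -> rule text; per_node maps
    name -> dict of NodeSpec overrides (p_a, p_d, role, ...)."""
    nodes = []
    for name, text in rules.items():
        kwargs = {"p_a": pa, "p_d": pd}
        kwargs.update(per_node.get(name, {}))
        nodes.append(NodeSpec(name=name, rule=parse_expression(text), **kwargs))
    return LogicModel(nodes=tuple(nodes), name="test")


@pytest.fixture
def two_node_chain():
    """A is constant-true, B copies A; deterministic switching."""
    return make_model({"A": "1", "B": "A"}, pa=1.0, pd=0.0)


@pytest.fixture
def toggle_model():
    """Single self-inhibiting node: birth-death chain with steady
    ON-fraction pa/(pa+pd) = 10/11 at the default propensities."""
    return make_model({"A": "!A"}, pa=0.5, pd=0.05)
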