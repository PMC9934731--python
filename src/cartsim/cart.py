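"""The curated CAR T-cell / tumor-cell interaction network and its
in-silico experiments.

The packaged model has 59 nodes: four ligand-expression inputs (TAex,
IL2ex, PDL1L2ex, CD8086ex), three signaling-signature readouts (CFUNC =
CART-cell function by proxy of AP1, NFAT and MTORC1; CINHIB = CART-cell
inhibition by proxy of dNFAT and BATF; TAPOP = tumor apoptosis through
CASP3CASP7) and the internal signaling cascade connecting them.  All nodes
carry the default propensities pa=0.5, pd=0.05: high activation alongside
slow degradation, reflecting all-or-none T-cell activation kinetics with
slow signal decay.

Experiments: the five named receptor-ligation scenarios (A-E) over the four
ligands, and a knockout/overexpression scan of internal CART-compartment
nodes that reports percent change of the steady readout fractions against a
control scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .engine import (
    EnsembleResult,
    PerturbationSpec,
    Scenario,
    knockout,
    overexpress,
    simulate_ensemble,
    steady_state_summary,
)
from .model import LogicModel, activatable_closure, loads_model

__all__ = [
    "ALIASES",
    "READOUTS",
    "ReadoutSet",
    "SCENARIO_INPUTS",
    "build_cart_model",
    "canonical_name",
    "load_scenario_library",
    "make_scenario",
    "run_scenario",
    "default_scan_targets",
    "perturbation_scan",
    "trajectory_report",
    "scenario_closure",
    "structural_zeros",
]

# Printed node-name variants accepted when referring to packaged-model nodes.
ALIASES = {"PERGRZM": "PERGRZB", "CINHI": "CINHIB"}


@dataclass(frozen=True)
class ReadoutSet:
    cfunc: str = "CFUNC"
    cinhib: str = "CINHIB"
    tapop: str = "TAPOP"

    def validate_against(self, model: LogicModel) -> None:
        for name in (self.cfunc, self.cinhib, self.tapop):
            if name not in model or model[name].role != "readout":
                raise ValueError(f"{name!r} is not a readout node of the model")

    def names(self) -> tuple[str, str, str]:
        return (self.cfunc, self.cinhib, self.tapop)


READOUTS = ReadoutSet()

# Active-input sets of the five named ligation scenarios.
SCENARIO_INPUTS: dict[str, frozenset[str]] = {
    "A": frozenset({"TAex"}),
    "B": frozenset({"TAex", "IL2ex"}),
    "C": frozenset({"TAex", "IL2ex", "PDL1L2ex", "CD8086ex"}),
    "D": frozenset({"TAex", "IL2ex", "CD8086ex"}),
    "E": frozenset({"TAex", "IL2ex", "PDL1L2ex"}),
}


def canonical_name(name: str) -> str:
    """Resolve printed-variant node names (PERGRZM, CINHI) to canonical."""
    return ALIASES.get(name, name)


def build_cart_model() -> LogicModel:
    """Load and validate the packaged 59-node model."""
    text = (
        resources.files("cartsim").joinpath("data/cart_table1.model").read_text("utf-8")
    )
    return loads_model(text, name="cart_table1")


def load_scenario_library() -> dict:
    text = (
        resources.files("cartsim")
        .joinpath("data/scenarios_fig3.yaml")
        .read_text("utf-8")
    )
    return yaml.safe_load(text)


def make_scenario(
    name: str,
    replicates: int = 10_000,
    horizon: int = 100,
    steady_window: int = 20,
    seed: int = 0,
    perturbations: tuple[PerturbationSpec, ...] = (),
) -> Scenario:
    """Scenario object for one of the named ligation scenarios A-E."""
    if name not in SCENARIO_INPUTS:
        raise KeyError(
            f"unknown scenario {name!r}; expected one of {sorted(SCENARIO_INPUTS)}"
        )
    return Scenario(
        active_inputs=SCENARIO_INPUTS[name],
        perturbations=perturbations,
        horizon=horizon,
        replicates=replicates,
        seed=seed,
        steady_window=steady_window,
        name=name,
    )


def run_scenario(
    name: str,
    replicates: int = 10_000,
    horizon: int = 100,
    steady_window: int = 20,
    seed: int = 0,
    model: LogicModel | None = None,
    perturbations: tuple[PerturbationSpec, ...] = (),
) -> tuple[EnsembleResult, pd.DataFrame]:
    """Simulate a named ligation scenario; returns (ensemble, summary).

    The summary holds the steady fraction and its standard error for every
    node; the readout rows are the reported p_cfunc / p_cinhib / p_tapop.
    """
    if model is None:
        model = build_cart_model()
    scenario = make_scenario(
        name,
        replicates=replicates,
        horizon=horizon,
        steady_window=steady_window,
        seed=seed,
        perturbations=perturbations,
    )
    result = simulate_ensemble(model, scenario)
    return result, steady_state_summary(result)


def default_scan_targets(model: LogicModel) -> list[str]:
    """Internal CART-compartment nodes: the default perturbation-scan set.

    Excludes the ligand-expression inputs, interface and tumor-side nodes,
    and the readouts themselves.
    """
    return [
        n.name
        for n in model.nodes
        if n.role == "internal" and n.compartment == "cart"
    ]


def perturbation_scan(
    model: LogicModel | None = None,
    control: Scenario | None = None,
    targets: list[str] | None = None,
    replicates: int = 10_000,
    horizon: int = 100,
    steady_window: int = 20,
    seed: int = 0,
    readouts: ReadoutSet = READOUTS,
    strict_overexpression: bool = False,
) -> pd.DataFrame:
    """Knockout / overexpression scan of readout steady fractions.

    For every target node, runs a knockout ensemble (initial 0, pa=0) and an
    overexpression ensemble (initial 1, pa=1) under the control scenario's
    active inputs and reports, per readout, the raw steady fraction, its
    standard error, and the percent change vs. control
    100*(p_perturbed - p_control)/p_control.  Percent change is NaN (not 0)
    where the control fraction is 0.  Percentages are not clipped.

    Control and perturbed runs use the same replicate count, horizon,
    window and base seed policy, so percent changes carry Monte-Carlo error
    of order the reported standard errors.
    """
    if model is None:
        model = build_cart_model()
    readouts.validate_against(model)
    if control is None:
        control = make_scenario(
            "C",
            replicates=replicates,
            horizon=horizon,
            steady_window=steady_window,
            seed=seed,
        )
    if targets is None:
        targets = default_scan_targets(model)
    targets = [canonical_name(t) for t in targets]
    unknown = [t for t in targets if t not in model]
    if unknown:
        raise KeyError(f"scan target(s) not in model: {unknown}")

    control_result = simulate_ensemble(model, control)
    csum = steady_state_summary(control_result)
    rnames = list(readouts.names())
    p_ctrl = csum.loc[rnames, "steady"]
    if (p_ctrl == 0).all():
        raise RuntimeError(
            "control readout fractions are all zero; scan aborted "
            f"(control scenario {control.name or control.active_inputs})"
        )

    rows = []
    for target in targets:
        for mode, pert in (
            ("knockout", knockout(target)),
            ("overexpression", overexpress(target, strict=strict_overexpression)),
        ):
            scenario = Scenario(
                active_inputs=control.active_inputs,
                perturbations=control.perturbations + (pert,),
                horizon=control.horizon,
                replicates=control.replicates,
                seed=control.seed,
                steady_window=control.steady_window,
                name=f"{control.name or 'control'}:{target}:{mode}",
            )
            summary = steady_state_summary(simulate_ensemble(model, scenario))
            row: dict[str, object] = {"node": target, "mode": mode}
            for label, rname in zip(("cfunc", "cinhib", "tapop"), rnames):
                p = summary.loc[rname, "steady"]
                se = summary.loc[rname, "se"]
                pc = p_ctrl[rname]
                row[f"p_{label}"] = p
                row[f"se_{label}"] = se
                # algebraically 100*(p - pc)/pc; this form is exactly -100
                # when the perturbed fraction is zero
                row[f"pct_{label}"] = (
                    100.0 * p / pc - 100.0 if pc > 0 else float("nan")
                )
            rows.append(row)

    out = pd.DataFrame(rows)
    for label, rname in zip(("cfunc", "cinhib", "tapop"), rnames):
        out[f"control_p_{label}"] = p_ctrl[rname]
        out[f"control_se_{label}"] = csum.loc[rname, "se"]
    return out


def trajectory_report(result: EnsembleResult, nodes: list[str]) -> pd.DataFrame:
    """Long-format (iteration, node, activity) table for selected nodes,
    e.g. the receptor-to-AP1 cascade SCFV -> ZAP70 -> ... -> AP1."""
    return result.to_tidy([canonical_name(n) for n in nodes])


# ---------------------------------------------------------------------------
# Structural reachability


def scenario_closure(model: LogicModel, scenario: Scenario) -> set[str]:
    """Nodes that can ever switch ON under the scenario.

    Active inputs and LCK (and any perturbation forced ON) seed the
    closure; knockouts (forced 0 with pa=0) are pinned OFF.  Everything
    outside the closure is a structural zero of the ensemble.
    """
    scenario.validate_against(model)
    forced_on = {
        p.node for p in scenario.perturbations if p.forced_initial == 1
    }
    never_on = {
        p.node
        for p in scenario.perturbations
        if p.forced_initial == 0 and p.p_a_override == 0.0
    }
    initially_on = set(scenario.active_inputs) | forced_on
    if "LCK" in model and "LCK" not in never_on:
        lck_forced = {
            p.node for p in scenario.perturbations if p.forced_initial is not None
        }
        if "LCK" not in lck_forced:
            initially_on.add("LCK")
    # inactive inputs are constant 0: pin them off
    never_on |= {
        n for n in model.input_names if n not in scenario.active_inputs
    } - forced_on
    return activatable_closure(model, initially_on, never_on)


def structural_zeros(model: LogicModel, scenario: Scenario) -> set[str]:
    """Nodes whose activity is exactly 0 at every iteration."""
    return set(model.node_names) - scenario_closure(model, scenario)
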