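"""The packaged 59-node CAR T-cell network and its experiments."""

import numpy as np
import pytest

from cartsim.cart import (
    READOUTS,
    SCENARIO_INPUTS,
    canonical_name,
    default_scan_targets,
    load_scenario_library,
    make_scenario,
    perturbation_scan,
    run_scenario,
    scenario_closure,
    structural_zeros,
    trajectory_report,
)
from cartsim.engine import Scenario, knockout, simulate_ensemble
from cartsim.expr import AND, NOT, VAR, parse_expression
from cartsim.model import dependency_graph, dumps_model, loads_model


class TestPackagedModel:
    def test_node_and_role_counts(self, cart_model):
        assert len(cart_model) == 59
        assert set(cart_model.input_names) == {"TAex", "IL2ex", "PDL1L2ex", "CD8086ex"}
        assert set(cart_model.readout_names) == {"CFUNC", "CINHIB", "TAPOP"}

    def test_readout_set_validates(self, cart_model):
        READOUTS.validate_against(cart_model)

    def test_il2_gene_expression_rule(self, cart_model):
        assert cart_model["IL2ge"].rule == AND(VAR("AP1"), VAR("NFKB"), VAR("NFAT"))

    def test_immune_synapse_rule(self, cart_model):
        assert cart_model["IS"].rule == NOT(VAR("CASP3CASP7"))

    def test_default_propensities_everywhere(self, cart_model):
        assert all(n.p_a == 0.5 and n.p_d == 0.05 for n in cart_model.nodes)

    def test_lck_rule_balanced_correction(self, cart_model):
        expected = parse_expression(
            "!LCK & ((!SHP1 | (SHP1 & ERK)) & ((!SHP2 | (SHP2 & ERK))))"
        )
        assert cart_model["LCK"].rule == expected

    def test_cfunc_rule_drops_undefined_symbol(self, cart_model):
        assert cart_model["CFUNC"].rule == AND(VAR("AP1"), VAR("NFAT"), VAR("MTORC1"))
        assert "CDSYF" not in cart_model["CFUNC"].rule.variables()

    def test_curation_notes_recorded_in_metadata(self, cart_model):
        joined = " ".join(cart_model.metadata.values())
        for token in ("LCK", "PERGRZB", "CINHIB", "CDSYF"):
            assert token in joined

    def test_printed_name_aliases(self):
        assert canonical_name("PERGRZM") == "PERGRZB"
        assert canonical_name("CINHI") == "CINHIB"
        assert canonical_name("ZAP70") == "ZAP70"

    def test_model_roundtrips_through_serialization(self, cart_model):
        again = loads_model(dumps_model(cart_model), name=cart_model.name)
        assert again.nodes == cart_model.nodes

    def test_apoptosis_wired_through_cytotoxic_granules(self, cart_model):
        g = dependency_graph(cart_model)
        assert set(g.predecessors("CASP3CASP7")) == {"FASL", "PERGRZB"}
        assert set(g.predecessors("TAPOP")) == {"CASP3CASP7"}
        assert set(g.predecessors("CYTOGRAN")) == {
            "WASPCDC42", "PKCtheta", "Calcium", "PI3K",
        }


class TestScenarios:
    def test_library_matches_named_input_sets(self):
        lib = load_scenario_library()
        for name, inputs in SCENARIO_INPUTS.items():
            assert set(lib["scenarios"][name]["active_inputs"]) == set(inputs)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            make_scenario("Z")

    def test_no_input_scenario_has_tapop_structurally_zero(self, cart_model):
        scn = Scenario(active_inputs=frozenset(), horizon=100,
                       replicates=1_000, seed=21)
        zeros = structural_zeros(cart_model, scn)
        assert "TAPOP" in zeros and "CASP3CASP7" in zeros
        res = simulate_ensemble(cart_model, scn)
        assert np.all(res.node_activity("TAPOP") == 0.0)

    def test_car_only_scenario_pd1_batf_structurally_zero(self, cart_model):
        scn = Scenario(active_inputs=frozenset({"TAex"}), horizon=100,
                       replicates=1_000, seed=22)
        zeros = structural_zeros(cart_model, scn)
        assert {"PD1", "BATF"} <= zeros
        res = simulate_ensemble(cart_model, scn)
        assert np.all(res.node_activity("PD1") == 0.0)
        assert np.all(res.node_activity("BATF") == 0.0)

    def test_engine_respects_every_structural_zero(self, cart_model):
        """No node outside the activatable closure may ever show activity."""
        scn = Scenario(active_inputs=frozenset({"IL2ex"}), horizon=60,
                       replicates=1_000, seed=23)
        zeros = structural_zeros(cart_model, scn)
        assert "TAPOP" in zeros  # IL2 alone cannot drive cytotoxicity
        res = simulate_ensemble(cart_model, scn)
        for name in zeros:
            assert np.all(res.node_activity(name) == 0.0), name

    def test_ap1_rises_to_sustained_plateau_under_car_ligation(self, cart_model):
        res, _ = run_scenario("A", replicates=3_000, seed=24, model=cart_model)
        ap1 = res.node_activity("AP1")
        assert ap1[0] == 0.0
        late = ap1[-20:]
        assert late.mean() > 0.05
        # smoothed trajectory is non-decreasing up to the plateau
        smooth = np.convolve(ap1, np.ones(9) / 9, mode="valid")
        rise = smooth[: np.argmax(smooth) + 1]
        assert np.all(np.diff(rise) > -0.02)

    def test_run_scenario_returns_summary_with_readouts(self, cart_model):
        res, summary = run_scenario("A", replicates=500, horizon=40,
                                    steady_window=10, seed=25, model=cart_model)
        assert {"CFUNC", "CINHIB", "TAPOP"} <= set(summary.index)
        assert res.horizon == 40


class TestTrajectoryReport:
    def test_all_nodes_shape_contract(self, cart_model):
        scn = Scenario(active_inputs=frozenset({"TAex"}), horizon=15,
                       replicates=200, seed=26, steady_window=5)
        res = simulate_ensemble(cart_model, scn)
        tidy = trajectory_report(res, cart_model.node_names)
        assert len(tidy) == 16 * 59
        assert list(tidy.columns) == ["iteration", "node", "activity"]

    def test_inactive_input_series_is_zero(self, cart_model):
        scn = Scenario(active_inputs=frozenset({"TAex"}), horizon=15,
                       replicates=200, seed=27, steady_window=5)
        res = simulate_ensemble(cart_model, scn)
        tidy = trajectory_report(res, ["IL2ex"])
        assert (tidy["activity"] == 0.0).all()

    def test_unknown_node_rejected(self, cart_model):
        scn = Scenario(active_inputs=frozenset(), horizon=5, replicates=50,
                       seed=0, steady_window=2)
        res = simulate_ensemble(cart_model, scn)
        with pytest.raises(KeyError, match="NOPE"):
            trajectory_report(res, ["NOPE"])

    def test_cascade_half_maximum_times_ordered(self, cart_model):
        """Signal propagates receptor-proximal to distal: half-maximum
        crossing times along the strict dependency chain SCFV -> ZAP70 ->
        PLCgamma1 -> DAG -> RASGRP are non-decreasing (1-iteration slack
        for ties).  ERK is deliberately absent: its GRB2SOS input gives it
        a parallel route that can fire before the DAG arm."""
        res, _ = run_scenario("A", replicates=5_000, seed=28, model=cart_model)
        chain = ["SCFV", "ZAP70", "PLCgamma1", "DAG", "RASGRP"]
        times = []
        for name in chain:
            act = res.node_activity(name)
            half = act.max() / 2
            times.append(int(np.argmax(act >= half)))
        assert all(t2 >= t1 - 1 for t1, t2 in zip(times, times[1:]))


class TestPerturbationScan:
    def test_default_targets_are_internal_cart_nodes(self, cart_model):
        targets = set(default_scan_targets(cart_model))
        assert len(targets) == 45
        # ligand inputs, tumor-side nodes and readouts are excluded
        assert not targets & {"TAex", "IL2ex", "PDL1L2ex", "CD8086ex"}
        assert not targets & {"TA", "FAS", "CASP3CASP7", "TAPOP"}
        assert not targets & {"CFUNC", "CINHIB"}
        assert {"ZAP70", "PD1", "BATF", "ERK", "MTORC1"} <= targets

    def test_zap70_knockout_kills_function_exactly(self, cart_model):
        """NFAT needs calcineurin or P38, both downstream of ZAP70, so the
        knockout zeroes p_cfunc and the scan cell reads -100%."""
        scn = make_scenario("C", replicates=2_000, seed=29)
        zeros = structural_zeros(
            cart_model,
            Scenario(active_inputs=scn.active_inputs,
                     perturbations=(knockout("ZAP70"),),
                     horizon=100, replicates=2_000, seed=29),
        )
        assert {"NFAT", "CFUNC"} <= zeros
        tab = perturbation_scan(model=cart_model, control=scn,
                                targets=["ZAP70"], replicates=2_000, seed=29)
        ko = tab[(tab.node == "ZAP70") & (tab["mode"] == "knockout")].iloc[0]
        assert ko.p_cfunc == 0.0
        assert ko.pct_cfunc == -100.0

    def test_caspase_knockout_zeroes_tumor_apoptosis(self, cart_model):
        scn = make_scenario("C", replicates=1_000, seed=30)
        tab = perturbation_scan(model=cart_model, control=scn,
                                targets=["CASP3CASP7"], replicates=1_000, seed=30)
        ko = tab[tab["mode"] == "knockout"].iloc[0]
        assert ko.p_tapop == 0.0
        assert ko.pct_tapop == -100.0

    def test_percent_change_undefined_when_control_zero(self, cart_model):
        """A control with the caspase knocked out has p_tapop = 0: the
        percent change for that readout is NaN, not 0, and the raw
        fractions are still reported."""
        scn = Scenario(active_inputs=SCENARIO_INPUTS["B"],
                       perturbations=(knockout("CASP3CASP7"),),
                       horizon=60, replicates=800, seed=31,
                       steady_window=10, name="B-caspase-ko")
        tab = perturbation_scan(model=cart_model, control=scn,
                                targets=["ERK"], replicates=800, seed=31)
        assert np.isnan(tab["pct_tapop"]).all()
        assert np.isfinite(tab["p_tapop"]).all()
        assert np.isfinite(tab["pct_cfunc"]).all()

    def test_scan_aborts_when_control_all_zero(self, cart_model):
        scn = Scenario(active_inputs=frozenset(), horizon=30, replicates=200,
                       seed=32, steady_window=5, name="dead")
        with pytest.raises(RuntimeError, match="control readout"):
            perturbation_scan(model=cart_model, control=scn, targets=["ZAP70"])

    def test_unknown_target_rejected(self, cart_model):
        scn = make_scenario("C", replicates=200, horizon=20, steady_window=5, seed=33)
        with pytest.raises(KeyError, match="NOPE"):
            perturbation_scan(model=cart_model, control=scn, targets=["NOPE"])

    def test_alias_targets_resolved(self, cart_model):
        scn = make_scenario("C", replicates=400, horizon=30, steady_window=5, seed=34)
        tab = perturbation_scan(model=cart_model, control=scn,
                                targets=["PERGRZM"], replicates=400, seed=34)
        assert set(tab["node"]) == {"PERGRZB"}


def test_closure_includes_immune_synapse_without_inputs(cart_model):
    scn = Scenario(active_inputs=frozenset(), replicates=1)
    closure = scenario_closure(cart_model, scn)
    # IS = !CASP3CASP7 is satisfiable at the all-zero state; LCK starts ON
    assert {"IS", "LCK"} <= closure
    assert "TAPOP" not in closure
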