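"""Normalized-Hill network semantics: parsing, gates, dynamics, steady states."""

import numpy as np
import pandas as pd
import pytest

from vonet.network_core import (
    ModelParseError,
    NetworkModel,
    NodeSpec,
    Perturbation,
    ReactionSpec,
    SteadyStateError,
    fixed_point_state,
    hill_activation,
    integrate,
    ode_rhs,
    parse_model_tables,
    parse_rule,
    steady_state,
)
from vonet.synthetic_data import make_toy_network


def _hill_oracle(x, ec50, n):
    # independent closed form from the three anchors f(0)=0, f(EC50)=1/2, f(1)=1
    e = ec50**n
    b = (e - 1.0) / (2.0 * e - 1.0)
    return b * x**n / ((b - 1.0) + x**n)


def single_node_model(drive: float, tau: float = 1.0, ymax: float = 1.0) -> NetworkModel:
    return NetworkModel(
        [NodeSpec(id="Y", ymax=ymax, tau=tau, y0=0.0)],
        [ReactionSpec(rule="=> Y", w=drive)],
    )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class TestParsing:
    def test_three_node_table(self):
        nodes = pd.DataFrame(
            {"id": ["A", "B", "C"], "ymax": 1.0, "tau": 0.1, "y0": 0.0}
        )
        reactions = pd.DataFrame(
            {"rule": ["A => B", "!B => C"], "w": 1.0, "n": 1.4, "EC50": 0.5}
        )
        model = parse_model_tables(nodes, reactions)
        assert len(model.nodes) == 3
        assert len(model.reactions) == 2
        (name, neg), = model.reactions[1].operands
        assert (name, neg) == ("B", True)  # C inhibited by B

    def test_undeclared_target_rejected(self):
        nodes = pd.DataFrame({"id": ["A"], "tau": 0.1})
        reactions = pd.DataFrame({"rule": ["A => X"], "w": 1.0, "n": 1.4, "EC50": 0.5})
        with pytest.raises(ModelParseError, match="X"):
            parse_model_tables(nodes, reactions)

    def test_duplicate_node_id_rejected(self):
        nodes = pd.DataFrame({"id": ["A", "A"], "tau": 0.1})
        reactions = pd.DataFrame({"rule": ["=> A"], "w": 1.0, "n": 1.4, "EC50": 0.5})
        with pytest.raises(ModelParseError, match="duplicate"):
            parse_model_tables(nodes, reactions)

    def test_malformed_rule_rejected(self):
        with pytest.raises(ModelParseError, match="malformed"):
            parse_rule("A & => B")
        with pytest.raises(ModelParseError, match="malformed"):
            parse_rule("A B")

    def test_missing_hill_parameters_rejected(self):
        nodes = pd.DataFrame({"id": ["A", "B"], "tau": 0.1})
        reactions = pd.DataFrame({"rule": ["A => B"], "w": [1.0], "n": [1.4]})
        with pytest.raises(ModelParseError, match="ec50"):
            parse_model_tables(nodes, reactions)

    def test_input_rule_has_no_operands(self):
        ops, target = parse_rule("=> AGO")
        assert ops == [] and target == "AGO"

    def test_table_round_trip(self):
        toy = make_toy_network("crosstalk")
        nodes_df, reactions_df = toy.model.to_tables()
        again = parse_model_tables(nodes_df, reactions_df)
        assert again.node_ids == toy.model.node_ids
        assert [r.rule for r in again.reactions] == [r.rule for r in toy.model.reactions]


# ---------------------------------------------------------------------------
# Hill activation
# ---------------------------------------------------------------------------

class TestHill:
    @pytest.mark.parametrize("seed", range(5))
    def test_normalization_anchors(self, seed):
        rng = np.random.default_rng(seed)
        ec50 = rng.uniform(0.05, 0.95)
        n = rng.uniform(0.5, 4.0)
        assert hill_activation(0.0, ec50, n) == pytest.approx(0.0, abs=1e-12)
        assert hill_activation(ec50, ec50, n) == pytest.approx(0.5, abs=1e-12)
        assert hill_activation(1.0, ec50, n) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_value(self):
        # EC50=0.5, n=2 gives B=1.5, K^n=0.5; f(0.25)=1.5*0.0625/0.5625=1/6
        assert hill_activation(0.25, 0.5, 2.0) == pytest.approx(1.0 / 6.0, abs=1e-12)

    @pytest.mark.parametrize("ec50,n", [(0.2, 1.4), (0.7, 2.0), (0.5, 1.0)])
    def test_monotone_and_matches_oracle(self, ec50, n):
        x = np.linspace(0.0, 1.0, 101)
        f = hill_activation(x, ec50, n)
        assert np.all(np.diff(f) >= -1e-12)
        if abs(2 * ec50**n - 1) > 1e-9:
            assert np.allclose(f, _hill_oracle(x, ec50, n), atol=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_ec50_raises(self, bad):
        with pytest.raises(ValueError):
            hill_activation(0.5, bad, 2.0)


# ---------------------------------------------------------------------------
# Logic gates via reaction combination
# ---------------------------------------------------------------------------

class TestLogic:
    def or_model(self, w1, w2):
        nodes = [NodeSpec("A", tau=1.0), NodeSpec("B", tau=1.0), NodeSpec("C", tau=1.0)]
        rx = [
            ReactionSpec("=> A", w=w1),
            ReactionSpec("=> B", w=w2),
            ReactionSpec("A => C", w=1.0, n=1.0, ec50=0.6),
            ReactionSpec("B => C", w=1.0, n=1.0, ec50=0.6),
        ]
        return NetworkModel(nodes, rx)

    def test_or_of_saturated_inputs_is_one(self):
        model = self.or_model(1.0, 1.0)
        y = steady_state(model)
        assert y[model.index("C")] == pytest.approx(1.0, abs=1e-5)

    def test_or_inclusion_exclusion(self):
        # two drive reactions with activation 0.5 each on one target
        nodes = [NodeSpec("C", tau=1.0)]
        rx = [ReactionSpec("=> C", w=0.5, id="a"), ReactionSpec("=> C", w=0.5, id="b")]
        model = NetworkModel(nodes, rx)
        rate0 = ode_rhs(np.array([0.0]), model)
        assert rate0[0] == pytest.approx(0.75, abs=1e-12)  # 0.5+0.5-0.25

    def test_and_with_zero_operand_is_zero(self):
        nodes = [NodeSpec("A", tau=1.0), NodeSpec("B", tau=1.0), NodeSpec("C", tau=1.0)]
        rx = [
            ReactionSpec("=> A", w=0.8),
            ReactionSpec("=> B", w=0.0),
            ReactionSpec("A & B => C", w=1.0),
        ]
        y = steady_state(NetworkModel(nodes, rx))
        assert y[2] == pytest.approx(0.0, abs=1e-6)

    def test_not_of_zero_is_one(self):
        nodes = [NodeSpec("A", tau=1.0), NodeSpec("C", tau=1.0)]
        rx = [ReactionSpec("!A => C", w=1.0)]
        model = NetworkModel(nodes, rx)
        rate = ode_rhs(np.zeros(2), model)
        assert rate[model.index("C")] == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

class TestDynamics:
    def test_zero_everything_is_fixed_point(self):
        toy = make_toy_network("chain")
        pert = Perturbation(weight_overrides={
            toy.model.input_reaction_id(n): 0.0 for n in ("AGO", "STR", "BG", "ORPH")
        })
        rate = ode_rhs(np.zeros(len(toy.model.nodes)), toy.model, pert)
        assert np.allclose(rate, 0.0, atol=1e-12)

    def test_single_node_linear_relaxation_rate(self):
        model = single_node_model(drive=0.7, tau=1.0)
        y = np.array([0.2])
        assert ode_rhs(y, model)[0] == pytest.approx(0.5, abs=1e-12)

    def test_knockout_forces_zero_rate_and_activity(self):
        model = single_node_model(drive=1.0)
        pert = Perturbation(knockouts={"Y"})
        assert ode_rhs(np.array([0.0]), model, pert)[0] == pytest.approx(0.0)
        traj = integrate(model, pert, t_span=(0.0, 3.0))
        assert np.all(np.abs(traj.activities) < 1e-8)

    def test_single_node_closed_form(self):
        # dy/dt = 1 - y, y(0)=0 -> y(1) = 1 - 1/e
        model = single_node_model(drive=1.0, tau=1.0)
        traj = integrate(model, t_span=(0.0, 1.0), t_eval=np.array([0.0, 1.0]),
                         rtol=1e-10, atol=1e-12)
        assert traj.activities[-1, 0] == pytest.approx(1.0 - np.exp(-1.0), abs=1e-8)

    def test_steady_start_stays_flat(self, chain_system, truth):
        system, toy = chain_system
        pert = Perturbation(weight_overrides=system.baseline_weights(truth.weights))
        y_ss = steady_state(toy.model, pert)
        traj = integrate(toy.model, pert, t_span=(0.0, 5.0), y_init=y_ss)
        assert np.max(np.abs(traj.activities - y_ss)) < 1e-5

    def test_adaptive_solver_matches_explicit_euler(self, truth):
        """Step agonist input: LSODA vs dense fixed-step Euler on the chain toy."""
        toy = make_toy_network("chain")
        overrides = {
            toy.model.input_reaction_id("AGO"): 0.5,
            toy.model.input_reaction_id("STR"): 0.06,
            toy.model.input_reaction_id("BG"): 0.08,
        }
        pert = Perturbation(weight_overrides=overrides)
        t_end, dt = 2.0, 2e-4
        y = toy.model.y0.copy()
        for _ in range(int(t_end / dt)):
            y = y + dt * ode_rhs(y, toy.model, pert)
        traj = integrate(toy.model, pert, t_span=(0.0, t_end),
                         t_eval=np.array([0.0, t_end]), rtol=1e-8, atol=1e-10)
        assert np.max(np.abs(traj.activities[-1] - y)) < 1e-4
        # output rises monotonically toward its gated target
        full = integrate(toy.model, pert, t_span=(0.0, 5.0))
        cell = full.activity("CellArea")
        assert np.all(np.diff(cell) >= -1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_boundedness_on_random_networks(self, seed):
        """Activities of randomly wired valid networks stay inside [0, ymax]."""
        rng = np.random.default_rng(seed)
        n_nodes = int(rng.integers(3, 7))
        names = [f"N{i}" for i in range(n_nodes)]
        nodes = [
            NodeSpec(nm, ymax=1.0, tau=float(rng.uniform(0.05, 1.0)),
                     y0=float(rng.uniform(0.0, 1.0)))
            for nm in names
        ]
        rx = [ReactionSpec(f"=> {names[0]}", w=float(rng.uniform(0, 1)))]
        for i in range(1, n_nodes):
            src = names[int(rng.integers(0, i))]
            neg = "!" if rng.uniform() < 0.3 else ""
            rx.append(
                ReactionSpec(
                    f"{neg}{src} => {names[i]}",
                    w=float(rng.uniform(0.2, 1.0)),
                    n=float(rng.uniform(0.8, 3.0)),
                    ec50=float(rng.uniform(0.2, 0.8)),
                )
            )
        traj = integrate(NetworkModel(nodes, rx), t_span=(0.0, 5.0))
        assert traj.activities.min() >= -1e-6
        assert traj.activities.max() <= 1.0 + 1e-6

    def test_trajectory_tidy_export(self):
        model = single_node_model(drive=0.5)
        traj = integrate(model, t_span=(0.0, 1.0), t_eval=np.linspace(0, 1, 5))
        df = traj.to_frame()
        assert list(df.columns) == ["time", "node", "activity"]
        assert len(df) == 5


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

class TestSteadyState:
    @pytest.mark.parametrize("drive", [0.0, 0.3, 1.0])
    def test_single_node_settles_at_drive(self, drive):
        y = steady_state(single_node_model(drive))
        assert y[0] == pytest.approx(drive, abs=1e-6)

    def test_knockout_of_sole_upstream(self):
        toy = make_toy_network("chain")
        overrides = {toy.model.input_reaction_id(n): w
                     for n, w in [("AGO", 0.5), ("STR", 0.0), ("BG", 0.0), ("ORPH", 0.0)]}
        blocked = steady_state(toy.model, Perturbation(weight_overrides=overrides,
                                                       knockouts={"RA"}))
        silent = steady_state(toy.model, Perturbation(
            weight_overrides={**overrides, toy.model.input_reaction_id("AGO"): 0.0}))
        idx = toy.model.index("CellArea")
        assert blocked[idx] == pytest.approx(silent[idx], abs=1e-5)

    @pytest.mark.parametrize("variant", ["chain", "crosstalk", "runaway-prone"])
    def test_matches_long_horizon_integration(self, variant, truth):
        toy = make_toy_network(variant)
        overrides = {toy.model.input_reaction_id(n): w
                     for n, w in [("AGO", 0.12), ("STR", 0.06), ("BG", 0.08)]}
        pert = Perturbation(weight_overrides=overrides)
        y_ss = steady_state(toy.model, pert)
        brute = integrate(toy.model, pert, t_span=(0.0, 60.0),
                          t_eval=np.array([0.0, 60.0]), rtol=1e-9, atol=1e-11)
        assert np.max(np.abs(y_ss - brute.activities[-1])) < 1e-5
        fp = fixed_point_state(toy.model, pert)
        assert np.max(np.abs(fp - y_ss)) < 1e-5

    def test_time_varying_perturbation_rejected(self):
        model = single_node_model(drive=0.5)
        pert = Perturbation(weight_overrides={"r1": lambda t: 0.5})
        with pytest.raises(ValueError, match="constant"):
            steady_state(model, pert)

    def test_nonconvergence_raises(self):
        model = single_node_model(drive=1.0, tau=1.0)
        with pytest.raises(SteadyStateError):
            steady_state(model, max_time=0.5, tol=1e-12)
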