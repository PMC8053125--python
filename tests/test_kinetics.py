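"""Mass-action scheme construction, simulation and closed-form oracles."""

import numpy as np
import pytest

import aptakinetics as ak
from aptakinetics.errors import ConfigurationError
from aptakinetics.kinetics import Reaction, ReactionScheme, Species


class TestSchemeValidation:
    def test_builtin_schemes_well_formed(self):
        for sid, n_rates in [
            ("model1", 2), ("model2", 4), ("model3", 2), ("model4", 4), ("model5", 3),
        ]:
            scheme = ak.get_scheme(sid)
            assert len(scheme.rate_symbols) == n_rates
            assert sum(s.role == "ligand" for s in scheme.species) == 1

    @pytest.mark.parametrize(
        "species,reactions,match",
        [
            # duplicate species name
            (
                (Species("R", "receptor"), Species("R", "ligand")),
                (Reaction(("R",), ("R",), "k"),),
                "not unique",
            ),
            # no ligand
            (
                (Species("R", "receptor"), Species("B", "final-complex")),
                (Reaction(("R",), ("B",), "k"),),
                "exactly one ligand",
            ),
            # unknown species in reaction
            (
                (Species("R", "receptor"), Species("L", "ligand")),
                (Reaction(("R", "X"), ("L",), "k"),),
                "unknown",
            ),
            # duplicate rate symbol
            (
                (
                    Species("R", "receptor"),
                    Species("L", "ligand"),
                    Species("B", "final-complex"),
                ),
                (
                    Reaction(("R", "L"), ("B",), "k"),
                    Reaction(("B",), ("R",), "k"),
                ),
                "more than one reaction",
            ),
        ],
    )
    def test_invalid_schemes_rejected(self, species, reactions, match):
        with pytest.raises(ConfigurationError, match=match):
            ReactionScheme("bad", species, reactions)

    def test_orphan_species_rejected(self):
        with pytest.raises(ConfigurationError, match="appear in no reaction"):
            ReactionScheme(
                "bad",
                (
                    Species("R", "receptor"),
                    Species("L", "ligand"),
                    Species("B", "final-complex"),
                    Species("X", "intermediate-complex"),
                ),
                (Reaction(("R", "L"), ("B",), "k"),),
            )

    def test_unknown_role_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown role"):
            Species("R", "enzyme")

    def test_scheme_serialization_roundtrip(self):
        for sid in ak.kinetics.SCHEME_IDS:
            scheme = ak.get_scheme(sid)
            assert ReactionScheme.from_dict(scheme.to_dict()) == scheme


class TestBuildOde:
    def test_single_irreversible_term(self):
        ode = ak.build_ode("model1", {"k1": 1.0, "km1": 0.0})
        dy = ode(0.0, {"R": 1.0, "L": 1.0, "B": 0.0})
        assert dy["B"] == pytest.approx(1.0)
        assert dy["R"] == pytest.approx(-1.0)
        assert dy["L"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("sid", ["model1", "model2", "model3", "model4", "model5"])
    def test_all_rates_zero_gives_zero_derivatives(self, sid):
        scheme = ak.get_scheme(sid)
        rates = {sym: 0.0 for sym in scheme.rate_symbols}
        ode = ak.build_ode(scheme, rates)
        state = {name: 1.0 for name in scheme.species_names}
        assert all(v == 0.0 for v in ode(0.0, state).values())

    def test_model4_intermediate_formation_rate(self, a_model4):
        # dI/dt at mixing = k1 * R0 * L0 with the two-step A parameters
        scheme, rates = a_model4
        ode = ak.build_ode(scheme, rates)
        dy = ode(0.0, {"R": 2.0, "L": 4.0, "I": 0.0, "B": 0.0})
        assert dy["I"] == pytest.approx(10.0 * 2.0 * 4.0)

    def test_missing_rate_symbol_named_in_error(self):
        with pytest.raises(ConfigurationError, match="km1"):
            ak.build_ode("model1", {"k1": 1.0})

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError, match="negative"):
            ak.build_ode("model1", {"k1": 1.0, "km1": -0.1})


class TestSimulate:
    def test_pseudo_first_order_receptor_decay(self, time_grid):
        # R(t) ~ R0 exp(-k1 L0 t) when ligand is in vast excess; the residual
        # deviation is the O(R0/L0) ligand-depletion error, here 1e-4
        traj = ak.simulate(
            "model1", {"k1": 1.0, "km1": 0.0},
            {"R": 0.001, "L": 10.0, "B": 0.0}, time_grid,
        )
        np.testing.assert_allclose(
            traj["R"], 0.001 * np.exp(-10.0 * time_grid), rtol=1e-3, atol=1e-12
        )

    def test_equilibrium_bound_fraction_model1(self, time_grid):
        k1, km1, L0, R0 = 7.78, 0.33, 4.0, 0.01
        grid = np.linspace(0.0, 20.0, 50)
        traj = ak.simulate("model1", {"k1": k1, "km1": km1},
                           {"R": R0, "L": L0, "B": 0.0}, grid)
        bound_fraction = traj["B"][-1] / R0
        # the algebraic oracle ignores the 0.25% ligand depletion at R0=0.01
        assert bound_fraction == pytest.approx(L0 / (L0 + km1 / k1), rel=1e-3)

    @pytest.mark.parametrize(
        "preset", ["A-model1", "A-model4", "preRS-model4", "RS-model5"]
    )
    def test_mass_conservation(self, preset, time_grid):
        scheme, rates = ak.get_rate_preset(preset)
        init = ak.initial_state(scheme, 2.0, 8.0, rates)
        traj = ak.simulate(scheme, rates, init, time_grid)
        totals = traj.conserved_totals()
        assert np.max(np.abs(totals["L"] - 8.0)) < 1e-6
        assert np.max(np.abs(totals["R"] - 2.0)) < 1e-6

    def test_mass_conservation_model2(self, time_grid):
        rates = {"k_pre": 1.0, "k_unpre": 0.5, "k_on": 5.0, "k_off": 0.3}
        init = ak.initial_state("model2", 2.0, 8.0, rates)
        traj = ak.simulate("model2", rates, init, time_grid)
        totals = traj.conserved_totals()
        assert np.max(np.abs(totals["L"] - 8.0)) < 1e-6
        assert np.max(np.abs(totals["R"] - 2.0)) < 1e-6

    def test_model2_initial_state_preformation_split(self):
        rates = {"k_pre": 3.0, "k_unpre": 1.0, "k_on": 5.0, "k_off": 0.3}
        init = ak.initial_state("model2", 2.0, 8.0, rates)
        assert init["Ra"] == pytest.approx(1.5)
        assert init["Ri"] == pytest.approx(0.5)

    def test_detailed_balance_model4_at_equilibrium(self, a_model4):
        scheme, rates = a_model4
        grid = np.linspace(0.0, 50.0, 100)
        init = ak.initial_state(scheme, 2.0, 4.0, rates)
        traj = ak.simulate(scheme, rates, init, grid)
        R, L, I, B = (traj[s][-1] for s in ("R", "L", "I", "B"))
        assert rates["k1"] * R * L / I == pytest.approx(rates["km1"], rel=0.01)
        assert rates["k2"] * I / B == pytest.approx(rates["km2"], rel=0.01)

    def test_model5_bound_complex_monotone(self, time_grid):
        traj = ak.simulate(
            "model5", {"k1": 5.0, "km1": 0.0, "k2": 10.0},
            {"R": 2.0, "L": 8.0, "I": 0.0, "B": 0.0}, time_grid,
        )
        assert np.all(np.diff(traj["B"]) >= -1e-12)

    def test_batch_matches_single_simulations(self, a_model4, time_grid):
        scheme, rates = a_model4
        initials = [ak.initial_state(scheme, 2.0, L0, rates) for L0 in (4.0, 12.0)]
        batch = ak.simulate_batch(scheme, rates, initials, time_grid)
        for j, init in enumerate(initials):
            single = ak.simulate(scheme, rates, init, time_grid)
            np.testing.assert_allclose(
                batch[:, j, :], single.concentrations, rtol=1e-6, atol=1e-9
            )

    def test_invalid_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            ak.simulate("model1", {"k1": 1.0, "km1": 0.0},
                        {"R": 1.0, "L": 1.0}, np.array([0.1, 0.2]))
        with pytest.raises(ConfigurationError):
            ak.simulate("model1", {"k1": 1.0, "km1": 0.0},
                        {"R": 1.0, "L": 1.0}, np.array([0.0, 0.2, 0.1]))


class TestClosedFormOracle:
    def test_kobs_from_one_step_rates(self):
        assert ak.pfo_kobs(7.78, 0.33, 4.0) == pytest.approx(31.45)

    def test_complete_binding_when_no_back_rate(self, time_grid):
        b = ak.closed_form_model1_pfo(2.0, 0.0, 10.0, 0.5, time_grid)
        assert b[-1] == pytest.approx(0.5, rel=1e-6)

    def test_oracle_matches_simulation_under_ligand_excess(self):
        k1, km1, L0, R0 = 7.78, 0.33, 10.0, 0.1  # R0 = 0.01 * L0
        grid = np.linspace(0.0, 0.5, 200)
        closed = ak.closed_form_model1_pfo(k1, km1, L0, R0, grid)
        traj = ak.simulate("model1", {"k1": k1, "km1": km1},
                           {"R": R0, "L": L0, "B": 0.0}, grid)
        # residual difference is the depletion error, ~0.16% of R0 at this ratio
        assert np.max(np.abs(closed - traj["B"])) < 5e-3 * R0

    def test_parameter_validation(self, time_grid):
        with pytest.raises(ConfigurationError):
            ak.closed_form_model1_pfo(0.0, 0.1, 10.0, 0.1, time_grid)
        with pytest.raises(ConfigurationError):
            ak.closed_form_model1_pfo(1.0, 0.1, 1.0, 0.9, time_grid)


class TestApparentKd:
    def test_one_step_kd_vanishes_with_back_rate(self):
        assert ak.apparent_kd("model1", {"k1": 5.21, "km1": 1e-9}) < 1e-9

    def test_two_step_reversible_kd(self, a_model4):
        scheme, rates = a_model4
        assert ak.apparent_kd(scheme, rates) == pytest.approx(
            (1.6 / 10.0) * (2.3 / (4.0 + 2.3))
        )

    @pytest.mark.parametrize("sid,rates", [
        ("model5", {"k1": 7.62, "km1": 2.9, "k2": 23.0}),
        ("model3", {"k1": 5.0, "k2": 8.0}),
    ])
    def test_irreversible_sink_gives_zero(self, sid, rates):
        assert ak.apparent_kd(sid, rates) == 0.0

    def test_conformational_selection_unsupported(self):
        with pytest.raises(ConfigurationError, match="inactive"):
            ak.apparent_kd(
                "model2",
                {"k_pre": 1.0, "k_unpre": 1.0, "k_on": 5.0, "k_off": 0.5},
            )
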