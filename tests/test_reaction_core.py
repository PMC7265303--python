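"""Mass-action core: rate laws, Jacobians, conservation, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crisprikit.circuits import make_toggle
from crisprikit.errors import ConfigurationError, DomainError
from crisprikit.reaction_core import (
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
    conservation_laws,
    jacobian,
    network_from_json,
    network_from_text,
    network_to_json,
    network_to_sbml,
    network_to_text,
    rhs,
)

from conftest import finite_difference_jacobian


class TestRhs:
    def test_bimolecular_mass_action(self):
        net = ReactionNetwork(
            [Species("A"), Species("B"), Species("C")],
            [Reaction({"A": 1, "B": 1}, {"C": 1}, "k")],
        )
        dx = rhs(net, np.array([1.0, 3.0, 0.0]), ParameterSet({"k": 2.0}))
        assert np.allclose(dx, [-6.0, -6.0, 6.0])

    def test_birth_death_steady_state_identity(self, birth_death):
        net, params = birth_death
        assert rhs(net, np.array([2.0]), params)[0] == pytest.approx(0.0)

    def test_toggle_rhs_matches_per_reaction_flux_summation(self):
        """Independent oracle: sum each reaction's propensity into its
        species one reaction at a time."""
        net = make_toggle("unspecific_neutral")
        params = net.default_params
        x = net.initial_state(params)
        x[net.species_index("C1")] = 3.0
        x[net.species_index("C2")] = 7.0
        expected = np.zeros(net.n_species)
        for rxn in net.reactions:
            flux = params[rxn.rate_constant_name]
            for name, s in rxn.reactants.items():
                flux *= x[net.species_index(name)] ** s
            for name, s in rxn.reactants.items():
                expected[net.species_index(name)] -= s * flux
            for name, s in rxn.products.items():
                expected[net.species_index(name)] += s * flux
        assert np.allclose(rhs(net, x, params), expected, rtol=1e-12)

    def test_negative_state_rejected(self, birth_death):
        net, params = birth_death
        with pytest.raises(DomainError):
            rhs(net, np.array([-0.5]), params)

    def test_missing_parameter_named(self, birth_death):
        net, _ = birth_death
        with pytest.raises(ConfigurationError, match="delta"):
            rhs(net, np.array([1.0]), ParameterSet({"alpha": 1.0}))

    def test_constant_species_frozen(self):
        net = ReactionNetwork(
            [Species("I", "inducer", constant=True, init=5.0), Species("X")],
            [Reaction({"I": 1}, {"I": 1, "X": 1}, "k"), Reaction({"X": 1}, {}, "d")],
        )
        dx = rhs(net, np.array([5.0, 0.0]), ParameterSet({"k": 2.0, "d": 1.0}))
        assert dx[0] == 0.0
        assert dx[1] == pytest.approx(10.0)


class TestJacobian:
    def test_first_order_decay(self):
        net = ReactionNetwork([Species("X")], [Reaction({"X": 1}, {}, "d")])
        J = jacobian(net, np.array([3.7]), ParameterSet({"d": 0.3}))
        assert np.allclose(J, [[-0.3]])

    def test_bimolecular_product_rule(self):
        net = ReactionNetwork(
            [Species("A"), Species("B"), Species("C")],
            [Reaction({"A": 1, "B": 1}, {"C": 1}, "k")],
        )
        J = jacobian(net, np.array([1.5, 3.0, 0.0]), ParameterSet({"k": 2.0}))
        # d(dC/dt)/dA = k·B, d(dC/dt)/dB = k·A
        assert J[2, 0] == pytest.approx(2.0 * 3.0)
        assert J[2, 1] == pytest.approx(2.0 * 1.5)

    def test_second_order_self_reaction(self):
        net = ReactionNetwork([Species("X")], [Reaction({"X": 2}, {}, "k")])
        J = jacobian(net, np.array([4.0]), ParameterSet({"k": 0.5}))
        # d(-2·k·x²)/dx = -4·k·x
        assert np.allclose(J, [[-4.0 * 0.5 * 4.0]])

    @pytest.mark.parametrize("variant", ["specific_only", "unspecific_neutral"])
    def test_toggle_matches_finite_differences(self, variant):
        net = make_toggle(variant)
        params = net.default_params
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = rng.uniform(0.5, 50.0, net.n_species)
            J = jacobian(net, x, params)
            J_fd = finite_difference_jacobian(lambda v: rhs(net, v, params), x)
            assert np.allclose(J, J_fd, rtol=1e-5, atol=1e-5 * np.abs(J).max())


class TestConservation:
    def test_reversible_binding_totals(self, binding_network):
        net, _ = binding_network
        laws = conservation_laws(net)
        assert len(laws) == 2
        found = {tuple(w) for w in laws}
        assert (1.0, 0.0, 1.0) in found  # A + C
        assert (0.0, 1.0, 1.0) in found  # B + C

    @pytest.mark.parametrize("variant", ["specific_only", "unspecific_neutral",
                                         "unspecific_inhibitory"])
    def test_toggle_gene_totals_conserved(self, variant):
        net = make_toggle(variant)
        laws = conservation_laws(net)
        assert len(laws) == 2
        for w in laws:
            assert np.all(w >= 0)
            support = {net.species_names[i] for i in np.flatnonzero(w)}
            assert support <= {s.name for s in net.species if s.role == "gene_state"}

    def test_laws_annihilate_rhs_on_random_states(self):
        net = make_toggle("unspecific_neutral")
        params = net.default_params
        laws = conservation_laws(net)
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.uniform(0.0, 100.0, net.n_species)
            dx = rhs(net, x, params)
            for w in laws:
                assert abs(w @ dx) < 1e-12 * max(1.0, np.max(np.abs(dx)))


class TestValidation:
    def test_reactant_order_above_two_rejected(self):
        with pytest.raises(ConfigurationError, match="order"):
            Reaction({"A": 2, "B": 1}, {}, "k")

    def test_nonpositive_stoichiometry_rejected(self):
        with pytest.raises(ConfigurationError):
            Reaction({"A": 0}, {"B": 1}, "k")

    def test_duplicate_species_names_rejected(self):
        with pytest.raises(ConfigurationError, match="unique"):
            ReactionNetwork([Species("A"), Species("A")], [])

    def test_orphan_species_rejected(self):
        with pytest.raises(ConfigurationError, match="no reaction"):
            ReactionNetwork(
                [Species("A"), Species("B")],
                [Reaction({"A": 1}, {}, "k")],
            )

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            ParameterSet({"k": 0.0})
        with pytest.raises(ConfigurationError):
            ParameterSet({"k": -1.0})
        with pytest.raises(ConfigurationError):
            ParameterSet({"k": float("nan")})


class TestSerialization:
    def test_text_round_trip(self, binding_network):
        net, _ = binding_network
        text = network_to_text(net)
        assert "A + B -> C ; kon" in text
        back = network_from_text(text)
        assert back.n_reactions == net.n_reactions
        assert set(back.species_names) == set(net.species_names)

    def test_json_round_trip_preserves_structure(self):
        net = make_toggle("specific_only")
        back = network_from_json(network_to_json(net))
        assert back.species_names == net.species_names
        assert [r.format() for r in back.reactions] == [
            r.format() for r in net.reactions
        ]
        x = np.linspace(1.0, 2.0, net.n_species)
        params = net.default_params
        assert np.allclose(rhs(back, x, params), rhs(net, x, params))

    def test_sbml_export_is_valid_xml_with_all_species(self):
        from lxml import etree

        net = make_toggle("specific_only")
        doc = network_to_sbml(net, net.default_params)
        root = etree.fromstring(doc.encode())
        ns = "{http://www.sbml.org/sbml/level3/version2/core}"
        species = root.findall(f".//{ns}species")
        assert len(species) == net.n_species
        reactions = root.findall(f".//{ns}reaction")
        assert len(reactions) == net.n_reactions


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_random_networks_jacobian_matches_finite_differences(seed):
    """Property: analytic Jacobian agrees with central differences on
    randomized elementary networks with ≤ 20 species."""
    rng = np.random.default_rng(seed)
    n_sp = int(rng.integers(2, 12))
    names = [f"S{i}" for i in range(n_sp)]
    rxns = []
    for j in range(int(rng.integers(2, 20))):
        order = int(rng.integers(0, 3))
        reactants = {}
        for name in rng.choice(names, size=order, replace=True):
            reactants[name] = reactants.get(name, 0) + 1
        products = {str(rng.choice(names)): 1}
        rxns.append(Reaction(reactants, products, f"k{j}"))
    referenced = {n for r in rxns for n in list(r.reactants) + list(r.products)}
    species = [Species(n, constant=n not in referenced) for n in names]
    net = ReactionNetwork(species, rxns)
    params = ParameterSet({f"k{j}": float(rng.uniform(0.1, 5.0)) for j in range(len(rxns))})
    x = rng.uniform(0.1, 10.0, n_sp)
    J = jacobian(net, x, params)
    J_fd = finite_difference_jacobian(lambda v: rhs(net, v, params), x)
    assert np.allclose(J, J_fd, rtol=1e-5, atol=1e-6 * (1.0 + np.abs(J).max()))
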