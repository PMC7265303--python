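"""Simulation, steady-state enumeration and induction protocols."""

import numpy as np
import pytest

from crisprikit.circuits import make_not_gate_scaled, make_toggle
from crisprikit.dynamics import (
    InductionProtocol,
    Phase,
    ReducedSystem,
    conservation_drift,
    find_steady_states,
    run_protocol,
    simulate,
    steady_state_observable,
)
from crisprikit.errors import ConfigurationError, DomainError


class TestSimulate:
    def test_birth_death_closed_form(self, birth_death):
        """X(t) = (alpha/delta)(1 − e^{−delta·t}) from X(0) = 0."""
        net, params = birth_death
        ts = simulate(net, params, x0=np.zeros(1), t_end=5.0, n_points=101)
        expected = 2.0 * (1.0 - np.exp(-ts.t))
        assert np.allclose(ts.x[:, 0], expected, rtol=1e-6, atol=1e-8)
        assert ts.x[-1, 0] == pytest.approx(1.9865, abs=2e-4)

    def test_nonnegative_and_increasing_grid(self, birth_death):
        net, params = birth_death
        with pytest.raises(DomainError):
            simulate(net, params, x0=np.array([-1.0]))
        with pytest.raises(ConfigurationError):
            simulate(net, params, t_grid=np.array([0.0, 1.0, 1.0]))

    def test_conservation_drift_small_over_long_toggle_run(self):
        net = make_toggle("unspecific_neutral")
        ts = simulate(net, net.default_params, t_end=100.0, n_points=101)
        assert conservation_drift(ts, net) < 1e-6

    def test_observables_are_linear_combinations(self, birth_death):
        net, params = birth_death
        ts = simulate(net, params, t_end=1.0)
        assert np.allclose(ts.channel("X"), ts.x[:, 0])


class TestFindSteadyStates:
    def test_birth_death_unique_stable_root(self, birth_death):
        net, params = birth_death
        eqs = find_steady_states(net, params, n_starts=5, seed=0)
        assert len(eqs) == 1
        eq = eqs.equilibria[0]
        assert eq.stability == "stable"
        assert eq.state[0] == pytest.approx(2.0, rel=1e-8)

    def test_monostable_endpoint_matches_root(self):
        """Long-run simulation endpoint equals the unique Newton root."""
        net = make_not_gate_scaled(5.0)
        params = net.default_params
        eqs = find_steady_states(net, params, n_starts=10, seed=1)
        assert len(eqs.stable) == 1
        ts = simulate(net, params, t_end=400.0, n_points=41)
        root = eqs.stable[0].state
        assert np.allclose(ts.x[-1], root, rtol=1e-4, atol=1e-6 * root.max())

    def test_symmetric_toggle_equilibria_closed_under_node_swap(self):
        """With symmetric parameters the species-swap map preserves the
        equilibrium set."""
        net = make_toggle("unspecific_neutral")
        params = net.default_params  # symmetric defaults
        eqs = find_steady_states(net, params, n_starts=20, seed=2)
        swap = {}
        for name in net.species_names:
            if name.startswith("G1"):
                other = "G2" + name[2:]
            elif name.startswith("G2"):
                other = "G1" + name[2:]
            elif name in ("r1", "C1"):
                other = name[0] + "2"
            elif name in ("r2", "C2"):
                other = name[0] + "1"
            else:
                other = name
            swap[net.species_index(name)] = net.species_index(other)
        # swapping unspecific-occupancy identity too: G_i_{s}1 <-> G_i_{s}2
        def swap_state(x):
            y = np.zeros_like(x)
            for i, j in swap.items():
                y[j] = x[i]
            return y

        for eq in eqs:
            # skip reporter (gene-2 only, breaks strict symmetry)
            mask = [i for i, n in enumerate(net.species_names)
                    if not n.startswith("P") and "_" not in n[3:]]
            swapped = swap_state(eq.state)
            dists = [
                np.max(np.abs(np.log((swapped[mask] + 1e-6) / (other.state[mask] + 1e-6))))
                for other in eqs
            ]
            assert min(dists) < 0.2

    def test_stability_labels_invariant_to_budget_refinement(self):
        net = make_toggle("specific_only")
        params = net.default_params
        a = find_steady_states(net, params, n_starts=10, seed=3)
        b = find_steady_states(net, params, n_starts=20, seed=4)
        assert sorted(e.stability for e in a) == sorted(e.stability for e in b)
        assert len(a) == len(b)


class TestReducedSystem:
    def test_round_trip_and_conservation(self):
        net = make_toggle("specific_only")
        params = net.default_params
        red = ReducedSystem(net, params=params)
        x0 = net.initial_state(params)
        assert np.allclose(red.full_state(red.reduce_state(x0)), x0)
        assert red.n_reduced == net.n_species - 2

    def test_reduced_jacobian_consistent_with_finite_difference(self):
        from conftest import finite_difference_jacobian

        net = make_toggle("specific_only")
        params = net.default_params
        red = ReducedSystem(net, params=params)
        # interior state: spread each conserved total across its states
        x_full = np.full(net.n_species, 3.0)
        for w, total in zip(red.W, red.totals):
            sup = np.flatnonzero(w)
            x_full[sup] = total / (w[sup] * len(sup))
        x = red.reduce_state(x_full)
        J = red.jac(x, params)
        J_fd = finite_difference_jacobian(lambda v: red.f(v, params), x)
        assert np.allclose(J, J_fd, rtol=1e-5, atol=1e-5 * (1 + np.abs(J).max()))


class TestProtocols:
    def test_single_phase_no_dilution_equals_simulate(self, birth_death):
        net, params = birth_death
        proto = InductionProtocol([Phase(None, 0.0, 3.0, 1.0)])
        ts_p = run_protocol(net, params, proto, x0=np.zeros(1))
        ts_s = simulate(net, params, x0=np.zeros(1),
                        t_grid=ts_p.t)
        assert np.allclose(ts_p.x, ts_s.x, rtol=1e-6, atol=1e-9)

    def test_dilution_divides_free_molecules_not_genes(self):
        net = make_toggle("specific_only")
        params = net.default_params
        # second phase is vanishingly short: its end state is, up to
        # integration over 1e-6 h, the post-dilution state
        proto = InductionProtocol([
            Phase(None, 0.0, 1.0, 1.0),
            Phase(None, 0.0, 1e-6, 120.0),
        ])
        ts = run_protocol(net, params, proto)
        end1 = ts.phases[0]["end_state"]
        end2 = ts.phases[1]["end_state"]
        for i, sp in enumerate(net.species):
            if sp.role == "gene_state":
                assert end2[i] == pytest.approx(end1[i], rel=1e-3, abs=1e-6)
            elif end1[i] > 1e-6:
                assert end2[i] == pytest.approx(end1[i] / 120.0, rel=1e-2)

    def test_phase_validation(self):
        with pytest.raises(ConfigurationError):
            Phase(None, 0.0, -1.0)
        with pytest.raises(ConfigurationError):
            Phase(None, 0.0, 1.0, 0.5)

    def test_unknown_inducer_rejected(self, birth_death):
        net, params = birth_death
        proto = InductionProtocol([Phase("IPTG", 1.0, 1.0)])
        with pytest.raises(ConfigurationError, match="IPTG"):
            run_protocol(net, params, proto, x0=np.zeros(1))


def test_steady_state_observable_matches_analytic(birth_death):
    net, params = birth_death
    assert steady_state_observable(net, params, "X") == pytest.approx(2.0, rel=1e-6)
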