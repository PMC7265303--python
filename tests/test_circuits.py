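"""Circuit factories: presets, calibration, composition, inducer maps."""

import numpy as np
import pytest

from crisprikit.circuits import (
    ARA_MAP,
    InducerMap,
    PRESET_TARGET_FOLD,
    TOGGLE_WITNESS_NEUTRAL,
    calibrate_binding,
    compose,
    make_iffl,
    make_not_gate,
    make_not_gate_scaled,
    make_ring,
    make_toggle,
    make_toggle_control,
    measure_max_fold_repression,
    preset_scale,
    toggle_params,
)
from crisprikit.errors import CalibrationError, ConfigurationError
from crisprikit.reaction_core import conservation_laws
from crisprikit.dynamics import find_steady_states, steady_state_observable


class TestInducerMap:
    def test_leaky_at_zero_and_saturating(self):
        m = InducerMap(basal=0.01, K=0.02, n=2.0, beta_max=500.0)
        assert m.rate(0.0) == pytest.approx(5.0)
        assert m.rate(float("inf")) == pytest.approx(500.0)
        assert m.rate(m.K) == pytest.approx(0.5 * (500.0 + 5.0), rel=1e-2)

    def test_monotone_increasing(self):
        m = ARA_MAP
        doses = np.geomspace(1e-5, 10.0, 50)
        rates = [m.rate(d) for d in doses]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_invalid_basal_rejected(self):
        with pytest.raises(ConfigurationError):
            InducerMap(basal=0.0)
        with pytest.raises(ConfigurationError):
            InducerMap(basal=1.5)


class TestNotGate:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError, match="preset"):
            make_not_gate("sg9")

    def test_no_sgrna_control_equals_unrepressed_reporter(self):
        net = make_not_gate_scaled(5.0)
        params = net.default_params.updated(beta_r1=1e-12)
        rep = steady_state_observable(net, params, "reporter")
        # analytic unrepressed level: beta_p * g_total / delta_p
        expected = params["beta_p"] * params["g_total"] / params["delta_p"]
        assert rep == pytest.approx(expected, rel=1e-4)

    def test_fold_repression_monotone_in_binding_scale(self):
        folds = [measure_max_fold_repression(make_not_gate_scaled(s))
                 for s in (0.3, 1.0, 3.0, 10.0)]
        assert all(b > a for a, b in zip(folds, folds[1:]))

    def test_preset_ordering_matches_targets(self):
        # sg2 strongest, t4 presets strictly below their parents
        scales = {p: preset_scale(p) for p in PRESET_TARGET_FOLD}
        assert max(scales, key=scales.get) == "sg2"
        assert scales["sg1_t4"] < scales["sg1"]
        assert scales["sg4_t4"] < scales["sg4"]

    def test_leaky_inducer_represses_slightly_at_zero_dose(self):
        net = make_not_gate_scaled(10.0)
        params = net.default_params.updated(beta_r1=ARA_MAP.rate(0.0))
        rep0 = steady_state_observable(net, params, "reporter")
        control = steady_state_observable(
            net, net.default_params.updated(beta_r1=1e-12), "reporter")
        assert rep0 < control  # leak gives weak repression without inducer
        assert control / rep0 < 2.0


class TestCalibration:
    @pytest.mark.parametrize("target", [5.0, 15.0, 30.0])
    def test_round_trip(self, target):
        scale = calibrate_binding(lambda s: make_not_gate_scaled(s), target)
        fold = measure_max_fold_repression(make_not_gate_scaled(scale))
        assert fold == pytest.approx(target, abs=1e-3 * target)

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_binding(lambda s: make_not_gate_scaled(s), 1e6)
        with pytest.raises(CalibrationError):
            calibrate_binding(lambda s: make_not_gate_scaled(s), 0.5)


class TestToggleFactory:
    @pytest.mark.parametrize("variant,n_states", [
        ("specific_only", 2), ("unspecific_neutral", 6), ("unspecific_inhibitory", 6),
    ])
    def test_gene_state_count(self, variant, n_states):
        net = make_toggle(variant)
        genes1 = [s for s in net.species if s.name.startswith("G1")]
        assert len(genes1) == n_states

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            make_toggle("fancy")

    def test_inhibitory_blocks_transcription_from_occupied_unspecific_site(self):
        neutral = make_toggle("unspecific_neutral")
        inhib = make_toggle("unspecific_inhibitory")
        # the neutral variant transcribes from u=1,2 states; inhibitory doesn't
        def production_reactions(net):
            return {r.format() for r in net.reactions
                    if "r1" in r.products and r.reactants}
        assert production_reactions(inhib) < production_reactions(neutral)

    def test_gene_conservation_one_per_gene(self):
        for variant in ("specific_only", "unspecific_neutral"):
            assert len(conservation_laws(make_toggle(variant))) == 2

    def test_controls_disable_one_repression_arm(self):
        cl = make_toggle_control("cL")
        assert cl.default_params["beta1"] < 1e-6
        cr = make_toggle_control("cR")
        assert cr.default_params["beta2"] < 1e-6

    def test_shipped_witness_is_bistable_both_unspecific_variants(self):
        for variant in ("unspecific_neutral", "unspecific_inhibitory"):
            net = make_toggle(variant)
            params = toggle_params(variant, **TOGGLE_WITNESS_NEUTRAL)
            eqs = find_steady_states(net, params, n_starts=16, seed=0)
            assert len(eqs.stable) == 2
            assert len(eqs.unstable) == 1


class TestRing:
    def test_closed_ring_has_three_repression_edges(self):
        net = make_ring(False)
        edges = [r for r in net.reactions
                 if r.rate_constant_name == "k_s_eff"]
        assert len(edges) == 3

    def test_open_ring_removes_edge_into_node_one(self):
        net = make_ring(True)
        edges = [r for r in net.reactions if r.rate_constant_name == "k_s_eff"]
        assert len(edges) == 2
        assert not any("G1_0" in r.reactants for r in edges)

    def test_gene_conservation(self):
        assert len(conservation_laws(make_ring(False))) == 3


class TestIffl:
    def test_second_edge_removed_makes_response_monotone_decreasing(self):
        from crisprikit.phenotypes import default_dose_grid, dose_response

        net = make_iffl("set1")
        p = net.default_params
        net.default_params = p.updated(k_sC=1e-12)
        dr = dose_response(net, default_dose_grid(n=8), observables=["N3"])
        v = dr.values["N3"]
        assert v[0] == max(v)
        assert v[-1] == min(v)

    def test_weak_edge_removed_makes_response_increasing_at_high_dose(self):
        from crisprikit.phenotypes import default_dose_grid, dose_response

        net = make_iffl("set1")
        p = net.default_params
        net.default_params = p.updated(k_sB=1e-12)
        dr = dose_response(net, default_dose_grid(n=8), observables=["N3"])
        v = dr.values["N3"]
        assert v[-1] > 2.0 * v[0]  # pure double inversion: high at high input

    def test_single_reporter_variant_smaller(self):
        full = make_iffl("set1")
        single = make_iffl("set1", single_reporter=True)
        assert single.n_species == full.n_species - 2


class TestCompose:
    def test_self_composition_name_collision(self):
        a = make_iffl("set1")
        with pytest.raises(ConfigurationError, match="collision"):
            compose(a, make_iffl("set1"))

    def test_shared_dcas9_pool_merged_once(self):
        a = make_iffl("set1", prefix="a_")
        b = make_iffl("set2", prefix="b_")
        duo = compose(a, b)
        assert sum(1 for s in duo.species if s.name == "D") == 1
        production = [r for r in duo.reactions
                      if not r.reactants and r.products == {"D": 1}]
        assert len(production) == 1

    def test_composed_parameters_union(self):
        a = make_iffl("set1", prefix="a_")
        b = make_iffl("set2", prefix="b_")
        duo = compose(a, b)
        for k in a.default_params:
            assert k in duo.default_params
        for k in b.default_params:
            assert k in duo.default_params


class TestDecoyPool:
    def test_optional_decoy_pool_adds_conserved_site_family(self):
        from crisprikit.reaction_core import conservation_laws

        net = make_toggle("unspecific_neutral", decoy_sites=500.0)
        assert "U_free" in net.species_names
        laws = conservation_laws(net)
        assert len(laws) == 3  # two genes + the decoy pool
        assert net.default_params["decoy_total"] == 500.0
        eqs = find_steady_states(net, net.default_params, n_starts=8, seed=0)
        assert len(eqs) >= 1

    def test_decoy_pool_off_by_default(self):
        net = make_toggle("unspecific_neutral")
        assert "U_free" not in net.species_names
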