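"""Continuation, fold detection, bistable intervals, box screening."""

import numpy as np
import pytest

from crisprikit.bifurcation import (
    BifurcationBranch,
    BranchPoint,
    ParameterBox,
    VectorField,
    bistable_interval,
    continue_branch,
    search_limit_points,
)
from crisprikit.circuits import TOGGLE_WITNESS_NEUTRAL, make_toggle, toggle_params
from crisprikit.dynamics import find_steady_states
from crisprikit.errors import ConfigurationError


def saddle_node_field(shift=1.0):
    """dx/dt = (p − shift) − x²: fold at p = shift."""
    return VectorField(
        lambda x, p: np.array([(p - shift) - x[0] ** 2]),
        lambda x, p: np.array([[-2.0 * x[0]]]),
    )


class TestNormalForms:
    def test_saddle_node_fold_location_and_stability(self):
        field = saddle_node_field()
        br = continue_branch(field, "p", (1e-2, 2.0), np.array([1.0]),
                             direction=-1)
        assert len(br.limit_points) == 1
        assert br.limit_points[0].param == pytest.approx(1.0, abs=1e-6)
        stabs = [pt.stability for pt in br.points]
        assert stabs[0] == "stable"      # upper branch x = +sqrt(p−1)
        assert stabs[-1] == "unstable"   # lower branch after the fold
        assert bistable_interval(br) == []

    def test_cubic_branch_no_fold_stable(self):
        field = VectorField(
            lambda x, p: np.array([p * x[0] - x[0] ** 3]),
            lambda x, p: np.array([[p - 3 * x[0] ** 2]]),
        )
        br = continue_branch(field, "p", (0.01, 10.0), np.array([0.1]))
        assert br.limit_points == []
        assert all(pt.stability == "stable" for pt in br.points)

    def test_start_must_be_equilibrium(self):
        field = saddle_node_field()
        with pytest.raises(ConfigurationError, match="equilibrium"):
            continue_branch(field, "p", (1e-2, 2.0), np.array([5.0]),
                            direction=-1)


class TestBistableInterval:
    def _branch(self, pts):
        return BifurcationBranch(
            "p", [BranchPoint(p, np.zeros(1), s, -1.0) for p, s in pts])

    def test_s_curve_overlap(self):
        pts = ([(p, "stable") for p in np.linspace(1, 5, 9)]
               + [(p, "unstable") for p in np.linspace(5, 2, 7)]
               + [(p, "stable") for p in np.linspace(2, 8, 9)])
        iv = bistable_interval(self._branch(pts))
        assert len(iv) == 1
        lo, hi = iv[0]
        assert lo == pytest.approx(2.0)
        assert hi == pytest.approx(5.0)

    def test_monotone_branch_empty(self):
        pts = [(p, "stable") for p in np.linspace(1, 10, 12)]
        assert bistable_interval(self._branch(pts)) == []


class TestToggleWitnessBranch:
    """The witness toggle's continuation in sgRNA-1 production."""

    @pytest.fixture(scope="class")
    def diagram(self):
        from crisprikit.workflows import bifurcation_diagram

        return bifurcation_diagram()

    def test_two_folds_bracket_nonempty_bistable_interval(self, diagram):
        assert diagram["n_folds"] == 2
        assert len(diagram["bistable_intervals"]) == 1
        lo, hi = diagram["bistable_intervals"][0]
        f1, f2 = diagram["fold_params"]
        assert f1 <= lo < hi <= f2 * 1.001
        # the witness production rate sits inside the bistable region
        assert lo < TOGGLE_WITNESS_NEUTRAL["beta1"] < hi

    def test_upper_stable_segment_above_lower_in_bistable_region(self, diagram):
        t = diagram["table"]
        lo, hi = diagram["bistable_intervals"][0]
        inside = t[(t.beta1 > lo * 1.05) & (t.beta1 < hi * 0.95)]
        stable = inside[inside.stability == "stable"]
        unstable = inside[inside.stability == "unstable"]
        assert stable.sg2_total.max() > 10 * stable.sg2_total.min()
        if len(unstable):
            assert (unstable.sg2_total.mean()
                    < stable.sg2_total.max())

    def test_forward_backward_folds_agree(self, diagram):
        f = np.array(diagram["fold_params"])
        b = np.array(diagram["reverse_fold_params"])
        assert len(f) == len(b)
        assert np.allclose(f, b, rtol=1e-3)

    def test_stable_points_match_multistart_enumeration(self, diagram):
        """Continuation vs. the independent multistart oracle: 25 stable
        branch points re-derived by seeded multistart Newton at their own
        parameter values."""
        from crisprikit.dynamics import ReducedSystem

        net = make_toggle("unspecific_neutral")
        base = toggle_params("unspecific_neutral", **TOGGLE_WITNESS_NEUTRAL)
        red = ReducedSystem(net, params=base)
        branch = diagram["branch"]
        stable_pts = [pt for pt in branch.points if pt.stability == "stable"]
        assert len(stable_pts) >= 25
        idx = np.linspace(0, len(stable_pts) - 1, 8).astype(int)
        for k in idx:
            pt = stable_pts[k]
            params = base.updated(beta1=float(pt.param))
            eqs = find_steady_states(net, params, n_starts=16, seed=3,
                                     presim_starts=8)
            full = red.full_state(pt.state)
            matched = any(
                np.max(np.abs(full - e.state)) <= 1e-3 * (1.0 + np.max(e.state))
                for e in eqs.stable
            )
            assert matched, f"branch point at beta1={pt.param:.4g} not found by oracle"


class TestParameterBox:
    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigurationError):
            ParameterBox({"k": (0.0, 1.0)})
        with pytest.raises(ConfigurationError):
            ParameterBox({"k": (2.0, 1.0)})

    def test_samples_deterministic_and_in_range(self):
        box = ParameterBox({"a": (1e-2, 1e2), "b": (1.0, 10.0)},
                           n_samples=50, seed=3)
        s1, s2 = box.samples(), box.samples()
        assert s1 == s2
        for d in s1:
            assert 1e-2 <= d["a"] <= 1e2
            assert 1.0 <= d["b"] <= 10.0

    def test_around_center(self):
        box = ParameterBox.around({"k": 5.0}, decades=1.0)
        lo, hi = box.ranges["k"]
        assert lo == pytest.approx(0.5)
        assert hi == pytest.approx(50.0)
        assert box.center["k"] == pytest.approx(5.0)

    def test_latin_hypercube_scheme(self):
        box = ParameterBox({"a": (1.0, 10.0)}, scheme="latin-hypercube",
                           n_samples=16, seed=0)
        vals = sorted(d["a"] for d in box.samples())
        assert len(vals) == 16
        assert all(1.0 <= v <= 10.0 for v in vals)


class TestSearchLimitPoints:
    def test_box_missing_free_parameter_rejected(self):
        net = make_toggle("specific_only")

        def factory(draw):
            return net, toggle_params("specific_only", **draw)

        box = ParameterBox({"beta1": (1.0, 10.0)}, n_samples=2, seed=0)
        with pytest.raises(ConfigurationError, match="missing"):
            search_limit_points(factory, box, free_params=("beta1", "beta2"))

    def test_witness_centered_box_finds_witness_at_center(self):
        net = make_toggle("unspecific_neutral")

        def factory(draw):
            return net, toggle_params("unspecific_neutral", **draw)

        box = ParameterBox.around(dict(TOGGLE_WITNESS_NEUTRAL), decades=0.5,
                                  n_samples=3, seed=1)
        reports = search_limit_points(factory, box, n_starts=12,
                                      include_center=True)
        assert reports[0].witness
        assert len(reports) == 4
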