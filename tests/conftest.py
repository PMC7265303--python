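import numpy as np
import pytest

from crisprikit.reaction_core import (
    ParameterSet,
    Reaction,
    ReactionNetwork,
    Species,
)


def finite_difference_jacobian(fun, x, eps=1e-6):
    """Central finite differences of a vector function; test oracle."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    f0 = np.asarray(fun(x))
    J = np.zeros((len(f0), n))
    for i in range(n):
        h = eps * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] = max(xm[i] - h, 0.0)
        J[:, i] = (np.asarray(fun(xp)) - np.asarray(fun(xm))) / (xp[i] - xm[i])
    return J


@pytest.fixture
def birth_death():
    """∅ → X at alpha, X → ∅ at delta; steady state alpha/delta."""
    net = ReactionNetwork(
        [Species("X", "protein")],
        [Reaction({}, {"X": 1}, "alpha"), Reaction({"X": 1}, {}, "delta")],
        outputs={"X": {"X": 1.0}},
        name="birth_death",
    )
    return net, ParameterSet({"alpha": 2.0, "delta": 1.0})


@pytest.fixture
def binding_network():
    """A + B ⇌ C with conserved totals A+C and B+C."""
    net = ReactionNetwork(
        [Species("A", "protein"), Species("B", "protein"), Species("C", "complex")],
        [
            Reaction({"A": 1, "B": 1}, {"C": 1}, "kon"),
            Reaction({"C": 1}, {"A": 1, "B": 1}, "koff"),
        ],
        name="binding",
    )
    return net, ParameterSet({"kon": 2.0, "koff": 0.5})
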