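"""Factories for CRISPRi circuit models.

Builds the four circuit topologies studied in the package — the NOT gate,
the toggle switch, the stripe-forming type-2 incoherent feed-forward loop
(IFFL) and the 3-node ring oscillator ("CRISPRlator") — as mass-action
:class:`~crisprikit.reaction_core.ReactionNetwork` objects, together with
documented default parameterizations and calibration utilities.

Modeling conventions
--------------------
* Nodes are transcription units on a multicopy plasmid (default 10
  copies/cell).  A repressed node is a gene whose promoter-proximal
  operator can be occupied by a dCas9:sgRNA complex; occupancy sterically
  blocks transcription except for a small leak fraction.
* dCas9 (``D``) is produced constitutively and forms complexes ``C_i``
  with sgRNAs ``r_i``.  Complexes bound to DNA are cleared at the dilution
  rate (replication-driven loss), reflecting the very slow intrinsic
  dissociation of dCas9 from DNA.
* Inducer inputs (arabinose, AHL) enter as Hill-shaped production-rate
  modifiers on the induced node's transcription — the mass-action core
  itself stays strictly elementary.
* The toggle switch carries, per target gene, one *specific* operator for
  its cognate repressor complex and one *unspecific* (PAM-scanning
  surrogate) site that either repressor complex can occupy.  Specific and
  unspecific binding are independent (non-cooperative).  The
  ``unspecific_neutral`` variant transcribes regardless of unspecific-site
  occupancy; ``unspecific_inhibitory`` blocks transcription when either
  site is occupied; ``specific_only`` omits unspecific sites entirely.

Units: hours and molecules per cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigurationError
from .reaction_core import ParameterSet, Reaction, ReactionNetwork, Species

TOGGLE_VARIANTS = ("specific_only", "unspecific_neutral", "unspecific_inhibitory")


@dataclass(frozen=True)
class InducerMap:
    """Hill-shaped inducer → production-rate map.

    ``rate(c) = beta_max * (basal + (1 - basal) * c^n / (c^n + K^n))``

    ``basal`` is the leak fraction at zero inducer (promoters such as
    P_BAD are leaky), ``K`` the half-maximal concentration in the
    inducer's natural units (% arabinose, µM AHL), ``n`` the Hill
    exponent and ``beta_max`` the fully induced production rate in
    molecules/h.
    """

    basal: float = 1e-3
    K: float = 0.02
    n: float = 2.0
    beta_max: float = 600.0
    name: str = "inducer"

    def __post_init__(self) -> None:
        if not (0.0 < self.basal < 1.0):
            raise ConfigurationError("InducerMap basal fraction must be in (0,1)")
        if self.K <= 0 or self.n <= 0 or self.beta_max <= 0:
            raise ConfigurationError("InducerMap K, n, beta_max must be positive")

    def rate(self, concentration: float) -> float:
        if concentration < 0:
            raise ConfigurationError("inducer concentration must be nonnegative")
        if concentration == 0.0:
            return self.basal * self.beta_max
        if math.isinf(concentration):
            return self.beta_max
        h = concentration**self.n
        return self.beta_max * (self.basal + (1.0 - self.basal) * h / (h + self.K**self.n))


#: Default arabinose map: K = 0.02 % Ara (dose responses span 0–0.2 %), n = 2.
ARA_MAP = InducerMap(basal=1e-3, K=0.02, n=2.0, beta_max=600.0, name="Ara")
#: Default AHL map: K = 1 µM (doses up to 10 µM).
AHL_MAP = InducerMap(basal=1e-3, K=1.0, n=2.0, beta_max=600.0, name="AHL")


# ---------------------------------------------------------------------------
# Shared default rate constants
# ---------------------------------------------------------------------------

#: Dilution rate: ln 2 / 0.71 h doubling time, from the observed
#: period-to-generations correspondence (≈11 h ≈ 15.5 generations).
DELTA_DIL = math.log(2) / 0.71

_BASE_RATES = {
    "delta": DELTA_DIL,        # 1/h, growth dilution (applies to all species)
    "delta_r": 6.0,            # 1/h, sgRNA turnover (Csy4-processed small RNA)
    "delta_p": 2.0,            # 1/h, reporter turnover (degradation-tagged)
    "alpha_D": 500.0,          # molecules/h, constitutive dCas9 production
    "k_c": 0.1,                # 1/(molecule·h), dCas9 + sgRNA complex formation
    "k_s": 0.01,               # 1/(molecule·h), base specific operator binding
    "k_ms": 0.01,              # 1/h, specific unbinding (dilution-dominated)
    "beta_p": 30.0,            # molecules/(copy·h), reporter production
    "leak_b": 0.01,            # leak fraction of a CRISPRi-blocked promoter
    "g_total": 10.0,           # plasmid copies per cell
}

_BASE_PROVENANCE = {
    "delta": "ln2 / 0.71 h doubling time (period-to-generations correspondence)",
    "delta_r": "minutes-scale sgRNA half-life, package default",
    "delta_p": "degradation-tagged fluorescent reporter, package default",
    "alpha_D": "constitutive dCas9 vector; free pool ~500 molecules/cell",
    "k_c": "fast dCas9:sgRNA loading, package default",
    "k_s": "base specific dCas9 target binding; presets scale this",
    "k_ms": "specific dissociation slower than dilution",
    "beta_p": "strong promoter, per plasmid copy",
    "leak_b": "residual transcription from an occupied operator",
    "g_total": "medium-copy variable vector",
}


# ---------------------------------------------------------------------------
# sgRNA preset table
# ---------------------------------------------------------------------------

#: Target maximal fold-repression per sgRNA preset.  Only the 10–30-fold
#: window and the ordering (sgRNA-2 strongest) are experimentally pinned;
#: sg2 sits at the top of the window, sg3 at the bottom, sg1 and sg4 at
#: documented interior values.  The t4 (5'-truncated) presets are derived
#: from their parents by the measured 20 % / 45 % reductions in maximal
#: repression.
PRESET_TARGET_FOLD = {
    "sg1": 20.0,
    "sg2": 30.0,
    "sg3": 10.0,
    "sg4": 15.0,
    "sg1_t4": 20.0 * (1.0 - 0.20),
    "sg4_t4": 15.0 * (1.0 - 0.45),
}

_preset_scale_cache: dict[str, float] = {}


def preset_scale(preset: str) -> float:
    """Specific-binding scale for a named sgRNA preset.

    Obtained by calibrating the NOT-gate model so its maximal
    fold-repression hits the preset's documented target; cached after the
    first computation.
    """
    if preset not in PRESET_TARGET_FOLD:
        raise ConfigurationError(
            f"unknown sgRNA preset {preset!r}; known: {sorted(PRESET_TARGET_FOLD)}"
        )
    if preset not in _preset_scale_cache:
        target = PRESET_TARGET_FOLD[preset]
        _preset_scale_cache[preset] = calibrate_binding(
            lambda s: make_not_gate_scaled(s), target
        )
    return _preset_scale_cache[preset]


# ---------------------------------------------------------------------------
# NOT gate
# ---------------------------------------------------------------------------


def _not_gate_network() -> ReactionNetwork:
    species = [
        Species("r1", "rna", "sgRNA produced by the induced node N1"),
        Species("D", "protein", "free dCas9"),
        Species("C1", "complex", "dCas9:sgRNA-1"),
        Species("G2_free", "gene_state", "N2 gene, operator free", init="g_total"),
        Species("G2_bound", "gene_state", "N2 gene, operator occupied"),
        Species("P", "protein", "N2 fluorescent reporter (sfGFP)"),
    ]
    rxns = [
        Reaction({}, {"r1": 1}, "beta_r1", "inducible sgRNA production"),
        Reaction({"r1": 1}, {}, "delta_r", "sgRNA turnover"),
        Reaction({}, {"D": 1}, "alpha_D", "dCas9 production"),
        Reaction({"D": 1}, {}, "delta", "dCas9 dilution"),
        Reaction({"D": 1, "r1": 1}, {"C1": 1}, "k_c", "complex formation"),
        Reaction({"C1": 1}, {}, "delta", "complex dilution"),
        Reaction({"C1": 1, "G2_free": 1}, {"G2_bound": 1}, "k_s_eff", "specific binding"),
        Reaction({"G2_bound": 1}, {"G2_free": 1, "C1": 1}, "k_ms", "specific unbinding"),
        Reaction({"G2_bound": 1}, {"G2_free": 1}, "delta", "replication clearance"),
        Reaction({"G2_free": 1}, {"G2_free": 1, "P": 1}, "beta_p", "reporter production"),
        Reaction({"G2_bound": 1}, {"G2_bound": 1, "P": 1}, "beta_p_leak", "leak"),
        Reaction({"P": 1}, {}, "delta_p", "reporter turnover"),
    ]
    return ReactionNetwork(
        species,
        rxns,
        outputs={"reporter": {"P": 1.0}, "sgRNA": {"r1": 1.0}},
        name="not_gate",
    )


def not_gate_params(scale: float, inducer_map: InducerMap = ARA_MAP,
                    **overrides: float) -> ParameterSet:
    vals = dict(_BASE_RATES)
    vals.update(overrides)
    vals["k_s_eff"] = vals["k_s"] * scale
    vals["beta_r1"] = inducer_map.beta_max
    vals["beta_p_leak"] = vals["leak_b"] * vals["beta_p"]
    prov = dict(_BASE_PROVENANCE)
    prov["k_s_eff"] = f"k_s × preset scale {scale:g}"
    return ParameterSet(vals, prov)


def make_not_gate_scaled(scale: float,
                         inducer_map: InducerMap = ARA_MAP) -> ReactionNetwork:
    """NOT gate with an explicit specific-binding scale (calibration hook)."""
    net = _not_gate_network()
    net.inducer_inputs = {inducer_map.name: [("beta_r1", inducer_map)]}
    net.default_params = not_gate_params(scale, inducer_map)
    return net


def make_not_gate(preset: str = "sg2",
                  inducer_map: InducerMap = ARA_MAP) -> ReactionNetwork:
    """The 2-node NOT circuit: Ara induces N1's sgRNA, which represses N2.

    ``preset`` selects the sgRNA strength (``sg1``–``sg4`` and the
    truncated ``sg1_t4``/``sg4_t4`` variants).
    """
    return make_not_gate_scaled(preset_scale(preset), inducer_map)


# ---------------------------------------------------------------------------
# Toggle switch
# ---------------------------------------------------------------------------

#: Free kinetic parameters of the toggle models; the bistability search
#: samples exactly these (controller and reporter rates are instrument
#: settings, not model degrees of freedom).
TOGGLE_FREE_PARAMS = {
    "specific_only": (
        "beta1", "beta2", "leak_eps", "delta_r", "alpha_D", "delta",
        "k_c", "k_s", "k_ms", "g1_total", "g2_total",
    ),
    "unspecific_neutral": (
        "beta1", "beta2", "leak_eps", "delta_r", "alpha_D", "delta",
        "k_c", "k_s", "k_ms", "k_u", "k_mu", "g1_total", "g2_total",
    ),
    "unspecific_inhibitory": (
        "beta1", "beta2", "leak_eps", "delta_r", "alpha_D", "delta",
        "k_c", "k_s", "k_ms", "k_u", "k_mu", "g1_total", "g2_total",
    ),
}

#: Symmetric toggle defaults.  Unspecific affinity is far weaker than
#: specific (k_mu/k_u >> k_ms/k_s) and specific unbinding is slower than
#: dilution.
TOGGLE_DEFAULTS = {
    "beta1": 60.0,        # molecules/(copy·h), sgRNA-1 production (gene 1)
    "beta2": 60.0,        # sgRNA-2 production (gene 2)
    "leak_eps": 0.01,     # leak fraction of a specifically blocked promoter
    "delta_r": 6.0,
    "alpha_D": 500.0,
    "delta": DELTA_DIL,
    "k_c": 0.1,
    "k_s": 0.1,           # specific operator binding
    "k_ms": 0.01,
    "k_u": 0.01,          # unspecific (PAM-surrogate) binding
    "k_mu": 10.0,         # unspecific unbinding: fast, low affinity
    "g1_total": 10.0,
    "g2_total": 10.0,
    # instrument layer (reporter on gene 2, controller sgRNA inputs)
    "beta_ctrl1": ARA_MAP.rate(0.0),
    "beta_ctrl2": AHL_MAP.rate(0.0),
    "beta_p": 30.0,
    "delta_p": 2.0,
}

#: Bistability witness for the unspecific-binding toggle variants, found
#: by the package's own parameter-box search (see analysis/03) and frozen
#: (lightly rounded) so downstream analyses — the bifurcation diagram and
#: the hysteresis protocol — have a reproducible anchor.  Verified:
#: 2 stable states (reporter ≈ 133 vs ≈ 1.5) + 1 saddle, for both the
#: neutral and the inhibitory unspecific-binding variants.
TOGGLE_WITNESS_NEUTRAL: dict[str, float] = {
    "beta1": 16.0,
    "beta2": 24.0,
    "leak_eps": 0.008,
    "delta_r": 1.5,
    "alpha_D": 200.0,
    "delta": 1.0,
    "k_c": 0.05,
    "k_s": 8.0,
    "k_ms": 0.025,
    "k_u": 0.045,
    "k_mu": 75.0,
    "g1_total": 19.0,
    "g2_total": 11.0,
}
TOGGLE_WITNESS_INHIBITORY: dict[str, float] = dict(TOGGLE_WITNESS_NEUTRAL)


def toggle_params(variant: str, **overrides: float) -> ParameterSet:
    """Full derived ParameterSet for a toggle variant.

    Derived entries: per-gene leak transcription rates and reporter leak.
    """
    if variant not in TOGGLE_VARIANTS:
        raise ConfigurationError(
            f"unknown toggle variant {variant!r}; expected one of {TOGGLE_VARIANTS}"
        )
    vals = dict(TOGGLE_DEFAULTS)
    vals.update(overrides)
    vals["beta1_leak"] = vals["leak_eps"] * vals["beta1"]
    vals["beta2_leak"] = vals["leak_eps"] * vals["beta2"]
    vals["beta_p_leak"] = vals["leak_eps"] * vals["beta_p"]
    return ParameterSet(vals)


def _toggle_gene_states(i: int, unspecific: bool) -> list[str]:
    if not unspecific:
        return [f"G{i}_0", f"G{i}_1"]
    return [f"G{i}_{s}{u}" for s in (0, 1) for u in (0, 1, 2)]


def make_toggle(variant: str = "unspecific_neutral",
                params: ParameterSet | dict | None = None,
                decoy_sites: float | None = None) -> ReactionNetwork:
    """Two mutually repressing sgRNA nodes; gene 2 carries the GFP reporter.

    Gene state ``G{i}_{s}{u}``: ``s`` = specific operator free (0) /
    occupied by the cognate complex (1); ``u`` = unspecific site free (0) /
    occupied by C1 (1) / by C2 (2).  The ``specific_only`` variant has no
    ``u`` index.  A controller input layer (Ara → extra sgRNA-1,
    AHL → extra sgRNA-2 production) implements the induction experiments.

    ``decoy_sites`` optionally adds a genome-wide pool of that many
    unspecific decoy sites (off by default): either complex can park
    there with the same unspecific kinetics as the per-gene sites.
    """
    if variant not in TOGGLE_VARIANTS:
        raise ConfigurationError(
            f"unknown toggle variant {variant!r}; expected one of {TOGGLE_VARIANTS}"
        )
    unspecific = variant != "specific_only"
    neutral = variant == "unspecific_neutral"

    species: list[Species] = []
    for i in (1, 2):
        states = _toggle_gene_states(i, unspecific)
        for nm in states:
            init = f"g{i}_total" if nm == states[0] else 0.0
            species.append(Species(nm, "gene_state", f"gene {i} binding state", init=init))
    species += [
        Species("r1", "rna", "sgRNA-1 (from gene 1, represses gene 2)"),
        Species("r2", "rna", "sgRNA-2 (from gene 2, represses gene 1)"),
        Species("D", "protein", "free dCas9"),
        Species("C1", "complex", "dCas9:sgRNA-1"),
        Species("C2", "complex", "dCas9:sgRNA-2"),
        Species("P", "protein", "gene-2 reporter (sfGFP)"),
    ]

    rxns: list[Reaction] = []
    u_range = (0, 1, 2) if unspecific else (None,)

    def gname(i: int, s: int, u) -> str:
        return f"G{i}_{s}{u}" if unspecific else f"G{i}_{s}"

    for i in (1, 2):
        j = 3 - i
        for u in u_range:
            uu = 0 if u is None else u
            g0, g1 = gname(i, 0, u), gname(i, 1, u)
            # transcription (inhibitory variant requires the unspecific site free)
            if neutral or not unspecific or uu == 0:
                rxns.append(Reaction({g0: 1}, {g0: 1, f"r{i}": 1}, f"beta{i}"))
                rxns.append(Reaction({g1: 1}, {g1: 1, f"r{i}": 1}, f"beta{i}_leak"))
                if i == 2:
                    rxns.append(Reaction({g0: 1}, {g0: 1, "P": 1}, "beta_p"))
                    rxns.append(Reaction({g1: 1}, {g1: 1, "P": 1}, "beta_p_leak"))
            # specific binding of the cognate repressor C_j
            rxns.append(Reaction({f"C{j}": 1, g0: 1}, {g1: 1}, "k_s"))
            rxns.append(Reaction({g1: 1}, {g0: 1, f"C{j}": 1}, "k_ms"))
            rxns.append(Reaction({g1: 1}, {g0: 1}, "delta", "replication clearance"))
        if unspecific:
            for s in (0, 1):
                gf = gname(i, s, 0)
                for m in (1, 2):
                    gm = gname(i, s, m)
                    rxns.append(Reaction({f"C{m}": 1, gf: 1}, {gm: 1}, "k_u"))
                    rxns.append(Reaction({gm: 1}, {gf: 1, f"C{m}": 1}, "k_mu"))
                    rxns.append(Reaction({gm: 1}, {gf: 1}, "delta", "replication clearance"))

    for i in (1, 2):
        rxns.append(Reaction({}, {f"r{i}": 1}, f"beta_ctrl{i}", "controller input"))
        rxns.append(Reaction({f"r{i}": 1}, {}, "delta_r"))
        rxns.append(Reaction({"D": 1, f"r{i}": 1}, {f"C{i}": 1}, "k_c"))
        rxns.append(Reaction({f"C{i}": 1}, {}, "delta"))
    rxns.append(Reaction({}, {"D": 1}, "alpha_D"))
    rxns.append(Reaction({"D": 1}, {}, "delta"))
    rxns.append(Reaction({"P": 1}, {}, "delta_p"))

    if decoy_sites is not None:
        species.append(Species("U_free", "gene_state",
                               "genome-wide unspecific decoy pool",
                               init="decoy_total"))
        for m in (1, 2):
            species.append(Species(f"U_C{m}", "gene_state",
                                   f"decoy site occupied by C{m}"))
            rxns.append(Reaction({f"C{m}": 1, "U_free": 1}, {f"U_C{m}": 1}, "k_u"))
            rxns.append(Reaction({f"U_C{m}": 1}, {"U_free": 1, f"C{m}": 1}, "k_mu"))
            rxns.append(Reaction({f"U_C{m}": 1}, {"U_free": 1}, "delta"))

    sg2_total = {"r2": 1.0, "C2": 1.0}
    if decoy_sites is not None:
        sg2_total["U_C2"] = 1.0
    if unspecific:
        for i in (1, 2):
            for s in (0, 1):
                sg2_total[gname(i, s, 2)] = 1.0
        for u in u_range:
            sg2_total[gname(1, 1, u)] = sg2_total.get(gname(1, 1, u), 0.0) + 1.0
    else:
        sg2_total["G1_1"] = 1.0

    net = ReactionNetwork(
        species,
        rxns,
        outputs={
            "reporter": {"P": 1.0},
            "sg1_free": {"r1": 1.0},
            "sg2_total": sg2_total,
        },
        name=f"toggle_{variant}",
        inducer_inputs={
            "Ara": [("beta_ctrl1", ARA_MAP)],
            "AHL": [("beta_ctrl2", AHL_MAP)],
        },
    )
    if params is None:
        net.default_params = toggle_params(variant)
    elif isinstance(params, ParameterSet):
        net.default_params = params
    else:
        net.default_params = toggle_params(variant, **params)
    if decoy_sites is not None and "decoy_total" not in net.default_params:
        net.default_params = net.default_params.updated(decoy_total=float(decoy_sites))
    net.variant = variant
    return net


def make_toggle_control(which: str, variant: str = "unspecific_neutral",
                        params: ParameterSet | dict | None = None) -> ReactionNetwork:
    """Monostable controls: ``cL`` deletes gene 1's sgRNA (biased HIGH),
    ``cR`` deletes gene 2's sgRNA (biased LOW).

    Deletion is modeled by pinning that node's transcription rate to a
    negligible value; the controller inputs still work.
    """
    if which not in ("cL", "cR"):
        raise ConfigurationError("control must be 'cL' or 'cR'")
    net = make_toggle(variant, params)
    dead = "beta1" if which == "cL" else "beta2"
    net.default_params = net.default_params.updated(**{dead: 1e-9})
    net.name = f"toggle_{which}_{variant}"
    return net


# ---------------------------------------------------------------------------
# Ring oscillator (CRISPRlator) and open-ring control
# ---------------------------------------------------------------------------

RING_DEFAULTS = {
    "beta": 60.0,         # molecules/(copy·h), sgRNA production per node
    "leak_eps": 0.01,
    "delta_r": 2.0,       # slower sgRNA turnover lengthens each stage's memory
    "alpha_D": 150.0,     # limiting dCas9 pool: sgRNA competition sharpens switching
    "delta": DELTA_DIL,
    "k_c": 0.1,
    "k_s": 0.1,           # scaled by the oscillator calibration factor
    "k_ms": 0.01,
    "g_total": 10.0,
    "beta_p": 30.0,
    "delta_p": 2.0,
}

#: Global specific-binding scale for the shipped CRISPRlator defaults, set
#: by deterministic bisection (analysis/06) so the limit-cycle period sits
#: at 11 h, the midpoint of the observed 10–12 h window.
RING_BINDING_SCALE = 139.76


def ring_params(**overrides: float) -> ParameterSet:
    vals = dict(RING_DEFAULTS)
    vals.update(overrides)
    vals["beta_leak"] = vals["leak_eps"] * vals["beta"]
    vals["beta_p_leak"] = vals["leak_eps"] * vals["beta_p"]
    vals.setdefault("k_s_eff", vals["k_s"] * RING_BINDING_SCALE)
    return ParameterSet(vals)


def make_ring(open_ring: bool = False,
              params: ParameterSet | dict | None = None) -> ReactionNetwork:
    """3-node cyclic repression network: node i's sgRNA represses node i+1.

    ``open_ring=True`` removes the edge from node 3 back to node 1
    (the monostable control circuit).
    """
    species: list[Species] = []
    for i in (1, 2, 3):
        species.append(Species(f"G{i}_0", "gene_state", f"node {i} free", init="g_total"))
        species.append(Species(f"G{i}_1", "gene_state", f"node {i} repressed"))
    for i in (1, 2, 3):
        species.append(Species(f"r{i}", "rna", f"sgRNA {i}"))
        species.append(Species(f"C{i}", "complex", f"dCas9:sgRNA-{i}"))
        species.append(Species(f"P{i}", "protein", f"node {i} reporter"))
    species.append(Species("D", "protein", "free dCas9"))

    rxns: list[Reaction] = []
    for i in (1, 2, 3):
        g0, g1 = f"G{i}_0", f"G{i}_1"
        rxns.append(Reaction({g0: 1}, {g0: 1, f"r{i}": 1}, "beta"))
        rxns.append(Reaction({g1: 1}, {g1: 1, f"r{i}": 1}, "beta_leak"))
        rxns.append(Reaction({g0: 1}, {g0: 1, f"P{i}": 1}, "beta_p"))
        rxns.append(Reaction({g1: 1}, {g1: 1, f"P{i}": 1}, "beta_p_leak"))
        rxns.append(Reaction({f"P{i}": 1}, {}, "delta_p"))
        rxns.append(Reaction({f"r{i}": 1}, {}, "delta_r"))
        rxns.append(Reaction({"D": 1, f"r{i}": 1}, {f"C{i}": 1}, "k_c"))
        rxns.append(Reaction({f"C{i}": 1}, {}, "delta"))
        target = i % 3 + 1  # node i represses node i+1 (mod 3)
        if open_ring and i == 3:
            continue
        t0, t1 = f"G{target}_0", f"G{target}_1"
        rxns.append(Reaction({f"C{i}": 1, t0: 1}, {t1: 1}, "k_s_eff"))
        rxns.append(Reaction({t1: 1}, {t0: 1, f"C{i}": 1}, "k_ms"))
        rxns.append(Reaction({t1: 1}, {t0: 1}, "delta", "replication clearance"))
    rxns.append(Reaction({}, {"D": 1}, "alpha_D"))
    rxns.append(Reaction({"D": 1}, {}, "delta"))

    net = ReactionNetwork(
        species,
        rxns,
        outputs={f"reporter{i}": {f"P{i}": 1.0} for i in (1, 2, 3)},
        name="open_ring" if open_ring else "ring",
    )
    if params is None:
        net.default_params = ring_params()
    elif isinstance(params, ParameterSet):
        net.default_params = params
    else:
        net.default_params = ring_params(**params)
    return net


# ---------------------------------------------------------------------------
# Incoherent feed-forward loop (I2)
# ---------------------------------------------------------------------------

IFFL_DEFAULTS = {
    "delta_r": 6.0,
    "alpha_D": 20000.0,   # generous dCas9 pool: composed circuits stay independent
    "delta": DELTA_DIL,
    "k_c": 0.1,
    "k_s": 0.01,
    "k_ms": 0.01,
    "leak_b": 0.01,
    "g_total": 10.0,
    "beta_p": 30.0,
    "delta_p": 2.0,
    "beta2": 10.0,        # molecules/(copy·h), N2's sgRNA production
}

#: The t4-truncated guide on the weak direct edge loses association rate
#: far faster than saturated fold-repression (which the NOT-gate
#: calibration pins); this factor carries the extra affinity loss and
#: positions the stripe window.
TRUNCATION_AFFINITY_FACTOR = 0.2

#: Named preset sets: (strong, weak, second) sgRNA presets, the weak-edge
#: affinity factor and the relative strength of the N1 guide cassette.
#: The second set's stronger cassette offsets its band-pass window so the
#: two stripes of the composed circuit peak at distinct inducer doses.
IFFL_PRESET_SETS = {
    "set1": {"presets": ("sg1", "sg1_t4", "sg2"),
             "weak_affinity": TRUNCATION_AFFINITY_FACTOR, "n1_rate": 1.0},
    "set2": {"presets": ("sg4", "sg4_t4", "sg3"),
             "weak_affinity": 0.1, "n1_rate": 3.0},
}


def make_iffl(preset_set="set1",
              single_reporter: bool = False,
              prefix: str = "",
              inducer_map: InducerMap = ARA_MAP,
              params: dict | None = None,
              weak_affinity_factor: float | None = None,
              n1_rate_factor: float | None = None) -> ReactionNetwork:
    """Type-2 IFFL: input induces N1; N1 represses N2 (strong sgRNA) and N3
    (weak, truncated sgRNA); N2 represses N3.  N3 peaks ("stripe") at
    intermediate input.

    ``preset_set`` is ``(strong, weak, second)`` sgRNA preset names or a
    named set.  ``prefix`` namespaces all species except the shared dCas9
    pool ``D`` so parallel circuits can be composed.
    """
    if isinstance(preset_set, str):
        try:
            entry = IFFL_PRESET_SETS[preset_set]
        except KeyError:
            raise ConfigurationError(
                f"unknown IFFL preset set {preset_set!r}; known: {sorted(IFFL_PRESET_SETS)}"
            ) from None
        preset_set = entry["presets"]
        if weak_affinity_factor is None:
            weak_affinity_factor = entry["weak_affinity"]
        if n1_rate_factor is None:
            n1_rate_factor = entry["n1_rate"]
    if weak_affinity_factor is None:
        weak_affinity_factor = TRUNCATION_AFFINITY_FACTOR
    if n1_rate_factor is None:
        n1_rate_factor = 1.0
    if n1_rate_factor != 1.0:
        inducer_map = InducerMap(inducer_map.basal, inducer_map.K,
                                 inducer_map.n,
                                 inducer_map.beta_max * n1_rate_factor,
                                 inducer_map.name)
    strong, weak, second = preset_set
    sA = preset_scale(strong)
    sB = preset_scale(weak) * weak_affinity_factor
    sC = preset_scale(second)

    def p(name: str) -> str:
        return f"{prefix}{name}" if prefix else name

    species = [
        Species(p("rA"), "rna", f"N1 sgRNA ({strong}), represses N2"),
        Species(p("rB"), "rna", f"N1 sgRNA ({weak}), weakly represses N3"),
        Species(p("rC"), "rna", f"N2 sgRNA ({second}), represses N3"),
        Species(p("CA"), "complex"),
        Species(p("CB"), "complex"),
        Species(p("CC"), "complex"),
        Species(p("G2_free"), "gene_state", "N2 operator free", init=f"{prefix}g_total" if prefix else "g_total"),
        Species(p("G2_bound"), "gene_state", "N2 operator occupied by CA"),
        Species(p("G3_ff"), "gene_state", "N3 both sites free", init=f"{prefix}g_total" if prefix else "g_total"),
        Species(p("G3_bf"), "gene_state", "N3 weak site occupied by CB"),
        Species(p("G3_fb"), "gene_state", "N3 second site occupied by CC"),
        Species(p("G3_bb"), "gene_state", "N3 both sites occupied"),
        Species("D", "protein", "free dCas9 (shared pool)"),
        Species(p("P3"), "protein", "N3 reporter"),
    ]
    if not single_reporter:
        species.append(Species(p("P1"), "protein", "N1 reporter (mKO2)"))
        species.append(Species(p("P2"), "protein", "N2 reporter"))

    k = {n: f"{prefix}{n}" if prefix else n for n in
         ("beta_n1", "beta_n1_p", "beta2", "beta2_leak", "beta_p", "beta_p_leak",
          "k_sA", "k_sB", "k_sC", "g_total")}
    shared = {n: n for n in ("delta", "delta_r", "delta_p", "alpha_D", "k_c", "k_ms")}
    k.update(shared)

    rxns: list[Reaction] = [
        Reaction({}, {p("rA"): 1}, k["beta_n1"], "N1 strong sgRNA (induced)"),
        Reaction({}, {p("rB"): 1}, k["beta_n1"], "N1 weak sgRNA (induced)"),
        Reaction({p("rA"): 1}, {}, k["delta_r"]),
        Reaction({p("rB"): 1}, {}, k["delta_r"]),
        Reaction({p("rC"): 1}, {}, k["delta_r"]),
        Reaction({}, {"D": 1}, k["alpha_D"]),
        Reaction({"D": 1}, {}, k["delta"]),
    ]
    for r, c in (("rA", "CA"), ("rB", "CB"), ("rC", "CC")):
        rxns.append(Reaction({"D": 1, p(r): 1}, {p(c): 1}, k["k_c"]))
        rxns.append(Reaction({p(c): 1}, {}, k["delta"]))
    # N2: repressed by CA, produces rC (and P2)
    rxns += [
        Reaction({p("CA"): 1, p("G2_free"): 1}, {p("G2_bound"): 1}, k["k_sA"]),
        Reaction({p("G2_bound"): 1}, {p("G2_free"): 1, p("CA"): 1}, k["k_ms"]),
        Reaction({p("G2_bound"): 1}, {p("G2_free"): 1}, k["delta"]),
        Reaction({p("G2_free"): 1}, {p("G2_free"): 1, p("rC"): 1}, k["beta2"]),
        Reaction({p("G2_bound"): 1}, {p("G2_bound"): 1, p("rC"): 1}, k["beta2_leak"]),
    ]
    # N3: two independent operators (CB weak site, CC second site)
    for c, pair in (("CB", (("G3_ff", "G3_bf"), ("G3_fb", "G3_bb"))),
                    ("CC", (("G3_ff", "G3_fb"), ("G3_bf", "G3_bb")))):
        kon = k["k_sB"] if c == "CB" else k["k_sC"]
        for free, bound in pair:
            rxns.append(Reaction({p(c): 1, p(free): 1}, {p(bound): 1}, kon))
            rxns.append(Reaction({p(bound): 1}, {p(free): 1, p(c): 1}, k["k_ms"]))
            rxns.append(Reaction({p(bound): 1}, {p(free): 1}, k["delta"]))
    # reporters
    rxns.append(Reaction({p("G3_ff"): 1}, {p("G3_ff"): 1, p("P3"): 1}, k["beta_p"]))
    for blocked in ("G3_bf", "G3_fb", "G3_bb"):
        rxns.append(Reaction({p(blocked): 1}, {p(blocked): 1, p("P3"): 1}, k["beta_p_leak"]))
    rxns.append(Reaction({p("P3"): 1}, {}, k["delta_p"]))
    outputs = {p("N3"): {p("P3"): 1.0}}
    if not single_reporter:
        rxns.append(Reaction({}, {p("P1"): 1}, k["beta_n1_p"], "N1 reporter (induced)"))
        rxns.append(Reaction({p("P1"): 1}, {}, k["delta_p"]))
        rxns.append(Reaction({p("G2_free"): 1}, {p("G2_free"): 1, p("P2"): 1}, k["beta_p"]))
        rxns.append(Reaction({p("G2_bound"): 1}, {p("G2_bound"): 1, p("P2"): 1}, k["beta_p_leak"]))
        rxns.append(Reaction({p("P2"): 1}, {}, k["delta_p"]))
        outputs[p("N1")] = {p("P1"): 1.0}
        outputs[p("N2")] = {p("P2"): 1.0}

    vals = dict(IFFL_DEFAULTS)
    if params:
        vals.update(params)
    pv = {k["g_total"]: vals["g_total"],
          k["beta2"]: vals["beta2"],
          k["beta2_leak"]: vals["leak_b"] * vals["beta2"],
          k["beta_p"]: vals["beta_p"],
          k["beta_p_leak"]: vals["leak_b"] * vals["beta_p"],
          k["k_sA"]: vals["k_s"] * sA,
          k["k_sB"]: vals["k_s"] * sB,
          k["k_sC"]: vals["k_s"] * sC,
          k["beta_n1"]: inducer_map.rate(0.0),
          k["beta_n1_p"]: inducer_map.rate(0.0) / 2.0,
          }
    for n in shared:
        pv[n] = vals[n]
    pv["delta_p"] = vals["delta_p"]

    inducer_entries = [
        (k["beta_n1"], inducer_map),
        (k["beta_n1_p"], InducerMap(inducer_map.basal, inducer_map.K,
                                    inducer_map.n, inducer_map.beta_max / 2.0,
                                    inducer_map.name)),
    ]
    net = ReactionNetwork(
        species, rxns, outputs=outputs,
        name=f"iffl_{prefix or 'main'}",
        inducer_inputs={inducer_map.name: inducer_entries},
    )
    net.default_params = ParameterSet(pv)
    net.preset_scales = {"strong": sA, "weak": sB, "second": sC}
    return net


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def compose(*networks: ReactionNetwork,
            shared: tuple[str, ...] = ("D",),
            name: str = "composite") -> ReactionNetwork:
    """Union of circuits sharing only the free-dCas9 pool (by default).

    Non-shared species names must be disjoint; identical reactions on
    shared species (e.g. dCas9 production) are merged, so resource
    coupling happens only through the shared pool.
    """
    species: list[Species] = []
    seen: dict[str, Species] = {}
    for net in networks:
        for sp in net.species:
            if sp.name in seen:
                if sp.name not in shared:
                    raise ConfigurationError(
                        f"species name collision on {sp.name!r}: only shared "
                        f"species {shared} may appear in several circuits"
                    )
                continue
            seen[sp.name] = sp
            species.append(sp)
    rxns: list[Reaction] = []
    sigs: set[tuple] = set()
    for net in networks:
        for rxn in net.reactions:
            sig = (tuple(sorted(rxn.reactants.items())),
                   tuple(sorted(rxn.products.items())), rxn.rate_constant_name)
            if sig in sigs:
                continue
            sigs.add(sig)
            rxns.append(rxn)
    outputs: dict[str, dict[str, float]] = {}
    for net in networks:
        for k, v in net.outputs.items():
            if k in outputs and outputs[k] != v:
                raise ConfigurationError(f"observable name collision on {k!r}")
            outputs[k] = v
    inducers: dict[str, list] = {}
    for net in networks:
        for ind, entries in net.inducer_inputs.items():
            inducers.setdefault(ind, [])
            for e in entries:
                if e not in inducers[ind]:
                    inducers[ind].append(e)
    out = ReactionNetwork(species, rxns, outputs=outputs, name=name,
                          inducer_inputs=inducers)
    vals: dict[str, float] = {}
    for net in networks:
        ps = getattr(net, "default_params", None)
        if ps is None:
            continue
        for k, v in ps.items():
            if k in vals and not math.isclose(vals[k], v, rel_tol=1e-12):
                raise ConfigurationError(
                    f"parameter {k!r} has conflicting defaults in composed circuits"
                )
            vals[k] = v
    if vals:
        out.default_params = ParameterSet(vals)
    return out


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def measure_max_fold_repression(network: ReactionNetwork,
                                params: ParameterSet | None = None) -> float:
    """Steady-state fold-repression at saturating inducer vs. a no-sgRNA control."""
    from .dynamics import steady_state_observable

    params = params or network.default_params
    induced = steady_state_observable(network, params, "reporter")
    control = steady_state_observable(
        network, params.updated(beta_r1=1e-9), "reporter"
    )
    from .phenotypes import fold_repression

    return fold_repression(induced, control)


def calibrate_binding(network_factory, target_fold: float,
                      rtol: float = 1e-4,
                      bracket: tuple[float, float] = (1e-6, 1e6)) -> float:
    """Find the specific-binding scale giving a target maximal fold-repression.

    Monotone bracketing root search on log10(scale); the NOT gate's
    fold-repression increases monotonically with the association constant.
    """
    from scipy.optimize import brentq

    if not target_fold > 1.0:
        raise CalibrationError("target fold-repression must exceed 1")

    def f(log_scale: float) -> float:
        net = network_factory(10.0**log_scale)
        return math.log(measure_max_fold_repression(net) / target_fold)

    lo, hi = math.log10(bracket[0]), math.log10(bracket[1])
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise CalibrationError(
            f"target fold {target_fold:g} unreachable within scale bracket {bracket}"
        )
    root = brentq(f, lo, hi, xtol=rtol / 10.0)
    return 10.0**root

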