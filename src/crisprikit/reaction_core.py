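"""Mass-action reaction networks: species, reactions, rate laws and structure.

Every circuit in the package compiles down to a :class:`ReactionNetwork` —
a list of species and elementary (at most bimolecular) reactions with
mass-action kinetics.  The module provides the time-derivative field
(:func:`rhs`), its analytic Jacobian (:func:`jacobian`) and detection of
linear conservation laws (:func:`conservation_laws`), which downstream
steady-state and continuation code relies on.

Units throughout the package: time in hours, abundances in molecules per
cell (copy-number scale), so bimolecular rate constants are in
1/(molecule·h) and zero-order production rates in molecules/h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError

SPECIES_ROLES = frozenset(
    {"gene_state", "rna", "protein", "complex", "inducer", "auxiliary"}
)


@dataclass(frozen=True)
class Species:
    """A chemical species.

    ``role`` is one of ``gene_state``, ``rna``, ``protein``, ``complex``,
    ``inducer`` or ``auxiliary``.  ``constant`` species take part in
    propensities but their own time derivative is pinned to zero (used for
    externally held inducers).  ``init`` is either a number or the name of
    a parameter supplying the default initial abundance.
    """

    name: str
    role: str = "auxiliary"
    description: str = ""
    constant: bool = False
    init: float | str = 0.0

    def __post_init__(self) -> None:
        if self.role not in SPECIES_ROLES:
            raise ConfigurationError(
                f"species {self.name!r}: unknown role {self.role!r}; "
                f"expected one of {sorted(SPECIES_ROLES)}"
            )


@dataclass(frozen=True)
class Reaction:
    """An elementary reaction with a named mass-action rate constant.

    ``reactants`` and ``products`` map species names to positive integer
    stoichiometries.  The total reactant order must be at most two
    (elementary reactions only).
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant_name: str
    label: str = ""

    def __post_init__(self) -> None:
        for side, mapping in (("reactant", self.reactants), ("product", self.products)):
            for name, stoich in mapping.items():
                if not (isinstance(stoich, (int, np.integer)) and stoich > 0):
                    raise ConfigurationError(
                        f"{side} stoichiometry of {name!r} in reaction "
                        f"{self.label or self.rate_constant_name!r} must be a "
                        f"positive integer, got {stoich!r}"
                    )
        if sum(self.reactants.values()) > 2:
            raise ConfigurationError(
                f"reaction {self.label or self.rate_constant_name!r} has reactant "
                "order > 2; only elementary (at most bimolecular) reactions are allowed"
            )
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))

    def format(self) -> str:
        def side(mapping: Mapping[str, int]) -> str:
            if not mapping:
                return "0"
            terms = []
            for name in mapping:
                s = mapping[name]
                terms.append(name if s == 1 else f"{s} {name}")
            return " + ".join(terms)

        return f"{side(self.reactants)} -> {side(self.products)} ; {self.rate_constant_name}"


class ParameterSet:
    """Named, strictly positive rate constants and copy numbers.

    Behaves like a read-only mapping.  ``provenance`` carries a free-text
    note per parameter explaining where its default value comes from.
    """

    def __init__(
        self,
        values: Mapping[str, float],
        provenance: Mapping[str, str] | None = None,
    ) -> None:
        vals = {}
        for name, v in values.items():
            v = float(v)
            if not np.isfinite(v) or v <= 0.0:
                raise ConfigurationError(
                    f"parameter {name!r} must be strictly positive and finite, got {v}"
                )
            vals[name] = v
        self._values = vals
        self.provenance = dict(provenance or {})

    def __getitem__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise ConfigurationError(f"missing parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def keys(self):
        return self._values.keys()

    def items(self):
        return self._values.items()

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def updated(self, **overrides: float) -> "ParameterSet":
        """Return a copy with some values replaced."""
        vals = dict(self._values)
        vals.update(overrides)
        prov = dict(self.provenance)
        for k in overrides:
            prov[k] = prov.get(k, "") + " [override]"
        return ParameterSet(vals, prov)

    def __repr__(self) -> str:
        return f"ParameterSet({self._values!r})"


class ReactionNetwork:
    """An ordered species list plus mass-action reactions.

    ``outputs`` maps observable names (e.g. ``"reporter"``) to linear
    combinations of species, given as ``{species_name: coefficient}``.
    ``inducer_inputs`` maps an inducer name (e.g. ``"Ara"``) to a
    ``(parameter_name, inducer_map)`` pair: setting the inducer to
    concentration ``c`` means overriding that production-rate parameter
    with ``inducer_map.rate(c)``.
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        outputs: Mapping[str, Mapping[str, float]] | None = None,
        name: str = "network",
        inducer_inputs: Mapping[str, tuple] | None = None,
    ) -> None:
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ConfigurationError("species names must be unique within a network")
        self.species = list(species)
        self.reactions = list(reactions)
        self.outputs = {k: dict(v) for k, v in (outputs or {}).items()}
        self.name = name
        self.inducer_inputs = dict(inducer_inputs or {})
        self._index = {n: i for i, n in enumerate(names)}

        referenced: set[str] = set()
        for rxn in self.reactions:
            for n in list(rxn.reactants) + list(rxn.products):
                if n not in self._index:
                    raise ConfigurationError(
                        f"reaction {rxn.format()!r} references unknown species {n!r}"
                    )
                referenced.add(n)
        for sp in self.species:
            if sp.name not in referenced and not sp.constant:
                raise ConfigurationError(
                    f"species {sp.name!r} appears in no reaction and is not "
                    "flagged constant"
                )
        for obs, combo in self.outputs.items():
            for n in combo:
                if n not in self._index:
                    raise ConfigurationError(
                        f"observable {obs!r} references unknown species {n!r}"
                    )
        self._compiled: dict | None = None

    # -- basic structure ---------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ConfigurationError(f"unknown species {name!r}") from None

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def parameter_names(self) -> list[str]:
        """Rate-constant names in first-appearance order (no duplicates)."""
        seen: list[str] = []
        for rxn in self.reactions:
            if rxn.rate_constant_name not in seen:
                seen.append(rxn.rate_constant_name)
        return seen

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry S (species × reactions), integer entries.

        Rows of constant species are zeroed: their abundance is externally
        held, so reactions do not change it.
        """
        S = np.zeros((self.n_species, self.n_reactions), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for n, s in rxn.reactants.items():
                S[self._index[n], j] -= s
            for n, s in rxn.products.items():
                S[self._index[n], j] += s
        for i, sp in enumerate(self.species):
            if sp.constant:
                S[i, :] = 0
        return S

    def initial_state(self, params: ParameterSet) -> np.ndarray:
        """Default initial state: per-species ``init`` (number or parameter name)."""
        x0 = np.zeros(self.n_species)
        for i, sp in enumerate(self.species):
            x0[i] = params[sp.init] if isinstance(sp.init, str) else float(sp.init)
        return x0

    def observe(self, x: np.ndarray) -> dict[str, float]:
        """Evaluate all observables at one state vector."""
        out = {}
        for obs, combo in self.outputs.items():
            out[obs] = float(sum(c * x[self._index[n]] for n, c in combo.items()))
        return out

    # -- compiled kinetics -------------------------------------------------

    def _compile(self) -> dict:
        if self._compiled is not None:
            return self._compiled
        nr = self.n_reactions
        idx1 = np.full(nr, -1, dtype=np.int64)
        idx2 = np.full(nr, -1, dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            slots: list[int] = []
            for n, s in rxn.reactants.items():
                slots.extend([self._index[n]] * s)
            if len(slots) >= 1:
                idx1[j] = slots[0]
            if len(slots) == 2:
                idx2[j] = slots[1]
        S = self.stoichiometry_matrix().astype(float)
        self._compiled = {
            "idx1": idx1,
            "idx2": idx2,
            "S": S,
            "knames": [rxn.rate_constant_name for rxn in self.reactions],
            "constant_mask": np.array([sp.constant for sp in self.species]),
        }
        return self._compiled

    def rate_vector(self, params: ParameterSet) -> np.ndarray:
        c = self._compile()
        return np.array([params[name] for name in c["knames"]])


def _factors(network: ReactionNetwork, state: np.ndarray):
    c = network._compile()
    i1, i2 = c["idx1"], c["idx2"]
    f1 = np.where(i1 >= 0, state[np.clip(i1, 0, None)], 1.0)
    f2 = np.where(i2 >= 0, state[np.clip(i2, 0, None)], 1.0)
    return c, i1, i2, f1, f2


def propensities(
    network: ReactionNetwork, state: np.ndarray, params: ParameterSet
) -> np.ndarray:
    """Mass-action reaction rates v_j = k_j · ∏ x_i^{s_ij}."""
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise DomainError(
            f"state has length {state.size}, network has {network.n_species} species"
        )
    if np.any(state < 0):
        bad = network.species_names[int(np.argmin(state))]
        raise DomainError(f"negative abundance for species {bad!r}")
    c, _, _, f1, f2 = _factors(network, state)
    return network.rate_vector(params) * f1 * f2


def rhs(
    network: ReactionNetwork, state: np.ndarray, params: ParameterSet
) -> np.ndarray:
    """Time derivative S·v(x) under mass-action kinetics.

    Constant-flagged species get derivative exactly 0.
    """
    v = propensities(network, state, params)
    return network._compile()["S"] @ v


def jacobian(
    network: ReactionNetwork, state: np.ndarray, params: ParameterSet
) -> np.ndarray:
    """Analytic Jacobian ∂(dx/dt)/∂x of the mass-action field."""
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise DomainError(
            f"state has length {state.size}, network has {network.n_species} species"
        )
    if np.any(state < 0):
        bad = network.species_names[int(np.argmin(state))]
        raise DomainError(f"negative abundance for species {bad!r}")
    c, i1, i2, f1, f2 = _factors(network, state)
    k = network.rate_vector(params)
    nr, ns = network.n_reactions, network.n_species
    dv = np.zeros((nr, ns))
    rows = np.arange(nr)
    m1 = i1 >= 0
    # d v_j / d x_{i1}: k * f2 (covers x^2 via i1 == i2 accumulation)
    np.add.at(dv, (rows[m1], i1[m1]), (k * f2)[m1])
    m2 = i2 >= 0
    np.add.at(dv, (rows[m2], i2[m2]), (k * f1)[m2])
    return c["S"] @ dv


def conservation_laws(network: ReactionNetwork) -> list[np.ndarray]:
    """Nonnegative basis of the left null space of the stoichiometry matrix.

    Returns vectors ``w`` (length ``n_species``) with ``wᵀS = 0``, found by
    exact rational elimination.  Where a nonnegative basis exists (the usual
    case here: each gene's binding states sum to its copy number) the
    returned vectors are nonnegative with disjoint-gene structure; trivial
    laws on constant species are excluded.
    """
    from itertools import combinations

    from scipy.linalg import null_space

    S = network.stoichiometry_matrix()
    dyn = [i for i, sp in enumerate(network.species) if not sp.constant]
    if not dyn:
        return []
    N = null_space(S[dyn, :].T.astype(float))
    d = N.shape[1]
    if d == 0:
        return []
    tol = 1e-10
    rays: list[np.ndarray] = []

    Sd = S[dyn, :].astype(float)
    s_scale = max(1.0, float(np.max(np.abs(Sd))))

    def push(a: np.ndarray) -> None:
        w = N @ a
        if not (np.all(w >= -tol) and np.max(w) > tol):
            return
        w = np.clip(w, 0.0, None)
        w = w / np.max(w)
        # snap numerical dust to zero, then re-verify the law exactly
        w_clean = np.where(w < 1e-7, 0.0, w)
        if np.max(np.abs(Sd.T @ w_clean)) < 1e-7 * s_scale:
            w = w_clean / np.max(w_clean)
        for r in rays:
            if np.max(np.abs(r - w)) < 1e-6:
                return
        rays.append(w)

    if d == 1:
        push(np.array([1.0]))
        push(np.array([-1.0]))
    else:
        # extreme rays of {a : N a ≥ 0}: each ray saturates d-1 of the
        # inequality constraints (rows of N)
        for rows in combinations(range(N.shape[0]), d - 1):
            sub = N[list(rows), :]
            basis = null_space(sub)
            if basis.shape[1] != 1:
                continue
            push(basis[:, 0])
            push(-basis[:, 0])
    # prefer the sparsest rays (pure single-gene sums over mixtures)
    rays.sort(key=lambda w: int(np.count_nonzero(w > 1e-9)))
    if not rays or len(rays) < d:
        # no (full) nonnegative description; return an orthonormal basis
        rays = [N[:, j] for j in range(d)]
    elif len(rays) > d:
        # keep an independent subset so downstream elimination stays square
        kept: list[np.ndarray] = []
        for r in rays:
            cand = np.array(kept + [r])
            if np.linalg.matrix_rank(cand, tol=1e-9) == len(cand):
                kept.append(r)
            if len(kept) == d:
                break
        rays = kept
    out = []
    for v in rays:
        # rescale to small integers when the structure allows it
        pos = v[np.abs(v) > tol]
        if len(pos):
            v = v / np.min(np.abs(pos))
            if np.allclose(v, np.round(v), atol=1e-6):
                v = np.round(v)
        full = np.zeros(network.n_species)
        full[dyn] = v
        out.append(full)
    return out


# -- serialization ---------------------------------------------------------


def network_to_text(network: ReactionNetwork) -> str:
    """One reaction per line: ``A + B -> C ; k_name``."""
    return "\n".join(rxn.format() for rxn in network.reactions) + "\n"


def _parse_side(text: str) -> dict[str, int]:
    text = text.strip()
    if text in ("0", "", "∅"):
        return {}
    out: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        parts = term.split()
        if len(parts) == 2:
            stoich, name = int(parts[0]), parts[1]
        elif len(parts) == 1:
            stoich, name = 1, parts[0]
        else:
            raise ConfigurationError(f"cannot parse reaction term {term!r}")
        out[name] = out.get(name, 0) + stoich
    return out


def network_from_text(
    text: str,
    name: str = "network",
    roles: Mapping[str, str] | None = None,
    outputs: Mapping[str, Mapping[str, float]] | None = None,
) -> ReactionNetwork:
    """Parse a reaction-list text block (inverse of :func:`network_to_text`).

    Species roles default to ``auxiliary`` unless given in ``roles``.
    """
    roles = dict(roles or {})
    reactions = []
    seen: list[str] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ";" not in line or "->" not in line:
            raise ConfigurationError(f"cannot parse reaction line {line!r}")
        body, kname = line.rsplit(";", 1)
        lhs, rhs_ = body.split("->")
        reactants, products = _parse_side(lhs), _parse_side(rhs_)
        reactions.append(Reaction(reactants, products, kname.strip()))
        for n in list(reactants) + list(products):
            if n not in seen:
                seen.append(n)
    species = [Species(n, roles.get(n, "auxiliary")) for n in seen]
    return ReactionNetwork(species, reactions, outputs=outputs, name=name)


def network_to_json(network: ReactionNetwork) -> str:
    doc = {
        "name": network.name,
        "species": [
            {
                "name": s.name,
                "role": s.role,
                "description": s.description,
                "constant": s.constant,
                "init": s.init,
            }
            for s in network.species
        ],
        "reactions": [
            {
                "reactants": r.reactants,
                "products": r.products,
                "rate_constant": r.rate_constant_name,
                "label": r.label,
            }
            for r in network.reactions
        ],
        "outputs": network.outputs,
    }
    return json.dumps(doc, indent=2)


def network_from_json(text: str) -> ReactionNetwork:
    doc = json.loads(text)
    species = [
        Species(
            d["name"],
            d.get("role", "auxiliary"),
            d.get("description", ""),
            d.get("constant", False),
            d.get("init", 0.0),
        )
        for d in doc["species"]
    ]
    reactions = [
        Reaction(
            d["reactants"], d["products"], d["rate_constant"], d.get("label", "")
        )
        for d in doc["reactions"]
    ]
    return ReactionNetwork(
        species, reactions, outputs=doc.get("outputs"), name=doc.get("name", "network")
    )


def network_to_sbml(network: ReactionNetwork, params: ParameterSet) -> str:
    """Minimal SBML Level 3 Version 2 document with mass-action kinetic laws.

    Hand-written XML (species, parameters, reactions with
    ``k·x1·x2`` MathML rate laws); intended for interoperability checks
    with SBML-aware tools, not as a full-featured exporter.
    """
    from lxml import etree

    SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
    MATHML_NS = "http://www.w3.org/1998/Math/MathML"
    sbml = etree.Element("sbml", nsmap={None: SBML_NS})
    sbml.set("level", "3")
    sbml.set("version", "2")
    model = etree.SubElement(sbml, "model", id=network.name)
    lc = etree.SubElement(model, "listOfCompartments")
    etree.SubElement(
        lc, "compartment", id="cell", spatialDimensions="3", size="1", constant="true"
    )
    ls = etree.SubElement(model, "listOfSpecies")
    for sp in network.species:
        etree.SubElement(
            ls,
            "species",
            id=sp.name,
            compartment="cell",
            initialAmount=str(
                params[sp.init] if isinstance(sp.init, str) else float(sp.init)
            ),
            hasOnlySubstanceUnits="true",
            boundaryCondition="true" if sp.constant else "false",
            constant="false",
        )
    lp = etree.SubElement(model, "listOfParameters")
    for pname in network.parameter_names:
        etree.SubElement(
            lp, "parameter", id=pname, value=str(params[pname]), constant="true"
        )
    lr = etree.SubElement(model, "listOfReactions")
    for j, rxn in enumerate(network.reactions):
        r = etree.SubElement(
            lr, "reaction", id=f"r{j}", reversible="false"
        )
        if rxn.reactants:
            lref = etree.SubElement(r, "listOfReactants")
            for n, s in rxn.reactants.items():
                etree.SubElement(
                    lref, "speciesReference", species=n, stoichiometry=str(s),
                    constant="true",
                )
        if rxn.products:
            lprod = etree.SubElement(r, "listOfProducts")
            for n, s in rxn.products.items():
                etree.SubElement(
                    lprod, "speciesReference", species=n, stoichiometry=str(s),
                    constant="true",
                )
        kl = etree.SubElement(r, "kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
        apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
        ci = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
        ci.text = rxn.rate_constant_name
        for n, s in rxn.reactants.items():
            for _ in range(s):
                ci = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
                ci.text = n
    return etree.tostring(
        sbml, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()
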