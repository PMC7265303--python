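"""Equilibrium continuation, tangent-bifurcation detection and
multistationarity screening.

The continuation engine works on a generic differentiable vector-field
contract (state field ``f(x, p)`` with Jacobians), so saddle-node normal
forms are first-class test systems.  Reaction networks are adapted
through the conservation-reduced system: conserved gene totals are
eliminated by substitution before continuation, otherwise the Jacobian
is structurally singular along each conservation law.

The screening routine mirrors optimization-toolbox practice for
multistationarity: sample a log-box of kinetic parameters, enumerate
equilibria per sample with the multistart Newton backend, and report
bistability witnesses.  A negative screen is evidence of absence at the
stated budget, not a proof.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dynamics import ReducedSystem, classify_stability, find_steady_states
from .errors import ConfigurationError, DomainError, SolverError
from .reaction_core import ParameterSet, ReactionNetwork


# ---------------------------------------------------------------------------
# Vector-field contract
# ---------------------------------------------------------------------------


class VectorField:
    """A parameterized field ``f(x, p)`` with analytic state Jacobian.

    ``jac_p`` defaults to a central finite difference on the scalar
    parameter.
    """

    def __init__(self, f: Callable, jac_x: Callable,
                 jac_p: Callable | None = None, n: int | None = None) -> None:
        self.f = f
        self.jac_x = jac_x
        self._jac_p = jac_p
        self.n = n

    def jac_p(self, x: np.ndarray, p: float) -> np.ndarray:
        if self._jac_p is not None:
            return self._jac_p(x, p)
        h = 1e-6 * max(abs(p), 1e-6)
        return (self.f(x, p + h) - self.f(x, p - h)) / (2.0 * h)

    @classmethod
    def from_network(cls, network: ReactionNetwork, params: ParameterSet,
                     free_param: str) -> tuple["VectorField", ReducedSystem]:
        """Adapt a network to the contract, continuing in ``free_param``.

        Conservation laws are eliminated first; the returned field acts on
        the reduced coordinates.
        """
        if free_param not in params:
            raise ConfigurationError(f"unknown parameter {free_param!r}")
        red = ReducedSystem(network, params=params)

        def f(x, p):
            return red.f(x, params.updated(**{free_param: p}))

        def jx(x, p):
            return red.jac(x, params.updated(**{free_param: p}))

        return cls(f, jx, n=red.n_reduced), red


# ---------------------------------------------------------------------------
# Branch containers
# ---------------------------------------------------------------------------


@dataclass
class BranchPoint:
    param: float
    state: np.ndarray
    stability: str
    leading_eigenvalue: float


@dataclass
class LimitPoint:
    param: float
    state: np.ndarray
    tangent_param_component: float


@dataclass
class BifurcationBranch:
    """A continuation curve of equilibria versus one parameter."""

    free_param: str
    points: list[BranchPoint]
    limit_points: list[LimitPoint] = field(default_factory=list)
    failure: str | None = None

    def __len__(self) -> int:
        return len(self.points)

    @property
    def params(self) -> np.ndarray:
        return np.array([pt.param for pt in self.points])

    def to_frame(self, observable: Callable | None = None,
                 name: str = "value") -> pd.DataFrame:
        rows = []
        for pt in self.points:
            row = {self.free_param: pt.param, "stability": pt.stability}
            if observable is not None:
                row[name] = observable(pt.state)
            rows.append(row)
        return pd.DataFrame(rows)


def bistable_interval(branch: BifurcationBranch) -> list[tuple[float, float]]:
    """Maximal parameter intervals where ≥ 2 stable branch points coexist.

    Stable sub-segments of the branch are projected onto the parameter
    axis; pairwise overlaps are merged.
    """
    if not branch.points:
        raise ConfigurationError("empty branch")
    segments: list[tuple[float, float]] = []
    cur: list[float] = []
    for pt in branch.points:
        if pt.stability == "stable":
            cur.append(pt.param)
        else:
            if len(cur) >= 2:
                segments.append((min(cur), max(cur)))
            cur = []
    if len(cur) >= 2:
        segments.append((min(cur), max(cur)))
    overlaps: list[tuple[float, float]] = []
    for i in range(len(segments)):
        for j in range(i + 1, len(segments)):
            lo = max(segments[i][0], segments[j][0])
            hi = min(segments[i][1], segments[j][1])
            if lo < hi:
                overlaps.append((lo, hi))
    overlaps.sort()
    merged: list[tuple[float, float]] = []
    for lo, hi in overlaps:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# Pseudo-arclength continuation
# ---------------------------------------------------------------------------


def _stability_from_eigs(J: np.ndarray, tol: float = 1e-8) -> tuple[str, float]:
    lead = float(np.max(np.linalg.eigvals(J).real))
    if lead < -tol:
        return "stable", lead
    if lead > tol:
        return "unstable", lead
    return "marginal", lead


def _corrector(field: VectorField, y_pred: np.ndarray, tangent: np.ndarray,
               weights: np.ndarray, tol: float = 1e-10,
               max_iter: int = 12) -> np.ndarray | None:
    """Newton on the augmented system {f = 0, tangent·(y − y_pred) = 0}.

    ``y`` stacks (state, log10 parameter); ``weights`` scale the state
    block of the arclength metric.
    """
    y = y_pred.copy()
    n = len(y) - 1
    for _ in range(max_iter):
        x, u = y[:n], y[-1]
        p = 10.0**u
        try:
            fv = field.f(x, p)
        except (DomainError, FloatingPointError):
            return None
        g = np.concatenate([fv, [tangent @ ((y - y_pred) * weights)]])
        if np.max(np.abs(g[:-1])) < tol * (1.0 + np.max(np.abs(x))) and abs(g[-1]) < 1e-10:
            return y
        Jx = field.jac_x(x, p)
        Jp = field.jac_p(x, p) * p * math.log(10.0)
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = Jx
        A[:n, -1] = Jp
        A[-1, :] = tangent * weights
        try:
            step = np.linalg.solve(A, -g)
        except np.linalg.LinAlgError:
            return None
        y = y + step
        if not np.all(np.isfinite(y)):
            return None
    return None


def _tangent(field: VectorField, y: np.ndarray, weights: np.ndarray,
             prev: np.ndarray | None) -> np.ndarray | None:
    n = len(y) - 1
    x, u = y[:n], y[-1]
    p = 10.0**u
    Jx = field.jac_x(x, p)
    Jp = field.jac_p(x, p) * p * math.log(10.0)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = Jx
    A[:n, -1] = Jp
    A[-1, :] = prev * weights if prev is not None else np.eye(n + 1)[-1] * weights
    b = np.zeros(n + 1)
    b[-1] = 1.0
    try:
        t = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        # fall back to the null space of [Jx Jp]
        M = np.hstack([Jx, Jp[:, None]])
        _, _, Vt = np.linalg.svd(M)
        t = Vt[-1]
    norm = math.sqrt(float((t * weights) @ (t * weights)))
    if norm == 0 or not np.isfinite(norm):
        return None
    t = t / norm
    if prev is not None and (t * weights) @ (prev * weights) < 0:
        t = -t
    return t


def continue_branch(field: VectorField, free_param: str,
                    p_range: tuple[float, float], x_start: np.ndarray,
                    direction: int = +1,
                    max_steps: int = 2000,
                    h0: float = 0.01, h_min: float = 1e-4, h_max: float = 0.1,
                    stability_tol: float = 1e-8) -> BifurcationBranch:
    """Pseudo-arclength continuation with fold detection.

    Continues in log10 of the parameter, starting at the low end of
    ``p_range`` (``direction=+1``) or the high end (``direction=-1``);
    steps are fractions of the parameter's log-range, adapted between
    ``h_min`` and ``h_max``.  Folds are located by bisection on the sign
    change of the parameter-direction tangent component and recorded as
    :class:`LimitPoint`.  Terminates at the range boundary, after
    ``max_steps``, or on corrector failure (annotated on the branch).
    """
    p_lo, p_hi = p_range
    if not (0 < p_lo < p_hi):
        raise ConfigurationError("parameter range must satisfy 0 < lo < hi")
    u_lo, u_hi = math.log10(p_lo), math.log10(p_hi)
    log_span = u_hi - u_lo
    n = len(x_start)
    # state weights: relative scaling so molecule counts and log-parameter
    # contribute comparably to arclength
    weights = np.ones(n + 1)
    weights[:n] = 1.0 / (1.0 + np.abs(x_start))

    p_start = p_lo if direction > 0 else p_hi
    y = np.concatenate([np.asarray(x_start, dtype=float),
                        [u_lo if direction > 0 else u_hi]])
    fv = field.f(y[:n], p_start)
    scale = 1.0 + float(np.max(np.abs(x_start)))
    if np.max(np.abs(fv)) > 1e-8 * scale:
        raise ConfigurationError(
            "x_start is not an equilibrium at the start of the range "
            f"(‖f‖∞ = {np.max(np.abs(fv)):.3g})"
        )

    branch = BifurcationBranch(free_param, [])

    def record(yv: np.ndarray) -> None:
        x, u = yv[:n], yv[-1]
        J = field.jac_x(x, 10.0**u)
        stab, lead = _stability_from_eigs(J, stability_tol)
        branch.points.append(BranchPoint(10.0**u, x.copy(), stab, lead))

    record(y)
    t = _tangent(field, y, weights, None)
    if t is None:
        branch.failure = "no initial tangent"
        return branch
    if t[-1] * direction < 0:
        t = -t  # move into the range
    h = h0 * log_span

    for _ in range(max_steps):
        moved = False
        while h >= h_min * log_span * 0.999:
            y_pred = y + h * t
            y_new = _corrector(field, y_pred, t, weights)
            if y_new is not None:
                moved = True
                break
            h *= 0.5
        if not moved:
            branch.failure = f"corrector failed near p = {10.0**y[-1]:.4g}"
            break
        t_new = _tangent(field, y_new, weights, t)
        if t_new is None:
            branch.failure = f"tangent failed near p = {10.0**y_new[-1]:.4g}"
            break
        # fold: parameter-direction tangent component changes sign
        if t[-1] * t_new[-1] < 0:
            fold = _locate_fold(field, y, t, y_new, weights)
            if fold is not None:
                branch.limit_points.append(fold)
        # refresh weights so states crossing decades stay balanced
        weights = np.ones(n + 1)
        weights[:n] = 1.0 / (1.0 + np.abs(y_new[:n]))
        y, t = y_new, t_new
        record(y)
        h = min(h * 1.3, h_max * log_span)
        if y[-1] > u_hi + 1e-9 or y[-1] < u_lo - 1e-9:
            break
    return branch


def _locate_fold(field: VectorField, y_a: np.ndarray, t_a: np.ndarray,
                 y_b: np.ndarray, weights: np.ndarray,
                 iters: int = 60) -> LimitPoint | None:
    """Bisect the arclength between two points bracketing a tangent sign
    change."""
    n = len(y_a) - 1
    ta = t_a
    a, b = y_a.copy(), y_b.copy()
    sign_a = ta[-1]
    for _ in range(iters):
        mid_pred = 0.5 * (a + b)
        t_mid_dir = b - a
        norm = np.linalg.norm(t_mid_dir * weights)
        if norm == 0:
            break
        t_dir = t_mid_dir / norm
        y_mid = _corrector(field, mid_pred, t_dir, weights)
        if y_mid is None:
            break
        t_mid = _tangent(field, y_mid, weights, t_dir)
        if t_mid is None:
            break
        if abs(t_mid[-1]) < 1e-10 or np.linalg.norm((b - a) * weights) < 1e-12:
            return LimitPoint(10.0**y_mid[-1], y_mid[:n].copy(), float(t_mid[-1]))
        if t_mid[-1] * sign_a > 0:
            a = y_mid
        else:
            b = y_mid
    y_mid = 0.5 * (a + b)
    return LimitPoint(10.0**y_mid[-1], y_mid[:n].copy(), 0.0)


# ---------------------------------------------------------------------------
# Parameter boxes and multistationarity screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterBox:
    """Per-parameter log-ranges with a sampling scheme."""

    ranges: dict[str, tuple[float, float]]
    scheme: str = "log-uniform"  # or "latin-hypercube"
    n_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo < hi):
                raise ConfigurationError(
                    f"box range for {name!r} must satisfy 0 < lo < hi"
                )
        if self.scheme not in ("log-uniform", "latin-hypercube"):
            raise ConfigurationError(f"unknown sampling scheme {self.scheme!r}")

    @classmethod
    def around(cls, center: dict[str, float], decades: float = 1.0,
               **kwargs) -> "ParameterBox":
        """Box spanning ``center`` ± ``decades`` in log10 per parameter."""
        f = 10.0**decades
        return cls({k: (v / f, v * f) for k, v in center.items()}, **kwargs)

    @property
    def center(self) -> dict[str, float]:
        return {k: math.sqrt(lo * hi) for k, (lo, hi) in self.ranges.items()}

    def samples(self) -> list[dict[str, float]]:
        rng = np.random.default_rng(self.seed)
        names = list(self.ranges)
        los = np.log([self.ranges[k][0] for k in names])
        his = np.log([self.ranges[k][1] for k in names])
        if self.scheme == "latin-hypercube":
            from scipy.stats import qmc

            u = qmc.LatinHypercube(d=len(names), seed=rng).random(self.n_samples)
        else:
            u = rng.uniform(size=(self.n_samples, len(names)))
        draws = np.exp(los + u * (his - los))
        return [dict(zip(names, row)) for row in draws]


@dataclass
class BistabilityReport:
    params: dict[str, float]
    n_stable: int
    n_unstable: int
    witness: bool
    error: str | None = None
    fold_residual: float | None = None

    @property
    def n_equilibria(self) -> int:
        return self.n_stable + self.n_unstable


def search_limit_points(factory: Callable[[dict], tuple[ReactionNetwork, ParameterSet]],
                        box: ParameterBox,
                        n_starts: int = 8,
                        presim_starts: int = 2,
                        include_center: bool = True,
                        attempt_fold: bool = False,
                        free_params: Sequence[str] | None = None
                        ) -> list[BistabilityReport]:
    """Screen a parameter box for bistability witnesses.

    ``factory`` maps a parameter draw to ``(network, ParameterSet)``.
    Each sampled set is screened by multistart equilibrium enumeration;
    a witness has ≥ 2 stable equilibria.  With ``include_center`` the
    box's geometric center is evaluated first (the nominal parameter
    set).  With ``attempt_fold``, monostable samples additionally get a
    local fold search: the residual of the augmented system
    {f = 0, smallest singular value of the Jacobian = 0} is minimized
    over (state, first free parameter) and recorded.

    Deterministic given the box seed.
    """
    if free_params is not None:
        missing = [p for p in free_params if p not in box.ranges]
        if missing:
            raise ConfigurationError(f"box is missing free parameters {missing}")
    draws = ([box.center] if include_center else []) + box.samples()
    reports: list[BistabilityReport] = []
    for k, draw in enumerate(draws):
        try:
            network, params = factory(draw)
            eqs = find_steady_states(network, params, n_starts=n_starts,
                                     seed=box.seed + k,
                                     presim_starts=presim_starts)
        except Exception as exc:  # noqa: BLE001 — a failed draw is a report, not a crash
            reports.append(BistabilityReport(draw, 0, 0, False, error=str(exc)))
            continue
        n_stable = len(eqs.stable)
        rep = BistabilityReport(draw, n_stable, len(eqs) - n_stable,
                                witness=n_stable >= 2)
        if attempt_fold and n_stable == 1 and len(eqs) == 1:
            rep.fold_residual = _fold_residual_search(
                network, params, eqs.equilibria[0].state,
                next(iter(box.ranges)), box.ranges)
        reports.append(rep)
    return reports


def _fold_residual_search(network: ReactionNetwork, params: ParameterSet,
                          x_eq: np.ndarray, pname: str,
                          ranges: dict[str, tuple[float, float]]) -> float:
    """Minimize ‖f‖² + σ_min(J)² over (log state, log parameter)."""
    from scipy.optimize import minimize

    red = ReducedSystem(network, params=params)
    x0 = np.log(red.reduce_state(x_eq) + 1e-9)
    lo, hi = ranges[pname]
    p0 = math.log(params[pname])

    def obj(z):
        x = np.exp(z[:-1])
        p = math.exp(z[-1])
        if not (lo <= p <= hi):
            return 1e6
        pp = params.updated(**{pname: p})
        try:
            fv = red.f(x, pp)
            J = red.jac(x, pp)
        except DomainError:
            return 1e6
        smin = float(np.linalg.svd(J, compute_uv=False)[-1])
        scale = 1.0 + float(np.max(np.abs(x)))
        return float(np.sum((fv / scale) ** 2)) + (smin / (1e-12 + np.linalg.norm(J))) ** 2

    res = minimize(obj, np.concatenate([x0, [p0]]), method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-8, "fatol": 1e-14})
    return float(res.fun)


# ---------------------------------------------------------------------------
# The toggle-switch bifurcation diagram
# ---------------------------------------------------------------------------


def toggle_branch(witness_params: dict[str, float] | ParameterSet,
                  variant: str = "unspecific_neutral",
                  free_param: str = "beta1",
                  span_decades: float = 1.5,
                  direction: int = +1):
    """Continuation of the toggle's equilibria in the sgRNA-1 production
    rate, reporting total sgRNA-2 — the bifurcation-diagram view of the
    bistable switch.

    Returns ``(branch, table)``: the branch carries fold locations
    (tangent bifurcations); the table is plot-ready with columns
    (parameter, sg2 level, stability).  The ordinate is the *total*
    sgRNA-2 complex level (free + DNA-bound).
    """
    from .circuits import make_toggle, toggle_params

    net = make_toggle(variant)
    if isinstance(witness_params, ParameterSet):
        params = witness_params
    else:
        params = toggle_params(variant, **witness_params)
    p0 = params[free_param]
    p_lo, p_hi = p0 / 10.0**span_decades, p0 * 10.0**span_decades

    p_start = p_lo if direction > 0 else p_hi
    params_start = params.updated(**{free_param: p_start})
    eqs = find_steady_states(net, params_start, n_starts=24, seed=1)
    # at low sgRNA-1 production the high-sgRNA-2 state dominates and
    # vice versa; pick the attractor the sweep direction starts from
    key = (max if direction > 0 else min)
    start = key(eqs.stable, key=lambda e: net.observe(e.state)["sg2_total"])

    field, red = VectorField.from_network(net, params, free_param)
    branch = continue_branch(field, free_param, (p_lo, p_hi),
                             red.reduce_state(start.state),
                             direction=direction)

    vec = np.zeros(net.n_species)
    for sp, c in net.outputs["sg2_total"].items():
        vec[net.species_index(sp)] += c

    def ordinate(x_red: np.ndarray) -> float:
        return float(vec @ red.full_state(x_red))

    table = branch.to_frame(observable=ordinate, name="sg2_total")
    return branch, table
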