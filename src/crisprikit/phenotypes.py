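"""Quantification of in-silico circuit behaviors.

These are the same summary statistics used to characterize the wet
circuits: maximal fold-repression of a NOT gate, dose-response curves,
stripe (band-pass) detection for IFFLs, hysteresis state retention for
the toggle switch, and limit-cycle period for the ring oscillator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import correlate, find_peaks, savgol_filter

from .dynamics import TimeSeries, find_steady_states, steady_state_observable
from .errors import ConfigurationError, DomainError
from .reaction_core import ParameterSet, ReactionNetwork


def fold_repression(induced_level: float, control_level: float) -> float:
    """Reporter of a no-sgRNA control divided by the repressed circuit's."""
    if induced_level <= 0 or control_level <= 0:
        raise DomainError("fold_repression requires strictly positive levels")
    return control_level / induced_level


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------


@dataclass
class DoseResponse:
    """Steady-state observables on an inducer grid (log-spaced incl. 0)."""

    inducer: str
    grid: np.ndarray
    values: dict[str, np.ndarray]
    normalization: str = "raw"  # "raw" | "percent"

    def percent(self) -> "DoseResponse":
        vals = {k: 100.0 * v / np.max(v) for k, v in self.values.items()}
        return DoseResponse(self.inducer, self.grid.copy(), vals, "percent")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({self.inducer: self.grid})
        for k, v in self.values.items():
            df[k] = v
        return df


def default_dose_grid(lo: float = 1e-4, hi: float = 0.2, n: int = 12) -> np.ndarray:
    """Log-spaced inducer grid with an explicit zero dose prepended."""
    return np.concatenate([[0.0], np.geomspace(lo, hi, n - 1)])


def dose_response(network: ReactionNetwork, grid: np.ndarray,
                  inducer: str | None = None,
                  observables: list[str] | None = None,
                  params: ParameterSet | None = None,
                  percent: bool = False,
                  check_monostable: bool = False,
                  n_starts: int = 8, seed: int = 0) -> DoseResponse:
    """Steady-state observables at each inducer level.

    With ``check_monostable=True`` each grid point is screened by
    multistart enumeration and a multistable point raises, directing the
    user to the continuation tools instead.
    """
    params = params or network.default_params
    if inducer is None:
        if len(network.inducer_inputs) != 1:
            raise ConfigurationError(
                "network defines several inducers; name one explicitly"
            )
        inducer = next(iter(network.inducer_inputs))
    if inducer not in network.inducer_inputs:
        raise ConfigurationError(f"unknown inducer {inducer!r}")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ConfigurationError("inducer grid must be strictly increasing")
    observables = observables or list(network.outputs)
    values = {k: np.empty(len(grid)) for k in observables}
    for i, c in enumerate(grid):
        overrides = {p: imap.rate(c) for p, imap in network.inducer_inputs[inducer]}
        p_c = params.updated(**overrides)
        if check_monostable:
            eqs = find_steady_states(network, p_c, n_starts=n_starts, seed=seed)
            if len(eqs.stable) > 1:
                raise ConfigurationError(
                    f"multistability at {inducer} = {c:g}: dose_response is "
                    "undefined; use the bifurcation tools"
                )
        for k in observables:
            values[k][i] = steady_state_observable(network, p_c, k)
    dr = DoseResponse(inducer, grid, values)
    return dr.percent() if percent else dr


# ---------------------------------------------------------------------------
# Stripe detection
# ---------------------------------------------------------------------------


@dataclass
class StripeCall:
    peak_present: bool
    peak_inducer: float | None = None
    peak_height: float | None = None
    window: tuple[float, float] | None = None  # ON-window at fraction of peak


def stripe_call(dr: DoseResponse, node: str, fraction: float = 0.5,
                peak_factor: float = 1.5) -> StripeCall:
    """Detect an interior maximum ("stripe") in a dose-response curve.

    A peak is called when the interior maximum exceeds both boundary
    values by at least ``peak_factor``.  The ON-window is the inducer
    range where the curve stays above ``fraction`` of the peak
    (linearly interpolated on log-dose away from zero).
    """
    if len(dr.grid) < 7:
        raise ConfigurationError("stripe_call needs at least 7 grid points")
    y = np.asarray(dr.values[node], dtype=float)
    x = np.asarray(dr.grid, dtype=float)
    i = int(np.argmax(y[1:-1])) + 1
    peak = y[i]
    if not (peak >= peak_factor * y[0] and peak >= peak_factor * y[-1]):
        return StripeCall(False)
    level = fraction * peak
    above = y >= level

    def cross(j0: int, j1: int) -> float:
        x0, x1, y0, y1 = x[j0], x[j1], y[j0], y[j1]
        if x0 > 0 and x1 > 0:
            lx = np.log(x0) + (level - y0) * (np.log(x1) - np.log(x0)) / (y1 - y0)
            return float(np.exp(lx))
        return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))

    lo = x[0] if above[0] else None
    for j in range(i, 0, -1):
        if not above[j - 1]:
            lo = cross(j - 1, j)
            break
    hi = x[-1] if above[-1] else None
    for j in range(i, len(x) - 1):
        if not above[j + 1]:
            hi = cross(j, j + 1)
            break
    return StripeCall(True, float(x[i]), float(peak),
                      (float(lo if lo is not None else x[0]),
                       float(hi if hi is not None else x[-1])))


# ---------------------------------------------------------------------------
# Hysteresis
# ---------------------------------------------------------------------------


@dataclass
class HysteresisResult:
    labels: list[str]              # per-phase-end "HIGH"/"LOW"
    retentions: list[bool]         # per inducer-free phase: kept predecessor label
    threshold: float
    warning: str | None = None

    @property
    def all_retained(self) -> bool:
        return all(self.retentions) if self.retentions else False


def hysteresis_score(protocol_ts: TimeSeries, channel: str = "reporter",
                     threshold: float | None = None,
                     stable_levels: tuple[float, float] | None = None) -> HysteresisResult:
    """Label each phase-end state HIGH/LOW and score state retention.

    The default threshold is the geometric mean of the two stable reporter
    levels (``stable_levels``), the model analog of the cytometry gate.
    A retention flag is set per inducer-free phase: did it keep the
    preceding phase's label?
    """
    if len(protocol_ts.phases) < 2:
        raise ConfigurationError("hysteresis needs a protocol with ≥ 2 phases")
    if threshold is None:
        if stable_levels is None:
            raise ConfigurationError(
                "supply threshold or the two stable reporter levels"
            )
        lo, hi = sorted(stable_levels)
        if lo <= 0:
            raise DomainError("stable reporter levels must be positive")
        threshold = float(np.sqrt(lo * hi))
    ends = [ph["end_observables"][channel] for ph in protocol_ts.phases]
    warning = None
    if not (min(ends) < threshold < max(ends)):
        warning = (
            f"threshold {threshold:.4g} is not bracketed by observed phase-end "
            f"levels [{min(ends):.4g}, {max(ends):.4g}]"
        )
    labels = ["HIGH" if v > threshold else "LOW" for v in ends]
    retentions = []
    for k, ph in enumerate(protocol_ts.phases):
        if k > 0 and ph["inducer"] is None:
            retentions.append(labels[k] == labels[k - 1])
    return HysteresisResult(labels, retentions, threshold, warning)


# ---------------------------------------------------------------------------
# Oscillations
# ---------------------------------------------------------------------------


@dataclass
class OscillationSummary:
    sustained: bool
    period: float | None = None          # hours
    period_dispersion: float | None = None  # CV of successive-maxima spacings
    amplitude: float | None = None
    n_peaks: int = 0
    phase_offsets: dict[str, float] = field(default_factory=dict)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    window = max(3, int(window))
    if window % 2 == 0:
        window += 1
    if window >= len(y):
        window = len(y) - 1 if (len(y) - 1) % 2 == 1 else len(y) - 2
    if window < 3:
        return y
    return savgol_filter(y, window, polyorder=2)


def oscillation_summary(ts: TimeSeries, channel: str,
                        transient: float = 20.0,
                        smooth_window: int = 7,
                        decay_threshold: float = 0.9) -> OscillationSummary:
    """Period and sustainment of a putatively oscillating channel.

    The first ``transient`` hours are discarded (imaging started after
    20 h in the source experiments), the channel is smoothed with a local
    polynomial (Savitzky–Golay) filter, and the period is the mean
    spacing of successive maxima.  Sustained oscillation requires the
    amplitude over the last three cycles to hold at ≥ ``decay_threshold``
    of the amplitude three cycles earlier.  Fewer than two maxima give a
    not-oscillating result rather than an error.
    """
    mask = ts.t >= transient
    t = ts.t[mask]
    y = ts.channel(channel)[mask]
    if len(t) < 5:
        raise ConfigurationError("time series too short after transient removal")
    ys = _smooth(y, smooth_window)
    span = float(np.max(ys) - np.min(ys))
    if span <= 0:
        return OscillationSummary(False)
    peaks, props = find_peaks(ys, prominence=0.1 * span)
    if len(peaks) < 2:
        return OscillationSummary(False, n_peaks=len(peaks))
    spacings = np.diff(t[peaks])
    period = float(np.mean(spacings))
    dispersion = float(np.std(spacings) / period) if period > 0 else None
    prom = props["prominences"]
    if len(prom) >= 4:
        decay = float(prom[-1] / prom[-4])
    else:
        decay = float(prom[-1] / prom[0])
    sustained = decay >= decay_threshold
    amplitude = float(np.mean(prom[-3:]))
    offsets = {}
    dt = float(np.median(np.diff(t)))
    for name in ts.observables:
        if name == channel:
            continue
        other = _smooth(ts.channel(name)[mask], smooth_window)
        a = ys - np.mean(ys)
        b = other - np.mean(other)
        cc = correlate(b, a, mode="full")
        lags = (np.arange(len(cc)) - (len(a) - 1)) * dt
        sel = np.abs(lags) <= period
        lag = float(lags[sel][np.argmax(cc[sel])])
        offsets[name] = lag % period
    return OscillationSummary(sustained, period, dispersion, amplitude,
                              n_peaks=len(peaks), phase_offsets=offsets)


def measure_not_gate_fold(preset: str | None = None,
                          network: ReactionNetwork | None = None,
                          params: ParameterSet | None = None) -> float:
    """Maximal fold-repression of a NOT gate (saturating inducer vs.
    no-sgRNA control); accepts a preset name or a prebuilt network."""
    from .circuits import make_not_gate, measure_max_fold_repression

    if network is None:
        if preset is None:
            raise ConfigurationError("give a preset name or a network")
        network = make_not_gate(preset)
    return measure_max_fold_repression(network, params)
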