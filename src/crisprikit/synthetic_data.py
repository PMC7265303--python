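"""Synthetic wet-lab readouts and their normalization.

Emulates the three measurement modalities used to characterize the
circuits — microplate-reader fluorescence, flow-cytometry single-cell
distributions and 10-min-interval time-lapse traces — and implements the
exact normalization and gating procedures applied to the real data:

* plate reader: blank subtraction, OD600 correction, autofluorescence
  subtraction, percent-of-max scaling;
* cytometry: threshold gating of green cells at 330 a.u.;
* time lapse: per-channel minimum subtraction, percent-of-max scaling.

All generators are deterministic given a seed.  Noise magnitudes are
package defaults (the measurements themselves don't publish them): 5 %
multiplicative lognormal CV, blank 100 ± 5 a.u., autofluorescence
200 a.u., OD600 0.5 ± 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigurationError, DomainError
from .phenotypes import DoseResponse


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for the synthetic generators."""

    cv: float = 0.05                 # multiplicative lognormal CV
    blank_mean: float = 100.0        # additive plate/medium background (a.u.)
    blank_sd: float = 5.0
    autofluorescence: float = 200.0  # per-OD cell autofluorescence (a.u.)
    od_mean: float = 0.5             # OD600 of non-blank wells after growth
    od_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.blank_sd < 0 or self.od_sd < 0:
            raise ConfigurationError("noise magnitudes must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NOISELESS = NoiseModel(cv=0.0, blank_sd=0.0, od_sd=0.0)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Plate reader
# ---------------------------------------------------------------------------


def gen_platereader(dr: DoseResponse, noise: NoiseModel = NoiseModel(),
                    replicates: int = 3) -> pd.DataFrame:
    """Synthetic 96-well plate-reader table for a dose-response truth.

    Each row is one well: raw fluorescence =
    ``(true·lognormal(CV) + autofluorescence)·OD + blank``.
    Blank wells (medium only) and an autofluorescence control strain
    (no reporter) are included per dose so the normalization procedure
    has its references.
    """
    if replicates < 1:
        raise ConfigurationError("need at least one replicate")
    rng = noise.rng()
    channels = list(dr.values)
    rows = []
    well = 0
    for rep in range(replicates):
        # blank well (medium only: no cells, no OD signal beyond blank)
        blank = rng.normal(noise.blank_mean, noise.blank_sd, size=len(channels))
        rows.append({"well": f"W{well:03d}", "dose": np.nan, "replicate": rep,
                     "od600": 1.0, "is_blank": True, "is_autofluor": False,
                     **{f"raw_{c}": max(b, 0.0) for c, b in zip(channels, blank)}})
        well += 1
        # autofluorescence control strain, one well per dose
        for dose in dr.grid:
            od = max(rng.normal(noise.od_mean, noise.od_sd), 1e-3)
            blank = rng.normal(noise.blank_mean, noise.blank_sd, size=len(channels))
            raw = {f"raw_{c}": noise.autofluorescence * od + max(b, 0.0)
                   for c, b in zip(channels, blank)}
            rows.append({"well": f"W{well:03d}", "dose": dose, "replicate": rep,
                         "od600": od, "is_blank": False, "is_autofluor": True, **raw})
            well += 1
        for i, dose in enumerate(dr.grid):
            od = max(rng.normal(noise.od_mean, noise.od_sd), 1e-3)
            blank = rng.normal(noise.blank_mean, noise.blank_sd, size=len(channels))
            raw = {}
            for c, b in zip(channels, blank):
                true = dr.values[c][i]
                meas = true * _lognormal_factor(rng, noise.cv, None)
                raw[f"raw_{c}"] = (meas + noise.autofluorescence) * od + max(b, 0.0)
            rows.append({"well": f"W{well:03d}", "dose": dose, "replicate": rep,
                         "is_blank": False, "is_autofluor": False, "od600": od, **raw})
            well += 1
    return pd.DataFrame(rows)


def normalize_platereader(records: pd.DataFrame,
                          percent: bool = True) -> pd.DataFrame:
    """Blank subtraction → OD600 division → autofluorescence subtraction
    (→ percent-of-max scaling), mirroring the plate-reader pipeline.

    Requires blank wells and an autofluorescence control strain in the
    table.  Returns one row per sample well with ``corr_*`` (and
    ``pct_*``) columns.
    """
    channels = [c[4:] for c in records.columns if c.startswith("raw_")]
    blanks = records[records["is_blank"]]
    autos = records[records["is_autofluor"]]
    if blanks.empty or autos.empty:
        raise ConfigurationError(
            "table must contain blank wells and an autofluorescence control strain"
        )
    samples = records[~records["is_blank"] & ~records["is_autofluor"]].copy()
    for c in channels:
        blank = blanks[f"raw_{c}"].mean()
        # autofluorescence control, itself blank-subtracted and OD-corrected
        auto = ((autos[f"raw_{c}"] - blank) / autos["od600"]).mean()
        samples[f"corr_{c}"] = (samples[f"raw_{c}"] - blank) / samples["od600"] - auto
    if percent:
        for c in channels:
            top = samples[f"corr_{c}"].max()
            samples[f"pct_{c}"] = 100.0 * samples[f"corr_{c}"] / top if top > 0 else 0.0
    return samples


# ---------------------------------------------------------------------------
# Flow cytometry
# ---------------------------------------------------------------------------

GATE_THRESHOLD = 330.0  # FITC-H a.u.; the published green-cell gate


@dataclass
class FlowSample:
    """Single-channel per-event fluorescence values with the gate used."""

    values: np.ndarray
    gate_threshold: float = GATE_THRESHOLD

    @property
    def n_events(self) -> int:
        return len(self.values)


def gen_flow(low_level: float, high_level: float, high_fraction: float,
             n_events: int = 20_000, log10_sd: float = 0.35,
             seed: int = 0) -> FlowSample:
    """Two-component lognormal mixture of single-cell green fluorescence.

    ``high_fraction`` of cells sit in the HIGH basin (center
    ``high_level``), the rest at ``low_level``; both components have the
    given log10 standard deviation (typical cytometry spread).
    """
    if not 0.0 <= high_fraction <= 1.0:
        raise ConfigurationError("high_fraction must be in [0, 1]")
    if low_level <= 0 or high_level <= 0:
        raise DomainError("component centers must be positive")
    rng = np.random.default_rng(seed)
    n_high = int(rng.binomial(n_events, high_fraction))
    vals = np.concatenate([
        10.0 ** rng.normal(np.log10(high_level), log10_sd, n_high),
        10.0 ** rng.normal(np.log10(low_level), log10_sd, n_events - n_high),
    ])
    rng.shuffle(vals)
    return FlowSample(vals)


def gate_green(sample: FlowSample,
               threshold: float = GATE_THRESHOLD) -> float:
    """Percent of events strictly above the gate threshold."""
    if sample.n_events == 0:
        raise ConfigurationError("empty flow sample")
    return 100.0 * float(np.sum(sample.values > threshold)) / sample.n_events


# ---------------------------------------------------------------------------
# Time-lapse traces
# ---------------------------------------------------------------------------


def gen_timelapse(ts, channels: list[str] | None = None,
                  frame_interval_h: float = 1.0 / 6.0,
                  noise: NoiseModel = NoiseModel()) -> pd.DataFrame:
    """Resample a trajectory to the imaging frame grid, add measurement
    noise, then apply the time-lapse normalization: per-channel minimum
    subtraction and percent-of-max scaling.

    Returns a tidy frame with ``raw_*`` and ``norm_*`` columns.
    """
    channels = channels or list(ts.observables)
    t0, t1 = float(ts.t[0]), float(ts.t[-1])
    frames = np.arange(t0, t1 + 1e-9, frame_interval_h)
    if len(frames) < 2:
        raise ConfigurationError("trajectory too short for the frame interval")
    rng = noise.rng()
    out = {"time_h": frames}
    for c in channels:
        true = np.interp(frames, ts.t, ts.channel(c))
        raw = true * _lognormal_factor(rng, noise.cv, len(frames))
        out[f"raw_{c}"] = raw
        norm = normalize_trace(raw)
        out[f"norm_{c}"] = norm
    return pd.DataFrame(out)


def normalize_trace(raw: np.ndarray) -> np.ndarray:
    """Minimum subtraction then percent-of-max; idempotent on its output."""
    shifted = np.asarray(raw, dtype=float) - np.min(raw)
    top = np.max(shifted)
    return 100.0 * shifted / top if top > 0 else shifted


# ---------------------------------------------------------------------------
# Hill-curve recovery
# ---------------------------------------------------------------------------


def hill_response(dose: np.ndarray, top: float, bottom: float,
                  K: float, n: float) -> np.ndarray:
    """Decreasing Hill curve (a NOT gate's reporter vs. inducer)."""
    dose = np.asarray(dose, dtype=float)
    h = np.where(dose > 0, dose**n, 0.0)
    return bottom + (top - bottom) * K**n / (K**n + h)


def fit_hill(dose: np.ndarray, response: np.ndarray,
             p0: tuple | None = None) -> dict[str, float]:
    """Least-squares fit of a decreasing Hill curve; returns top, bottom,
    K and n."""
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    top0 = float(np.max(response))
    bot0 = float(max(np.min(response), 1e-6))
    pos = dose[dose > 0]
    K0 = float(np.sqrt(pos.min() * pos.max())) if len(pos) else 1.0
    p0 = p0 or (top0, bot0, K0, 1.5)
    bounds = ([1e-9, 0.0, 1e-9, 0.2], [np.inf, np.inf, np.inf, 8.0])
    popt, _ = curve_fit(hill_response, dose, response, p0=p0, bounds=bounds,
                        maxfev=20_000)
    return {"top": popt[0], "bottom": popt[1], "K": popt[2], "n": popt[3]}


def hill_recovery_study(K: float = 0.02, n: float = 2.0,
                        top: float = 1000.0, bottom: float = 40.0,
                        doses: np.ndarray | None = None,
                        replicates: int = 3, cv: float = 0.05,
                        n_trials: int = 100, seed: int = 0,
                        tolerance: float = 0.15) -> dict:
    """Parameter-recovery study: generate noisy plate-reader data from a
    known Hill dose-response, re-fit (K, n), and report the fraction of
    trials recovering both within ``tolerance`` relative error.
    """
    if doses is None:
        doses = np.concatenate([[0.0], np.geomspace(1e-3, 0.2, 7)])
    truth = DoseResponse("Ara", doses, {"gfp": hill_response(doses, top, bottom, K, n)})
    ok = 0
    fits = []
    for trial in range(n_trials):
        noise = NoiseModel(cv=cv, seed=seed * 100_003 + trial)
        rec = gen_platereader(truth, noise, replicates=replicates)
        norm = normalize_platereader(rec, percent=False)
        agg = norm.groupby("dose", dropna=False)["corr_gfp"].mean().reset_index()
        fit = fit_hill(agg["dose"].to_numpy(), agg["corr_gfp"].to_numpy())
        fits.append(fit)
        if (abs(fit["K"] - K) / K <= tolerance
                and abs(fit["n"] - n) / n <= tolerance):
            ok += 1
    return {"success_fraction": ok / n_trials, "n_trials": n_trials,
            "fits": fits, "K": K, "n": n}
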