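"""Rate statistics and nitrogen-balance diagnostics from fitted sigmoids.

From a fitted Boltzmann curve for a cumulative product series this module
derives the quantities used to characterise nitrification potential:

* the **average rate** over a window [T_i, T_f],
  V̄ = (y_fit(T_f) − y_fit(T_i)) / (T_f − T_i) — evaluated on *fitted*
  endpoint values (a raw-endpoint mode exists for comparison).  Applied
  to the NOx⁻ = NO2⁻+NO3⁻ fit it is the average ammonia-oxidation rate
  V̄ₐ; applied to the NO3⁻ fit, the average nitrite-oxidation rate V̄ₙ;
* the **instantaneous rate curve** dy/dt with its maximum and the time
  at which it occurs (closed form: (A2−A1)/(4·dt) at t0 when t0 lies in
  the window, else the derivative at the window endpoint nearer t0);
* the **lag / exponential / plateau segmentation**, defined by where the
  rate crosses a fraction of its maximum (closed-form quadratic in e^u);
* the **index of nitrogen balance** INB(t) = DIN(t)/DIN(0): values below
  1 indicate net nitrogen loss (denitrification, anammox, assimilation),
  above 1 net release by organic-matter mineralization.

`SampleModel` ties these together into the per-sample workflow: fit NOx
(→ V̄ₐ) and NO3 (→ V̄ₙ), build both rate profiles and the INB series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boltzmann import BoltzmannModel, BoltzmannResults
from .exceptions import ValidationError
from .series import IncubationSeries

__all__ = [
    "average_rate",
    "average_rate_raw",
    "instantaneous_profile",
    "segment_phases",
    "compute_inb",
    "RateProfile",
    "INBSeries",
    "SampleModel",
    "SampleResults",
    "analyze_sample",
]


def _check_window(window):
    t_i, t_f = float(window[0]), float(window[1])
    if not (math.isfinite(t_i) and math.isfinite(t_f)):
        raise ValidationError("window endpoints must be finite")
    if t_f <= t_i:
        raise ValidationError(f"window must satisfy T_final > T_initial, got {window}")
    return t_i, t_f


def average_rate(fit: BoltzmannResults, window) -> float:
    """Average production rate over a window, from fitted endpoint values.

    V̄ = (y_fit(T_f) − y_fit(T_i)) / (T_f − T_i), in µmol L⁻¹ h⁻¹.
    """
    t_i, t_f = _check_window(window)
    return float((fit.predict(t_f) - fit.predict(t_i)) / (t_f - t_i))


def average_rate_raw(times, values, window=None) -> float:
    """Raw-endpoint average rate (Δconcentration / Δtime), for comparison.

    Uses the measured values at the window endpoints (nearest sampled
    times); defaults to the full sampled span.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window is None:
        window = (times[0], times[-1])
    t_i, t_f = _check_window(window)
    i = int(np.argmin(np.abs(times - t_i)))
    f = int(np.argmin(np.abs(times - t_f)))
    if times[f] == times[i]:
        raise ValidationError("window collapses to a single sampled time")
    return float((values[f] - values[i]) / (times[f] - times[i]))


@dataclass(frozen=True)
class RateProfile:
    """Average + instantaneous rate description of one analyte fit."""

    analyte_basis: str  # "NOx" -> Va, "NO3" -> Vn
    v_avg: float  # µmol L⁻¹ h⁻¹
    v_max: float  # µmol L⁻¹ h⁻¹
    t_at_vmax: float  # h
    window: tuple  # (T_initial, T_final), h
    lag_end: float  # h
    plateau_start: float  # h
    grid_times: np.ndarray = field(repr=False)
    grid_rates: np.ndarray = field(repr=False)

    @property
    def rate_label(self) -> str:
        return {"NOx": "Va", "NO3": "Vn"}.get(self.analyte_basis, "V")

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready (time, instantaneous rate) grid."""
        return pd.DataFrame(
            {"time_h": self.grid_times, "rate_umol_L_h": self.grid_rates}
        )


def instantaneous_profile(
    fit: BoltzmannResults, window, threshold_frac=0.10, n_grid=201
) -> RateProfile:
    """Build the instantaneous-rate profile of a fit over a window.

    The derivative of a Boltzmann sigmoid is unimodal with its maximum at
    t0, so v_max is closed-form: (A2−A1)/(4·dt) when t0 ∈ window, else
    the derivative at the window endpoint nearer t0 (the derivative is
    monotone on either side of t0).
    """
    t_i, t_f = _check_window(window)
    if t_i <= fit.t0 <= t_f:
        t_at_vmax = fit.t0
    else:
        t_at_vmax = t_i if abs(t_i - fit.t0) <= abs(t_f - fit.t0) else t_f
    v_max = float(fit.rate(t_at_vmax))
    grid = np.linspace(t_i, t_f, n_grid)
    lag_end, plateau_start = segment_phases(fit, (t_i, t_f), threshold_frac)
    return RateProfile(
        analyte_basis=fit.analyte or "NOx",
        v_avg=average_rate(fit, (t_i, t_f)),
        v_max=v_max,
        t_at_vmax=float(t_at_vmax),
        window=(t_i, t_f),
        lag_end=lag_end,
        plateau_start=plateau_start,
        grid_times=grid,
        grid_rates=np.asarray(fit.rate(grid)),
    )


def segment_phases(fit: BoltzmannResults, window=None, threshold_frac=0.10):
    """Lag-end and plateau-start times of a rising sigmoid fit.

    The boundaries are where the instantaneous rate equals
    ``threshold_frac`` × its maximum (A2−A1)/(4·dt).  Substituting
    r = e^((t−t0)/dt) gives the quadratic

        r² − (4/f − 2)·r + 1 = 0,   f = threshold_frac,

    whose roots r± are reciprocal, so the boundaries are symmetric:
    t = t0 ± dt·ln(r₊).  Results are clipped to the window when given.
    """
    if not 0 < threshold_frac < 1:
        if threshold_frac == 1:
            # degenerate limit: the threshold sits at the maximum itself
            lag_end = plateau_start = fit.t0
            if window is not None:
                t_i, t_f = _check_window(window)
                lag_end = min(max(lag_end, t_i), t_f)
                plateau_start = min(max(plateau_start, t_i), t_f)
            return float(lag_end), float(plateau_start)
        raise ValidationError(
            f"threshold_frac must lie in (0, 1], got {threshold_frac}"
        )
    b = 4.0 / threshold_frac - 2.0
    r_plus = 0.5 * (b + math.sqrt(b * b - 4.0))
    half_width = abs(fit.dt) * math.log(r_plus)
    lag_end = fit.t0 - half_width
    plateau_start = fit.t0 + half_width
    if window is not None:
        t_i, t_f = _check_window(window)
        lag_end = min(max(lag_end, t_i), t_f)
        plateau_start = min(max(plateau_start, t_i), t_f)
    return float(lag_end), float(plateau_start)


@dataclass(frozen=True)
class INBSeries:
    """Time-resolved index of nitrogen balance with interpretation labels.

    INB(t) = DIN(t)/DIN(0) on replicate means.  Labels: ``loss`` when
    INB < 1 − tolerance, ``mineralization`` when INB > 1 + tolerance,
    otherwise ``balanced``.
    """

    times: np.ndarray
    inb: np.ndarray
    labels: list
    tolerance: float

    @property
    def final(self) -> float:
        """Eq.-style final/initial ratio: the last sampled INB value."""
        return float(self.inb[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.times, "inb": self.inb, "label": self.labels}
        )


def _label_inb(value, tolerance):
    if value < 1.0 - tolerance:
        return "loss"
    if value > 1.0 + tolerance:
        return "mineralization"
    return "balanced"


def compute_inb(series: IncubationSeries, tolerance=0.05) -> INBSeries:
    """Index of nitrogen balance DIN(t)/DIN(0) on replicate means."""
    if not 0 <= tolerance < 1:
        raise ValidationError(f"tolerance must lie in [0, 1), got {tolerance}")
    long = series.analyte("DIN")
    grouped = long.groupby("time_h")["value"].mean()
    times = grouped.index.to_numpy(dtype=float)
    din = grouped.to_numpy(dtype=float)
    if din[0] <= 0:
        raise ValidationError(
            "initial DIN is zero: the nitrogen-balance ratio is undefined"
        )
    inb = din / din[0]
    labels = [_label_inb(v, tolerance) for v in inb]
    return INBSeries(times=times, inb=inb, labels=labels, tolerance=tolerance)


# ---------------------------------------------------------------------------
# per-sample workflow


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the per-sample analysis.

    window : (T_initial, T_final) in hours, or None for the sampled span.
    threshold_frac : rate fraction defining the lag/plateau boundaries.
    inb_tolerance : half-width of the "balanced" INB band.
    weighted : weight the fit by 1/SD across replicates.
    seed : seed for the fit's jittered restarts.
    """

    window: tuple | None = None
    threshold_frac: float = 0.10
    inb_tolerance: float = 0.05
    weighted: bool = False
    seed: int = 0

    def to_dict(self):
        return {
            "window": list(self.window) if self.window else None,
            "threshold_frac": self.threshold_frac,
            "inb_tolerance": self.inb_tolerance,
            "weighted": self.weighted,
            "seed": self.seed,
        }


class SampleModel:
    """Full nitrification-kinetics model of one incubation sample.

    Fits NOx⁻ (ammonia oxidation, V̄ₐ) and NO3⁻ (nitrite oxidation, V̄ₙ)
    with the Boltzmann sigmoid and assembles rate profiles and the INB
    diagnostic.  Deterministic given the series and config.
    """

    def __init__(self, series: IncubationSeries, config: AnalysisConfig | None = None):
        self.series = series
        self.config = config or AnalysisConfig()

    def fit(self) -> "SampleResults":
        cfg = self.config
        fits, profiles = {}, {}
        for analyte in ("NOx", "NO3"):
            try:
                model = BoltzmannModel.from_series(
                    self.series, analyte=analyte, weighted=cfg.weighted
                )
                res = model.fit(seed=cfg.seed)
            except Exception as exc:
                raise type(exc)(f"[stage fit:{analyte}] {exc}") from exc
            window = cfg.window or (model.times[0], model.times[-1])
            fits[analyte] = res
            profiles[analyte] = instantaneous_profile(
                res, window, threshold_frac=cfg.threshold_frac
            )
        try:
            inb = compute_inb(self.series, tolerance=cfg.inb_tolerance)
        except Exception as exc:
            raise type(exc)(f"[stage inb] {exc}") from exc
        return SampleResults(
            series=self.series,
            config=cfg,
            ao_fit=fits["NOx"],
            no_fit=fits["NO3"],
            ao_profile=profiles["NOx"],
            no_profile=profiles["NO3"],
            inb=inb,
        )


@dataclass(frozen=True)
class SampleResults:
    """Fitted per-sample report: two sigmoid fits, two rate profiles, INB."""

    series: IncubationSeries
    config: AnalysisConfig
    ao_fit: BoltzmannResults
    no_fit: BoltzmannResults
    ao_profile: RateProfile
    no_profile: RateProfile
    inb: INBSeries

    def rates_table(self) -> pd.DataFrame:
        """One row per analyte: V̄, v_max, t_at_vmax, phase bounds, R²."""
        rows = []
        for fit, prof in ((self.ao_fit, self.ao_profile), (self.no_fit, self.no_profile)):
            rows.append(
                {
                    "analyte": prof.analyte_basis,
                    "rate": prof.rate_label,
                    "v_avg_umol_L_h": prof.v_avg,
                    "v_max_umol_L_h": prof.v_max,
                    "t_at_vmax_h": prof.t_at_vmax,
                    "lag_end_h": prof.lag_end,
                    "plateau_start_h": prof.plateau_start,
                    "r2": fit.rsquared,
                }
            )
        return pd.DataFrame(rows)

    def fits_table(self) -> pd.DataFrame:
        return pd.DataFrame([self.ao_fit.to_record(), self.no_fit.to_record()])

    def curves_table(self) -> pd.DataFrame:
        """Plot-ready grid: fitted values, instantaneous rates, per analyte."""
        frames = []
        for fit, prof in ((self.ao_fit, self.ao_profile), (self.no_fit, self.no_profile)):
            frames.append(
                pd.DataFrame(
                    {
                        "analyte": prof.analyte_basis,
                        "time_h": prof.grid_times,
                        "fitted_umol_L": fit.predict(prof.grid_times),
                        "rate_umol_L_h": prof.grid_rates,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        lines = ["Nitrification kinetics report", "=" * 30]
        for fit in (self.ao_fit, self.no_fit):
            lines.append(fit.summary())
            lines.append("")
        for prof in (self.ao_profile, self.no_profile):
            lines.append(
                f"{prof.rate_label} ({prof.analyte_basis}): "
                f"avg {prof.v_avg:.3f}, max {prof.v_max:.3f} µmol L⁻¹ h⁻¹ "
                f"at {prof.t_at_vmax:.2f} h; lag ends {prof.lag_end:.2f} h, "
                f"plateau from {prof.plateau_start:.2f} h"
            )
        final = self.inb.final
        lines.append(
            f"INB: final {final:.3f} ({_label_inb(final, self.inb.tolerance)}); "
            f"range [{self.inb.inb.min():.3f}, {self.inb.inb.max():.3f}]"
        )
        return "\n".join(lines)

    def plot(self, axes=None):
        """Three-panel figure: concentrations, rate curves, INB."""
        import matplotlib.pyplot as plt  # deferred: plotting is optional

        if axes is None:
            _, axes = plt.subplots(1, 3, figsize=(13, 4))
        ax0, ax1, ax2 = axes
        for analyte, style in (("NH4", "o-"), ("NO2", "s-"), ("NO3", "^-")):
            long = self.series.analyte(analyte)
            m = long.groupby("time_h")["value"].mean()
            ax0.plot(m.index, m.values, style, label=analyte)
        ax0.set_xlabel("time (h)"), ax0.set_ylabel("µmol L⁻¹"), ax0.legend()
        for prof in (self.ao_profile, self.no_profile):
            ax1.plot(prof.grid_times, prof.grid_rates, label=prof.rate_label)
        ax1.set_xlabel("time (h)"), ax1.set_ylabel("µmol L⁻¹ h⁻¹"), ax1.legend()
        ax2.plot(self.inb.times, self.inb.inb, "o-")
        ax2.axhline(1.0, color="grey", ls="--")
        ax2.set_xlabel("time (h)"), ax2.set_ylabel("INB")
        return axes


def analyze_sample(
    series: IncubationSeries, config: AnalysisConfig | None = None
) -> SampleResults:
    """Run the full per-sample workflow (fit → rates → INB)."""
    return SampleModel(series, config).fit()
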