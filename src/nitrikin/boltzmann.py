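"""Boltzmann sigmoid model for cumulative oxidation-product series.

Nitrification in a batch incubation is a non-linear dynamic process: the
cumulative oxidation products (NOx⁻ = NO2⁻ + NO3⁻ for ammonia oxidation,
NO3⁻ for nitrite oxidation) rise through a lag phase, an exponential
phase and a plateau.  A two- or three-point linear regression badly
misestimates such rates, so the series is instead smoothed with the
four-parameter Boltzmann sigmoid

    y(t) = A2 + (A1 - A2) / (1 + exp((t - t0) / dt))

with A1 the initial asymptote, A2 the final asymptote, t0 the inflection
time and dt the slope factor (all concentrations in µmol L⁻¹, times in
hours).  Its analytic first derivative

    dy/dt = (A2 - A1) * e^u / (dt * (1 + e^u)^2),   u = (t - t0) / dt

is the instantaneous volumetric rate (µmol L⁻¹ h⁻¹); it peaks at
(A2 - A1)/(4*dt), attained exactly at t = t0.

The public surface follows the Model/Results idiom: build a
:class:`BoltzmannModel` from data, call :meth:`~BoltzmannModel.fit`, and
read estimates, covariance and diagnostics off the returned
:class:`BoltzmannResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitConvergenceError, ValidationError

PARAM_NAMES = ("A1", "A2", "t0", "dt")

__all__ = [
    "boltzmann_value",
    "boltzmann_derivative",
    "BoltzmannModel",
    "BoltzmannResults",
    "fit_boltzmann",
]


def boltzmann_value(t, a1, a2, t0, dt):
    """Evaluate the Boltzmann sigmoid y(t) = A2 + (A1-A2)/(1+e^((t-t0)/dt)).

    Overflow-safe for large |t - t0| / dt; accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    if not np.isfinite(t).all():
        raise ValidationError("non-finite evaluation time")
    if dt == 0:
        raise ValidationError("slope factor dt must be nonzero")
    u = (t - t0) / dt
    # sigmoid expressed via expit-style stable branches
    out = np.where(
        u >= 0,
        a2 + (a1 - a2) * np.exp(-np.clip(u, 0, 700)) / (1.0 + np.exp(-np.clip(u, 0, 700))),
        a1 + (a2 - a1) / (1.0 + np.exp(np.clip(u, -700, 0))) * np.exp(np.clip(u, -700, 0)),
    )
    return out if out.ndim else float(out)


def boltzmann_derivative(t, a1, a2, t0, dt):
    """Analytic first derivative dy/dt of the Boltzmann sigmoid.

    Maximum (A2-A1)/(4*dt) at t = t0; symmetric about t0; overflow-safe.
    """
    t = np.asarray(t, dtype=float)
    if not np.isfinite(t).all():
        raise ValidationError("non-finite evaluation time")
    if dt == 0:
        raise ValidationError("slope factor dt must be nonzero")
    u = np.abs((t - t0) / dt)  # e^u/(1+e^u)^2 is even in u
    eu = np.exp(-np.clip(u, 0, 700))  # <= 1, never overflows
    out = (a2 - a1) * eu / (dt * (1.0 + eu) ** 2)
    return out if out.ndim else float(out)


class BoltzmannModel:
    """Nonlinear least-squares Boltzmann fit of one analyte series.

    Parameters
    ----------
    times, values : array_like
        Sampling times (h, strictly increasing) and replicate-mean
        concentrations (µmol L⁻¹).
    weights : array_like, optional
        Per-point weights applied to residuals (e.g. 1/SD); default
        unweighted.
    analyte : str, optional
        Label carried into the results ("NOx", "NO3", ...).
    """

    def __init__(self, times, values, weights=None, analyte=None):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValidationError("times and values must be 1-D and equal length")
        if len(times) < 5:
            raise ValidationError(
                f"need >= 5 points to fit 4 parameters, got {len(times)}"
            )
        if not (np.diff(times) > 0).all():
            raise ValidationError("times must be strictly increasing")
        if not (np.isfinite(times).all() and np.isfinite(values).all()):
            raise ValidationError("non-finite times or values")
        if np.ptp(values) == 0:
            raise ValidationError(
                "degenerate flat series: all values equal, sigmoid unidentifiable"
            )
        self.times = times
        self.values = values
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        self.analyte = analyte

    @classmethod
    def from_series(cls, series, analyte="NOx", weighted=False):
        """Build from an :class:`~nitrikin.series.IncubationSeries`.

        Replicates are averaged first; with ``weighted=True`` points are
        weighted by 1/SD (times with SD of 0 fall back to the median SD).
        """
        times, mean, sd = series.prepare_analyte_series(analyte)
        weights = None
        if weighted:
            if sd is None:
                raise ValidationError("weighted fit requires replicate SDs (n >= 2)")
            sd = np.where(sd > 0, sd, np.median(sd[sd > 0]) if (sd > 0).any() else 1.0)
            weights = 1.0 / sd
        return cls(times, mean, weights=weights, analyte=analyte)

    # -- initialization ------------------------------------------------

    def _initial_params(self):
        t, y = self.times, self.values
        a1, a2 = y[0], y[-1]
        mid = 0.5 * (a1 + a2)
        # first crossing of the midpoint, by linear interpolation;
        # multiple noisy crossings tie-break to the first
        t0 = t[len(t) // 2]
        rising = a2 >= a1
        for i in range(len(t) - 1):
            y0, y1 = y[i], y[i + 1]
            crosses = (y0 <= mid <= y1) if rising else (y0 >= mid >= y1)
            if crosses and y1 != y0:
                t0 = t[i] + (mid - y0) / (y1 - y0) * (t[i + 1] - t[i])
                break
        dt = (t[-1] - t[0]) / 10.0
        return np.array([a1, a2, t0, dt])

    def _bounds(self):
        t, y = self.times, self.values
        rng = np.ptp(y)
        span = t[-1] - t[0]
        lo = [y.min() - rng, y.min() - rng, t[0] - span, 1e-6]
        hi = [y.max() + rng, y.max() + rng, t[-1] + span, span]
        return np.array(lo), np.array(hi)

    # -- fitting -------------------------------------------------------

    def fit(self, n_restarts=3, jitter=0.2, seed=0, xtol=1e-10, max_nfev=2000):
        """Fit by trust-region least squares with jittered restarts.

        The first attempt starts from data-driven heuristics (A1 <- first
        value, A2 <- last, t0 <- midpoint crossing, dt <- span/10); up to
        ``n_restarts`` further attempts multiply the start by seeded
        ±``jitter`` factors.  The best converged attempt wins; if none
        converges a :class:`FitConvergenceError` carrying all diagnostics
        is raised — a silently bad fit is never returned.
        """
        w = self.weights if self.weights is not None else 1.0

        def resid(p):
            return (boltzmann_value(self.times, *p) - self.values) * w

        p0 = self._initial_params()
        lo, hi = self._bounds()
        rng = np.random.default_rng(seed)
        starts = [p0]
        for _ in range(n_restarts):
            jittered = p0 * (1.0 + jitter * rng.uniform(-1, 1, size=4))
            starts.append(np.clip(jittered, lo + 1e-12, hi - 1e-12))

        best, diagnostics = None, []
        for k, start in enumerate(starts):
            start = np.clip(start, lo + 1e-12, hi)
            sol = least_squares(
                resid,
                start,
                bounds=(lo, hi),
                xtol=xtol,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
            diagnostics.append(
                {
                    "start": start.tolist(),
                    "success": bool(sol.success),
                    "status": int(sol.status),
                    "cost": float(sol.cost),
                    "nfev": int(sol.nfev),
                    "message": sol.message,
                }
            )
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol

        if best is None:
            raise FitConvergenceError(
                f"Boltzmann fit did not converge in {len(starts)} attempts "
                f"(analyte={self.analyte!r}, n={len(self.times)})",
                diagnostics=diagnostics,
            )
        return self._results(best, diagnostics)

    def _results(self, sol, diagnostics):
        p = sol.x
        resid_raw = boltzmann_value(self.times, *p) - self.values
        rss = float(np.sum(resid_raw**2))
        tss = float(np.sum((self.values - self.values.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        n, k = len(self.times), 4
        # Gauss-Newton covariance from the Jacobian at the optimum
        cov = np.full((4, 4), np.nan)
        if n > k:
            s2 = rss / (n - k)
            try:
                jtj = sol.jac.T @ sol.jac
                cov = np.linalg.inv(jtj) * s2
            except np.linalg.LinAlgError:
                pass
        return BoltzmannResults(
            model=self,
            params=p.copy(),
            cov_params=cov,
            rss=rss,
            rsquared=r2,
            nobs=n,
            analyte=self.analyte,
            convergence=diagnostics,
        )


@dataclass
class BoltzmannResults:
    """Fitted Boltzmann sigmoid: estimates, uncertainty and diagnostics.

    Attributes
    ----------
    params : ndarray
        ``(A1, A2, t0, dt)``.
    cov_params : ndarray
        4×4 Gauss–Newton covariance (NaN when d.o.f. = 0).
    rss, rsquared, nobs, analyte, convergence
        Residual sum of squares, coefficient of determination, number of
        fitted points, analyte label, per-restart solver diagnostics.
    """

    model: BoltzmannModel
    params: np.ndarray
    cov_params: np.ndarray
    rss: float
    rsquared: float
    nobs: int
    analyte: str | None = None
    convergence: list = field(default_factory=list, repr=False)

    @property
    def a1(self):
        return float(self.params[0])

    @property
    def a2(self):
        return float(self.params[1])

    @property
    def t0(self):
        return float(self.params[2])

    @property
    def dt(self):
        return float(self.params[3])

    @property
    def bse(self):
        """Standard errors of (A1, A2, t0, dt)."""
        return np.sqrt(np.diag(self.cov_params))

    @property
    def peak_rate(self):
        """Analytic maximum of dy/dt: (A2 - A1)/(4*dt), at t = t0."""
        return (self.a2 - self.a1) / (4.0 * self.dt)

    def predict(self, t):
        """Fitted concentration y(t) (µmol L⁻¹)."""
        return boltzmann_value(t, *self.params)

    def rate(self, t):
        """Instantaneous rate dy/dt at t (µmol L⁻¹ h⁻¹)."""
        return boltzmann_derivative(t, *self.params)

    def to_record(self):
        """Flat dict for CSV/JSON serialization (one row per fit)."""
        se = self.bse
        rec = {"analyte": self.analyte}
        rec.update({name: float(v) for name, v in zip(PARAM_NAMES, self.params)})
        rec.update(
            {f"se_{name}": float(s) for name, s in zip(PARAM_NAMES, se)}
        )
        rec.update(
            {"rss": self.rss, "r2": self.rsquared, "n_points": self.nobs}
        )
        return rec

    def summary(self):
        """Plain-text summary table in the estimates/std-err layout."""
        se = self.bse
        lines = [
            "Boltzmann sigmoid fit"
            + (f" — analyte {self.analyte}" if self.analyte else ""),
            f"  n = {self.nobs}    RSS = {self.rss:.6g}    R² = {self.rsquared:.6f}",
            f"  {'param':<6}{'estimate':>14}{'std err':>14}",
        ]
        for name, v, s in zip(PARAM_NAMES, self.params, se):
            lines.append(f"  {name:<6}{v:>14.6g}{s:>14.4g}")
        lines.append(
            f"  peak rate (A2-A1)/(4·dt) = {self.peak_rate:.6g} µmol L⁻¹ h⁻¹ at t0 = {self.t0:.4g} h"
        )
        return "\n".join(lines)

    def plot(self, ax=None, t_grid=None, show_rate=True):
        """Plot data, fitted curve and (optionally) the rate curve."""
        import matplotlib.pyplot as plt  # deferred: plotting is optional

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.times
        if t_grid is None:
            t_grid = np.linspace(t[0], t[-1], 300)
        ax.plot(t, self.model.values, "o", label="data")
        ax.plot(t_grid, self.predict(t_grid), "-", label="Boltzmann fit")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (µmol L⁻¹)")
        if show_rate:
            ax2 = ax.twinx()
            ax2.plot(t_grid, self.rate(t_grid), "--", color="C2", label="dy/dt")
            ax2.set_ylabel("rate (µmol L⁻¹ h⁻¹)")
        ax.legend(loc="best")
        return ax


def fit_boltzmann(times, values, weights=None, analyte=None, **fit_kw):
    """One-call convenience wrapper: build the model and fit it."""
    return BoltzmannModel(times, values, weights=weights, analyte=analyte).fit(
        **fit_kw
    )
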