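"""Forward simulation of two-step nitrification incubations.

The simulator emulates a dark, aerated activated-sludge slurry incubation
in which ammonia oxidizers convert NH4⁺ to NO2⁻ and nitrite oxidizers
convert NO2⁻ to NO3⁻.  The mechanistic model is a three-pool ODE with
Monod (saturation) kinetics and fixed maximal rates — microbial biomass
is not modelled, but each oxidation step may switch on through a smooth
logistic activity ramp, standing in for enzymatic induction of a guild
that starts the incubation inactive:

    dNH4/dt = m − v_ao(t)
    dNO2/dt = v_ao(t) − v_no(t) − λ·NO2
    dNO3/dt = v_no(t) − λ·NO3

    v_ao(t) = v_ao_max · ramp_ao(t) · NH4/(k_ao + NH4)
    v_no(t) = v_no_max · ramp_no(t) · NO2/(k_no + NO2)

with m a zero-order NH4⁺ source (net mineralization of organic nitrogen)
and λ a first-order loss acting on the oxidized pools (denitrification,
anammox, assimilation — processes that consume NO2⁻/NO3⁻).  With m = 0
and λ = 0 total dissolved inorganic nitrogen (DIN) is conserved.

Measurement is emulated by sampling the trajectories on a regular grid
(every 6 h by default, matching slurry-incubation practice), adding
independent Gaussian noise per analyte/time/replicate, and clipping
negative values to zero.  The noiseless trajectories and the true rate
curves are returned alongside, so every downstream estimator can be
scored against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import SimulationError, ValidationError
from .series import IncubationSeries

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_incubation",
    "generate_boltzmann_series",
    "PRESETS",
    "get_preset",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated incubation.

    Concentrations in µmol L⁻¹, times in hours, rates in µmol L⁻¹ h⁻¹.

    Attributes
    ----------
    nh4_0, no2_0, no3_0 : initial NH4⁺ / NO2⁻ / NO3⁻ concentrations.
    v_ao_max, v_no_max : maximal volumetric ammonia- and nitrite-
        oxidation rates.
    k_ao, k_no : Monod half-saturation constants; substrate ≪ k gives
        the first-order limit.
    induction_lag_ao, ramp_ao : centre and width (h) of the logistic
        activity ramp on ammonia oxidation; lag 0 means fully active
        from the start.
    induction_lag_no, ramp_no : the same for nitrite oxidation.
    loss_rate : first-order loss coefficient λ (h⁻¹) on NO2⁻ and NO3⁻.
    mineralization_rate : zero-order NH4⁺ source m.
    t_end, sample_interval : incubation length and sampling spacing (h).
    noise_sd : Gaussian measurement noise SD.
    n_replicates : replicate bottles measured per time point.
    seed : RNG seed; equal configs reproduce bit-identical output.
    """

    nh4_0: float = 400.0
    no2_0: float = 2.0
    no3_0: float = 10.0
    v_ao_max: float = 10.0
    v_no_max: float = 12.0
    k_ao: float = 50.0
    k_no: float = 25.0
    induction_lag_ao: float = 0.0
    ramp_ao: float = 2.0
    induction_lag_no: float = 0.0
    ramp_no: float = 2.0
    loss_rate: float = 0.0
    mineralization_rate: float = 0.0
    t_end: float = 68.0
    sample_interval: float = 6.0
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        nonneg = [
            "nh4_0", "no2_0", "no3_0", "v_ao_max", "v_no_max", "k_ao", "k_no",
            "induction_lag_ao", "induction_lag_no", "loss_rate",
            "mineralization_rate", "noise_sd",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("ramp_ao", "ramp_no", "t_end", "sample_interval"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.k_ao == 0 or self.k_no == 0:
            raise ValidationError("half-saturation constants must be positive")

    def to_dict(self):
        return asdict(self)

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    # -- plain key=value config-file round trip ------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key} = {value}\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        kw = {}
        int_fields = {"n_replicates", "seed"}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 'key = value', got {raw!r}"
                    )
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in cls.__dataclass_fields__:
                    raise ValidationError(f"{path}:{lineno}: unknown parameter {key!r}")
                kw[key] = int(value) if key in int_fields else float(value)
        return cls(**kw)


@dataclass(frozen=True)
class SimTruth:
    """Noiseless ground truth of a simulated incubation.

    Dense-grid trajectories and true rate curves, plus the true average
    rates over [0, t_end] (time averages of v_ao and v_no, computed from
    cumulative-oxidation states integrated alongside the ODE).
    """

    t_grid: np.ndarray
    nh4: np.ndarray
    no2: np.ndarray
    no3: np.ndarray
    v_ao: np.ndarray
    v_no: np.ndarray
    cum_ao: np.ndarray
    cum_no: np.ndarray
    config: SimConfig = field(repr=False)

    @property
    def v_ao_avg(self) -> float:
        """True average ammonia-oxidation rate over [0, t_end]."""
        return float(self.cum_ao[-1] / self.t_grid[-1])

    @property
    def v_no_avg(self) -> float:
        return float(self.cum_no[-1] / self.t_grid[-1])

    @property
    def v_ao_max(self) -> float:
        return float(self.v_ao.max())

    @property
    def v_no_max(self) -> float:
        return float(self.v_no.max())

    @property
    def din(self) -> np.ndarray:
        return self.nh4 + self.no2 + self.no3

    def average_ao(self, window) -> float:
        """True average AO rate over a window (cumulative-state difference)."""
        t_i, t_f = window
        c = np.interp([t_i, t_f], self.t_grid, self.cum_ao)
        return float((c[1] - c[0]) / (t_f - t_i))

    def average_no(self, window) -> float:
        t_i, t_f = window
        c = np.interp([t_i, t_f], self.t_grid, self.cum_no)
        return float((c[1] - c[0]) / (t_f - t_i))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t_grid,
                "nh4_umol_L": self.nh4,
                "no2_umol_L": self.no2,
                "no3_umol_L": self.no3,
                "v_ao_umol_L_h": self.v_ao,
                "v_no_umol_L_h": self.v_no,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _ramp(t, lag, width):
    """Logistic activity ramp in [0, 1]; identically 1 when lag <= 0."""
    if lag <= 0:
        return np.ones_like(np.asarray(t, dtype=float))
    u = np.clip((np.asarray(t, dtype=float) - lag) / width, -700, 700)
    return 1.0 / (1.0 + np.exp(-u))


def _rates(t, nh4, no2, cfg: SimConfig):
    v_ao = cfg.v_ao_max * _ramp(t, cfg.induction_lag_ao, cfg.ramp_ao) * nh4 / (
        cfg.k_ao + nh4
    )
    v_no = cfg.v_no_max * _ramp(t, cfg.induction_lag_no, cfg.ramp_no) * no2 / (
        cfg.k_no + no2
    )
    return v_ao, v_no


def simulate_incubation(config: SimConfig, n_dense=401):
    """Simulate one incubation; returns (noisy series, noiseless truth).

    The ODE is integrated with an adaptive stiff-capable method (LSODA)
    at relative tolerance 1e-8; cumulative oxidation is carried as two
    extra states so the true average rates are solver-accurate.  Equal
    configs (including seed) give bit-identical output.
    """

    cfg = config

    def rhs(t, y):
        nh4, no2, _no3, _ca, _cn = y
        v_ao, v_no = _rates(t, max(nh4, 0.0), max(no2, 0.0), cfg)
        return [
            cfg.mineralization_rate - v_ao,
            v_ao - v_no - cfg.loss_rate * y[1],
            v_no - cfg.loss_rate * y[2],
            v_ao,
            v_no,
        ]

    t_samples = np.arange(0.0, cfg.t_end + 1e-9, cfg.sample_interval)
    t_grid = np.union1d(np.linspace(0.0, cfg.t_end, n_dense), t_samples)
    y0 = [cfg.nh4_0, cfg.no2_0, cfg.no3_0, 0.0, 0.0]
    sol = solve_ivp(
        rhs,
        (0.0, cfg.t_end),
        y0,
        method="LSODA",
        t_eval=t_grid,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success or not np.isfinite(sol.y).all():
        raise SimulationError(
            f"ODE integration failed ({sol.message}) for parameters {cfg.to_dict()}"
        )

    nh4, no2, no3, cum_ao, cum_no = sol.y
    v_ao, v_no = _rates(sol.t, np.maximum(nh4, 0), np.maximum(no2, 0), cfg)
    truth = SimTruth(
        t_grid=sol.t, nh4=nh4, no2=no2, no3=no3,
        v_ao=v_ao, v_no=v_no, cum_ao=cum_ao, cum_no=cum_no, config=cfg,
    )

    idx = np.searchsorted(sol.t, t_samples)
    clean = np.vstack([nh4[idx], no2[idx], no3[idx]])
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        noise = (
            rng.normal(0.0, cfg.noise_sd, size=clean.shape)
            if cfg.noise_sd > 0
            else np.zeros_like(clean)
        )
        noisy = np.clip(clean + noise, 0.0, None)
        rows.append(
            pd.DataFrame(
                {
                    "time_h": t_samples,
                    "replicate": rep,
                    "nh4_umol_L": noisy[0],
                    "no2_umol_L": noisy[1],
                    "no3_umol_L": noisy[2],
                }
            )
        )
    series = IncubationSeries(pd.concat(rows, ignore_index=True))
    return series, truth


def generate_boltzmann_series(a1, a2, t0, dt, times, noise_sd=0.0, seed=None):
    """Sample a Boltzmann sigmoid on a grid, with optional Gaussian noise.

    A fixture generator for fit-recovery studies: returns
    y(tᵢ) = A2 + (A1−A2)/(1+exp((tᵢ−t0)/dt)) + ε, ε ~ N(0, noise_sd²),
    seed-reproducible.
    """
    from .boltzmann import boltzmann_value

    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("times must be non-empty")
    if times.ndim != 1 or (times.size > 1 and not (np.diff(times) > 0).all()):
        raise ValidationError("times must be 1-D and strictly increasing")
    if dt == 0:
        raise ValidationError("slope factor dt must be nonzero")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    y = np.asarray(boltzmann_value(times, a1, a2, t0, dt), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=times.shape)
    return y


# ---------------------------------------------------------------------------
# presets: the two qualitative incubation regimes plus a closed system

PRESETS: dict[str, SimConfig] = {
    # slow nitrifiers, delayed nitrite oxidation -> transient nitrite peak,
    # sigmoidal NOx with a pronounced lag phase (~68 h incubation, 6-h sampling)
    "sample_A_like": SimConfig(
        nh4_0=450.0, no2_0=2.0, no3_0=10.0,
        v_ao_max=12.0, k_ao=40.0, induction_lag_ao=18.0, ramp_ao=6.0,
        v_no_max=14.0, k_no=25.0, induction_lag_no=30.0, ramp_no=6.0,
        loss_rate=0.0, mineralization_rate=0.0,
        t_end=68.0, sample_interval=6.0, noise_sd=2.0, n_replicates=3, seed=0,
    ),
    # fast nitrifiers, nitrite oxidation active from the start and stronger
    # than ammonia oxidation -> no nitrite accumulation, short incubation
    "sample_B_like": SimConfig(
        nh4_0=120.0, no2_0=2.0, no3_0=10.0,
        v_ao_max=200.0, k_ao=500.0, induction_lag_ao=0.0,
        v_no_max=300.0, k_no=15.0, induction_lag_no=0.0,
        loss_rate=0.0, mineralization_rate=0.0,
        t_end=12.0, sample_interval=1.0, noise_sd=1.0, n_replicates=3, seed=0,
    ),
    # conservation check: no loss, no mineralization, no noise
    "closed_system": SimConfig(
        nh4_0=400.0, no2_0=2.0, no3_0=10.0,
        v_ao_max=10.0, k_ao=40.0, induction_lag_ao=12.0, ramp_ao=4.0,
        v_no_max=12.0, k_no=25.0, induction_lag_no=20.0, ramp_no=4.0,
        loss_rate=0.0, mineralization_rate=0.0,
        t_end=68.0, sample_interval=6.0, noise_sd=0.0, n_replicates=1, seed=0,
    ),
}


def get_preset(name: str) -> SimConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
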