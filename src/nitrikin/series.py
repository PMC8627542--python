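"""Incubation time-series container and CSV I/O.

An incubation experiment follows dissolved inorganic nitrogen (DIN) in a
sludge slurry over time: ammonium (NH4+), nitrite (NO2-) and nitrate (NO3-)
concentrations in µmol L⁻¹, sampled on a common time grid (hours), usually
in replicate.  Two derived series drive the kinetic analysis:

* ``NOx = NO2- + NO3-`` — cumulative product of ammonia oxidation, and
* ``DIN = NH4+ + NO2- + NO3-`` — the conserved pool in a closed system.

Both are always recomputed from the stored analytes, never cached.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: canonical CSV column order
COLUMNS = ["time_h", "replicate", "nh4_umol_L", "no2_umol_L", "no3_umol_L"]

_ANALYTE_COLS = {
    "NH4": ["nh4_umol_L"],
    "NO2": ["no2_umol_L"],
    "NO3": ["no3_umol_L"],
    "NOx": ["no2_umol_L", "no3_umol_L"],
    "DIN": ["nh4_umol_L", "no2_umol_L", "no3_umol_L"],
}

#: minimum distinct time points for a 4-parameter sigmoid fit (4 + 1 d.o.f.)
MIN_FIT_POINTS = 5


@dataclass(frozen=True)
class IncubationSeries:
    """Validated long-format DIN incubation measurements.

    Parameters
    ----------
    data : pandas.DataFrame
        Long format with columns ``time_h, replicate, nh4_umol_L,
        no2_umol_L, no3_umol_L``; one row per (time, replicate).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "data", _validate_frame(self.data))

    # -- constructors -------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IncubationSeries":
        return cls(df)

    @classmethod
    def from_arrays(cls, time_h, nh4, no2, no3, replicate=1) -> "IncubationSeries":
        """Build a single-replicate series from parallel arrays."""
        time_h = np.asarray(time_h, dtype=float)
        df = pd.DataFrame(
            {
                "time_h": time_h,
                "replicate": replicate,
                "nh4_umol_L": np.asarray(nh4, dtype=float),
                "no2_umol_L": np.asarray(no2, dtype=float),
                "no3_umol_L": np.asarray(no3, dtype=float),
            }
        )
        return cls(df)

    # -- basic views ---------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        """Sorted distinct sampling times (h)."""
        return np.unique(self.data["time_h"].to_numpy())

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique().tolist())

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def analyte(self, name: str) -> pd.DataFrame:
        """Long-format (time_h, replicate, value) table for one analyte.

        ``name`` is one of NH4, NO2, NO3, NOx, DIN; the composite series
        NOx and DIN are recomputed as sums on every call.
        """
        cols = _analyte_columns(name)
        out = self.data[["time_h", "replicate"]].copy()
        out["value"] = self.data[cols].sum(axis=1)
        return out

    def prepare_analyte_series(self, name: str):
        """Replicate-average one analyte for curve fitting.

        Returns
        -------
        times : ndarray
            Distinct sampling times, ascending.
        mean : ndarray
            Replicate mean concentration at each time (µmol L⁻¹).
        sd : ndarray or None
            Per-time sample standard deviation (ddof=1); ``None`` when
            there is a single replicate (an SD of a singleton is
            undefined, not zero).

        Raises
        ------
        ValidationError
            Fewer than 5 distinct time points — a 4-parameter sigmoid
            fit would have no residual degrees of freedom.
        """
        long = self.analyte(name)
        grouped = long.groupby("time_h")["value"]
        times = np.array(sorted(grouped.groups))
        if len(times) < MIN_FIT_POINTS:
            raise ValidationError(
                f"analyte {name!r}: only {len(times)} distinct time points "
                f"after replicate averaging; at least {MIN_FIT_POINTS} are "
                "required to fit a 4-parameter sigmoid"
            )
        mean = grouped.mean().reindex(times).to_numpy()
        counts = grouped.count().reindex(times).to_numpy()
        if (counts > 1).all():
            sd = grouped.std(ddof=1).reindex(times).to_numpy()
        else:
            sd = None
        return times, mean, sd

    # -- I/O -----------------------------------------------------------

    def to_csv(self, path) -> None:
        self.data[COLUMNS].to_csv(path, index=False)

    def sha256(self) -> str:
        """Content hash of the canonical CSV rendering (for provenance)."""
        text = self.data[COLUMNS].to_csv(index=False)
        return hashlib.sha256(text.encode()).hexdigest()

    def __len__(self) -> int:
        return len(self.data)


def _analyte_columns(name: str):
    try:
        return _ANALYTE_COLS[name]
    except KeyError:
        raise ValidationError(
            f"unknown analyte {name!r}; choose from {sorted(_ANALYTE_COLS)}"
        ) from None


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    df = df[COLUMNS].copy()
    if len(df) == 0:
        raise ValidationError("empty series: no measurement rows")
    conc = ["nh4_umol_L", "no2_umol_L", "no3_umol_L"]
    values = df[["time_h"] + conc].to_numpy(dtype=float)
    bad = ~np.isfinite(values).all(axis=1)
    if bad.any():
        rows = df.index[bad].tolist()[:10]
        raise ValidationError(f"non-finite time or concentration in rows {rows}")
    neg = (df[conc].to_numpy(dtype=float) < 0).any(axis=1)
    if neg.any():
        rows = df.index[neg].tolist()[:10]
        raise ValidationError(f"negative concentration in rows {rows}")
    dup = df.duplicated(subset=["time_h", "replicate"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise ValidationError(f"duplicate (time, replicate) pairs in rows {rows}")
    # replicates must share the time grid once aligned
    grids = df.groupby("replicate")["time_h"].apply(lambda s: tuple(sorted(s)))
    if len(set(grids)) > 1:
        raise ValidationError(
            "replicates do not share a common time grid: "
            + "; ".join(f"rep {r}: {len(g)} times" for r, g in grids.items())
        )
    return df.sort_values(["time_h", "replicate"], kind="mergesort").reset_index(
        drop=True
    )


def read_incubation_csv(path) -> IncubationSeries:
    """Read a long-format incubation CSV into a validated series.

    The dialect is fixed: comma-separated, UTF-8, header row
    ``time_h,replicate,nh4_umol_L,no2_umol_L,no3_umol_L`` with
    concentrations in µmol L⁻¹ and time in hours.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file does not exist: {path}")
    # round_trip parser: write->read preserves float64 values bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    return IncubationSeries(df)
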