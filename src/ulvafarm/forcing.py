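"""Environmental forcing: hourly tables and a synthetic estuary generator.

The simulator is driven by hourly series of water temperature T (°C),
surface irradiance I0 (μmol photons m⁻² s⁻¹), salinity S (PSU) and the
dissolved-N concentration of the upstream water N_up (μmol-N l⁻¹), plus a
daylight mask. The synthetic generator emulates a semi-arid Mediterranean
estuary: a sinusoidal annual temperature cycle (~15 °C in late winter to
~29.5 °C in high summer, passing the growth optimum of 18 °C in early
spring and late autumn), a half-sine diurnal light curve whose peak and day
length (10–14 h) follow the season, constant salinity (30 PSU) and a
seasonal nutrient level. It stands in for measured estuary/meteorological
records so every module is testable offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ForcingSeries",
    "SyntheticForcingSpec",
    "generate_synthetic_forcing",
    "read_forcing_table",
    "write_forcing_table",
    "light_hour_mask",
    "seasonal_spec",
    "SEASON_STARTS",
    "SEASON_N_LEVELS",
]

logger = logging.getLogger(__name__)

COLUMNS = ["T", "I0", "S", "N_up", "is_light"]

#: Representative mid-season cycle start dates (month, day).
SEASON_STARTS = {
    "winter": (1, 15),
    "spring": (4, 15),
    "summer": (7, 15),
    "autumn": (10, 15),
}

#: Default seasonal upstream dissolved-N levels, μmol-N l⁻¹ (eutrophic
#: estuary: richest after winter rains, poorest in the dry summer).
SEASON_N_LEVELS = {
    "winter": 350.0,
    "spring": 250.0,
    "summer": 150.0,
    "autumn": 300.0,
}


@dataclass(frozen=True)
class ForcingSeries:
    """Validated hourly forcing table (columns T, I0, S, N_up, is_light)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in COLUMNS if c not in f.columns]
        if missing:
            raise ValueError(f"forcing table missing columns: {missing}")
        if len(f) == 0:
            raise ValueError("forcing table is empty")
        if not isinstance(f.index, pd.DatetimeIndex):
            raise ValueError("forcing table needs a datetime index")
        dt = np.diff(f.index.view("int64"))
        if len(dt) and not np.all(dt == 3_600_000_000_000):
            raise ValueError("timestamps must be strictly increasing hourly")
        if np.any(f["I0"].to_numpy() < 0):
            raise ValueError("I0 must be non-negative")
        dark = ~f["is_light"].to_numpy(dtype=bool)
        if np.any(f["I0"].to_numpy()[dark] > 0):
            raise ValueError("I0 must be zero outside light hours")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def hours(self) -> int:
        return len(self.frame)

    def slice_hours(self, start: int, n_hours: int) -> "ForcingSeries":
        """Return hours [start, start + n_hours) as a new series."""
        if start + n_hours > len(self.frame):
            raise ValueError("requested slice exceeds forcing length")
        return ForcingSeries(self.frame.iloc[start:start + n_hours])


@dataclass(frozen=True)
class SyntheticForcingSpec:
    """Parameters of the synthetic annual forcing cycle.

    The annual temperature sinusoid is T_mean + T_amp·sin(2π(doy − T_phase)/365),
    peaking at doy = T_phase + 91 (≈ 29.5 °C in early August by default) and
    bottoming out at ~15 °C in early February. Day length and peak
    irradiance follow sinusoids phased on the solstices.
    """

    T_mean: float = 22.25          # °C
    T_amp: float = 7.25            # °C
    T_phase_doy: float = 128.0     # day of year; peak at T_phase + 365/4
    day_length_mean: float = 12.0  # h
    day_length_amp: float = 2.0    # h; 10 h mid-winter, 14 h mid-summer
    I_peak_mean: float = 1500.0    # μmol photons m⁻² s⁻¹ at solar noon
    I_peak_amp: float = 500.0
    light_phase_doy: float = 80.0  # phases day length / peak light on solstices
    S: float = 30.0                # PSU, constant
    N_up: float = 250.0            # μmol-N l⁻¹ upstream level
    light_threshold: float = 1.0   # μmol photons m⁻² s⁻¹ daylight cut-off
    noise: float = 0.0             # relative (multiplicative) noise on I0, N_up
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T_amp < 0 or self.day_length_amp < 0 or self.I_peak_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.N_up < 0 or self.I_peak_mean < 0:
            raise ValueError("N_up and I_peak_mean must be non-negative")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")


def generate_synthetic_forcing(
    spec: SyntheticForcingSpec,
    start: str = "2021-01-01",
    days: int = 14,
) -> ForcingSeries:
    """Generate ``days`` of hourly synthetic forcing starting at ``start``.

    Deterministic for a fixed spec (including its seed). The diurnal light
    curve is a half sine between sunrise and sunset, evaluated at hour
    centres; hours whose irradiance exceeds the daylight threshold carry the
    light-hour flag.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    index = pd.date_range(start=start, periods=days * 24, freq="h")
    doy = index.dayofyear.to_numpy(dtype=float)
    hour_c = index.hour.to_numpy(dtype=float) + 0.5  # hour centre

    T = spec.T_mean + spec.T_amp * np.sin(
        2.0 * np.pi * (doy - spec.T_phase_doy) / 365.0
    )
    day_len = spec.day_length_mean + spec.day_length_amp * np.sin(
        2.0 * np.pi * (doy - spec.light_phase_doy) / 365.0
    )
    I_peak = spec.I_peak_mean + spec.I_peak_amp * np.sin(
        2.0 * np.pi * (doy - spec.light_phase_doy) / 365.0
    )
    sunrise = 12.0 - day_len / 2.0
    sunset = 12.0 + day_len / 2.0
    up = (hour_c > sunrise) & (hour_c < sunset)
    I0 = np.where(
        up, I_peak * np.sin(np.pi * (hour_c - sunrise) / np.maximum(day_len, 1e-9)), 0.0
    )
    I0 = np.clip(I0, 0.0, None)
    N_up = np.full(len(index), spec.N_up, dtype=float)

    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        I0 = I0 * np.exp(rng.normal(0.0, spec.noise, len(index)))
        N_up = N_up * np.exp(rng.normal(0.0, spec.noise, len(index)))

    is_light = I0 > spec.light_threshold
    I0 = np.where(is_light, I0, 0.0)

    frame = pd.DataFrame(
        {
            "T": T,
            "I0": I0,
            "S": np.full(len(index), spec.S, dtype=float),
            "N_up": N_up,
            "is_light": is_light,
        },
        index=index,
    )
    frame.index.name = "timestamp"
    return ForcingSeries(frame)


def seasonal_spec(season: str, base: SyntheticForcingSpec | None = None) -> tuple[str, SyntheticForcingSpec]:
    """Return (cycle start date, spec) for a named season preset.

    Presets are pure functions of the base spec: only the upstream N level
    changes between seasons; temperature/light follow the annual cycle at
    the season's representative start date.
    """
    if season not in SEASON_STARTS:
        raise ValueError(f"unknown season {season!r}; choose from {sorted(SEASON_STARTS)}")
    base = base or SyntheticForcingSpec()
    month, day = SEASON_STARTS[season]
    start = f"2021-{month:02d}-{day:02d}"
    return start, replace(base, N_up=SEASON_N_LEVELS[season])


def light_hour_mask(series: ForcingSeries, threshold: float = 1.0) -> np.ndarray:
    """Boolean daylight mask: true where I0 exceeds the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return series.frame["I0"].to_numpy(dtype=float) > threshold


def write_forcing_table(series: ForcingSeries, path) -> None:
    """Write the hourly table as CSV (ISO-8601 timestamps, header row)."""
    out = series.frame.copy()
    out.index.name = "timestamp"
    out.to_csv(path, date_format="%Y-%m-%dT%H:%M:%S")


def read_forcing_table(path, light_threshold: float = 1.0) -> ForcingSeries:
    """Read an hourly forcing CSV (timestamp, T, I0, S, N_up[, is_light]).

    Gaps of up to 3 hours are filled by linear interpolation (logged);
    longer gaps are an error. The daylight flag is recomputed from the
    threshold when absent.
    """
    frame = pd.read_csv(path, parse_dates=["timestamp"], index_col="timestamp")
    required = ["T", "I0", "S", "N_up"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"forcing table missing columns: {missing}")
    if frame.index.isna().any():
        raise ValueError("unparseable timestamps in forcing table")
    if not frame.index.is_monotonic_increasing or frame.index.has_duplicates:
        raise ValueError("timestamps must be strictly increasing")

    full = pd.date_range(frame.index[0], frame.index[-1], freq="h")
    if len(full) != len(frame):
        gaps = full.difference(frame.index)
        # contiguous run lengths of missing hours
        run, longest, runs = 0, 0, 0
        prev = None
        for t in gaps:
            if prev is not None and (t - prev) == pd.Timedelta(hours=1):
                run += 1
            else:
                run = 1
                runs += 1
            longest = max(longest, run)
            prev = t
        if longest > 3:
            raise ValueError(
                f"forcing table has a gap of {longest} h (> 3 h); cannot interpolate"
            )
        frame = frame.reindex(full)
        frame[required] = frame[required].interpolate(method="linear")
        if "is_light" in frame.columns:
            frame = frame.drop(columns=["is_light"])
        logger.warning(
            "interpolated %d missing hour(s) across %d gap(s) in %s",
            len(gaps), runs, path,
        )
        frame.index.name = "timestamp"
    if "is_light" not in frame.columns:
        frame["is_light"] = frame["I0"].to_numpy(dtype=float) > light_threshold
    frame["is_light"] = frame["is_light"].astype(bool)
    frame["I0"] = np.where(frame["is_light"], frame["I0"], 0.0)
    return ForcingSeries(frame[COLUMNS])
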