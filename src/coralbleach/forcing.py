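"""Environmental forcing: synthetic driver series, file I/O and the DHW metric.

The simulator is driven by four time series on a common grid: downwelling
photosynthetically active radiation (PAR, umol photon m-2 s-1), water
temperature (degC) and the dissolved inorganic nitrogen and phosphorus
concentrations (DIN, DIP; umol l-1).  This module can generate the series
synthetically from the statistics of the four-treatment heat x shade tank
experiment the model was configured for, read/write them as delimited text,
interpolate them at arbitrary times, and compute the degree-heating-week
(DHW) thermal-stress metric.

Coordinate convention: time is in fractional days with t = 0 at 0:00 h on
the first experimental day.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScenarioSpec",
    "ForcingSeries",
    "generate_temperature",
    "generate_par",
    "generate_nutrients",
    "generate_forcing",
    "compute_dhw",
    "daily_light_integral",
    "read_forcing",
    "write_forcing",
    "interpolate_forcing",
    "PRESET_NAMES",
    "preset",
]

#: seconds per day times 1e-6, converting umol m-2 s-1 integrated over a day
#: to mol photon m-2 d-1
_UMOL_S_TO_MOL_D = 86400.0 * 1e-6

#: required file columns, in writing order
_COLUMNS = ["time_days", "par_umol_m2_s", "temp_C", "din_umol_l", "dip_umol_l"]

#: offsets added to the scenario seed to derive independent streams, so that
#: treatments sharing a seed share "weather"
_LIGHT_STREAM = 0
_NUTRIENT_STREAM = 104729


@dataclass(frozen=True)
class ScenarioSpec:
    """Specification of one synthetic-forcing treatment.

    Defaults reproduce the nominal conditions of the tank experiment: a
    heat-hold temperature profile (ambient 26.4 degC; linear ramp to
    32.6 degC completing at day 14, then a 9-day hold), a 12-h truncated
    sinusoid of diel light with day-to-day lognormal cloudiness scaled to a
    23-day mean DLI of 7.21 mol photon m-2 d-1 (30% shade transmits 0.70),
    and nutrient concentrations redrawn every 2 days from the measured
    supply-water statistics (DIN 3.35 +/- 1.14, DIP 0.58 +/- 0.20 umol/l).
    """

    temperature_treatment: str = "ambient"  # "ambient" | "heat"
    shade_treatment: str = "unshaded"       # "unshaded" | "shaded"
    days: float = 23.0
    seed: int = 1
    mmm: float = 28.6                 # degC, maximum monthly mean
    ambient_temp: float = 26.4        # degC
    heat_temp: float = 32.6           # degC
    ramp_rate: float = 6.2 / 14.0     # degC d-1; endpoint-consistent ~0.443
    hold_days: float = 9.0
    dli_mean: float = 7.21            # mol photon m-2 d-1, unshaded target
    dli_sd: float = 2.99              # mol photon m-2 d-1
    par_peak: float = 818.0           # umol photon m-2 s-1, clear-sky noon peak
    shade_fraction: float = 0.70      # light transmitted under the shade cloth
    din_mean: float = 3.35            # umol l-1
    din_sd: float = 1.14
    dip_mean: float = 0.58            # umol l-1
    dip_sd: float = 0.20
    nutrient_sampling_interval: float = 2.0  # days
    grid_minutes: float = 5.0         # forcing grid resolution
    photoperiod_hours: float = 12.0
    temp_jitter_sd: float = 0.0       # optional AR(1) jitter, default off

    def __post_init__(self) -> None:
        if self.temperature_treatment not in ("ambient", "heat"):
            raise ValueError(
                f"temperature_treatment must be 'ambient' or 'heat', "
                f"got {self.temperature_treatment!r}"
            )
        if self.shade_treatment not in ("unshaded", "shaded"):
            raise ValueError(
                f"shade_treatment must be 'unshaded' or 'shaded', "
                f"got {self.shade_treatment!r}"
            )
        if not (0.0 < self.shade_fraction <= 1.0):
            raise ValueError("shade_fraction must lie in (0, 1]")
        if self.dli_mean <= 0:
            raise ValueError("dli_mean must be positive")
        if self.din_mean < 0 or self.dip_mean < 0:
            raise ValueError("nutrient means must be non-negative")
        if self.days <= 0:
            raise ValueError("days must be positive")
        if self.grid_minutes <= 0 or self.grid_minutes > 15.0:
            raise ValueError("grid_minutes must lie in (0, 15]")
        if self.temperature_treatment == "heat":
            ramp = self.ramp_duration
            if ramp + self.hold_days > self.days + 1e-9:
                raise ValueError(
                    f"ramp ({ramp:.2f} d from ramp_rate={self.ramp_rate}) plus "
                    f"hold_days={self.hold_days} exceeds days={self.days}"
                )

    @property
    def ramp_duration(self) -> float:
        """Days taken by the linear ramp from ambient_temp to heat_temp."""
        return (self.heat_temp - self.ambient_temp) / self.ramp_rate

    @property
    def light_fraction(self) -> float:
        return self.shade_fraction if self.shade_treatment == "shaded" else 1.0

    def time_grid(self) -> np.ndarray:
        step = self.grid_minutes / (24.0 * 60.0)
        n = int(round(self.days / step))
        return np.arange(n + 1) * step


PRESET_NAMES = (
    "ambient_unshaded",
    "ambient_shaded",
    "heat_unshaded",
    "heat_shaded",
)


def preset(name: str, **overrides) -> ScenarioSpec:
    """Return one of the four factorial treatment specs by name."""
    if name not in PRESET_NAMES:
        raise ValueError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        )
    temperature, shade = name.split("_")
    return ScenarioSpec(
        temperature_treatment=temperature, shade_treatment=shade, **overrides
    )


@dataclass
class ForcingSeries:
    """Environmental drivers on a common, strictly increasing time grid."""

    time: np.ndarray   # days since experiment start
    par: np.ndarray    # umol photon m-2 s-1
    temp: np.ndarray   # degC
    din: np.ndarray    # umol l-1
    dip: np.ndarray    # umol l-1
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.par = np.asarray(self.par, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        self.din = np.asarray(self.din, dtype=float)
        self.dip = np.asarray(self.dip, dtype=float)
        n = self.time.size
        if n == 0:
            raise ValueError("forcing series is empty")
        for name in ("par", "temp", "din", "dip"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name} has mismatched length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.par < 0):
            raise ValueError("par must be non-negative")
        if np.any(self.din < 0) or np.any(self.dip < 0):
            raise ValueError("nutrient concentrations must be non-negative")

    def __len__(self) -> int:
        return self.time.size

    def at(self, t):
        """Interpolate (par, temp, din, dip) at time(s) ``t`` in days.

        PAR and temperature are interpolated linearly; DIN and DIP use
        previous-value (step) interpolation because they are plateau samples.
        Extrapolation outside the covered span is an error.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.time[0] - 1e-12) or np.any(
            t_arr > self.time[-1] + 1e-12
        ):
            raise ValueError(
                f"time {t} outside forcing span "
                f"[{self.time[0]}, {self.time[-1]}]"
            )
        par = np.interp(t_arr, self.time, self.par)
        temp = np.interp(t_arr, self.time, self.temp)
        idx = np.clip(np.searchsorted(self.time, t_arr, side="right") - 1, 0, None)
        din = self.din[idx]
        dip = self.dip[idx]
        return par, temp, din, dip

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "time_days": self.time,
                "par_umol_m2_s": self.par,
                "temp_C": self.temp,
                "din_umol_l": self.din,
                "dip_umol_l": self.dip,
            }
        )
        if self.extra is not None:
            for col in self.extra.columns:
                frame[col] = np.asarray(self.extra[col])
        return frame


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_temperature(spec: ScenarioSpec) -> np.ndarray:
    """Heat-hold (or constant ambient) temperature on the scenario grid."""
    t = spec.time_grid()
    if spec.temperature_treatment == "ambient":
        temp = np.full_like(t, spec.ambient_temp)
    else:
        ramp = spec.ramp_duration
        temp = spec.ambient_temp + spec.ramp_rate * np.minimum(t, ramp)
        temp = np.minimum(temp, spec.heat_temp)
    if spec.temp_jitter_sd > 0:
        # AR(1) jitter with ~6 h decorrelation, optional (default off)
        rng = _rng(spec.seed, 2 * _NUTRIENT_STREAM)
        dt = np.diff(t, prepend=t[0])
        phi = np.exp(-dt / 0.25)
        eps = rng.normal(0.0, spec.temp_jitter_sd * np.sqrt(1 - phi**2))
        x = np.empty_like(t)
        x[0] = rng.normal(0.0, spec.temp_jitter_sd)
        for i in range(1, t.size):
            x[i] = phi[i] * x[i - 1] + eps[i]
        temp = temp + x
    return temp


def _clear_sky_par(spec: ScenarioSpec, t: np.ndarray) -> np.ndarray:
    """Truncated sinusoid: zero at night, peak par_peak at solar noon."""
    hour = (t % 1.0) * 24.0
    half = spec.photoperiod_hours / 2.0
    phase = (hour - 12.0) / spec.photoperiod_hours  # 0 at noon
    shape = np.where(
        np.abs(hour - 12.0) < half, np.cos(np.pi * phase), 0.0
    )
    return spec.par_peak * np.maximum(shape, 0.0)


def _day_multipliers(spec: ScenarioSpec) -> np.ndarray:
    """Per-day lognormal cloudiness multipliers.

    Drawn so that the *expected* DLI matches dli_mean with spread dli_sd,
    then rescaled multiplicatively so the realised sample-mean DLI over the
    generated days equals dli_mean exactly for every seed (the sd remains
    approximate).
    """
    n_days = int(np.ceil(spec.days - 1e-9))
    dli_clear = (
        spec.par_peak
        * (2.0 / np.pi)
        * spec.photoperiod_hours
        * 3600.0
        * 1e-6
    )
    mean_mult = spec.dli_mean / dli_clear
    cv = spec.dli_sd / spec.dli_mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean_mult) - sigma2 / 2.0
    rng = _rng(spec.seed, _LIGHT_STREAM)
    mult = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_days)
    mult *= mean_mult / mult.mean()
    return mult


def generate_par(spec: ScenarioSpec) -> np.ndarray:
    """Diel PAR series on the scenario grid (umol photon m-2 s-1).

    Shading multiplies every value by ``shade_fraction``; with the same seed
    the shaded series is exactly ``shade_fraction`` times the unshaded one.
    """
    t = spec.time_grid()
    par = _clear_sky_par(spec, t)
    mult = _day_multipliers(spec)
    day = np.minimum(np.floor(t).astype(int), mult.size - 1)
    return par * mult[day] * spec.light_fraction


def generate_nutrients(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """DIN and DIP step series (umol l-1), redrawn every sampling interval.

    Values are truncated-normal (bounded below at zero) and held constant
    between draws, matching the experiment's 2-day water sampling.
    """
    t = spec.time_grid()
    rng = _rng(spec.seed, _NUTRIENT_STREAM)
    n_draws = int(np.floor((spec.days - 1e-9) / spec.nutrient_sampling_interval)) + 1

    def draw(mean: float, sd: float) -> np.ndarray:
        if sd == 0.0:
            return np.full(n_draws, mean)
        a = (0.0 - mean) / sd
        return stats.truncnorm.rvs(
            a, np.inf, loc=mean, scale=sd, size=n_draws, random_state=rng
        )

    din_draws = draw(spec.din_mean, spec.din_sd)
    dip_draws = draw(spec.dip_mean, spec.dip_sd)
    epoch = np.minimum(
        np.floor(t / spec.nutrient_sampling_interval).astype(int), n_draws - 1
    )
    return din_draws[epoch], dip_draws[epoch]


def generate_forcing(spec: ScenarioSpec) -> ForcingSeries:
    """Full synthetic forcing for one treatment; deterministic given spec."""
    din, dip = generate_nutrients(spec)
    return ForcingSeries(
        time=spec.time_grid(),
        par=generate_par(spec),
        temp=generate_temperature(spec),
        din=din,
        dip=dip,
    )


def compute_dhw(
    time: np.ndarray,
    temp: np.ndarray,
    mmm: float = 28.6,
    horizon: float = 84.0,
) -> np.ndarray:
    """Degree-heating weeks at each series time (degC-weeks).

    DHW(t) sums, over the completed days d within [t - horizon, t], the
    daily-mean temperature anomaly above ``mmm`` wherever that anomaly is at
    least 1 degC (the NOAA hotspot gate), divided by 7 to convert degC-days
    to degC-weeks.
    """
    time = np.asarray(time, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if time.size == 0:
        raise ValueError("empty temperature series")
    day = np.floor(time + 1e-9).astype(int)
    n_days = day.max() + 1
    counts = np.bincount(day, minlength=n_days)
    sums = np.bincount(day, weights=temp, minlength=n_days)
    with np.errstate(invalid="ignore"):
        daily_mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    anomaly = daily_mean - mmm
    hotspot = np.where(anomaly >= 1.0, anomaly, 0.0)
    dhw = np.empty_like(time)
    for i, t_i in enumerate(time):
        # completed days: day index d with d+1 <= t, within the horizon
        last = int(np.floor(t_i + 1e-9))
        first = max(0, int(np.ceil(t_i - horizon - 1e-9)))
        dhw[i] = hotspot[first:last].sum() / 7.0
    return dhw


def daily_light_integral(
    time: np.ndarray, par: np.ndarray, day_index: int
) -> float:
    """Trapezoidal DLI of one full day, mol photon m-2 d-1."""
    time = np.asarray(time, dtype=float)
    par = np.asarray(par, dtype=float)
    t0, t1 = float(day_index), float(day_index + 1)
    step = np.median(np.diff(time)) if time.size > 1 else np.inf
    if time[0] > t0 + step + 1e-9 or time[-1] < t1 - step - 1e-9:
        raise ValueError(f"day {day_index} not fully covered by the series")
    mask = (time >= t0 - 1e-9) & (time <= t1 + 1e-9)
    t_day = time[mask]
    p_day = par[mask]
    return float(np.trapezoid(p_day, t_day) * _UMOL_S_TO_MOL_D)


def mean_dli(series: ForcingSeries, n_days: int | None = None) -> float:
    """Sample-mean DLI over the whole days covered by the series."""
    if n_days is None:
        n_days = int(np.floor(series.time[-1] + 1e-9))
    values = [
        daily_light_integral(series.time, series.par, d) for d in range(n_days)
    ]
    return float(np.mean(values))


def write_forcing(series: ForcingSeries, path, sep: str = ",") -> None:
    """Write the series as delimited text with the standard header."""
    series.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_forcing(path) -> ForcingSeries:
    """Read a delimited forcing file (delimiter sniffed; UTF-8).

    Requires the columns time_days, par_umol_m2_s, temp_C, din_umol_l and
    dip_umol_l; unknown columns are preserved but ignored.
    """
    with open(path, "r", encoding="utf-8") as fh:
        sample = fh.read(4096)
    try:
        sep = csv.Sniffer().sniff(sample.splitlines()[0], delimiters=",\t; ").delimiter
    except (csv.Error, IndexError):
        sep = ","
    # the C engine with round_trip parsing reproduces written doubles exactly
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing column {missing[0]}")
    extra_cols = [c for c in frame.columns if c not in _COLUMNS]
    extra = frame[extra_cols] if extra_cols else None
    return ForcingSeries(
        time=frame["time_days"].to_numpy(),
        par=frame["par_umol_m2_s"].to_numpy(),
        temp=frame["temp_C"].to_numpy(),
        din=frame["din_umol_l"].to_numpy(),
        dip=frame["dip_umol_l"].to_numpy(),
        extra=extra,
    )


def interpolate_forcing(series: ForcingSeries, t):
    """Functional alias for :meth:`ForcingSeries.at`."""
    return series.at(t)


def with_shade(spec: ScenarioSpec, shaded: bool) -> ScenarioSpec:
    """Copy of ``spec`` with the shade treatment switched."""
    return replace(spec, shade_treatment="shaded" if shaded else "unshaded")
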