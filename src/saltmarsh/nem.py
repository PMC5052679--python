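"""Non-steady-state dissolved-oxygen metabolism for tidal creek control volumes.

A single sonde + pressure logger in a creek channel yields depth,
temperature, salinity, oxygen saturation, wind and current. For a control
volume of unit creek length with a trapezoidal cross-section, the oxygen
budget is

    d(V C)/dt = Q_adv * C_b + F_gas + NEM

with V the wetted volume per unit length (m^3 m^-1), C the oxygen
concentration (mmol m^-3), Q_adv = dV/dt the tidal advective volume flux,
C_b the boundary concentration of the advected water (taken equal to the
in-creek concentration for a well-mixed volume), and F_gas the air-water
exchange flux. Solving for NEM (mmol O2 m^-1 min^-1) gives the net balance
of photosynthesis and respiration: positive = net autotrophy. Freshwater,
porewater and platform-drainage volume fluxes are ~1% of the tidal flux in
these creeks and are not modelled.

NEM is summarized over the hour of each high tide (when the low marsh is
flooded and exchanging with the creek), and windows whose peak depth tops
the marsh-platform flooding elevation are flagged: at those tides the
single-channel volume model is biased and a constant bias correction can
be subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from saltmarsh.tables import TidalCreekSeries

# Combined-fit oxygen solubility coefficients (Benson & Krause data,
# Garcia-Gordon functional form), volumetric (cm^3 dm^-3) and per-mass
# (umol kg^-1) parameter sets.
_SOL_VOL = {
    "A": (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767),
    "B": (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3),
    "C0": -4.88682e-7,
}
_SOL_MASS = {
    "A": (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369),
    "B": (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3),
    "C0": -2.75915e-7,
}
_ML_PER_MMOL = 22.3916  # molar volume of O2 at STP, cm^3 mmol^-1


def o2_saturation_concentration(temperature, salinity, unit: str = "mmol_m3"):
    """Equilibrium (100% saturation) dissolved O2 at one atmosphere.

    Parameters are in deg C (-2..40) and practical salinity (0..42); the
    default unit is mmol m^-3 (volumetric), with ``unit="umol_kg"`` for the
    per-mass fit. Vectorized over array input.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    if np.any((t < -2) | (t > 40)):
        raise ValueError("temperature outside -2..40 degC")
    if np.any((s < 0) | (s > 42)):
        raise ValueError("salinity outside 0..42")
    coef = _SOL_VOL if unit == "mmol_m3" else _SOL_MASS
    if unit not in ("mmol_m3", "umol_kg"):
        raise ValueError(f"unknown unit: {unit!r}")
    ts = np.log((298.15 - t) / (273.15 + t))
    a = coef["A"]
    b = coef["B"]
    ln_c = (a[0] + a[1] * ts + a[2] * ts**2 + a[3] * ts**3 + a[4] * ts**4
            + a[5] * ts**5
            + s * (b[0] + b[1] * ts + b[2] * ts**2 + b[3] * ts**3)
            + coef["C0"] * s**2)
    c = np.exp(ln_c)
    if unit == "mmol_m3":
        c = c / _ML_PER_MMOL * 1000.0  # cm^3/dm^3 -> mmol m^-3
    return c if c.ndim else float(c)


def schmidt_number_o2(temperature) -> np.ndarray:
    """Schmidt number of O2 in seawater (S = 35) as a quartic in T (deg C)."""
    t = np.asarray(temperature, dtype=float)
    sc = (1920.4 - 135.6 * t + 5.2122 * t**2 - 0.10939 * t**3
          + 0.00093777 * t**4)
    return sc if sc.ndim else float(sc)


@dataclass(frozen=True)
class GasExchangeModel:
    """Gas transfer velocity k(wind, current, depth) for a shallow channel.

    Additive wind and current contributions referenced to Sc = 600 and
    rescaled to O2 by (Sc/600)^schmidt_exponent:

        k600 [cm h^-1] = current_coef * sqrt(current / depth)
                         + wind_coef * wind^2

    The quadratic wind term and square-root surface-renewal current term are
    the standard functional forms for limited-fetch estuarine channels; the
    coefficients are configuration, not physics constants. k is returned in
    m min^-1 and is non-decreasing in wind and in current by construction.
    """

    name: str
    wind_coef: float = 0.266      # cm/h per (m/s)^2
    current_coef: float = 0.77    # cm/h per sqrt((m/s)/m)
    schmidt_exponent: float = -0.5

    def k(self, wind, current, depth, temperature=20.0):
        wind = np.asarray(wind, dtype=float)
        current = np.asarray(current, dtype=float)
        depth = np.asarray(depth, dtype=float)
        if np.any(depth <= 0):
            raise ValueError("depth must be positive for gas exchange")
        k600 = (self.current_coef * np.sqrt(np.maximum(current, 0.0) / depth)
                + self.wind_coef * np.maximum(wind, 0.0) ** 2)
        sc = schmidt_number_o2(temperature)
        k = k600 * (sc / 600.0) ** self.schmidt_exponent
        k = k / 100.0 / 60.0  # cm/h -> m/min
        return k if np.ndim(k) else float(k)


GAS_EXCHANGE_MODELS: dict[str, GasExchangeModel] = {
    "wind_current": GasExchangeModel("wind_current"),
    "wind_only": GasExchangeModel("wind_only", current_coef=0.0),
    "current_only": GasExchangeModel("current_only", wind_coef=0.0),
}


@dataclass(frozen=True)
class CreekGeometry:
    """Trapezoidal channel cross-section per unit creek length.

    ``bank_slope`` is the horizontal run per unit rise on each bank, so the
    wetted surface width at depth h is bottom_width + 2 * bank_slope * h and
    the wetted cross-section area (= volume per unit length) is
    bottom_width * h + bank_slope * h^2. ``platform_elevation`` is the depth
    above which the marsh platform floods and the channel model is biased.
    """

    bottom_width: float = 3.0
    bank_slope: float = 1.0
    platform_elevation: float = 1.8

    def __post_init__(self) -> None:
        if self.bottom_width <= 0:
            raise ValueError("bottom_width must be positive")
        if self.bank_slope < 0:
            raise ValueError("bank_slope must be >= 0")

    def width(self, depth):
        return self.bottom_width + 2.0 * self.bank_slope * np.asarray(depth, dtype=float)

    def volume(self, depth):
        h = np.asarray(depth, dtype=float)
        return self.bottom_width * h + self.bank_slope * h**2


def water_balance(depth: np.ndarray, dt_minutes: float, geometry: CreekGeometry
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wetted volume per unit length, its time derivative and the advective
    volume flux from a uniformly sampled depth record.

    Central differences in the interior, one-sided at the ends. Freshwater,
    porewater and platform-drainage inputs are neglected, so
    Q_adv = dV/dt exactly.
    """
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be >= 0")
    if dt_minutes <= 0:
        raise ValueError("dt must be positive")
    v = geometry.volume(depth)
    dvdt = np.gradient(v, dt_minutes)
    return v, dvdt, dvdt


def gas_exchange_flux(model: GasExchangeModel, wind, current, depth,
                      concentration, saturation_concentration,
                      geometry: CreekGeometry, temperature=20.0):
    """Air-water O2 flux per unit creek length (mmol O2 m^-1 min^-1):
    F = k * (C_sat - C) * surface_width. Positive = invasion."""
    k = model.k(wind, current, depth, temperature)
    width = geometry.width(depth)
    f = k * (np.asarray(saturation_concentration, float)
             - np.asarray(concentration, float)) * width
    return f if np.ndim(f) else float(f)


@dataclass
class NEMResult:
    """Per-timestep NEM with its budget terms and high-tide summaries.

    ``series`` columns (all mmol O2 m^-1 min^-1 except as noted): ``nem``,
    ``gas_flux``, ``advective`` (Q_adv * C_b), ``storage`` (d(VC)/dt),
    ``volume`` (m^3 m^-1), ``concentration`` (mmol m^-3), ``depth`` (m).
    ``windows`` is filled by :func:`high_tide_means`.
    """

    series: pd.DataFrame
    geometry: CreekGeometry
    gas_model: str
    windows: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def nem(self) -> pd.Series:
        return self.series["nem"]


def nem_series(series: TidalCreekSeries, geometry: CreekGeometry,
               gas_model: GasExchangeModel | str = "wind_current",
               dt_eval_minutes: float = 10.0) -> NEMResult:
    """Solve the non-steady-state O2 balance for NEM at every evaluation step.

    ``dt_eval_minutes`` must be an integer multiple of the series step; the
    record is subsampled to that resolution before differencing. The
    boundary concentration of the advective term is the in-creek
    concentration (well-mixed control volume, single-sensor deployment).
    """
    if isinstance(gas_model, str):
        gas_model = GAS_EXCHANGE_MODELS[gas_model]
    dt0 = series.dt_minutes
    stride = dt_eval_minutes / dt0
    if abs(stride - round(stride)) > 1e-9 or stride < 1:
        raise ValueError("dt_eval must be a positive multiple of the series step")
    df = series.data.iloc[:: int(round(stride))]
    dt = dt_eval_minutes

    c_sat = o2_saturation_concentration(df["temperature"].to_numpy(),
                                        df["salinity"].to_numpy())
    if "o2_concentration" in df.columns:
        c = df["o2_concentration"].to_numpy(float)
    else:
        c = df["o2_saturation"].to_numpy(float) / 100.0 * c_sat

    depth = df["depth"].to_numpy(float)
    v, dvdt, q_adv = water_balance(depth, dt, geometry)
    f_gas = gas_exchange_flux(gas_model, df["wind"].to_numpy(float),
                              df["current"].to_numpy(float), depth, c, c_sat,
                              geometry, df["temperature"].to_numpy(float))
    storage = np.gradient(v * c, dt)
    advective = q_adv * c  # boundary concentration = in-creek concentration
    nem = storage - advective - f_gas
    out = pd.DataFrame({
        "nem": nem, "gas_flux": f_gas, "advective": advective,
        "storage": storage, "volume": v, "concentration": c, "depth": depth,
    }, index=df.index)
    return NEMResult(out, geometry, gas_model.name)


def high_tide_means(result: NEMResult, window_minutes: float = 60.0,
                    min_separation_hours: float = 6.0) -> pd.DataFrame:
    """Mean and s.d. of NEM over the hour of each high tide.

    High tides are local depth maxima separated by at least
    ``min_separation_hours`` (semidiurnal default); each window spans
    ``window_minutes`` centred on the peak. Windows truncated by the record
    boundary are dropped with a warning; windows whose peak depth exceeds
    the platform flooding elevation are flagged ``peak_flood_bias``. The
    summary table is also stored on ``result.windows``.
    """
    df = result.series
    dt = (df.index[1] - df.index[0]).total_seconds() / 60.0
    depth = df["depth"].to_numpy()
    min_sep = int(np.ceil(min_separation_hours * 60.0 / dt))
    peaks, _ = find_peaks(depth, distance=min_sep)
    half = int(round(window_minutes / 2.0 / dt))
    rows = []
    for p in peaks:
        lo, hi = p - half, p + half
        if lo < 0 or hi >= len(df):
            warnings.warn(f"dropping high-tide window truncated at record boundary "
                          f"(peak {df.index[p]})")
            continue
        nem = df["nem"].to_numpy()[lo: hi + 1]
        rows.append({
            "center": df.index[p],
            "mean_nem": float(nem.mean()),
            "sd_nem": float(nem.std(ddof=1)) if len(nem) > 1 else 0.0,
            "peak_depth": float(depth[p]),
            "peak_flood_bias": bool(depth[p] > result.geometry.platform_elevation),
            "n": len(nem),
        })
    windows = pd.DataFrame(rows)
    result.windows = windows
    return windows


def creek_difference(a: NEMResult, b: NEMResult,
                     tolerance_minutes: float = 90.0) -> pd.DataFrame:
    """Per-high-tide difference of mean NEM between two creeks (a - b).

    Windows are matched by tide time within ``tolerance_minutes``; the
    difference s.d. is propagated as sqrt(sd_a^2 + sd_b^2). Unequal window
    counts are an error (the records must cover the same tides).
    """
    if a.windows is None or b.windows is None:
        raise ValueError("run high_tide_means on both results first")
    wa, wb = a.windows, b.windows
    if len(wa) != len(wb):
        raise ValueError(f"unmatched window counts: {len(wa)} vs {len(wb)}")
    rows = []
    for (_, ra), (_, rb) in zip(wa.iterrows(), wb.iterrows()):
        gap = abs((ra["center"] - rb["center"]).total_seconds()) / 60.0
        if gap > tolerance_minutes:
            raise ValueError(f"high-tide windows misaligned by {gap:.0f} min")
        rows.append({
            "center": ra["center"],
            "diff_mean_nem": ra["mean_nem"] - rb["mean_nem"],
            "sd": float(np.hypot(ra["sd_nem"], rb["sd_nem"])),
            "peak_flood_bias": bool(ra["peak_flood_bias"] or rb["peak_flood_bias"]),
        })
    return pd.DataFrame(rows)


def apply_bias_correction(result: NEMResult, bias: float) -> NEMResult:
    """Subtract a constant positive bias (e.g. platform-drainage oxygen
    import, ~0.35 mmol O2 m^-1 min^-1) from the mean NEM of every window
    flagged ``peak_flood_bias``. Returns a new result; unflagged windows
    are untouched."""
    if bias < 0:
        raise ValueError("bias must be >= 0")
    if result.windows is None:
        raise ValueError("run high_tide_means first")
    windows = result.windows.copy()
    flagged = windows["peak_flood_bias"]
    if not flagged.any():
        warnings.warn("no flagged windows; bias correction is an identity")
    windows.loc[flagged, "mean_nem"] -= bias
    corrected = NEMResult(result.series, result.geometry, result.gas_model,
                          windows, list(result.notes))
    corrected.notes.append(
        f"bias {bias} mmol O2 m^-1 min^-1 subtracted from "
        f"{int(flagged.sum())} peak-flood window(s)")
    return corrected
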