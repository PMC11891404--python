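"""Differential scanning calorimetry: thermograms and equilibrium fits.

Reads DSC thermograms, fits the calorimetric two-state model

    Cp,app(T) = a + b·T + ΔHcal·ΔHVH/(R·T²) · K/(1+K)²

(K the Van't Hoff equilibrium constant with melting temperature Tm),
computes baseline-subtracted calorimetric enthalpies and upscan/rescan
reversibility, exports ΔG(T) points inside the thermal transition, and
summarizes scan-rate dependence as an equilibrium diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

from . import io
from .constants import CELSIUS_OFFSET, R_CAL, celsius_to_kelvin
from .models import (
    TwoStateThermalParams,
    apparent_heat_capacity,
    excess_heat_capacity,
    fraction_unfolded,
    unfolding_dG,
    vant_hoff_K,
)

__all__ = [
    "Thermogram",
    "ThermalFitResult",
    "ReversibilityResult",
    "ScanRateSummary",
    "read_thermogram",
    "write_thermogram",
    "fit_thermal_two_state",
    "calorimetric_enthalpy",
    "reversibility",
    "dsc_dG_points",
    "scan_rate_summary",
]

MIN_POINTS = 50


@dataclass
class Thermogram:
    """One DSC scan: ordered temperature grid (K) and apparent molar heat
    capacity (kcal·mol⁻¹·K⁻¹), with scan metadata."""

    temperature: np.ndarray
    cp_app: np.ndarray
    scan_rate: float = 2.0          # K/min
    scan_kind: str = "upscan"       # "upscan" | "rescan"
    condition_label: str = ""
    protein_conc: float | None = None  # µM, metadata only

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.cp_app = np.asarray(self.cp_app, dtype=float)
        if self.temperature.shape != self.cp_app.shape:
            raise ValueError("temperature and cp_app must have the same length")
        if self.temperature.size < MIN_POINTS:
            raise ValueError(
                f"thermogram needs at least {MIN_POINTS} points, got {self.temperature.size}")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be positive")
        if self.scan_kind not in ("upscan", "rescan"):
            raise ValueError(f"scan_kind must be 'upscan' or 'rescan', got {self.scan_kind!r}")


@dataclass
class ThermalFitResult:
    """Outcome of a two-state DSC fit."""

    params: TwoStateThermalParams
    uncertainties: dict[str, float]
    fit_window: tuple[float, float]
    residual_norm: float
    n_points: int
    scan_rate: float = 2.0
    condition_label: str = ""

    @property
    def ratio_cal_vh(self) -> float:
        return self.params.ratio_cal_vh


@dataclass
class ReversibilityResult:
    """Calorimetric-enthalpy ratio of a rescan to its upscan."""

    h_upscan: float
    h_rescan: float
    percent: float
    flagged: bool = False  # True when percent > 100 (unphysical)


@dataclass
class ScanRateSummary:
    """Per-rate Tm/ΔHVH table with the linear trend of Tm against rate."""

    table: pd.DataFrame
    slope: float            # K per (K/min)
    slope_se: float
    threshold: float
    equilibrium_questionable: bool = field(default=False)


# ---------------------------------------------------------------------------
# I/O

def read_thermogram(path) -> Thermogram:
    """Read a thermogram CSV (columns ``temperature``, ``cp``).

    Header keys: ``temperature_unit`` (C|K, default C), ``scan_rate``
    (K/min), ``scan_kind`` (upscan|rescan), ``condition``, ``protein_conc_uM``.
    Rows are sorted by ascending temperature; duplicate temperatures are
    rejected.
    """
    df, meta = io.read_table(path)
    io.require_columns(df, ["temperature", "cp"], path)
    df = io.coerce_numeric(df, ["temperature", "cp"], path)
    if len(df) < MIN_POINTS:
        raise io.FormatError(f"{path}: fewer than {MIN_POINTS} usable rows ({len(df)})")
    unit = meta.get("temperature_unit", "C").upper()
    temp = df["temperature"].to_numpy()
    if unit == "C":
        temp = celsius_to_kelvin(temp)
    elif unit != "K":
        raise io.FormatError(f"{path}: unknown temperature_unit {unit!r}")
    order = np.argsort(temp, kind="stable")
    temp = temp[order]
    cp = df["cp"].to_numpy()[order]
    dup = np.flatnonzero(np.diff(temp) == 0)
    if dup.size:
        raise io.FormatError(f"{path}: duplicate temperature at sorted row {int(dup[0])}")
    conc = meta.get("protein_conc_uM")
    return Thermogram(
        temperature=temp,
        cp_app=cp,
        scan_rate=float(meta.get("scan_rate", 2.0)),
        scan_kind=meta.get("scan_kind", "upscan"),
        condition_label=meta.get("condition", ""),
        protein_conc=float(conc) if conc is not None else None,
    )


def write_thermogram(path, scan: Thermogram, temperature_unit: str = "K") -> None:
    """Write a thermogram in the dialect :func:`read_thermogram` consumes."""
    temp = scan.temperature
    if temperature_unit.upper() == "C":
        temp = temp - CELSIUS_OFFSET
    meta = {
        "temperature_unit": temperature_unit.upper(),
        "scan_rate": scan.scan_rate,
        "scan_kind": scan.scan_kind,
    }
    if scan.condition_label:
        meta["condition"] = scan.condition_label
    if scan.protein_conc is not None:
        meta["protein_conc_uM"] = scan.protein_conc
    io.write_table(path, pd.DataFrame({"temperature": temp, "cp": scan.cp_app}), meta)


# ---------------------------------------------------------------------------
# Baseline and peak heuristics

def _initial_estimates(scan: Thermogram) -> TwoStateThermalParams:
    """Reproducible starting point: native baseline from the coolest 20 % of
    the grid, Tm at the detrended maximum, ΔHcal from the detrended area and
    ΔHVH from the two-state peak-height relation ΔHVH = 4·R·Tm²·Cpmax/ΔHcal."""
    T, cp = scan.temperature, scan.cp_app
    n_low = max(int(0.2 * T.size), 5)
    b, a = np.polyfit(T[:n_low], cp[:n_low], 1)
    detrended = cp - (a + b * T)
    i_peak = int(np.argmax(detrended))
    tm0 = float(T[i_peak])
    cp_max = float(detrended[i_peak])
    if cp_max <= 0:
        raise RuntimeError("no calorimetric peak above the native baseline")
    dh_cal0 = float(np.trapezoid(np.clip(detrended, 0, None), T)) or 1.0
    dh_vh0 = 4.0 * R_CAL * tm0**2 * cp_max / dh_cal0 / 1000.0
    return TwoStateThermalParams(
        tm=tm0, dh_cal=abs(dh_cal0), dh_vh=max(abs(dh_vh0), 1.0),
        baseline_a=float(a), baseline_b=float(b))


def _default_window(scan: Thermogram, init: TwoStateThermalParams,
                    tail_fraction: float = 0.05) -> tuple[float, float]:
    """Fit window excluding the post-transition region.

    The unfolded-state baseline is the part of a scan most distorted by
    incomplete reversibility, so the window ends where the initial-estimate
    excess heat capacity has fallen below ``tail_fraction`` of its peak on
    the high-temperature side.
    """
    T = scan.temperature
    excess = excess_heat_capacity(T, init)
    i_peak = int(np.argmax(excess))
    cutoff = tail_fraction * excess[i_peak]
    above = np.flatnonzero(excess[i_peak:] >= cutoff)
    i_hi = i_peak + (int(above[-1]) if above.size else 0)
    return float(T[0]), float(T[i_hi])


# ---------------------------------------------------------------------------
# Fitting

def fit_thermal_two_state(scan: Thermogram,
                          window: tuple[float, float] | None = None,
                          ) -> ThermalFitResult:
    """Least-squares fit of the two-state model to one thermogram.

    Parameters {Tm, ΔHcal, ΔHVH, a, b} are estimated with uncertainties
    from the curvature of the objective.  When ``window`` is None the
    post-transition region is excluded automatically (see
    :func:`_default_window`).

    Raises
    ------
    RuntimeError
        If the apparent-Cp peak sits at a grid edge ("transition not
        spanned") or the optimizer fails to converge (the diagnostic lists
        the initial guesses used).
    """
    init = _initial_estimates(scan)
    T_all, cp_all = scan.temperature, scan.cp_app
    detrended = cp_all - (init.baseline_a + init.baseline_b * T_all)
    i_peak = int(np.argmax(detrended))
    if i_peak == 0 or i_peak == T_all.size - 1:
        raise RuntimeError("transition not spanned: apparent-Cp peak at grid edge")

    if window is None:
        window = _default_window(scan, init)
    lo, hi = window
    if lo < T_all[0] - 1e-9 or hi > T_all[-1] + 1e-9:
        raise ValueError("fit window outside the thermogram's temperature range")
    mask = (T_all >= lo) & (T_all <= hi)
    T, cp = T_all[mask], cp_all[mask]

    pars = lmfit.Parameters()
    pars.add("tm", value=init.tm, min=T_all[0], max=T_all[-1])
    pars.add("dh_cal", value=init.dh_cal, min=1e-6)
    pars.add("dh_vh", value=init.dh_vh, min=1e-6)
    pars.add("baseline_a", value=init.baseline_a)
    pars.add("baseline_b", value=init.baseline_b)

    def residual(p):
        params = TwoStateThermalParams(
            tm=p["tm"].value, dh_cal=p["dh_cal"].value, dh_vh=p["dh_vh"].value,
            baseline_a=p["baseline_a"].value, baseline_b=p["baseline_b"].value)
        return apparent_heat_capacity(T, params) - cp

    result = lmfit.minimize(residual, pars, method="leastsq")
    if not result.success:
        raise RuntimeError(
            "DSC fit failed to converge; initial guesses were "
            f"Tm={init.tm:.2f} K, dHcal={init.dh_cal:.2f}, dHvh={init.dh_vh:.2f}, "
            f"a={init.baseline_a:.4g}, b={init.baseline_b:.4g}")
    fitted = TwoStateThermalParams(
        tm=result.params["tm"].value,
        dh_cal=result.params["dh_cal"].value,
        dh_vh=result.params["dh_vh"].value,
        baseline_a=result.params["baseline_a"].value,
        baseline_b=result.params["baseline_b"].value)
    unc = {name: (result.params[name].stderr if result.params[name].stderr is not None
                  else float("nan"))
           for name in ("tm", "dh_cal", "dh_vh", "baseline_a", "baseline_b")}
    return ThermalFitResult(
        params=fitted,
        uncertainties=unc,
        fit_window=(float(lo), float(hi)),
        residual_norm=float(np.sqrt(np.mean(result.residual**2))),
        n_points=int(T.size),
        scan_rate=scan.scan_rate,
        condition_label=scan.condition_label,
    )


# ---------------------------------------------------------------------------
# Enthalpy integration and reversibility

def calorimetric_enthalpy(scan: Thermogram, flat_quantile: float = 0.1,
                          peak_threshold: float = 0.02) -> float:
    """Baseline-subtracted area under the calorimetric peak, kcal·mol⁻¹.

    The integration baseline is the straight line joining the medians of
    the pre- and post-transition flat regions (identified as everything
    outside the contiguous region where a first-pass detrended signal
    exceeds ``peak_threshold`` of its maximum).  This policy needs no model
    fit, so rescans lacking a clean transition are handled identically.

    Returns 0 (with a warning) when no peak rises above the flat regions,
    which lets a fully irreversible rescan report 0 % reversibility.
    """
    T, cp = scan.temperature, scan.cp_app
    n_edge = max(int(flat_quantile * T.size), 3)

    # first pass: rough line through the two edge-region medians
    def _line_through_medians(lo_idx, hi_idx):
        t0, c0 = np.median(T[lo_idx]), np.median(cp[lo_idx])
        t1, c1 = np.median(T[hi_idx]), np.median(cp[hi_idx])
        slope = (c1 - c0) / (t1 - t0)
        return c0 + slope * (T - t0)

    rough = _line_through_medians(slice(None, n_edge), slice(-n_edge, None))
    detrended = cp - rough
    peak = float(detrended.max())
    scale = max(peak, float(np.abs(detrended).max()))
    floor = 1e-9 * max(float(np.abs(cp).max()), 1.0)  # fp noise on a pure line
    if scale <= floor or peak <= peak_threshold * scale:
        warnings.warn("no calorimetric peak identified; enthalpy set to 0",
                      stacklevel=2)
        return 0.0

    in_peak = detrended > peak_threshold * peak
    i_peak = int(np.argmax(detrended))
    # contiguous peak region around the maximum
    left = i_peak
    while left > 0 and in_peak[left - 1]:
        left -= 1
    right = i_peak
    while right < T.size - 1 and in_peak[right + 1]:
        right += 1
    # widen by half the peak width on each side: the transition tails decay
    # fast but still bias the flat-region medians at the threshold boundary
    margin = (right - left) // 2
    left = max(left - margin, 0)
    right = min(right + margin, T.size - 1)
    pre = slice(None, max(left, 3))
    post = slice(min(right + 1, T.size - 3), None)
    baseline = _line_through_medians(pre, post)
    return float(np.trapezoid(cp - baseline, T))


def reversibility(upscan: Thermogram, rescan: Thermogram) -> ReversibilityResult:
    """Percent reversibility: 100 × ΔHcal(rescan)/ΔHcal(upscan)."""
    h_up = calorimetric_enthalpy(upscan)
    if h_up <= 0:
        raise ValueError("upscan calorimetric enthalpy is not positive; "
                         "reversibility undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # flat rescan legitimately yields 0
        h_re = calorimetric_enthalpy(rescan)
    pct = 100.0 * h_re / h_up
    return ReversibilityResult(h_upscan=h_up, h_rescan=h_re, percent=pct,
                               flagged=pct > 100.0)


# ---------------------------------------------------------------------------
# ΔG(T) inside the transition

def dsc_dG_points(fit: ThermalFitResult,
                  bounds: tuple[float, float] = (0.05, 0.95),
                  n_points: int = 25,
                  enthalpy: str = "vh") -> pd.DataFrame:
    """ΔG = −R·T·ln K at temperatures within the thermal transition.

    Points are emitted where the unfolded fraction lies in ``bounds``
    (default 5–95 %).  ``enthalpy`` selects which enthalpy enters the
    Van't Hoff K: ``"vh"`` (default — the parameter the equilibrium
    constant is written with) or ``"cal"``.  ΔG decreases monotonically
    with T across the window and crosses zero at Tm.
    """
    lo, hi = bounds
    if not (0 < lo < hi < 1):
        raise ValueError("population bounds must satisfy 0 < lo < hi < 1")
    if enthalpy not in ("vh", "cal"):
        raise ValueError("enthalpy must be 'vh' or 'cal'")
    dh = fit.params.dh_vh if enthalpy == "vh" else fit.params.dh_cal
    tm = fit.params.tm
    # invert f = K/(1+K): T at the population bounds
    dh_cal_units = dh * 1000.0
    def T_at_fraction(f):
        K = f / (1.0 - f)
        return 1.0 / (1.0 / tm - R_CAL * np.log(K) / dh_cal_units)
    T = np.linspace(T_at_fraction(lo), T_at_fraction(hi), n_points)
    if T.size == 0:
        raise ValueError("empty transition window")
    K = vant_hoff_K(T, tm, dh)
    dG = unfolding_dG(K, T)
    frac = fraction_unfolded(np.asarray(K))
    return pd.DataFrame({"T": T, "dG": dG, "fraction_unfolded": frac})


# ---------------------------------------------------------------------------
# Scan-rate diagnostics

def scan_rate_summary(fits: list[ThermalFitResult],
                      threshold: float = 0.5) -> ScanRateSummary:
    """Tabulate Tm and ΔHVH against scan rate and test for a Tm trend.

    A slope of Tm versus rate larger (in absolute value) than ``threshold``
    K per (K·min⁻¹) flags the equilibrium assumption as questionable —
    equilibrium unfolding should be scan-rate independent.
    """
    rates = np.array([f.scan_rate for f in fits], dtype=float)
    if np.unique(rates).size < 2:
        raise ValueError("scan-rate summary needs at least 2 distinct rates")
    table = pd.DataFrame({
        "scan_rate": rates,
        "tm": [f.params.tm for f in fits],
        "dh_vh": [f.params.dh_vh for f in fits],
    }).sort_values("scan_rate", ignore_index=True)
    x = table["scan_rate"].to_numpy()
    y = table["tm"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    dof = max(x.size - 2, 1)
    sxx = np.sum((x - x.mean()) ** 2)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return ScanRateSummary(
        table=table, slope=float(slope), slope_se=se, threshold=threshold,
        equilibrium_questionable=bool(abs(slope) > threshold))
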