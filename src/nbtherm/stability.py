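"""Stability curves: ΔCp estimation and Gibbs–Helmholtz fits.

Two independent routes to the unfolding heat-capacity change ΔCp:

* a Kirchhoff-style regression of the calorimetric enthalpy against the
  melting temperature across mildly destabilizing conditions (low GdmHCl):
  dΔH/dTm = ΔCp;
* fitting the integrated Gibbs–Helmholtz equation to ΔG(T) points pooled
  from chemical denaturation (low temperatures, ΔG = m_eq·Cm) and DSC
  (near Tm, ΔG = −R·T·ln K).

The Gibbs–Helmholtz fit always holds Tm fixed (it is the best-determined
parameter) and either floats both ΔH and ΔCp or holds ΔH at its
calorimetric value and floats ΔCp only.  With Tm fixed the model is linear
in the remaining parameters, so the fit is an ordinary least-squares
problem and passes exactly through (Tm, 0) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chemdenat import ChemFitResult
from .constants import celsius_to_kelvin
from .dsc import ThermalFitResult, dsc_dG_points
from .models import GibbsHelmholtzParams, gibbs_helmholtz_dG, stability_maximum

__all__ = [
    "DGPoint",
    "KirchhoffPoint",
    "DcpEstimate",
    "StabilityCurveFit",
    "estimate_dcp_kirchhoff",
    "assemble_dg_points",
    "fit_stability_curve",
    "stability_summary",
]

MODES = ("float_dh_dcp", "fixed_dh_float_dcp")


@dataclass(frozen=True)
class DGPoint:
    """One unfolding free-energy point with provenance."""

    T: float                    # K
    dG: float                   # kcal/mol
    source: str                 # "dsc" | "chemical"
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.source not in ("dsc", "chemical"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class KirchhoffPoint:
    """(Tm, ΔHcal) pair measured under a perturbing condition."""

    tm: float                   # K
    dh_cal: float               # kcal/mol
    denaturant: float = 0.0     # M, annotation
    variant: str = ""

    def __post_init__(self) -> None:
        if self.tm <= 0 or self.dh_cal <= 0:
            raise ValueError("Tm and dH_cal must be positive")


@dataclass
class DcpEstimate:
    """Kirchhoff slope dΔHcal/dTm with its standard error."""

    dcp: float                  # kcal/mol/K
    se: float
    intercept: float
    n: int
    r_squared: float


@dataclass
class StabilityCurveFit:
    """Gibbs–Helmholtz fit of pooled ΔG(T) points."""

    params: GibbsHelmholtzParams
    mode: str
    fixed_inputs: dict[str, float]
    r_squared: float
    uncertainties: dict[str, float]
    residual_norm: float
    n_points: int
    dcp_not_identifiable: bool = field(default=False)


def estimate_dcp_kirchhoff(points: list[KirchhoffPoint],
                           variant: str | None = None) -> DcpEstimate:
    """ΔCp as the OLS slope of ΔHcal against Tm.

    By default all points are pooled into one regression (one overall
    line); pass ``variant`` to restrict to a single variant's points.
    Requires ≥ 3 points with non-degenerate Tm spread.
    """
    if variant is not None:
        points = [p for p in points if p.variant == variant]
    if len(points) < 3:
        raise ValueError("Kirchhoff regression needs at least 3 points")
    tm = np.array([p.tm for p in points])
    dh = np.array([p.dh_cal for p in points])
    if np.ptp(tm) < 1e-9:
        raise ValueError("degenerate Tm spread: all melting temperatures equal")
    res = stats.linregress(tm, dh)
    return DcpEstimate(dcp=float(res.slope), se=float(res.stderr),
                       intercept=float(res.intercept), n=len(points),
                       r_squared=float(res.rvalue**2))


def assemble_dg_points(thermal: ThermalFitResult,
                       chem: list[ChemFitResult],
                       bounds: tuple[float, float] = (0.05, 0.95),
                       n_thermal: int = 25,
                       enthalpy: str = "vh") -> list[DGPoint]:
    """Pool chemical and DSC free-energy points for a stability-curve fit.

    Chemical points contribute (T, m_eq·Cm); thermal points are the ΔG
    values within the DSC transition (including the (Tm, 0) anchor), with
    ``enthalpy`` selecting which enthalpy enters the Van't Hoff K.
    """
    if not chem:
        raise ValueError("no chemical-denaturation results supplied")
    pts = [DGPoint(T=c.temperature, dG=c.dG, source="chemical") for c in chem]
    thermal_tab = dsc_dG_points(thermal, bounds=bounds, n_points=n_thermal,
                                enthalpy=enthalpy)
    pts += [DGPoint(T=float(t), dG=float(g), source="dsc")
            for t, g in zip(thermal_tab["T"], thermal_tab["dG"])]
    if not any(abs(p.dG) < 1e-9 for p in pts if p.source == "dsc"):
        pts.append(DGPoint(T=thermal.params.tm, dG=0.0, source="dsc"))
    return pts


def fit_stability_curve(points: list[DGPoint], tm: float,
                        mode: str = "float_dh_dcp",
                        dh: float | None = None,
                        use_weights: bool = False) -> StabilityCurveFit:
    """Least-squares Gibbs–Helmholtz fit with Tm held fixed.

    ``mode="float_dh_dcp"`` floats ΔH and ΔCp; ``mode="fixed_dh_float_dcp"``
    holds ΔH at the supplied (calorimetric) value and floats ΔCp only.
    With Tm fixed the model ΔG = ΔH·(1−T/Tm) + ΔCp·(T−Tm−T·ln(T/Tm)) is
    linear in the free parameters, so estimates and standard errors come
    from ordinary least squares.  A ΔCp standard error exceeding |ΔCp| is
    flagged as "ΔCp not identifiable" rather than suppressed.

    Weights: equal by default; with ``use_weights=True`` points carrying a
    ``weight`` are used as multiplicative least-squares weights
    (e.g. inverse variances).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if mode == "fixed_dh_float_dcp" and dh is None:
        raise ValueError("fixed-dH mode requires a dH value")
    T = np.array([p.T for p in points])
    y = np.array([p.dG for p in points])
    x_dh = 1.0 - T / tm
    x_dcp = T - tm - T * np.log(T / tm)
    if mode == "float_dh_dcp":
        X = np.column_stack([x_dh, x_dcp])
        names = ["dh", "dcp"]
        target = y
    else:
        X = x_dcp[:, None]
        names = ["dcp"]
        target = y - dh * x_dh
    n, p_free = X.shape
    if n < p_free + 1:
        raise ValueError(f"need at least {p_free + 1} points for mode {mode!r}")

    w = np.ones(n)
    if use_weights:
        w = np.array([p.weight if p.weight is not None else 1.0 for p in points])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], target * sw, rcond=None)

    est = dict(zip(names, beta))
    dh_fit = est.get("dh", dh)
    dcp_fit = est["dcp"]
    params = GibbsHelmholtzParams(tm=tm, dh=float(dh_fit), dcp=float(dcp_fit))

    pred = gibbs_helmholtz_dG(T, params)
    resid = y - pred
    dof = max(n - p_free, 1)
    sigma2 = float(np.sum(w * resid**2) / dof)
    xtx_inv = np.linalg.inv((X * w[:, None]).T @ X)
    ses = np.sqrt(sigma2 * np.diag(xtx_inv))
    unc = dict(zip(names, ses.astype(float)))

    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    fixed: dict[str, float] = {"tm": float(tm)}
    if mode == "fixed_dh_float_dcp":
        fixed["dh"] = float(dh)
    return StabilityCurveFit(
        params=params, mode=mode, fixed_inputs=fixed,
        r_squared=r2, uncertainties=unc,
        residual_norm=float(np.sqrt(np.mean(resid**2))),
        n_points=n,
        dcp_not_identifiable=bool(unc["dcp"] > abs(dcp_fit)))


def stability_summary(fit: StabilityCurveFit,
                      report_temps_celsius: tuple[float, ...] = (4.0, 25.0, 37.0),
                      ) -> pd.DataFrame:
    """ΔG at the requested temperatures plus the stability maximum.

    Returns one row per requested temperature and, when ΔCp > 0, a final
    row for the temperature of maximal stability Ts = Tm·exp(−ΔH/(Tm·ΔCp)).
    """
    p = fit.params
    rows = []
    for t_c in report_temps_celsius:
        t_k = float(celsius_to_kelvin(t_c))
        rows.append({"label": f"{t_c:g} C", "T": t_k,
                     "dG": float(gibbs_helmholtz_dG(t_k, p))})
    if p.dcp > 0:
        ts, dg_max = stability_maximum(p)
        rows.append({"label": "Ts (max stability)", "T": ts, "dG": dg_max})
    return pd.DataFrame(rows)
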