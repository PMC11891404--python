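"""Two-state equilibrium unfolding models.

This module is the single source of truth for the thermodynamic forms used
by every fitting and simulation stage:

* the Van't Hoff equilibrium constant ``K(T)`` of a two-state unfolding
  transition with melting temperature ``Tm`` (the temperature at which
  ``K = 1``),
* the unfolding free energy ``ΔG = −R·T·ln K``,
* the excess heat capacity of a calorimetric transition,
  ``ΔHcal·ΔHVH/(R·T²) · K/(1+K)²``, whose integral over the transition is
  the calorimetric enthalpy ``ΔHcal``,
* the integrated Gibbs–Helmholtz stability curve
  ``ΔG(T) = ΔH·(1 − T/Tm) + ΔCp·(T − Tm − T·ln(T/Tm))``.

Sign convention: ΔG is the *unfolding* free energy, positive when the
native state is favored (K < 1). Enthalpies and free energies are in
kcal·mol⁻¹, heat capacities in kcal·mol⁻¹·K⁻¹, temperatures in K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KCAL_TO_CAL, R_CAL

__all__ = [
    "TwoStateThermalParams",
    "GibbsHelmholtzParams",
    "vant_hoff_K",
    "unfolding_dG",
    "fraction_unfolded",
    "excess_heat_capacity",
    "apparent_heat_capacity",
    "gibbs_helmholtz_dG",
    "stability_maximum",
]


@dataclass(frozen=True)
class TwoStateThermalParams:
    """Parameters of the calorimetric two-state model.

    Attributes
    ----------
    tm : float
        Melting temperature, K (equilibrium constant equals 1).
    dh_cal : float
        Calorimetric enthalpy — area under the excess heat-capacity peak,
        kcal·mol⁻¹.
    dh_vh : float
        Van't Hoff enthalpy — governs the temperature dependence of K,
        kcal·mol⁻¹.
    baseline_a, baseline_b : float
        Intercept (kcal·mol⁻¹·K⁻¹) and slope (kcal·mol⁻¹·K⁻²) of the linear
        native-state heat-capacity baseline a + b·T.
    """

    tm: float
    dh_cal: float
    dh_vh: float
    baseline_a: float = 0.0
    baseline_b: float = 0.0

    def __post_init__(self) -> None:
        if self.tm <= 0:
            raise ValueError(f"Tm must be positive, got {self.tm}")
        if self.dh_cal <= 0 or self.dh_vh <= 0:
            raise ValueError("enthalpies must be positive")

    @property
    def ratio_cal_vh(self) -> float:
        """Cooperativity diagnostic ΔHcal/ΔHVH (≈1 for two-state unfolding)."""
        return self.dh_cal / self.dh_vh


@dataclass(frozen=True)
class GibbsHelmholtzParams:
    """Parameters of the integrated Gibbs–Helmholtz stability curve.

    ``tm`` in K; ``dh`` is the unfolding enthalpy at Tm, kcal·mol⁻¹;
    ``dcp`` the unfolding heat-capacity change, kcal·mol⁻¹·K⁻¹.
    """

    tm: float
    dh: float
    dcp: float

    def __post_init__(self) -> None:
        if self.tm <= 0:
            raise ValueError(f"Tm must be positive, got {self.tm}")


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return T


def vant_hoff_K(T, tm: float, dh_vh: float):
    """Equilibrium constant of unfolding at temperature ``T`` (K).

    K = exp(−(ΔHVH/R)·(1/T − 1/Tm)); K(Tm) = 1 and K is strictly
    increasing in T for positive ΔHVH.

    Parameters are ``tm`` in K and ``dh_vh`` in kcal·mol⁻¹.
    """
    T = _check_temperature(T)
    if tm <= 0:
        raise ValueError("Tm must be positive")
    if not np.isfinite(dh_vh):
        raise ValueError("dh_vh must be finite")
    exponent = -(dh_vh * KCAL_TO_CAL / R_CAL) * (1.0 / T - 1.0 / tm)
    out = np.exp(exponent)
    return out if out.ndim else float(out)


def unfolding_dG(K, T):
    """Unfolding free energy ΔG = −R·T·ln K, kcal·mol⁻¹.

    Positive when the native state is favored (K < 1).
    """
    T = _check_temperature(T)
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("equilibrium constant must be positive")
    out = -R_CAL * T * np.log(K) / KCAL_TO_CAL
    return out if out.ndim else float(out)


def fraction_unfolded(K):
    """Population of the unfolded state, f = K/(1+K) ∈ [0, 1]."""
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("equilibrium constant must be non-negative")
    out = K / (1.0 + K)
    return out if out.ndim else float(out)


def excess_heat_capacity(T, params: TwoStateThermalParams):
    """Excess heat capacity of the transition, kcal·mol⁻¹·K⁻¹.

    ΔHcal·ΔHVH/(R·T²) · K/(1+K)², with K from :func:`vant_hoff_K`.  Since
    d fU/dT = ΔHVH/(R·T²)·K/(1+K)², the integral of the excess heat
    capacity across the whole transition equals ΔHcal; at Tm the population
    factor is exactly 1/4.
    """
    T = _check_temperature(T)
    K = np.asarray(vant_hoff_K(T, params.tm, params.dh_vh))
    pop = K / (1.0 + K) ** 2
    dh_cal = params.dh_cal * KCAL_TO_CAL
    dh_vh = params.dh_vh * KCAL_TO_CAL
    out = dh_cal * dh_vh / (R_CAL * T**2) * pop / KCAL_TO_CAL
    return out if out.ndim else float(out)


def apparent_heat_capacity(T, params: TwoStateThermalParams):
    """Full apparent heat capacity: native baseline a + b·T plus the excess."""
    T = _check_temperature(T)
    out = params.baseline_a + params.baseline_b * T + excess_heat_capacity(T, params)
    return out if np.ndim(out) else float(out)


def gibbs_helmholtz_dG(T, p: GibbsHelmholtzParams):
    """Stability curve ΔG(T) = ΔH·(1 − T/Tm) + ΔCp·(T − Tm − T·ln(T/Tm)).

    Vanishes at Tm; slope there is −ΔH/Tm; for ΔCp > 0 the curve has its
    maximum at Ts = Tm·exp(−ΔH/(Tm·ΔCp)).
    """
    T = _check_temperature(T)
    out = p.dh * (1.0 - T / p.tm) + p.dcp * (T - p.tm - T * np.log(T / p.tm))
    return out if out.ndim else float(out)


def stability_maximum(p: GibbsHelmholtzParams) -> tuple[float, float]:
    """Closed-form temperature of maximal stability and ΔG there.

    Ts = Tm·exp(−ΔH/(Tm·ΔCp)); requires ΔCp > 0, otherwise ΔG(T) is
    monotone and has no interior maximum.
    """
    if p.dcp <= 0:
        raise ValueError("stability maximum requires dcp > 0")
    ts = p.tm * np.exp(-p.dh / (p.tm * p.dcp))
    return float(ts), float(gibbs_helmholtz_dG(ts, p))
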