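"""Chemical (GdmHCl) denaturation followed by tryptophan fluorescence.

Emission spectra (320–380 nm) are reduced to two observables — the spectral
center of mass (SCM) and the intensity ratio I365/I335, both of which
red-shift/rise as buried tryptophans become solvent-exposed — and the
denaturant dependence of both observables is fitted *globally* to the
two-state linear-extrapolation model

    S([D]) = (S_N + m_N·[D])·(1−fU) + (S_U + m_U·[D])·fU
    fU = exp(m_eq·([D]−Cm)/(R·T)) / (1 + exp(m_eq·([D]−Cm)/(R·T)))

with the cooperativity m_eq (kcal·mol⁻¹·M⁻¹) and the half-denaturation
concentration Cm (M) shared between observables.  The unfolding free energy
at zero denaturant is ΔG = m_eq·Cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

from . import io
from .constants import KCAL_TO_CAL, R_CAL, celsius_to_kelvin

__all__ = [
    "EmissionSpectrum",
    "DenaturationSeries",
    "ChemFitResult",
    "spectral_center_of_mass",
    "intensity_ratio",
    "chem_two_state_signal",
    "fraction_unfolded_chem",
    "fit_chem_two_state_global",
    "chem_dG",
    "read_spectrum",
    "write_spectrum",
    "read_series_manifest",
]

#: Default SCM integration window, nm.
SCM_RANGE = (320.0, 380.0)
#: Theoretical m-value for proteins of nanobody size (structure-energetics
#: correlation), used as the optimizer's starting point, kcal·mol⁻¹·M⁻¹.
M_EQ_INIT = 3.3


@dataclass
class EmissionSpectrum:
    """One tryptophan emission trace at a stated (denaturant, temperature)."""

    wavelength: np.ndarray   # nm, strictly increasing
    intensity: np.ndarray    # arbitrary units
    denaturant: float        # GdmHCl molarity, M
    temperature: float       # K

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity must have the same length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if not np.any(self.intensity > 0):
            raise ValueError("spectrum has no positive intensity")
        if self.denaturant < 0:
            raise ValueError("denaturant concentration must be non-negative")


def spectral_center_of_mass(s: EmissionSpectrum,
                            window: tuple[float, float] = SCM_RANGE) -> float:
    """Intensity-weighted mean emission wavelength over ``window``, nm.

    SCM = Σ(I_λ·λ)/Σ(I_λ); red-shifts on unfolding as tryptophans become
    solvent exposed.
    """
    lo, hi = window
    if lo < s.wavelength[0] or hi > s.wavelength[-1]:
        raise ValueError("SCM window outside the measured wavelength range")
    mask = (s.wavelength >= lo) & (s.wavelength <= hi)
    lam, inten = s.wavelength[mask], s.intensity[mask]
    total = inten.sum()
    if total <= 0:
        raise ValueError("undefined SCM: no positive intensity in window")
    return float((inten * lam).sum() / total)


def intensity_ratio(s: EmissionSpectrum, numerator_nm: float = 365.0,
                    denominator_nm: float = 335.0) -> float:
    """Ratio of emission intensities I(365)/I(335) (linear interpolation
    when the wavelengths are off-grid)."""
    for nm in (numerator_nm, denominator_nm):
        if nm < s.wavelength[0] or nm > s.wavelength[-1]:
            raise ValueError(f"wavelength {nm} nm outside measured range")
    i_num = float(np.interp(numerator_nm, s.wavelength, s.intensity))
    i_den = float(np.interp(denominator_nm, s.wavelength, s.intensity))
    if i_den <= 0:
        raise ValueError("undefined ratio: denominator intensity not positive")
    return i_num / i_den


@dataclass
class DenaturationSeries:
    """All observables of one denaturation experiment at one temperature."""

    temperature: float                  # K
    denaturant: np.ndarray              # M, distinct values
    scm: np.ndarray                     # nm
    ratio: np.ndarray                   # I365/I335
    spectra: list[EmissionSpectrum] = field(default_factory=list)

    MIN_POINTS = 8

    def __post_init__(self) -> None:
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.scm = np.asarray(self.scm, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if not (self.denaturant.shape == self.scm.shape == self.ratio.shape):
            raise ValueError("denaturant, scm and ratio must align")
        if self.denaturant.size < self.MIN_POINTS:
            raise ValueError(f"need at least {self.MIN_POINTS} denaturant points")
        if np.unique(self.denaturant).size != self.denaturant.size:
            raise ValueError("denaturant values must be distinct")

    @classmethod
    def from_spectra(cls, spectra: list[EmissionSpectrum]) -> "DenaturationSeries":
        temps = {round(s.temperature, 6) for s in spectra}
        if len(temps) != 1:
            raise ValueError(f"spectra span multiple temperatures: {sorted(temps)}")
        spectra = sorted(spectra, key=lambda s: s.denaturant)
        return cls(
            temperature=spectra[0].temperature,
            denaturant=np.array([s.denaturant for s in spectra]),
            scm=np.array([spectral_center_of_mass(s) for s in spectra]),
            ratio=np.array([intensity_ratio(s) for s in spectra]),
            spectra=spectra,
        )

    def observable_table(self) -> pd.DataFrame:
        return pd.DataFrame({"denaturant": self.denaturant,
                             "scm": self.scm, "ratio": self.ratio})


@dataclass
class ChemFitResult:
    """Globally fitted two-state chemical-denaturation parameters."""

    m_eq: float                 # kcal/mol/M
    cm: float                   # M
    temperature: float          # K
    baselines: dict[str, dict[str, float]]   # observable -> {s_n, m_n, s_u, m_u}
    uncertainties: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def dG(self) -> float:
        """Unfolding free energy at zero denaturant, ΔG = m_eq·Cm, kcal·mol⁻¹."""
        return chem_dG(self.m_eq, self.cm)


def chem_dG(m_eq: float, cm: float) -> float:
    """Linear-extrapolation free energy at zero denaturant, kcal·mol⁻¹."""
    return m_eq * cm


def fraction_unfolded_chem(conc, temperature: float, m_eq: float, cm: float):
    """Unfolded fraction at denaturant concentration ``conc`` (M)."""
    conc = np.asarray(conc, dtype=float)
    x = m_eq * KCAL_TO_CAL * (conc - cm) / (R_CAL * temperature)
    out = 1.0 / (1.0 + np.exp(-x))
    return out if out.ndim else float(out)


def chem_two_state_signal(conc, temperature: float, m_eq: float, cm: float,
                          s_n: float, m_n: float, s_u: float, m_u: float):
    """Two-state observable with linear native/unfolded baselines."""
    conc = np.asarray(conc, dtype=float)
    f = fraction_unfolded_chem(conc, temperature, m_eq, cm)
    out = (s_n + m_n * conc) * (1.0 - f) + (s_u + m_u * conc) * f
    return out if out.ndim else float(out)


def _cm_guess(conc: np.ndarray, signal: np.ndarray) -> float | None:
    """Concentration where the min-max-normalized signal crosses 0.5."""
    lo, hi = signal.min(), signal.max()
    if hi - lo <= 0:
        return None
    norm = (signal - lo) / (hi - lo)
    if signal[-1] < signal[0]:
        norm = 1.0 - norm
    crossings = np.flatnonzero(np.diff(np.sign(norm - 0.5)) != 0)
    if crossings.size == 0:
        return None
    i = int(crossings[0])
    x0, x1 = conc[i], conc[i + 1]
    y0, y1 = norm[i], norm[i + 1]
    return float(x0 + (0.5 - y0) * (x1 - x0) / (y1 - y0))


def fit_chem_two_state_global(series: DenaturationSeries) -> ChemFitResult:
    """Global two-observable fit of the two-state denaturation model.

    {m_eq, Cm} are shared between the SCM and I365/I335 tables; each
    observable gets its own four linear-baseline parameters.  Residuals of
    each observable are divided by the median absolute deviation of that
    observable's values before being combined, so a unitless ratio and an
    nm-scale SCM contribute comparably.

    Raises ``RuntimeError("no transition detected")`` for monotone-flat
    signals; a fitted Cm outside the sampled range is reported with an
    extrapolation warning rather than an error.
    """
    conc = series.denaturant
    observables = {"scm": series.scm, "ratio": series.ratio}
    T = series.temperature

    cm_guesses = [g for g in (_cm_guess(conc, y) for y in observables.values())
                  if g is not None]
    spans = [float(y.max() - y.min()) for y in observables.values()]
    # pure noise has span ≈ 3σ while successive |diffs| have median ≈ 1.3σ;
    # a real transition concentrates its span in a few steps, so span is
    # many times the median step
    noise_floor = [np.median(np.abs(np.diff(y))) for y in observables.values()]
    if not cm_guesses or all(s <= 8 * n for s, n in zip(spans, noise_floor)):
        raise RuntimeError("no transition detected: signals are flat in denaturant")
    cm0 = float(np.mean(cm_guesses))

    weights = {}
    for name, y in observables.items():
        mad = float(np.median(np.abs(y - np.median(y))))
        weights[name] = mad if mad > 0 else float(np.std(y)) or 1.0

    pars = lmfit.Parameters()
    pars.add("m_eq", value=M_EQ_INIT, min=1e-3)
    pars.add("cm", value=cm0, min=1e-6)
    n_quarter = max(conc.size // 4, 2)
    for name, y in observables.items():
        pars.add(f"s_n_{name}", value=float(y[:n_quarter].mean()))
        pars.add(f"m_n_{name}", value=0.0)
        pars.add(f"s_u_{name}", value=float(y[-n_quarter:].mean()))
        pars.add(f"m_u_{name}", value=0.0)

    def residual(p):
        res = []
        for name, y in observables.items():
            model = chem_two_state_signal(
                conc, T, p["m_eq"].value, p["cm"].value,
                p[f"s_n_{name}"].value, p[f"m_n_{name}"].value,
                p[f"s_u_{name}"].value, p[f"m_u_{name}"].value)
            res.append((model - y) / weights[name])
        return np.concatenate(res)

    result = lmfit.minimize(residual, pars, method="leastsq")
    if not result.success:
        raise RuntimeError("global chemical-denaturation fit did not converge")

    notes: list[str] = []
    cm_fit = result.params["cm"].value
    if not (conc.min() <= cm_fit <= conc.max()):
        notes.append(f"extrapolation: fitted Cm = {cm_fit:.3f} M outside the "
                     f"sampled range [{conc.min():.2f}, {conc.max():.2f}] M")

    baselines = {name: {k: result.params[f"{k}_{name}"].value
                        for k in ("s_n", "m_n", "s_u", "m_u")}
                 for name in observables}
    unc = {n: (result.params[n].stderr if result.params[n].stderr is not None
               else float("nan"))
           for n in result.params}
    return ChemFitResult(
        m_eq=result.params["m_eq"].value, cm=cm_fit, temperature=T,
        baselines=baselines, uncertainties=unc, warnings=notes)


# ---------------------------------------------------------------------------
# I/O

def read_spectrum(path) -> EmissionSpectrum:
    """Read one spectrum CSV (columns ``wavelength``, ``intensity``).

    Header keys: ``denaturant_M`` and ``temperature`` plus
    ``temperature_unit`` (C|K, default C).
    """
    df, meta = io.read_table(path)
    io.require_columns(df, ["wavelength", "intensity"], path)
    df = io.coerce_numeric(df, ["wavelength", "intensity"], path)
    if "denaturant_M" not in meta or "temperature" not in meta:
        raise io.FormatError(f"{path}: header must declare denaturant_M and temperature")
    temp = float(meta["temperature"])
    if meta.get("temperature_unit", "C").upper() == "C":
        temp = float(celsius_to_kelvin(temp))
    return EmissionSpectrum(
        wavelength=df["wavelength"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        denaturant=float(meta["denaturant_M"]),
        temperature=temp)


def write_spectrum(path, s: EmissionSpectrum) -> None:
    meta = {"denaturant_M": s.denaturant, "temperature": s.temperature,
            "temperature_unit": "K"}
    io.write_table(path, pd.DataFrame({"wavelength": s.wavelength,
                                       "intensity": s.intensity}), meta)


def read_series_manifest(path) -> DenaturationSeries:
    """Read a manifest (one spectrum-file path per line, relative to the
    manifest's directory) and build the denaturation series."""
    path = Path(path)
    entries = [line.strip() for line in path.read_text().splitlines()
               if line.strip() and not line.startswith("#")]
    if not entries:
        raise io.FormatError(f"{path}: empty manifest")
    spectra = [read_spectrum(path.parent / entry) for entry in entries]
    return DenaturationSeries.from_spectra(spectra)
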