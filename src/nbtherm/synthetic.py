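"""Synthetic-data generator with known ground truth.

Every input the pipeline consumes can be generated here from a
:class:`GroundTruth` bundle of generating parameters, so parameter
recovery can be tested end to end: DSC upscans and rescans (two-state
excess heat capacity on a linear native baseline, partial rescan
reversibility, Gaussian noise), tryptophan emission-spectrum series on a
GdmHCl grid, Kirchhoff (Tm, ΔHcal) points under mild destabilization, and
the expected ΔG(T) points of the generating stability curve.

Emission templates
------------------
The native and unfolded template spectra are skew-normal emission bands
(exact shape is arbitrary — only the derived sigmoids matter to the fits).
The unfolded template is built as a red band plus a narrow 335 nm
component, scaled so that both templates share the same total intensity
and the same intensity at 335 nm.  Mixed linearly by the unfolded
fraction, both derived observables (SCM and I365/I335) are then *exactly*
linear in that fraction, i.e. the generated observables follow the
two-state denaturation model exactly up to noise — without those
constraints each observable would follow a sigmoid with an apparent Cm
shifted by −R·T·ln(c)/m_eq, where c is the templates' intensity ratio at
the relevant wavelengths.

Determinism: every generator draws from a stream derived from
``GroundTruth.seed`` plus a fixed per-product label, so regenerating from
the same ground truth is bit-reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.special import erf

from .chemdenat import (
    DenaturationSeries,
    EmissionSpectrum,
    fraction_unfolded_chem,
    write_spectrum,
)
from .datasets import VARIANTS
from .dsc import Thermogram, write_thermogram
from .models import (
    GibbsHelmholtzParams,
    TwoStateThermalParams,
    excess_heat_capacity,
    gibbs_helmholtz_dG,
)
from .stability import DGPoint, KirchhoffPoint

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "default_ground_truth",
    "validate_ground_truth",
    "emission_templates",
    "gen_dsc_scan",
    "gen_emission_spectra",
    "gen_kirchhoff_points",
    "gen_stability_dataset",
    "StabilityDataset",
    "write_bundle",
    "save_ground_truth",
    "load_ground_truth",
]

#: Canonical emission wavelength grid, nm (excitation 295 nm).
WAVELENGTH_GRID = np.arange(320.0, 380.0 + 1e-9, 0.5)

# Frozen template-band parameters (center nm, width nm, skewness).
_NATIVE_BAND = (330.0, 9.0, 1.0)
_UNFOLDED_RED_BAND = (362.0, 11.0, 0.0)
_UNFOLDED_PIN_BAND = (335.0, 1.5, 0.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Per-channel noise scales (all Gaussian, additive).

    ``cp_frac_of_peak``: heat-capacity noise as a fraction of the upscan
    excess-Cp peak height.  ``fluor_frac_of_max``: fluorescence noise as a
    fraction of the series' maximum intensity.  ``dh_cal_sigma``: scatter
    of Kirchhoff ΔHcal values, kcal·mol⁻¹.
    """

    cp_frac_of_peak: float = 0.01
    fluor_frac_of_max: float = 0.01
    dh_cal_sigma: float = 1.0


@dataclass
class GroundTruth:
    """Complete generating parameter set for one synthetic protein."""

    thermal: TwoStateThermalParams
    chem_per_T: dict[float, tuple[float, float]]   # T (K) -> (m_eq, cm)
    gh: GibbsHelmholtzParams
    reversibility_fraction: float
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.reversibility_fraction <= 1.0:
            raise ValueError("reversibility_fraction must lie in [0, 1]")


def _rng(gt: GroundTruth, label: str) -> np.random.Generator:
    """Deterministic per-product stream derived from the ground-truth seed."""
    return np.random.default_rng([gt.seed, zlib.crc32(label.encode())])


def default_ground_truth(variant: str = "NB-AGT-2", seed: int = 0,
                         chem_temps_celsius: tuple[float, ...] = (18, 25, 32, 39, 46),
                         noise: NoiseSpec | None = None) -> GroundTruth:
    """Ground truth emulating one of the characterized nanobody variants.

    The stability curve uses the variant's published ΔCp and the Van't
    Hoff enthalpy at Tm, which makes the thermal ΔG route (−RT·ln K with
    ΔHVH) and the chemical route lie on the same generating curve; the
    half-denaturation concentrations are placed on that curve via
    Cm(T) = ΔG(T)/m_eq.
    """
    v = VARIANTS[variant]
    thermal = TwoStateThermalParams(
        tm=v.tm_kelvin, dh_cal=v.dh_cal, dh_vh=v.dh_vh,
        baseline_a=1.5, baseline_b=0.005)
    gh = GibbsHelmholtzParams(tm=v.tm_kelvin, dh=v.dh_vh, dcp=v.gh_dcp)
    chem: dict[float, tuple[float, float]] = {}
    for t_c in chem_temps_celsius:
        T = t_c + 273.15
        dg = float(gibbs_helmholtz_dG(T, gh))
        if dg <= 0:
            raise ValueError(f"generating curve not stable at {t_c} °C")
        chem[round(T, 6)] = (v.m_eq, dg / v.m_eq)
    return GroundTruth(thermal=thermal, chem_per_T=chem, gh=gh,
                       reversibility_fraction=v.reversibility_pct / 100.0,
                       noise=noise or NoiseSpec(), seed=seed, name=variant)


def validate_ground_truth(gt: GroundTruth, tol: float = 0.05) -> None:
    """Check internal consistency: every m_eq·Cm must lie on the generating
    stability curve within ``tol`` kcal·mol⁻¹.  Raises listing violators."""
    bad = []
    for T, (m_eq, cm) in gt.chem_per_T.items():
        expected = float(gibbs_helmholtz_dG(T, gt.gh))
        if abs(m_eq * cm - expected) > tol:
            bad.append(f"T={T:.2f} K: m_eq*Cm={m_eq * cm:.3f} vs curve {expected:.3f}")
    if bad:
        raise ValueError("ground truth inconsistent with its stability curve: "
                         + "; ".join(bad))


# ---------------------------------------------------------------------------
# DSC

def gen_dsc_scan(gt: GroundTruth, grid: np.ndarray | None = None,
                 rate: float = 2.0, kind: str = "upscan",
                 condition_label: str = "") -> Thermogram:
    """Simulated thermogram: native baseline + two-state excess Cp + noise.

    Rescans scale the excess term by the ground truth's reversibility
    fraction.  Noise σ is ``cp_frac_of_peak`` of the *upscan* peak height
    for both scan kinds (instrument noise does not shrink with the signal).
    """
    p = gt.thermal
    if grid is None:
        grid = np.arange(293.15, p.tm + 30.0 + 0.05, 0.1)
    grid = np.asarray(grid, dtype=float)
    if grid[0] > p.tm - 5.0 or grid[-1] < p.tm + 5.0:
        raise ValueError("temperature grid too short: transition not spanned")
    excess = np.asarray(excess_heat_capacity(grid, p))
    scale = gt.reversibility_fraction if kind == "rescan" else 1.0
    sigma = gt.noise.cp_frac_of_peak * float(excess.max())
    noise = _rng(gt, f"dsc:{kind}:{rate}:{condition_label}").normal(0.0, sigma, grid.size) \
        if sigma > 0 else 0.0
    cp = p.baseline_a + p.baseline_b * grid + scale * excess + noise
    return Thermogram(temperature=grid, cp_app=cp, scan_rate=rate,
                      scan_kind=kind, condition_label=condition_label)


# ---------------------------------------------------------------------------
# Fluorescence

def emission_templates(wavelength: np.ndarray = WAVELENGTH_GRID,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Native and unfolded template spectra on ``wavelength``.

    Scaled such that both share total integrated intensity and intensity
    at 335 nm (see module docstring); SCMs land near 335 and 355 nm.
    """
    lam = np.asarray(wavelength, dtype=float)

    def band(c, w, a):
        z = (lam - c) / w
        return np.exp(-0.5 * z**2) * (1.0 + erf(a * z / np.sqrt(2.0)))

    native = band(*_NATIVE_BAND)
    red = band(*_UNFOLDED_RED_BAND)
    pin = band(*_UNFOLDED_PIN_BAND)

    def at335(I):
        return float(np.interp(335.0, lam, I))

    coeffs = np.linalg.solve(
        np.array([[red.sum(), pin.sum()], [at335(red), at335(pin)]]),
        np.array([native.sum(), at335(native)]))
    unfolded = coeffs[0] * red + coeffs[1] * pin
    if np.any(unfolded < 0):
        raise RuntimeError("unfolded template not positive on this grid")
    return native, unfolded


def gen_emission_spectra(gt: GroundTruth, temperature: float,
                         denaturant_grid: np.ndarray | None = None,
                         amplitude_drift_per_M: float = -0.02,
                         intensity_scale: float = 100.0) -> DenaturationSeries:
    """Simulated emission-spectrum series at one temperature.

    Templates are mixed by the two-state unfolded fraction; the whole
    spectrum carries a linear amplitude drift in denaturant (which leaves
    both intensity-ratio observables untouched), and seeded Gaussian noise
    is added per wavelength point.
    """
    m_eq, cm = chem_params_at(gt, temperature)
    if denaturant_grid is None:
        denaturant_grid = np.linspace(0.0, 6.0, 13)
    denaturant_grid = np.asarray(denaturant_grid, dtype=float)
    if not (denaturant_grid.min() < cm < denaturant_grid.max()):
        warnings.warn(f"Cm = {cm:.2f} M outside the denaturant grid "
                      f"[{denaturant_grid.min():.2f}, {denaturant_grid.max():.2f}] M; "
                      "transition not spanned", stacklevel=2)
    native, unfolded = emission_templates()
    f = np.asarray(fraction_unfolded_chem(denaturant_grid, temperature, m_eq, cm))
    clean = [(1.0 + amplitude_drift_per_M * d) * intensity_scale
             * ((1.0 - fi) * native + fi * unfolded)
             for d, fi in zip(denaturant_grid, f)]
    sigma = gt.noise.fluor_frac_of_max * max(spec.max() for spec in clean)
    rng = _rng(gt, f"fluor:T={temperature:.4f}")
    spectra = []
    for d, spec in zip(denaturant_grid, clean):
        noisy = spec + (rng.normal(0.0, sigma, spec.size) if sigma > 0 else 0.0)
        spectra.append(EmissionSpectrum(
            wavelength=WAVELENGTH_GRID.copy(), intensity=np.clip(noisy, 1e-9, None),
            denaturant=float(d), temperature=float(temperature)))
    return DenaturationSeries.from_spectra(spectra)


def chem_params_at(gt: GroundTruth, temperature: float) -> tuple[float, float]:
    """Look up (m_eq, Cm) for a temperature in the ground truth."""
    for T, pair in gt.chem_per_T.items():
        if abs(T - temperature) < 1e-6:
            return pair
    raise KeyError(f"no chemical parameters at T = {temperature} K; "
                   f"available: {sorted(gt.chem_per_T)}")


# ---------------------------------------------------------------------------
# Kirchhoff points and the full bundle

def gen_kirchhoff_points(gt: GroundTruth,
                         denaturants: np.ndarray | None = None,
                         tm_shift_per_M: float = 6.0) -> list[KirchhoffPoint]:
    """(Tm, ΔHcal) pairs under low GdmHCl.

    The melting temperature decreases linearly with denaturant and ΔHcal
    follows the generating stability curve's ΔCp (Kirchhoff relation
    dΔH/dTm = ΔCp), plus Gaussian scatter on ΔHcal — so the Kirchhoff
    regression and the Gibbs–Helmholtz fit estimate the same quantity.
    """
    if denaturants is None:
        denaturants = np.linspace(0.0, 0.9, 10)
    denaturants = np.asarray(denaturants, dtype=float)
    rng = _rng(gt, "kirchhoff")
    p, dcp = gt.thermal, gt.gh.dcp
    pts = []
    for d in denaturants:
        tm_i = p.tm - tm_shift_per_M * d
        dh_i = p.dh_cal + dcp * (tm_i - p.tm) + rng.normal(0.0, gt.noise.dh_cal_sigma)
        pts.append(KirchhoffPoint(tm=float(tm_i), dh_cal=float(dh_i),
                                  denaturant=float(d), variant=gt.name))
    return pts


@dataclass
class StabilityDataset:
    """End-to-end synthetic bundle produced by :func:`gen_stability_dataset`."""

    ground_truth: GroundTruth
    upscan: Thermogram
    rescan: Thermogram
    series: list[DenaturationSeries]
    kirchhoff: list[KirchhoffPoint]
    expected_dg: list[DGPoint]


def gen_stability_dataset(gt: GroundTruth,
                          chem_temps: list[float] | None = None) -> StabilityDataset:
    """Generate the complete input bundle for one synthetic protein.

    Validates the ground truth's internal consistency first; the expected
    ΔG points are the chemical temperatures evaluated through the
    generating stability curve plus the (Tm, 0) anchor.
    """
    validate_ground_truth(gt)
    if chem_temps is None:
        chem_temps = sorted(gt.chem_per_T)
    series = [gen_emission_spectra(gt, T) for T in chem_temps]
    expected = [DGPoint(T=T, dG=float(gibbs_helmholtz_dG(T, gt.gh)), source="chemical")
                for T in chem_temps]
    expected.append(DGPoint(T=gt.gh.tm, dG=0.0, source="dsc"))
    return StabilityDataset(
        ground_truth=gt,
        upscan=gen_dsc_scan(gt, kind="upscan"),
        rescan=gen_dsc_scan(gt, kind="rescan"),
        series=series,
        kirchhoff=gen_kirchhoff_points(gt),
        expected_dg=expected,
    )


# ---------------------------------------------------------------------------
# Serialization

def save_ground_truth(path, gt: GroundTruth) -> None:
    """Serialize a ground truth to a YAML sidecar."""
    doc = {
        "name": gt.name,
        "seed": int(gt.seed),
        "reversibility_fraction": float(gt.reversibility_fraction),
        "thermal": asdict(gt.thermal),
        "gh": asdict(gt.gh),
        "chem_per_T": [{"T": float(T), "m_eq": float(m), "cm": float(c)}
                       for T, (m, c) in sorted(gt.chem_per_T.items())],
        "noise": asdict(gt.noise),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_ground_truth(path) -> GroundTruth:
    doc = yaml.safe_load(Path(path).read_text())
    return GroundTruth(
        thermal=TwoStateThermalParams(**doc["thermal"]),
        chem_per_T={row["T"]: (row["m_eq"], row["cm"]) for row in doc["chem_per_T"]},
        gh=GibbsHelmholtzParams(**doc["gh"]),
        reversibility_fraction=doc["reversibility_fraction"],
        noise=NoiseSpec(**doc["noise"]),
        seed=doc["seed"],
        name=doc["name"],
    )


def write_bundle(dataset: StabilityDataset, directory) -> Path:
    """Write a dataset to disk in the dialects the readers consume.

    Layout: ``dsc/upscan.csv``, ``dsc/rescan.csv``, one
    ``chem/T<kelvin>/`` directory per temperature (spectra plus a series
    manifest), ``kirchhoff.csv``, ``expected_dg.csv``,
    ``ground_truth.yaml`` and a top-level ``manifest.yaml``.
    """
    import pandas as pd  # local import keeps module load light

    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"name": dataset.ground_truth.name}

    write_thermogram(root / "dsc" / "upscan.csv", dataset.upscan)
    write_thermogram(root / "dsc" / "rescan.csv", dataset.rescan)
    manifest["dsc"] = {"upscan": "dsc/upscan.csv", "rescan": "dsc/rescan.csv"}

    chem_manifests = []
    for series in dataset.series:
        tdir = root / "chem" / f"T{series.temperature:.2f}"
        tdir.mkdir(parents=True, exist_ok=True)
        names = []
        for i, spec in enumerate(series.spectra):
            name = f"spectrum_{i:02d}.csv"
            write_spectrum(tdir / name, spec)
            names.append(name)
        (tdir / "manifest.txt").write_text("\n".join(names) + "\n")
        chem_manifests.append(str((tdir / "manifest.txt").relative_to(root)))
    manifest["chem_manifests"] = chem_manifests

    from . import io
    io.write_table(root / "kirchhoff.csv", pd.DataFrame(
        [{"tm": p.tm, "dh_cal": p.dh_cal, "denaturant": p.denaturant,
          "variant": p.variant} for p in dataset.kirchhoff]))
    io.write_table(root / "expected_dg.csv", pd.DataFrame(
        [{"T": p.T, "dG": p.dG, "source": p.source} for p in dataset.expected_dg]))
    manifest["kirchhoff"] = "kirchhoff.csv"
    manifest["expected_dg"] = "expected_dg.csv"

    save_ground_truth(root / "ground_truth.yaml", dataset.ground_truth)
    manifest["ground_truth"] = "ground_truth.yaml"
    (root / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return root
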