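"""Pipeline orchestration: config-driven runs and the consolidated report.

A run executes DSC fitting → chemical-denaturation fitting → stability
analysis (optionally generating a synthetic bundle first) and writes a
per-variant report: Tm (°C and K), ΔHcal, ΔHVH, their ratio,
reversibility %, per-temperature (m_eq, Cm, ΔG), the pooled Kirchhoff
ΔCp, and the stability-curve parameters with r².  Every tolerance and
threshold in effect is echoed into the report for provenance, along with
library versions, the config hash and the seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemdenat, dsc, io, stability, synthetic

log = logging.getLogger("nbtherm")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """Validated run configuration; paths are resolved against the config
    file's directory."""

    output_dir: Path
    seed: int = 0
    generate: dict | None = None          # {variant, chem_temps_celsius}
    dsc_inputs: dict | None = None        # {upscan, rescan?, extra_rates?: [paths]}
    chem_manifests: list[Path] = field(default_factory=list)
    kirchhoff_table: Path | None = None
    enthalpy_for_dg: str = "vh"
    population_bounds: tuple[float, float] = (0.05, 0.95)
    curve_modes: tuple[str, ...] = ("float_dh_dcp", "fixed_dh_float_dcp")
    report_temps_celsius: tuple[float, ...] = (4.0, 25.0, 37.0)
    base_dir: Path = Path(".")

    def resolve(self, p) -> Path:
        p = Path(p)
        return p if p.is_absolute() else (self.base_dir / p).absolute()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {"output_dir", "seed", "generate", "dsc", "chem", "kirchhoff",
             "stability", "report"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config section(s) {sorted(unknown)}")
    if "output_dir" not in doc:
        raise ConfigError(f"{path}: output_dir is required")

    stab = doc.get("stability", {}) or {}
    bounds = tuple(stab.get("population_bounds", (0.05, 0.95)))
    if not (0 < bounds[0] < bounds[1] < 1):
        raise ConfigError("stability.population_bounds must satisfy 0 < lo < hi < 1")
    cfg = RunConfig(
        output_dir=Path(doc["output_dir"]),
        seed=int(doc.get("seed", 0)),
        generate=doc.get("generate"),
        dsc_inputs=doc.get("dsc"),
        chem_manifests=[Path(p) for p in (doc.get("chem", {}) or {}).get("manifests", [])],
        kirchhoff_table=Path(doc["kirchhoff"]) if doc.get("kirchhoff") else None,
        enthalpy_for_dg=stab.get("enthalpy", "vh"),
        population_bounds=bounds,
        curve_modes=tuple(stab.get("modes", ("float_dh_dcp", "fixed_dh_float_dcp"))),
        report_temps_celsius=tuple((doc.get("report", {}) or {})
                                   .get("temps_celsius", (4.0, 25.0, 37.0))),
        base_dir=path.parent,
    )
    if cfg.enthalpy_for_dg not in ("vh", "cal"):
        raise ConfigError("stability.enthalpy must be 'vh' or 'cal'")
    for mode in cfg.curve_modes:
        if mode not in stability.MODES:
            raise ConfigError(f"unknown stability mode {mode!r}")
    if cfg.generate is None and cfg.dsc_inputs is None and not cfg.chem_manifests:
        raise ConfigError(f"{path}: nothing to do — provide generate, dsc or chem inputs")
    return cfg


@dataclass
class PipelineResult:
    """Everything a run computed, plus the on-disk report location."""

    thermal_fit: dsc.ThermalFitResult | None
    reversibility: dsc.ReversibilityResult | None
    chem_fits: list[chemdenat.ChemFitResult]
    dcp_kirchhoff: stability.DcpEstimate | None
    curve_fits: dict[str, stability.StabilityCurveFit]
    report_path: Path


def _read_kirchhoff(path) -> list[stability.KirchhoffPoint]:
    df, _ = io.read_table(path)
    io.require_columns(df, ["tm", "dh_cal"], path)
    df = io.coerce_numeric(df, ["tm", "dh_cal"], path)
    return [stability.KirchhoffPoint(
        tm=row.tm, dh_cal=row.dh_cal,
        denaturant=float(getattr(row, "denaturant", 0.0)),
        variant=str(getattr(row, "variant", "")))
        for row in df.itertuples()]


def _library_versions() -> dict[str, str]:
    import lmfit
    import scipy
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "lmfit": lmfit.__version__}


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the configured stages and write the consolidated report.

    Synthetic generation (when requested) happens first and its outputs
    feed the same readers real data would.  Stage failures raise; partial
    outputs written before the failure are retained with a failure marker.
    """
    out = cfg.resolve(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("library versions: %s", _library_versions())
    log.info("seed: %d", cfg.seed)

    dsc_inputs = cfg.dsc_inputs
    chem_manifests = list(cfg.chem_manifests)
    kirchhoff_path = cfg.kirchhoff_table
    variant_name = "sample"

    if cfg.generate is not None:
        variant_name = cfg.generate.get("variant", "NB-AGT-2")
        temps = tuple(cfg.generate.get("chem_temps_celsius", (18, 25, 32, 39, 46)))
        gt = synthetic.default_ground_truth(variant=variant_name, seed=cfg.seed,
                                            chem_temps_celsius=temps)
        bundle_dir = synthetic.write_bundle(
            synthetic.gen_stability_dataset(gt), out / "synthetic")
        log.info("synthetic bundle written to %s", bundle_dir)
        dsc_inputs = {"upscan": bundle_dir / "dsc" / "upscan.csv",
                      "rescan": bundle_dir / "dsc" / "rescan.csv"}
        chem_manifests = [bundle_dir / m
                          for m in yaml.safe_load((bundle_dir / "manifest.yaml")
                                                  .read_text())["chem_manifests"]]
        kirchhoff_path = bundle_dir / "kirchhoff.csv"

    marker = out / "FAILED"
    try:
        thermal_fit = rev = None
        if dsc_inputs:
            upscan = dsc.read_thermogram(cfg.resolve(dsc_inputs["upscan"]))
            thermal_fit = dsc.fit_thermal_two_state(upscan)
            if dsc_inputs.get("rescan"):
                rescan = dsc.read_thermogram(cfg.resolve(dsc_inputs["rescan"]))
                rev = dsc.reversibility(upscan, rescan)

        chem_fits = []
        for manifest in chem_manifests:
            series = chemdenat.read_series_manifest(cfg.resolve(manifest))
            chem_fits.append(chemdenat.fit_chem_two_state_global(series))

        dcp_est = None
        if kirchhoff_path is not None:
            dcp_est = stability.estimate_dcp_kirchhoff(
                _read_kirchhoff(cfg.resolve(kirchhoff_path)))

        curve_fits: dict[str, stability.StabilityCurveFit] = {}
        if thermal_fit is not None and len(chem_fits) >= 2:
            points = stability.assemble_dg_points(
                thermal_fit, chem_fits, bounds=cfg.population_bounds,
                enthalpy=cfg.enthalpy_for_dg)
            pd.DataFrame([{"T": p.T, "dG": p.dG, "source": p.source}
                          for p in points]).to_csv(out / "dg_points.csv", index=False)
            for mode in cfg.curve_modes:
                curve_fits[mode] = stability.fit_stability_curve(
                    points, tm=thermal_fit.params.tm, mode=mode,
                    dh=thermal_fit.params.dh_cal)
    except Exception as exc:
        marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    if marker.exists():
        marker.unlink()

    report_path = _write_report(out, cfg, variant_name, thermal_fit, rev,
                                chem_fits, dcp_est, curve_fits)
    return PipelineResult(thermal_fit=thermal_fit, reversibility=rev,
                          chem_fits=chem_fits, dcp_kirchhoff=dcp_est,
                          curve_fits=curve_fits, report_path=report_path)


def _write_report(out: Path, cfg: RunConfig, variant: str,
                  thermal, rev, chem_fits, dcp_est, curve_fits) -> Path:
    """Flat key-value report plus per-temperature and predicted-curve CSVs."""
    lines = [f"variant: {variant}", f"seed: {cfg.seed}"]
    for lib, ver in _library_versions().items():
        lines.append(f"version_{lib}: {ver}")
    lines += [f"population_bounds: {cfg.population_bounds[0]}-{cfg.population_bounds[1]}",
              f"enthalpy_for_dg: {cfg.enthalpy_for_dg}"]

    def absent(key, reason):
        lines.append(f"{key}: absent ({reason})")

    if thermal is not None:
        p = thermal.params
        lines += [
            f"tm_K: {p.tm:.2f}", f"tm_C: {p.tm - 273.15:.2f}",
            f"dh_cal_kcal_mol: {p.dh_cal:.1f}", f"dh_vh_kcal_mol: {p.dh_vh:.1f}",
            f"ratio_cal_vh: {p.ratio_cal_vh:.2f}",
            f"fit_window_K: {thermal.fit_window[0]:.2f}-{thermal.fit_window[1]:.2f}",
            f"residual_norm: {thermal.residual_norm:.4g}",
        ]
    else:
        absent("tm_K", "no DSC input")
    if rev is not None:
        lines.append(f"reversibility_pct: {rev.percent:.1f}")
    else:
        absent("reversibility_pct", "no rescan input")

    if chem_fits:
        rows = [{"T_K": f.temperature, "T_C": f.temperature - 273.15,
                 "m_eq": f.m_eq, "cm": f.cm, "dG": f.dG} for f in chem_fits]
        pd.DataFrame(rows).to_csv(out / "chem_fits.csv", index=False)
        m = np.array([f.m_eq for f in chem_fits])
        lines.append(f"m_eq_mean_kcal_mol_M: {m.mean():.2f}")
        lines.append(f"m_eq_sd_kcal_mol_M: {m.std(ddof=1) if m.size > 1 else 0.0:.2f}")
    else:
        absent("m_eq_mean_kcal_mol_M", "no chemical-denaturation input")

    if dcp_est is not None:
        lines.append(f"dcp_kirchhoff_kcal_mol_K: {dcp_est.dcp:.2f} +/- {dcp_est.se:.2f}")
    else:
        absent("dcp_kirchhoff_kcal_mol_K", "no Kirchhoff table")

    for mode, fit in curve_fits.items():
        tag = f"curve_{mode}"
        lines += [
            f"{tag}_dh_kcal_mol: {fit.params.dh:.1f}",
            f"{tag}_dcp_kcal_mol_K: {fit.params.dcp:.2f} +/- {fit.uncertainties['dcp']:.2f}",
            f"{tag}_r_squared: {fit.r_squared:.4f}",
        ]
        if fit.dcp_not_identifiable:
            lines.append(f"{tag}_flag: dCp not identifiable (SE exceeds |dCp|)")
        T_grid = np.linspace(273.15, fit.params.tm + 10, 200)
        from .models import gibbs_helmholtz_dG
        pd.DataFrame({"T": T_grid, "dG": gibbs_helmholtz_dG(T_grid, fit.params)}
                     ).to_csv(out / f"{tag}_predicted.csv", index=False)
        summary = stability.stability_summary(
            fit, report_temps_celsius=cfg.report_temps_celsius)
        summary.to_csv(out / f"{tag}_summary.csv", index=False)
    if not curve_fits:
        absent("curve_float_dh_dcp_dcp_kcal_mol_K",
               "needs a DSC fit plus >= 2 chemical temperatures")

    path = out / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    log.info("report written to %s", path)
    return path


def config_hash(path) -> str:
    """SHA-256 of the raw config file, for provenance logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
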