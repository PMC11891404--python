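"""Reference parameter sets for the anti-AGT nanobody variants.

Published equilibrium thermal-denaturation parameters (DSC, 2 K·min⁻¹ scans,
pH 7.4 phosphate buffer) for three nanobodies raised against alanine:
glyoxylate aminotransferase, together with the chemical-denaturation
m-values and stability-curve parameters determined for them.  These serve
as ground-truth templates for the synthetic-data generator and as the
arithmetic cross-checks of the unit conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["VariantParams", "VARIANTS"]


@dataclass(frozen=True)
class VariantParams:
    """Published thermodynamic parameters for one nanobody variant."""

    name: str
    tm_celsius: float
    tm_kelvin: float
    dh_cal: float            # kcal/mol
    dh_vh: float             # kcal/mol
    ratio_cal_vh: float      # ΔHcal/ΔHVH as printed (2 decimals)
    reversibility_pct: float
    m_eq: float              # kcal/mol/M, mean over 18-46 °C
    # Gibbs-Helmholtz fit with Tm fixed, ΔH and ΔCp floating:
    gh_dh: float             # kcal/mol
    gh_dcp: float            # kcal/mol/K


VARIANTS: dict[str, VariantParams] = {
    "NB-AGT-1": VariantParams(
        name="NB-AGT-1", tm_celsius=70.65, tm_kelvin=343.80,
        dh_cal=83.3, dh_vh=92.3, ratio_cal_vh=0.90, reversibility_pct=47.0,
        m_eq=3.1, gh_dh=73.4, gh_dcp=0.52,
    ),
    "NB-AGT-2": VariantParams(
        name="NB-AGT-2", tm_celsius=85.42, tm_kelvin=358.57,
        dh_cal=87.4, dh_vh=105.9, ratio_cal_vh=0.82, reversibility_pct=52.0,
        m_eq=4.4, gh_dh=151.3, gh_dcp=1.49,
    ),
    "NB-AGT-6": VariantParams(
        name="NB-AGT-6", tm_celsius=71.68, tm_kelvin=344.83,
        dh_cal=77.1, dh_vh=94.1, ratio_cal_vh=0.82, reversibility_pct=50.0,
        m_eq=4.1, gh_dh=103.3, gh_dcp=1.45,
    ),
}
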