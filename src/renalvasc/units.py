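"""Unit conversions for the canonical internal unit system (μm, s, N).

All geometry is carried in micrometres, time in seconds and force in
newtons, so that the material cost ``w_c π r² l`` and the power cost
``Q² 8μl/(πr⁴)`` both come out in N μm s⁻¹ (i.e. μW) without any hidden
scale factors.  Everything that crosses the package boundary in
physiological units (ml/min, Pa·s, mmHg, ...) goes through this module.
"""

from __future__ import annotations

#: μm³ in one millilitre (1 ml = 1 cm³ = (10⁴ μm)³).
UM3_PER_ML = 1.0e12

#: Pa expressed in internal pressure units: 1 Pa = 1 N/m² = 1e-12 N/μm².
N_PER_UM2_PER_PA = 1.0e-12

#: One conventional millimetre of mercury in pascal.
PA_PER_MMHG = 133.322

#: One mmHg in internal pressure units (N μm⁻²).
N_PER_UM2_PER_MMHG = PA_PER_MMHG * N_PER_UM2_PER_PA


def ml_per_min_to_um3_per_s(q: float) -> float:
    """Volumetric flow, ml/min → μm³/s (7 ml/min ≈ 1.167e11 μm³/s)."""
    return q * UM3_PER_ML / 60.0


def pa_s_to_n_s_per_um2(mu: float) -> float:
    """Dynamic viscosity, Pa·s → N s μm⁻² (3.6e-3 Pa·s → 3.6e-15)."""
    return mu * N_PER_UM2_PER_PA


def j_per_s_m3_to_n_per_um2_s(w: float) -> float:
    """Volumetric power density, J s⁻¹ m⁻³ → N μm⁻² s⁻¹.

    Used for the material-cost weight: 5e4 J s⁻¹ m⁻³ → 5e-8 N μm⁻² s⁻¹.
    """
    # J/m³ = N·m/m³ = N/m²; then N/m² → N/μm².
    return w * N_PER_UM2_PER_PA


def mmhg_to_n_per_um2(p: float) -> float:
    """Pressure, mmHg → internal N μm⁻²."""
    return p * N_PER_UM2_PER_MMHG


def n_per_um2_to_mmhg(p: float) -> float:
    """Pressure, internal N μm⁻² → mmHg."""
    return p / N_PER_UM2_PER_MMHG


def um3_per_s_to_nl_per_s(q: float) -> float:
    """Volumetric flow, μm³/s → nl/s (1 nl = 10⁶ μm³)."""
    return q / 1.0e6
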