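"""Physical transport coefficients from fitted correlation slopes.

Two exact routes to the electrical conductivity are implemented -- the
mean-square-dipole-displacement slope and the charge-weighted sum of
Onsager coefficients -- together with the approximate Nernst-Einstein (NE)
expression, the Yeh-Hummer hydrodynamic finite-size correction for
self-diffusion in a periodic box, and the empirical 0.7 rule that maps an
NE+YH conductivity onto a rough estimate of the exact one.

Sign conventions: ion-ion anticorrelation (pairing) makes the cation-anion
cross term negative, so the exact conductivity falls below the NE value;
NE never underestimates for physically paired systems.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    BOLTZMANN_J_PER_K,
    E2NM2_PER_PS_TO_SI,
    ELEMENTARY_CHARGE_C,
    NM2_PER_PS_TO_M2_PER_S,
    NM_IN_M,
    CorrelationSeries,
    OnsagerMatrix,
    SystemComposition,
    ThermoState,
    TransportEstimate,
    logger,
)
from .stats import fit_linear_slope

#: dimensionless hydrodynamic self-interaction constant of a cubic lattice
#: of point forces, used in the periodic-box diffusion correction
XI_YEH_HUMMER = 2.837

#: the paper-protocol default window for dipole-displacement fits (ps)
DEFAULT_FIT_WINDOW = (50.0, 1000.0)

#: empirical exact-to-NE conductivity ratio behind the rough estimate rule
NE_TO_EH_RATIO = 0.7


def _check_thermo(thermo: ThermoState) -> None:
    if thermo.volume <= 0 or thermo.temperature <= 0:
        raise ValueError("volume and temperature must be positive")


def conductivity_eh(dipole_msd: CorrelationSeries, thermo: ThermoState,
                    window: tuple = DEFAULT_FIT_WINDOW) -> TransportEstimate:
    """Conductivity from the mean-square dipole displacement slope.

    sigma = slope / (6 V k_B T), with the slope fitted by unweighted OLS
    over ``window`` (ps) on a series in e^2 nm^2.  Result in S/m.
    """
    _check_thermo(thermo)
    fit = fit_linear_slope(dipole_msd, *window)
    denom = 6.0 * thermo.volume_m3 * thermo.kt_joule
    scale = E2NM2_PER_PS_TO_SI / denom
    est = TransportEstimate(
        value=fit.slope * scale,
        uncertainty=fit.slope_stderr * scale,
        units="S/m", method="EH_dipole", fit_window=fit.window,
        diagnostics={"r_squared": fit.r_squared, "curvature": fit.curvature},
    )
    logger.info("EH dipole conductivity: %.6g +/- %.2g S/m (window %s ps)",
                est.value, est.uncertainty, fit.window)
    return est


def conductivity_from_onsager(lam: OnsagerMatrix, z_plus: float, z_minus: float,
                              thermo: ThermoState,
                              window: tuple | None = None) -> TransportEstimate:
    """Conductivity from the Onsager coefficients.

    sigma = (N e^2 / (V k_B T)) (z+^2 L_pp + z-^2 L_mm + 2 z+ z- L_pm),
    with the coefficients in nm^2/ps normalised per total ion count N.
    Strictly equivalent to the dipole route when computed on the same
    trajectory, sampling plan and window.
    """
    _check_thermo(thermo)
    if window is None:
        window = lam.window
    weighted = (z_plus**2 * lam.lambda_pp + z_minus**2 * lam.lambda_mm
                + 2.0 * z_plus * z_minus * lam.lambda_pm)
    scale = (lam.n_ions * ELEMENTARY_CHARGE_C**2 * NM2_PER_PS_TO_M2_PER_S
             / (thermo.volume_m3 * thermo.kt_joule))
    err = math.sqrt(
        (z_plus**2 * lam.stderrs.get("pp", 0.0))**2
        + (z_minus**2 * lam.stderrs.get("mm", 0.0))**2
        + (2.0 * z_plus * z_minus * lam.stderrs.get("pm", 0.0))**2) * scale
    return TransportEstimate(
        value=weighted * scale, uncertainty=err, units="S/m",
        method="EH_onsager", fit_window=tuple(window))


def contribution_decomposition(lam: OnsagerMatrix, z_plus: float,
                               z_minus: float, thermo: ThermoState) -> dict:
    """Per-pair conductivity contributions; they sum to the Onsager total."""
    _check_thermo(thermo)
    scale = (lam.n_ions * ELEMENTARY_CHARGE_C**2 * NM2_PER_PS_TO_M2_PER_S
             / (thermo.volume_m3 * thermo.kt_joule))
    return {
        "sigma_pp": z_plus**2 * lam.lambda_pp * scale,
        "sigma_mm": z_minus**2 * lam.lambda_mm * scale,
        "sigma_pm_total": 2.0 * z_plus * z_minus * lam.lambda_pm * scale,
    }


def self_diffusion(msd: CorrelationSeries,
                   window: tuple = DEFAULT_FIT_WINDOW) -> TransportEstimate:
    """Einstein self-diffusion coefficient D = slope/6 from an MSD fit (m^2/s).

    The fit's curvature diagnostic is propagated so ballistic or otherwise
    non-diffusive input is flagged rather than silently fitted.
    """
    fit = fit_linear_slope(msd, *window)
    scale = NM2_PER_PS_TO_M2_PER_S / 6.0
    return TransportEstimate(
        value=fit.slope * scale, uncertainty=fit.slope_stderr * scale,
        units="m^2/s", method="Einstein_D", fit_window=fit.window,
        diagnostics={"r_squared": fit.r_squared, "curvature": fit.curvature,
                     "nonlinear": float(fit.nonlinear)})


def yeh_hummer_increment(viscosity: float, box_edge: float,
                         temperature: float) -> float:
    """Periodic-box diffusion correction xi k_B T / (6 pi eta L) in m^2/s.

    viscosity in mPa s, box_edge in nm, temperature in K.
    """
    if viscosity <= 0 or box_edge <= 0 or temperature <= 0:
        raise ValueError("viscosity, box edge and temperature must be positive")
    eta_si = viscosity * 1e-3
    l_si = box_edge * NM_IN_M
    return (XI_YEH_HUMMER * BOLTZMANN_J_PER_K * temperature
            / (6.0 * math.pi * eta_si * l_si))


def yeh_hummer_correct(d_md: float, viscosity: float, box_edge: float,
                       temperature: float) -> float:
    """Finite-size-corrected diffusivity D = D_md + xi k_B T/(6 pi eta L)."""
    return d_md + yeh_hummer_increment(viscosity, box_edge, temperature)


def nernst_einstein(d_plus: float, d_minus: float, charge_e: float,
                    salt_density: float, temperature: float,
                    *, yh_corrected: bool = False) -> TransportEstimate:
    """Approximate conductivity sigma_NE = rho q^2 (D+ + D-) / (k_B T).

    d_plus, d_minus in m^2/s, charge_e in units of e, salt_density in ion
    pairs per m^3.  Neglects all distinct-ion correlations, hence
    overestimates the exact conductivity of pairing systems.
    """
    if d_plus < 0 or d_minus < 0:
        raise ValueError("diffusivities must be nonnegative")
    if salt_density <= 0 or temperature <= 0:
        raise ValueError("salt density and temperature must be positive")
    q = charge_e * ELEMENTARY_CHARGE_C
    value = salt_density * q**2 * (d_plus + d_minus) / (
        BOLTZMANN_J_PER_K * temperature)
    return TransportEstimate(value=value, uncertainty=0.0, units="S/m",
                             method="NE_YH" if yh_corrected else "NE")


def ne_yh_conductivity(sigma_ne: float, charge_e: float, salt_density: float,
                       viscosity: float, box_edge: float,
                       temperature: float = 298.15) -> TransportEstimate:
    """Add the Yeh-Hummer increment to an uncorrected NE conductivity.

    Both ions receive the same diffusivity increment, so the correction
    collapses to sigma_NE+YH = sigma_NE + q^2 rho xi / (3 pi eta L).
    sigma_ne in S/m, charge_e in e, salt_density in pairs/m^3, viscosity in
    mPa s, box_edge in nm.
    """
    if sigma_ne < 0:
        raise ValueError("sigma_ne must be nonnegative")
    inc_d = yeh_hummer_increment(viscosity, box_edge, temperature)
    q = charge_e * ELEMENTARY_CHARGE_C
    inc_sigma = salt_density * q**2 * 2.0 * inc_d / (
        BOLTZMANN_J_PER_K * temperature)
    return TransportEstimate(value=sigma_ne + inc_sigma, uncertainty=0.0,
                             units="S/m", method="NE_YH")


def eh_estimate_from_ne(sigma_ne_yh: float) -> TransportEstimate:
    """Rough exact-conductivity estimate: 0.7 x the NE+YH value.

    Empirical rule of thumb (typical error 5-8%); the result is flagged
    approximate and must not be mistaken for an Einstein-Helfand
    computation.
    """
    if sigma_ne_yh < 0:
        raise ValueError("input conductivity must be nonnegative")
    return TransportEstimate(value=NE_TO_EH_RATIO * sigma_ne_yh,
                             uncertainty=0.0, units="S/m",
                             method="NE_YH_scaled", approximate=True)


def box_length_from_composition(comp: SystemComposition,
                                density: float) -> float:
    """Cubic box edge (nm) from molecule counts and a density in kg/m^3."""
    if density <= 0:
        raise ValueError("density must be positive")
    volume_m3 = comp.total_mass_kg / density
    return volume_m3 ** (1.0 / 3.0) / NM_IN_M


def salt_number_density(n_salt: int, box_edge: float) -> float:
    """Ion-pair number density in pairs/m^3 from a cubic box edge in nm."""
    if box_edge <= 0:
        raise ValueError("box edge must be positive")
    return n_salt / (box_edge * NM_IN_M) ** 3
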