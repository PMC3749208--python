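"""Water-column physics and chemistry: stratification stability, turbulent
diffusivity, Fick fluxes, layer rates and plume inventories.

The stability of the water column is expressed through the Brunt-Väisälä
frequency, N^2 = (g/rho) * d(rho)/dz with depth z positive downward, so a
stable column (density increasing with depth) gives N^2 > 0.  Turbulent
diffusivity follows the Osborn relation Ez = gamma * eps / N^2 with mixing
coefficient gamma = 0.2 and a mean turbulent-kinetic-energy dissipation of
1.85e-9 W kg^-1 (an open-ocean thermocline value).  Diffusive fluxes follow
Fick's law, J = Ez * dC/dz; density and concentration gradients are
least-squares slopes over 4-m depth bins.

Unit conventions: depths m, density kg m^-3, concentrations µmol l^-1
(≡ mmol m^-3), so fluxes emerge in mmol m^-2 d^-1 after the per-day
conversion and layer rates in nmol l^-1 d^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhysicalConstants",
    "PlumeBudget",
    "stability_and_diffusivity",
    "column_gradient",
    "fick_flux",
    "layer_rate",
    "gradient_ratio",
    "plume_budget",
]


@dataclass(frozen=True)
class PhysicalConstants:
    g: float = 9.81                  # m s^-2
    gamma: float = 0.2               # mixing coefficient (dimensionless)
    epsilon: float = 1.85e-9         # TKE dissipation, W kg^-1
    bin_width: float = 4.0           # m
    seconds_per_day: float = 86400.0
    n2_floor: float = 1e-9           # s^-2; below this Ez is flagged, not reported

    def __post_init__(self):
        for name in ("g", "gamma", "epsilon", "bin_width", "seconds_per_day"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _bin_slope(depth: np.ndarray, values: np.ndarray) -> float:
    """Least-squares slope d(value)/d(depth); robust to uneven spacing."""
    return float(np.polyfit(depth, values, 1)[0])


def stability_and_diffusivity(
    profile: pd.DataFrame,
    constants: PhysicalConstants = PhysicalConstants(),
    density_column: str = "density",
) -> pd.DataFrame:
    """Per-bin Brunt-Väisälä frequency squared and turbulent diffusivity.

    The profile needs a strictly increasing ``depth`` column (m, positive
    downward) and a density column (kg m^-3).  Depths are cut into
    consecutive ``bin_width`` bins from the shallowest sample; each bin with
    at least two samples gets a least-squares density slope, from which
    N^2 = (g / mean rho) * slope and Ez = gamma * eps / N^2.  Bins with
    N^2 <= n2_floor (neutral or unstable stratification) are flagged and
    carry no diffusivity.
    """
    depth = profile["depth"].to_numpy(dtype=float)
    if np.any(np.diff(depth) <= 0):
        raise ValueError("depths must be strictly increasing")
    rho = profile[density_column].to_numpy(dtype=float)
    edges = np.arange(depth[0], depth[-1] + constants.bin_width, constants.bin_width)
    rows = []
    for k in range(len(edges) - 1):
        top, bottom = edges[k], edges[k + 1]
        mask = (depth >= top) & (depth < bottom) if k < len(edges) - 2 else (
            (depth >= top) & (depth <= bottom)
        )
        if mask.sum() < 2:
            continue
        slope = _bin_slope(depth[mask], rho[mask])
        rho_mean = float(rho[mask].mean())
        n2 = constants.g / rho_mean * slope
        stable = n2 > constants.n2_floor
        rows.append(
            {
                "bin_top": top,
                "bin_bottom": bottom,
                "rho_mean": rho_mean,
                "drho_dz": slope,
                "n2": n2,
                "ez": constants.gamma * constants.epsilon / n2 if stable else np.nan,
                "stable": stable,
            }
        )
    if not rows:
        raise ValueError("no bin contains two or more density samples")
    return pd.DataFrame(rows)


def column_gradient(
    profile: pd.DataFrame, column: str, top: float, bottom: float
) -> float:
    """Least-squares concentration gradient (per m) over a depth interval."""
    depth = profile["depth"].to_numpy(dtype=float)
    mask = (depth >= top) & (depth <= bottom)
    if mask.sum() < 2:
        raise ValueError(f"fewer than two samples in [{top}, {bottom}] m")
    return _bin_slope(depth[mask], profile[column].to_numpy(dtype=float)[mask])


def fick_flux(
    ez: float, gradient: float, constants: PhysicalConstants = PhysicalConstants()
) -> float:
    """Diffusive flux J = Ez * dC/dz in mmol m^-2 d^-1.

    ``ez`` in m^2 s^-1, ``gradient`` in µmol l^-1 m^-1 (≡ mmol m^-3 m^-1);
    positive gradient (concentration increasing with depth) gives a positive,
    upward flux.
    """
    if not (math.isfinite(ez) and math.isfinite(gradient)):
        raise ValueError("ez and gradient must be finite")
    if ez <= 0:
        raise ValueError("Ez must be positive")
    return ez * gradient * constants.seconds_per_day


def layer_rate(flux: float, thickness: float) -> float:
    """Volumetric turnover rate of a flux consumed within a layer.

    ``flux`` in mmol m^-2 d^-1 over ``thickness`` m gives mmol m^-3 d^-1
    (≡ µmol l^-1 d^-1), reported in nmol l^-1 d^-1.
    """
    if thickness <= 0:
        raise ValueError("layer thickness must be positive")
    return flux / thickness * 1000.0


def gradient_ratio(gradient_a: float, gradient_b: float) -> tuple[float, int, int]:
    """|A|/|B| of two opposing gradients, with the signs reported separately."""
    if gradient_b == 0:
        raise ValueError("gradient_b must be non-zero")
    sign = lambda x: (x > 0) - (x < 0)
    return abs(gradient_a) / abs(gradient_b), sign(gradient_a), sign(gradient_b)


@dataclass(frozen=True)
class PlumeBudget:
    area_km2: float
    thickness_m: float
    mean_concentration_umol_l: float
    molar_mass_g_mol: float
    volume_km3: float
    inventory_mol: float
    mass_tons: float


def plume_budget(
    area_km2: float,
    thickness_m: float,
    mean_concentration_umol_l: float,
    molar_mass_g_mol: float,
) -> PlumeBudget:
    """Volume, molar inventory and mass of a dissolved-species plume.

    volume = area x mean thickness; inventory = volume x concentration
    (µmol l^-1 ≡ mmol m^-3); mass in metric tons via the molar mass.
    """
    if min(area_km2, thickness_m, molar_mass_g_mol) <= 0 or mean_concentration_umol_l < 0:
        raise ValueError("plume budget inputs must be positive")
    volume_m3 = area_km2 * 1e6 * thickness_m
    inventory_mol = volume_m3 * mean_concentration_umol_l / 1000.0  # mmol m^-3 -> mol
    mass_tons = inventory_mol * molar_mass_g_mol / 1e6
    return PlumeBudget(
        area_km2=area_km2,
        thickness_m=thickness_m,
        mean_concentration_umol_l=mean_concentration_umol_l,
        molar_mass_g_mol=molar_mass_g_mol,
        volume_km3=volume_m3 / 1e9,
        inventory_mol=inventory_mol,
        mass_tons=mass_tons,
    )
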