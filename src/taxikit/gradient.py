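"""Point-source diffusion model of a nutrient-loaded alumina bead.

A dSi-loaded aluminium-oxide particle acts as a slow-release point source.
The module computes per-particle loading from the preparation recipe, the
steady-state radial concentration profile around the bead, the time needed
to establish that profile over the observation field, and the fraction of
the load released during an assay.

Two profile variants are provided. The ``literal`` variant is the
flat-chamber form C(r) = i / (4π √r D) with r in cm and the result read as
mol cm⁻³ (the √r correcting the gradient shape in a shallow chamber); it
reproduces the ~5 μM edge concentration of the assay. The ``spherical``
variant is the textbook 3-D point source C(r) = i / (4π D r). Internal
lengths in this module are cm, matching the units the constants are quoted
in; helpers accept μm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

#: 1 mol cm⁻³ expressed in μM (1 mol cm⁻³ = 10³ mol L⁻¹ = 10⁹ μM).
MOL_PER_CM3_TO_UM = 1e9

#: Default measured diffusive flux of dSi off one bead, mol s⁻¹.
DEFAULT_FLUX = 1.21e-13
#: Molecular diffusivity of silicic acid in water, cm² s⁻¹.
DEFAULT_DIFFUSIVITY = 1e-5
#: Default per-particle loading, mol (1.40 nmol).
DEFAULT_LOADING = 1.40e-9

Variant = Literal["literal", "spherical"]


def um_to_cm(r_um: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(r_um, dtype=float) * 1e-4 if np.ndim(r_um) else r_um * 1e-4


@dataclass(frozen=True)
class PointSourceGradient:
    """Constants of one bead source.

    flux: total diffusive flux i off the bead, mol s⁻¹ (measured, not derived).
    molecular_diffusivity: D_c of the solute in water, cm² s⁻¹.
    loading: total adsorbed amount per bead, mol.
    variant: which profile formula :func:`steady_state_concentration` uses.
    """

    flux: float = DEFAULT_FLUX
    molecular_diffusivity: float = DEFAULT_DIFFUSIVITY
    loading: float = DEFAULT_LOADING
    variant: Variant = "literal"

    def __post_init__(self) -> None:
        if self.flux < 0:
            raise ValueError("flux must be >= 0")
        if self.molecular_diffusivity <= 0:
            raise ValueError("molecular_diffusivity must be > 0")
        if self.loading <= 0:
            raise ValueError("loading must be > 0")
        if self.variant not in ("literal", "spherical"):
            raise ValueError(f"unknown variant {self.variant!r}")


def bead_loading(
    stock_volume_ul: float,
    stock_conc_mol_l: float,
    alox_mass_mg: float,
    particles_per_mg: float,
) -> float:
    """Moles of solute per particle from the evaporation recipe.

    A stock volume (μl) at a molar concentration is evaporated onto a mass
    of alumina (mg); the whole load distributes over
    ``alox_mass_mg * particles_per_mg`` particles.
    """
    for name, v in (
        ("stock_volume_ul", stock_volume_ul),
        ("stock_conc_mol_l", stock_conc_mol_l),
        ("alox_mass_mg", alox_mass_mg),
        ("particles_per_mg", particles_per_mg),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    total_mol = stock_volume_ul * 1e-6 * stock_conc_mol_l
    return total_mol / (alox_mass_mg * particles_per_mg)


def steady_state_concentration(
    gradient: PointSourceGradient,
    r_cm: float | np.ndarray,
    variant: Variant | None = None,
) -> float | np.ndarray:
    """Steady-state concentration at radius r (cm), in μM.

    ``literal``: C = i / (4π √r D), read as mol cm⁻³ (flat-chamber form).
    ``spherical``: C = i / (4π D r), mol cm⁻³ (3-D point source).
    """
    variant = variant or gradient.variant
    r = np.asarray(r_cm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0 (source singularity at r = 0)")
    i, d = gradient.flux, gradient.molecular_diffusivity
    if variant == "literal":
        c_mol_cm3 = i / (4.0 * math.pi * np.sqrt(r) * d)
    elif variant == "spherical":
        c_mol_cm3 = i / (4.0 * math.pi * d * r)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    c_um = c_mol_cm3 * MOL_PER_CM3_TO_UM
    return float(c_um) if np.ndim(r_cm) == 0 else c_um


def concentration_at_um(
    gradient: PointSourceGradient,
    r_um: float | np.ndarray,
    variant: Variant | None = None,
) -> float | np.ndarray:
    """Convenience wrapper: radius in μm, result in μM."""
    return steady_state_concentration(gradient, np.asarray(r_um, dtype=float) * 1e-4, variant)


def time_to_steady_state(gradient: PointSourceGradient, d_cm: float) -> float:
    """Diffusive time d²/D_c (s) to establish the profile over a field of diameter d."""
    if d_cm <= 0:
        raise ValueError("d must be > 0")
    return d_cm**2 / gradient.molecular_diffusivity


def fraction_released(gradient: PointSourceGradient, duration_s: float) -> float:
    """Fraction of the bead load released after a given time, capped at 1."""
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    return min(1.0, gradient.flux * duration_s / gradient.loading)


def gradient_profile(
    gradient: PointSourceGradient, radii_cm: Iterable[float]
) -> pd.DataFrame:
    """Tabulate both profile variants over a set of radii.

    Columns: r_cm, r_um, conc_literal_uM, conc_spherical_uM.
    """
    radii = np.asarray(list(radii_cm), dtype=float)
    if radii.size == 0:
        return pd.DataFrame(columns=["r_cm", "r_um", "conc_literal_uM", "conc_spherical_uM"])
    return pd.DataFrame(
        {
            "r_cm": radii,
            "r_um": radii * 1e4,
            "conc_literal_uM": steady_state_concentration(gradient, radii, "literal"),
            "conc_spherical_uM": steady_state_concentration(gradient, radii, "spherical"),
        }
    )
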