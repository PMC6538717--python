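"""Sphere mass <-> diameter conversions and unit constants.

The package works in one canonical unit system internally: seconds, mL,
ng (concentrations), nm (diameters), fg (per-particle masses). Densities
are g/cm^3 as tabulated in handbooks. Conversions to other units happen
only at the I/O boundary.
"""

from __future__ import annotations

import math

import numpy as np

#: femtograms per nanogram
FG_PER_NG = 1.0e6

#: (pi/6) * (1 nm)^3 in cm^3, times fg per g -> fg per (g/cm^3) per nm^3
# mass_fg = (pi/6) * density[g/cm^3] * d[nm]^3 * 1e-21 cm^3/nm^3 * 1e15 fg/g
_SPHERE_FACTOR = math.pi / 6.0 * 1.0e-6


def sphere_analyte_mass_fg(diameter_nm, density_g_cm3: float, mass_fraction: float = 1.0):
    """Analyte mass (fg) of a spherical particle of the given diameter.

    ``mass_fraction`` is the analyte mass over the whole-particle mass
    (1.0 for a pure-element particle such as Ag).
    """
    d = np.asarray(diameter_nm, dtype=float)
    return _SPHERE_FACTOR * density_g_cm3 * d**3 * mass_fraction


def mass_to_diameter_nm(analyte_mass_fg, density_g_cm3: float, mass_fraction: float = 1.0):
    """Spherical-equivalent diameter (nm) from the analyte mass (fg).

    Inverse of :func:`sphere_analyte_mass_fg`: the analyte mass is first
    scaled up to the whole-particle mass by ``mass_fraction``, then the
    sphere-volume formula is inverted.
    """
    m = np.asarray(analyte_mass_fg, dtype=float)
    if np.any(m < 0):
        raise ValueError("analyte mass must be non-negative")
    return np.cbrt(m / (_SPHERE_FACTOR * density_g_cm3 * mass_fraction))
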