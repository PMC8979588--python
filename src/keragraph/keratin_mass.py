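"""Estimate cellular keratin protein mass from total network length.

Two independent estimators, both linear in the total imaged bundle length
L_tot and the bundling factor Bf (the assumed number of 10-nm filaments
per imaged bundle):

* **Mass-per-length.**  Intermediate filaments have an experimentally
  determined linear mass density MPL ≈ 25 kDa/nm (range 19–30).  The
  cellular mass is  m = MPL · L_tot · Bf / N_A.

* **Tetramer counting.**  A keratin tetramer (2×K5 + 2×K14 in
  keratinocytes) is 44 nm long with a combined molecular weight of
  228,165 Da; 1000/44 ≈ 22.7 tetramers per µm of protofilament and ~6
  protofilaments per 10-nm filament give a per-µm single-filament MW of
  ≈ 3.11e7 Da, from which the total MW and mass follow.

At the defaults the tetramer route corresponds to an MPL of ≈ 31.1
kDa/nm, so the two estimates differ by a constant factor ≈ 25/31.1; both
lie inside the measured MPL range.

A tissue-scale extrapolation multiplies per-cell bundle length by an
epidermal cell count (~1.4e11 cells per human body).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MassParams",
    "mass_mpl",
    "mass_tetramer",
    "tissue_extrapolation",
    "round_sig",
]

AVOGADRO = 6.02214076e23  # mol⁻¹ (exact, SI)


@dataclass
class MassParams:
    """Physical constants of the keratin mass estimators.

    mpl_kda_per_nm
        Mass per length of a single 10-nm keratin filament, kDa/nm
        (measured range 19–30).
    bundling_factor
        Assumed number of single filaments per imaged bundle.
    tetramer_mw_da / tetramer_length_nm
        Molecular weight and length of the keratin tetramer subunit
        (K5/K14 heterotetramer by default).
    protofilaments_per_filament
        Protofilaments (tetramer chains) per 10-nm filament cross-section.
    """

    mpl_kda_per_nm: float = 25.0
    bundling_factor: float = 19.0
    avogadro: float = AVOGADRO
    tetramer_mw_da: float = 228165.0
    tetramer_length_nm: float = 44.0
    protofilaments_per_filament: int = 6

    def __post_init__(self) -> None:
        vals = [
            self.mpl_kda_per_nm,
            self.bundling_factor,
            self.avogadro,
            self.tetramer_mw_da,
            self.tetramer_length_nm,
            self.protofilaments_per_filament,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all mass parameters must be positive")

    @property
    def filament_mw_per_um(self) -> float:
        """Molecular weight of 1 µm of single filament, Da."""
        tetramers_per_um = 1000.0 / self.tetramer_length_nm
        return tetramers_per_um * self.tetramer_mw_da * self.protofilaments_per_filament


def mass_mpl(l_tot_mm: float, params: MassParams | None = None) -> float:
    """Keratin mass in pg from the mass-per-length estimator.

    ``l_tot_mm`` is the total imaged bundle length per cell in mm.
    """
    if params is None:
        params = MassParams()
    if l_tot_mm < 0:
        raise ValueError("total length must be >= 0")
    mpl_da_per_nm = params.mpl_kda_per_nm * 1000.0
    l_nm = l_tot_mm * 1e6
    total_da = mpl_da_per_nm * l_nm * params.bundling_factor
    return total_da / params.avogadro * 1e12  # Da·mol → g via N_A, g → pg


def mass_tetramer(
    l_tot_mm: float, params: MassParams | None = None
) -> tuple[float, float]:
    """Total molecular weight (Da) and mass (pg) from the tetramer estimator."""
    if params is None:
        params = MassParams()
    if l_tot_mm < 0:
        raise ValueError("total length must be >= 0")
    l_um = l_tot_mm * 1e3
    total_da = params.filament_mw_per_um * l_um * params.bundling_factor
    mass_pg = total_da / params.avogadro * 1e12
    return total_da, mass_pg


def tissue_extrapolation(
    l_tot_per_cell_mm: float,
    n_cells: float = 0.14e12,
    bundling_factor: float = 19.0,
) -> tuple[float, float]:
    """Whole-tissue filament length from per-cell length, in km.

    Returns (total bundle length, total single-filament length); the
    latter is the former times the bundling factor.  The default cell
    count is the estimated number of epidermal cells in a human body.
    """
    bundle_km = n_cells * l_tot_per_cell_mm * 1e-6  # mm → km
    return bundle_km, bundle_km * bundling_factor


def round_sig(x: float, sig: int) -> float:
    """Round to *sig* significant figures (printing convention for pg values)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
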