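"""Emulsion design arithmetic: droplet geometry and Poisson loading.

A vortexed water-in-oil emulsion disperses an aqueous phase into spherical
droplets. For design purposes droplets are treated as monodisperse spheres
at the mean diameter (real emulsions are polydisperse, typically 5-30 μm
with a mode near 10 μm; the simulator models that spread, this module does
not). With cells or molecules dispersed at random, the number of occupants
per droplet follows a Poisson law with mean λ, so the single-cell regime is
reached by diluting until λ << 1.

Internally volumes are carried in litres and converted at the boundary:
a 10 μm droplet is (π/6)·d³ ≈ 523.6 μm³ ≈ 0.5236 pL, so 255 μl of aqueous
phase yields ≈ 4.9e8 droplets, and a 10 pM solute loads ≈ 3.15 molecules
per droplet on average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import Avogadro

# unit factors (SI litres as the internal volume unit)
UL_PER_L = 1e6
PL_PER_L = 1e12
UM3_PER_L = 1e15  # 1 L = 1e-3 m^3 = 1e15 μm^3


@dataclass(frozen=True)
class DropletSpec:
    """Emulsion design parameters.

    Parameters
    ----------
    mean_diameter:
        Mean droplet diameter in μm.
    aqueous_volume:
        Total dispersed aqueous-phase volume in μl.
    """

    mean_diameter: float
    aqueous_volume: float

    def __post_init__(self) -> None:
        if not self.mean_diameter > 0:
            raise ValueError("mean_diameter must be > 0 μm")
        if not self.aqueous_volume > 0:
            raise ValueError("aqueous_volume must be > 0 μl")


@dataclass(frozen=True)
class LoadingStats:
    """Poisson occupancy summary for a mean of ``lam`` occupants/droplet."""

    lam: float
    p_empty: float
    p_single: float
    p_multi: float
    occupied_fraction: float
    multi_given_occupied: float


def droplet_volume(diameter_um: float) -> float:
    """Volume in pL of a spherical droplet of the given diameter (μm)."""
    if not diameter_um > 0:
        raise ValueError("diameter must be > 0 μm")
    vol_um3 = math.pi / 6.0 * diameter_um**3
    return vol_um3 / UM3_PER_L * PL_PER_L


def droplet_count(spec: DropletSpec) -> float:
    """Number of droplets the aqueous phase disperses into (unrounded).

    Simply aqueous volume over single-droplet volume; callers round for
    display (the design convention is one significant figure).
    """
    vol_l = spec.aqueous_volume / UL_PER_L
    droplet_l = droplet_volume(spec.mean_diameter) / PL_PER_L
    return vol_l / droplet_l


def molecules_per_droplet(concentration_molar: float, diameter_um: float) -> float:
    """Mean copies of a solute per droplet at the given molar concentration.

    concentration × N_A × droplet volume; e.g. 10 pM in 10 μm droplets
    loads ≈ 3.15 molecules per droplet.
    """
    if concentration_molar < 0:
        raise ValueError("concentration must be >= 0")
    droplet_l = droplet_volume(diameter_um) / PL_PER_L
    return concentration_molar * Avogadro * droplet_l


def occupancy_from_lambda(lam: float) -> LoadingStats:
    """Poisson occupancy probabilities at mean ``lam`` occupants/droplet."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p_empty = math.exp(-lam)
    p_single = lam * p_empty
    p_multi = 1.0 - p_empty - p_single
    # clamp the subtraction round-off at tiny lam
    p_multi = max(p_multi, 0.0)
    occupied = 1.0 - p_empty
    multi_given_occ = p_multi / occupied if occupied > 0 else 0.0
    return LoadingStats(
        lam=lam,
        p_empty=p_empty,
        p_single=p_single,
        p_multi=p_multi,
        occupied_fraction=occupied,
        multi_given_occupied=multi_given_occ,
    )


def occupancy(n_occupants: float, n_droplets: float) -> LoadingStats:
    """Poisson occupancy when ``n_occupants`` are dispersed into ``n_droplets``."""
    if not n_droplets > 0:
        raise ValueError("n_droplets must be > 0")
    if n_occupants < 0:
        raise ValueError("n_occupants must be >= 0")
    return occupancy_from_lambda(n_occupants / n_droplets)
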