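"""Hydrodynamic sizing: Stokes–Einstein radii and empirical residue-number
scaling for folded versus denatured chains.

A measured diffusion coefficient D converts to a hydrodynamic radius via
Rh = kB T / (6 pi eta D).  Empirical power laws Rh = A * N^nu relate radius
to chain length N: compact folded proteins scale with a small exponent
(A = 4.75 Å, nu = 0.29 by default) and denatured chains with a larger one
(A = 2.21 Å, nu = 0.57).  A measured radius lying beyond the denatured-chain
bound for the monomer length indicates an assembly, and the two scaling laws
bracket how many times larger than a monomer it could be.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KB = 1.380649e-23  # J/K

__all__ = [
    "HydroParams",
    "RhScaling",
    "stokes_einstein_rh",
    "residues_from_rh",
    "rh_from_residues",
    "classify_assembly",
]


@dataclass(frozen=True)
class HydroParams:
    """Temperature (K) and solvent viscosity (Pa·s); defaults are room
    temperature (21.5 °C ≈ 295.15 K) and water at that temperature."""

    T: float = 295.15
    eta: float = 9.55e-4
    kB: float = KB

    def __post_init__(self):
        if self.T <= 0 or self.eta <= 0:
            raise ValueError("T and eta must be positive")


@dataclass(frozen=True)
class RhScaling:
    """Coefficients (Å) and exponents of the folded/denatured Rh power laws."""

    A_folded: float = 4.75
    nu_folded: float = 0.29
    A_denatured: float = 2.21
    nu_denatured: float = 0.57

    def __post_init__(self):
        if min(self.A_folded, self.nu_folded, self.A_denatured,
               self.nu_denatured) <= 0:
            raise ValueError("scaling coefficients must be positive")
        if self.nu_denatured <= self.nu_folded:
            raise ValueError("denatured exponent must exceed folded exponent")


def stokes_einstein_rh(D: float, params: HydroParams = HydroParams()) -> float:
    """Hydrodynamic radius in nm from a diffusion coefficient in µm²/s."""
    if D <= 0:
        raise ValueError("D must be positive")
    d_si = D * 1e-12  # µm²/s -> m²/s
    rh_m = params.kB * params.T / (6.0 * np.pi * params.eta * d_si)
    return rh_m * 1e9


def rh_from_residues(n_residues: float, model: str,
                     scaling: RhScaling = RhScaling()) -> float:
    """Predicted Rh in Å for a chain of ``n_residues`` under one scaling law."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if model == "folded":
        return scaling.A_folded * n_residues ** scaling.nu_folded
    if model == "denatured":
        return scaling.A_denatured * n_residues ** scaling.nu_denatured
    raise ValueError(f"unknown model {model!r}")


def residues_from_rh(rh_angstrom: float, model: str,
                     scaling: RhScaling = RhScaling()) -> float:
    """Inverse of :func:`rh_from_residues`: N = (Rh/A)^(1/nu)."""
    if rh_angstrom <= 0:
        raise ValueError("Rh must be positive")
    if model == "folded":
        return (rh_angstrom / scaling.A_folded) ** (1.0 / scaling.nu_folded)
    if model == "denatured":
        return (rh_angstrom / scaling.A_denatured) ** (1.0 / scaling.nu_denatured)
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class AssemblyVerdict:
    within_monomer_boundary: bool
    fold_estimate_range: tuple[float, float]
    boundary_angstrom: tuple[float, float]  # (folded bound, denatured bound)


def classify_assembly(rh_measured: float, n_residues_monomer: int,
                      scaling: RhScaling = RhScaling()) -> AssemblyVerdict:
    """Compare a measured Rh (Å) against the folded–denatured monomer size
    boundary and bracket the assembly size in monomer equivalents.

    The monomer boundary is [Rh_folded(N), Rh_denatured(N)]; a radius at or
    below the denatured bound is compatible with a monomer.  The fold range
    divides the apparent residue count back-calculated under each scaling
    law by the monomer length, sorted ascending.
    """
    if rh_measured <= 0 or n_residues_monomer < 1:
        raise ValueError("inputs must be positive")
    lo = rh_from_residues(n_residues_monomer, "folded", scaling)
    hi = rh_from_residues(n_residues_monomer, "denatured", scaling)
    within = rh_measured <= hi
    folds = sorted((
        residues_from_rh(rh_measured, "folded", scaling) / n_residues_monomer,
        residues_from_rh(rh_measured, "denatured", scaling) / n_residues_monomer,
    ))
    return AssemblyVerdict(within_monomer_boundary=within,
                           fold_estimate_range=(folds[0], folds[1]),
                           boundary_angstrom=(lo, hi))
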