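"""Forward hydrodynamic estimates from bead models.

The translational friction of a rigid bead assembly is approximated by the
Kirkwood double sum: for N beads of radius a,

    Rh = N·a / (1 + (a/N) · Σ_{i≠j} 1/r_ij)

which is exact for a single Stokes sphere and accurate to ~5–10% for
low-resolution envelopes (no full Oseen/Rotne–Prager tensor inversion is
attempted).  From Rh, a molecular mass and a partial specific volume the
standard sedimentation chain follows:

    f      = 6πη·Rh
    s      = M(1 − v̄ρ) / (N_A·f)                 (reported in Svedberg)
    R0     = (3·M·v̄ / (4π·N_A))^(1/3)            (equivalent compact sphere)
    f/f0   = Rh / R0

A frictional ratio near 1 signals a compact globule; values well above 1
signal elongation — the argument used to conclude that an end-to-end complex
is "larger but similarly elongated" when its f/f0 matches the free component.

Lengths are Å internally and nm in reports; viscosity is in Pa·s, density in
g/ml, mass in kDa, v̄ in ml/g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .bead_models import BeadModel

__all__ = ["SolventSpec", "HydrodynamicEstimate", "kirkwood_rh",
           "hydrodynamic_summary"]

AVOGADRO = 6.02214076e23
SVEDBERG = 1e-13          # s


@dataclass(frozen=True)
class SolventSpec:
    """Solvent conditions; defaults are water at 20 °C."""

    viscosity: float = 1.002e-3      # Pa·s
    density: float = 0.9982          # g/ml
    temperature: float = 293.15      # K

    def __post_init__(self) -> None:
        if min(self.viscosity, self.density, self.temperature) <= 0:
            raise ValueError("solvent parameters must be positive")


@dataclass(frozen=True)
class HydrodynamicEstimate:
    rh: float          # nm
    s: float           # Svedberg
    f_over_f0: float
    mass: float        # kDa (input)
    vbar: float        # ml/g (input)
    sedimenting: bool = True

    def summary(self) -> str:
        lines = [
            "Hydrodynamic estimate",
            "---------------------",
            f"Rh        {self.rh:8.3f} nm",
            f"s         {self.s:8.3f} S",
            f"f/f0      {self.f_over_f0:8.3f}",
            f"mass      {self.mass:8.1f} kDa, vbar {self.vbar:g} ml/g",
        ]
        if not self.sedimenting:
            lines.append("WARNING: vbar*density >= 1, particle does not sediment")
        return "\n".join(lines)


def kirkwood_rh(model: BeadModel) -> float:
    """Kirkwood double-sum hydrodynamic radius of a bead model, in nm."""
    a = model.bead_radius
    n = model.n_beads
    inv_sum = 2.0 * float(np.sum(1.0 / pdist(model.centres)))   # Σ_{i≠j} 1/r_ij
    rh_angstrom = n * a / (1.0 + (a / n) * inv_sum)
    return rh_angstrom / 10.0


def single_sphere_rh(radius_angstrom: float) -> float:
    """Stokes radius of one bead (nm); the N = 1 limit of the Kirkwood sum."""
    return radius_angstrom / 10.0


def hydrodynamic_summary(rh: float, mass: float, vbar: float = 0.73,
                         solvent: SolventSpec = SolventSpec()) -> HydrodynamicEstimate:
    """Sedimentation coefficient and frictional ratio from Rh (nm) and mass (kDa)."""
    if min(rh, mass, vbar) <= 0:
        raise ValueError("rh, mass and vbar must be positive")
    buoyancy = 1.0 - vbar * solvent.density
    f = 6.0 * math.pi * solvent.viscosity * (rh * 1e-9)            # kg/s
    # mass in kDa == kg/mol
    s_seconds = mass * buoyancy / (AVOGADRO * f)
    volume = mass * 1e3 * vbar * 1e-6 / AVOGADRO                   # m^3
    r0 = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)           # m
    return HydrodynamicEstimate(
        rh=rh, s=s_seconds / SVEDBERG, f_over_f0=(rh * 1e-9) / r0,
        mass=mass, vbar=vbar, sedimenting=buoyancy > 0)
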