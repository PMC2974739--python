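"""Closed-form channel biophysics.

The quantitative core of the package: the biionic Goldman–Hodgkin–Katz (GHK)
permeability-ratio equation for Ca2+ against lumped intracellular monovalent
cations, its algebraic inverse used for per-batch calibration of the
intracellular monovalent concentration, the GHK current (constant-field flux)
equation used generatively by the simulator, and the Woodhull description of
voltage-dependent open-channel block.

Unit conventions, used at every public interface of the package:

* membrane potentials in mV (converted to V internally),
* concentrations in mM,
* currents in nA, inward current negative, depolarisation positive.

The biionic setting is an oocyte bathed in a Ringer in which Ca2+ is the only
putatively permeant extracellular cation (monovalents replaced by impermeant
NMDG) while the cytosol is treated as containing a single lumped monovalent
species of concentration ``mono_i``.  With those assumptions, setting the sum
of the GHK currents carried by Ca2+ (z = +2) and the monovalent (z = +1) to
zero at the reversal potential ``Erev`` yields

    P_Ca / P_mono = [Mono]_i * e^(u) * (e^(u) + 1) / (4 * [Ca]_o),

with ``u = Erev * F / (R * T)``.  ``calibrate_mono_i`` inverts this relation
for ``[Mono]_i`` given a reference channel whose ratio is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "PhysicalConstants",
    "SolutionSpec",
    "BiionicContext",
    "WoodhullParams",
    "ghk_permeability_ratio",
    "calibrate_mono_i",
    "ghk_current_density",
    "woodhull_unblocked_fraction",
    "ION_CHARGE",
]

#: valence of the species the simulator knows about; 0 marks impermeant cations
ION_CHARGE: dict[str, int] = {
    "Na": 1,
    "K": 1,
    "Cs": 1,
    "Mono": 1,
    "Ca": 2,
    "Mg": 2,
    "NMDG": 0,
}


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday constant, gas constant and absolute temperature.

    Defaults follow the convention used throughout oocyte work at room
    temperature: F = 9.65e4 C/mol, R = 8.314 J/(mol K), T = 293.15 K.
    """

    F: float = 9.65e4
    R: float = 8.314
    T: float = 293.15

    def __post_init__(self) -> None:
        if not (self.F > 0 and self.R > 0 and self.T > 0):
            raise ValueError("F, R and T must all be positive")

    @property
    def f_over_rt(self) -> float:
        """F/(RT) in 1/V."""
        return self.F / (self.R * self.T)


@dataclass(frozen=True)
class SolutionSpec:
    """Composition of one bath solution.

    ``ion_concentrations`` in mM, ``agonists`` in µM, ``blockers`` in mM.
    Labels follow the recording conventions: NFR (normal frog Ringer),
    "4 mM CaR" / "8 mM CaR" (biionic Ca2+ Ringers with NMDG replacing
    monovalents).
    """

    label: str
    ion_concentrations: Mapping[str, float] = field(default_factory=dict)
    pH: float = 7.2
    agonists: Mapping[str, float] = field(default_factory=dict)
    blockers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, conc in {**self.ion_concentrations, **self.blockers}.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {name!r}: {conc}")
        for name, conc in self.agonists.items():
            if conc < 0:
                raise ValueError(f"negative agonist concentration for {name!r}")

    @property
    def agonist_key(self) -> str:
        """Canonical key for agonist-set lookup, e.g. ``'glutamate+glycine'``."""
        return "+".join(sorted(self.agonists)) if self.agonists else ""


@dataclass(frozen=True)
class BiionicContext:
    """Concentrations entering the biionic GHK permeability equation."""

    mono_i: float
    ca_o: float
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mono_i) and self.mono_i > 0):
            raise ValueError(f"mono_i must be positive and finite, got {self.mono_i}")
        if not (math.isfinite(self.ca_o) and self.ca_o > 0):
            raise ValueError(f"ca_o must be positive and finite, got {self.ca_o}")


@dataclass(frozen=True)
class WoodhullParams:
    """One-site Woodhull block: a blocker binding at fractional electrical
    depth delta inside the pore, with effective valence-times-depth ``zdelta``
    and zero-voltage dissociation constant ``kd0`` (mM)."""

    kd0: float
    zdelta: float
    blocker_conc: float

    def __post_init__(self) -> None:
        if not self.kd0 > 0:
            raise ValueError(f"kd0 must be positive, got {self.kd0}")
        if not 0.0 <= self.zdelta <= 2.0:
            raise ValueError(f"zdelta must be in [0, 2], got {self.zdelta}")
        if self.blocker_conc < 0:
            raise ValueError(f"blocker_conc must be >= 0, got {self.blocker_conc}")


def _exp_u(erev_mv: float, constants: PhysicalConstants) -> float:
    return math.exp(erev_mv * 1e-3 * constants.f_over_rt)


def ghk_permeability_ratio(erev_mv: float, ctx: BiionicContext) -> float:
    """Ca2+/monovalent permeability ratio from a biionic reversal potential.

    Parameters
    ----------
    erev_mv
        Reversal potential in mV (junction-corrected).
    ctx
        Intracellular monovalent concentration, extracellular Ca2+ and the
        physical constants.

    Returns
    -------
    float
        P_Ca/P_mono, strictly positive and strictly increasing in ``erev_mv``.
    """
    if not math.isfinite(erev_mv):
        raise ValueError(f"erev must be finite, got {erev_mv}")
    e = _exp_u(erev_mv, ctx.constants)
    return ctx.mono_i * e * (e + 1.0) / (4.0 * ctx.ca_o)


def calibrate_mono_i(
    erev_ref_mv: float,
    p_ref: float,
    ca_o: float,
    constants: PhysicalConstants | None = None,
) -> float:
    """Intracellular monovalent concentration from a reference channel.

    Inverts the biionic GHK relation at the reference channel's measured
    reversal potential and its known P_Ca/P_mono.  Used per oocyte batch with
    a calibration receptor (classically GluR6(Q)); here also to back out
    mono_i from any published (Erev, ratio) pair.
    """
    if constants is None:
        constants = PhysicalConstants()
    if not (math.isfinite(p_ref) and p_ref > 0):
        raise ValueError(f"p_ref must be positive and finite, got {p_ref}")
    if not (math.isfinite(ca_o) and ca_o > 0):
        raise ValueError(f"ca_o must be positive and finite, got {ca_o}")
    if not math.isfinite(erev_ref_mv):
        raise ValueError(f"erev_ref must be finite, got {erev_ref_mv}")
    e = _exp_u(erev_ref_mv, constants)
    return 4.0 * ca_o * p_ref / (e * (e + 1.0))


def ghk_current_density(
    v_mv,
    charge: int,
    conc_in: float,
    conc_out: float,
    permeability: float = 1.0,
    constants: PhysicalConstants | None = None,
):
    """GHK (constant-field) current carried by one ion species.

    Accepts a scalar or array of membrane potentials in mV and returns the
    current density in arbitrary units proportional to
    ``P * z^2 * F * u * (c_in - c_out * exp(-z*u)) / (1 - exp(-z*u))`` with
    ``u = V F/(R T)``; the simulator's gain converts it to nA.  Outward
    current is positive, inward negative.  The removable singularity at
    V = 0 is handled by its analytic limit ``P * z * F * (c_in - c_out)``.

    Vanishes exactly at the species' Nernst potential.
    """
    if constants is None:
        constants = PhysicalConstants()
    if charge not in (1, 2):
        raise ValueError(f"charge must be +1 or +2, got {charge}")
    if conc_in < 0 or conc_out < 0:
        raise ValueError("concentrations must be non-negative")
    if conc_in == 0 and conc_out == 0:
        raise ValueError("at least one of conc_in/conc_out must be positive")

    v = np.asarray(v_mv, dtype=float)
    zu = charge * v * 1e-3 * constants.f_over_rt
    small = np.abs(zu) < 1e-9
    zu_safe = np.where(small, 1.0, zu)
    ratio = np.where(
        small,
        conc_in - conc_out,  # analytic limit of zu*(ci - co e^-zu)/(1 - e^-zu)
        zu_safe * (conc_in - conc_out * np.exp(-zu_safe)) / (1.0 - np.exp(-zu_safe)),
    )
    out = permeability * charge * constants.F * 1e-6 * ratio
    return float(out) if np.isscalar(v_mv) else out


def woodhull_unblocked_fraction(
    v_mv,
    params: WoodhullParams,
    constants: PhysicalConstants | None = None,
):
    """Fraction of channel current surviving voltage-dependent block.

    The blocker's dissociation constant at membrane potential V is
    ``Kd(V) = kd0 * exp(zdelta * V F/(R T))`` — an extracellular cationic
    blocker binds more tightly at hyperpolarised potentials — and the
    unblocked fraction is ``1 / (1 + [B]/Kd(V))``.  Monotone increasing in V
    for zdelta > 0, equal to 1 everywhere when no blocker is present.
    """
    if constants is None:
        constants = PhysicalConstants()
    v = np.asarray(v_mv, dtype=float)
    kd = params.kd0 * np.exp(params.zdelta * v * 1e-3 * constants.f_over_rt)
    frac = kd / (kd + params.blocker_conc)
    return float(frac) if np.isscalar(v_mv) else frac
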