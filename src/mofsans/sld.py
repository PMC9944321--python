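"""Neutron scattering-length-density (SLD) arithmetic.

Contrast variation in SANS rests on the large difference between the bound
coherent scattering lengths of protium (b_c = -3.742 fm) and deuterium
(b_c = +6.675 fm): mixing H2O and D2O tunes the solvent SLD from about
-0.56e-6 to +6.36e-6 1/A^2, and a component whose SLD equals the solvent's
is "matched out" of the coherent signal.  This module computes solvent
SLDs, match points, and composition SLDs including perdeuteration and
labile-hydrogen exchange.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .nsld_tables import (
    AVOGADRO,
    DENSITY_D2O,
    DENSITY_H2O,
    FM_TO_ANGSTROM,
    atomic_mass,
    b_coherent,
)

__all__ = [
    "Composition",
    "ContrastCondition",
    "solvent_sld",
    "match_point",
    "composition_sld",
    "contrast",
    "SLD_H2O",
    "SLD_D2O",
]


def _water_volume(mass: float, density: float) -> float:
    """Molecular volume in A^3 from molar mass (g/mol) and density (g/cm^3)."""
    return mass / (density * AVOGADRO) * 1e24


# molecular volumes of the two waters from their ambient densities
_V_H2O = _water_volume(2 * atomic_mass("H") + atomic_mass("O"), DENSITY_H2O)
_V_D2O = _water_volume(2 * atomic_mass("D") + atomic_mass("O"), DENSITY_D2O)

#: SLD of pure H2O / D2O at 25 C, 1/A^2
SLD_H2O = (2 * b_coherent("H") + b_coherent("O")) * FM_TO_ANGSTROM / _V_H2O
SLD_D2O = (2 * b_coherent("D") + b_coherent("O")) * FM_TO_ANGSTROM / _V_D2O


def solvent_sld(fD: float) -> float:
    """SLD of an H2O/D2O mixture, 1/A^2.

    Parameters
    ----------
    fD : float
        D2O volume fraction in [0, 1].  Volumes are assumed additive, so the
        mixture SLD is affine in fD.
    """
    if not 0.0 <= fD <= 1.0:
        raise ValueError(f"D2O volume fraction must be in [0, 1], got {fD}")
    return fD * SLD_D2O + (1.0 - fD) * SLD_H2O


def match_point(target_sld: float) -> float:
    """D2O volume fraction whose mixture SLD equals ``target_sld``.

    Closed-form inversion of :func:`solvent_sld`.  Raises if the target lies
    outside the attainable [SLD(H2O), SLD(D2O)] interval.
    """
    lo, hi = SLD_H2O, SLD_D2O
    if not min(lo, hi) <= target_sld <= max(lo, hi):
        raise ValueError(
            f"target SLD {target_sld:.3e} outside attainable range "
            f"[{lo:.3e}, {hi:.3e}] 1/A^2"
        )
    return (target_sld - lo) / (hi - lo)


@dataclasses.dataclass
class ContrastCondition:
    """Solvent isotope state and solute H/D bookkeeping.

    Attributes
    ----------
    fD : float
        D2O volume fraction of the solvent.
    deuterated_solute : bool
        If True, non-exchangeable solute hydrogens are deuterium
        (perdeuterated expression).
    exchange_fraction : float
        Fraction of labile (N/O/S-bound) hydrogens that adopt the solvent
        H/D ratio; 0.9 is the common assumption for folded proteins.
    """

    fD: float = 0.0
    deuterated_solute: bool = False
    exchange_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.fD <= 1.0:
            raise ValueError("fD must be in [0, 1]")
        if not 0.0 <= self.exchange_fraction <= 1.0:
            raise ValueError("exchange_fraction must be in [0, 1]")

    def b_exchangeable(self) -> float:
        """Mean b_c (fm) of one labile H site, after exchange."""
        base = b_coherent("D") if self.deuterated_solute else b_coherent("H")
        solvent_mix = self.fD * b_coherent("D") + (1.0 - self.fD) * b_coherent("H")
        f = self.exchange_fraction
        return (1.0 - f) * base + f * solvent_mix

    def b_nonexchangeable(self) -> float:
        """b_c (fm) of one non-labile H site."""
        return b_coherent("D") if self.deuterated_solute else b_coherent("H")


@dataclasses.dataclass
class Composition:
    """Stoichiometric formula with H/D bookkeeping for SLD arithmetic.

    Exactly one of ``density`` (g/cm^3) or ``molecular_volume`` (A^3) must be
    given.  The molecular volume is derived from the formula *as specified*
    (before any H->D substitution), so that isotopic substitution changes the
    scattering length sum but not the occupied volume.
    """

    counts: dict[str, float]
    n_exchangeable_H: float = 0.0
    density: float | None = None
    molecular_volume: float | None = None

    def __post_init__(self) -> None:
        if (self.density is None) == (self.molecular_volume is None):
            raise ValueError("give exactly one of density or molecular_volume")
        if self.density is not None and self.density <= 0:
            raise ValueError("density must be positive")
        if self.molecular_volume is not None and self.molecular_volume <= 0:
            raise ValueError("molecular_volume must be positive")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative stoichiometric count")
        if self.n_exchangeable_H > self.counts.get("H", 0.0) + self.counts.get("D", 0.0):
            raise ValueError("n_exchangeable_H exceeds total hydrogen count")

    @property
    def formula_mass(self) -> float:
        """Molar mass of the as-specified formula, g/mol."""
        return sum(n * atomic_mass(el) for el, n in self.counts.items())

    @property
    def volume(self) -> float:
        """Molecular volume, A^3."""
        if self.molecular_volume is not None:
            return self.molecular_volume
        return self.formula_mass / (self.density * AVOGADRO) * 1e24

    def scattering_length(self, cond: ContrastCondition | None = None) -> float:
        """Total coherent scattering length (fm) under a contrast condition.

        Hydrogens are partitioned into exchangeable sites (take the solvent
        ratio per ``cond.exchange_fraction``) and non-exchangeable sites
        (D if ``cond.deuterated_solute`` else as specified).  Explicit "D"
        counts in the formula are never back-exchanged unless listed in
        ``n_exchangeable_H``.
        """
        if cond is None:
            cond = ContrastCondition(fD=0.0, deuterated_solute=False,
                                     exchange_fraction=0.0)
        total = 0.0
        n_h = self.counts.get("H", 0.0)
        n_d = self.counts.get("D", 0.0)
        n_x = min(self.n_exchangeable_H, n_h + n_d)
        for el, n in self.counts.items():
            if el in ("H", "D"):
                continue
            total += n * b_coherent(el)
        # exchangeable sites are drawn first from the H count, then from D
        x_from_h = min(n_x, n_h)
        x_from_d = n_x - x_from_h
        total += n_x * cond.b_exchangeable()
        total += (n_h - x_from_h) * cond.b_nonexchangeable()
        total += (n_d - x_from_d) * b_coherent("D")
        return total

    def sld(self, cond: ContrastCondition | None = None) -> float:
        """SLD in 1/A^2 under a contrast condition."""
        return self.scattering_length(cond) * FM_TO_ANGSTROM / self.volume

    @classmethod
    def from_dict(cls, block: dict[str, str | float]) -> "Composition":
        """Build from a flat key/value block.

        Keys ``density`` / ``molecular_volume`` / ``n_exchangeable_H`` are
        reserved; every other key is an element or isotope count.
        """
        counts: dict[str, float] = {}
        kwargs: dict[str, float] = {}
        for key, val in block.items():
            k = key.strip()
            if k in ("density", "molecular_volume", "n_exchangeable_H"):
                kwargs[k] = float(val)
            else:
                counts[k] = float(val)
        return cls(counts=counts, **kwargs)

    @classmethod
    def from_config(cls, path: str | Path) -> "Composition":
        """Read a ``key: value`` config file (``#`` comments allowed)."""
        block: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition(":")
            if not _:
                raise ValueError(f"malformed config line: {raw!r}")
            block[key.strip()] = val.strip()
        return cls.from_dict(block)


def composition_sld(comp: Composition, cond: ContrastCondition | None = None) -> float:
    """SLD (1/A^2) of a composition under a contrast condition."""
    return comp.sld(cond)


def contrast(comp_sld: float, solvent_sld_value: float) -> float:
    """Excess SLD (contrast) of a component against the solvent, 1/A^2.

    Coherent scattered intensity scales with the square of this quantity;
    it vanishes at the match point.
    """
    return comp_sld - solvent_sld_value
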