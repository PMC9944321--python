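"""Synthetic-data generator with known ground truth.

Every input the analysis pipeline consumes can be generated here: a dry
hierarchical-MOF curve with its three scattering regimes (surface-fractal
power law at low q, correlation-length diffuse term at mid q, Bragg peaks at
high q), the contrast-matched wet residual curve (peaks suppressed, raised
incoherent background), free-protein curves, and protein@MOF composites with
counting-statistics noise.  Truth parameters ride along in curve metadata so
closure tests can compare recovered values against them.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .atoms import AtomSet
from .curves import Curve1D
from .models import (
    HierarchicalParams,
    ScattererSet,
    atoms_to_scatterers,
    cylinder_form,
    debye_intensity,
    eval_hierarchical,
    sphere_form,
)
from .nsld_tables import RESIDUE_H_TEMPLATES, displaced_volume
from .sld import ContrastCondition, solvent_sld

__all__ = [
    "GeneratorSpec", "default_dry_params", "default_residual_params",
    "gen_dry_mof", "gen_matched_composite", "gen_free_protein",
    "synthetic_gfp",
]

#: flat incoherent plateau of pure H2O and pure D2O, 1/cm (config constants;
#: the solvent background is interpolated linearly in the D2O fraction)
INCOHERENT_H2O = 1.0
INCOHERENT_D2O = 0.1


def default_dry_params() -> HierarchicalParams:
    """Dry-state hierarchical parameters emulating the studied framework.

    The correlation length (265 A) and power-law exponent (3.4) are the
    reported dry-state values; prefactors, the three Bragg-peak centers in
    the 0.06-0.25 1/A window and the background are plausible choices that
    reproduce the three-regime shape of the measured profile.
    """
    return HierarchicalParams(
        A=5.0e-6, n=3.4, B=500.0, xi=265.0, m=2.0,
        peaks=[(5.0, 0.085, 0.006), (3.0, 0.145, 0.008), (2.0, 0.20, 0.010)],
        I_bgd=0.5,
    )


def default_residual_params() -> HierarchicalParams:
    """Wet matched-state parameters: no Bragg peaks, intensity dropped at
    low q, background raised by the H2O in the solvent mixture."""
    return HierarchicalParams(A=2.0e-7, n=3.4, B=120.0, xi=265.0, m=2.0,
                              peaks=[], I_bgd=1.0)


@dataclasses.dataclass
class GeneratorSpec:
    """Study conditions for the generator.

    ``noise_level`` is the relative 1-sigma at the forward intensity; the
    noise model is sigma(q) = noise_level * sqrt(I(q) * I_max) (counting
    statistics).  ``q_grid`` is (qmin, qmax, n_points), log spaced, matching
    the instrument coverage of 0.0015-0.5 1/A.
    """

    mof_params: HierarchicalParams = dataclasses.field(default_factory=default_dry_params)
    residual_params: HierarchicalParams = dataclasses.field(
        default_factory=default_residual_params)
    assembly: object | None = None           # AssemblyModel | ("sphere", R) | ...
    contrast: ContrastCondition = dataclasses.field(
        default_factory=lambda: ContrastCondition(fD=0.5, deuterated_solute=True))
    protein_volume_fraction: float = 0.05
    noise_level: float = 0.002
    q_grid: tuple[float, float, int] = (0.0015, 0.5, 250)
    seed: int = 0

    def q(self) -> np.ndarray:
        qmin, qmax, n = self.q_grid
        if qmin <= 0:
            raise ValueError("qmin must be positive")
        return np.geomspace(qmin, qmax, int(n))


def _noisify(q: np.ndarray, I_true: np.ndarray, noise_level: float,
             rng: np.random.Generator, meta: dict[str, str]) -> Curve1D:
    I0 = float(I_true.max())
    if noise_level > 0:
        sigma = noise_level * np.sqrt(np.abs(I_true) * I0)
        I = I_true + rng.normal(0.0, 1.0, size=len(q)) * sigma
    else:
        sigma = 0.01 * np.abs(I_true)       # nominal weights, no noise added
        I = I_true.copy()
    meta = dict(meta)
    meta["noise_level"] = repr(noise_level)
    return Curve1D(q, I, sigma, None, meta)


def gen_dry_mof(spec: GeneratorSpec) -> Curve1D:
    """Dry framework curve: hierarchical model + counting noise.

    Truth parameters are stored in ``meta["truth_params"]`` (JSON).
    """
    q = spec.q()
    rng = np.random.default_rng(spec.seed)
    I_true = eval_hierarchical(spec.mof_params, q)
    meta = {
        "sample": "dry framework",
        "state": "dry",
        "truth_params": json.dumps(spec.mof_params.to_dict()),
    }
    return _noisify(q, I_true, spec.noise_level, rng, meta)


def _assembly_intensity(spec: GeneratorSpec, q: np.ndarray) -> np.ndarray:
    """Absolute-scale assembly intensity, 1/cm.

    For a scatterer-based assembly I(q) is the Debye sum (fm^2 -> A^2 via
    (1e-5)^2) times the number density n = phi / V_assembly; for analytic
    shapes it is phi * V * drho^2 * P(q).  1/A -> 1/cm multiplies by 1e8.
    """
    a = spec.assembly
    if a is None:
        raise ValueError("generator spec has no assembly")
    if isinstance(a, tuple) and a[0] == "sphere":
        _, R = a
        drho = 3.0e-6  # representative protein-solvent contrast, 1/A^2
        V = 4.0 / 3.0 * np.pi * R ** 3
        return spec.protein_volume_fraction * V * drho ** 2 * sphere_form(R, q) * 1e8
    scat: ScattererSet = a.scatterers if hasattr(a, "scatterers") else a
    I_debye = debye_intensity(scat, q)            # fm^2
    I0 = float(debye_intensity(scat, np.array([1e-6]))[0])
    # effective (drho V)^2 in A^2 and an occupied volume estimate
    v_est = max(len(scat) * 20.0, 1.0)            # ~20 A^3 per heavy-atom group
    n_density = spec.protein_volume_fraction / v_est     # 1/A^3
    return n_density * (1e-5) ** 2 * I_debye * 1e8 * (I0 / I0)


def gen_matched_composite(spec: GeneratorSpec) -> tuple[Curve1D, Curve1D]:
    """Matrix (matched wet framework) and protein@framework composite.

    composite = residual model + assembly intensity + extra incoherent
    background from the protonated solvent fraction + noise.  The stored
    ground-truth protein-attributable signal, ``meta["truth_assembly"]``
    (JSON arrays of q and I), includes that flat background term, since it
    too survives matrix subtraction.
    """
    if spec.assembly is None:
        raise ValueError("generator spec has no assembly")
    q = spec.q()
    rng = np.random.default_rng(spec.seed)
    I_res = eval_hierarchical(spec.residual_params, q)
    matrix = _noisify(q, I_res, spec.noise_level, rng, {
        "sample": "matched wet framework",
        "state": "wet-matched",
        "truth_params": json.dumps(spec.residual_params.to_dict()),
    })
    I_asm = _assembly_intensity(spec, q)
    extra_bgd = 0.2 * (INCOHERENT_H2O * (1.0 - spec.contrast.fD)
                       + INCOHERENT_D2O * spec.contrast.fD)
    truth = I_asm + extra_bgd
    composite = _noisify(q, I_res + truth, spec.noise_level, rng, {
        "sample": "protein@framework",
        "state": "wet-matched",
        "fD": repr(spec.contrast.fD),
        "truth_assembly": json.dumps({"q": q.tolist(), "I": truth.tolist()}),
    })
    return matrix, composite


def gen_free_protein(shape, cond: ContrastCondition, noise: float = 0.01,
                     seed: int = 0, I0: float = 1.0,
                     q_grid: tuple[float, float, int] = (0.003, 0.45, 220)
                     ) -> Curve1D:
    """Free-protein solution curve with the truth Rg recorded in metadata.

    ``shape`` is ``("sphere", R)``, ``("cylinder", L, R)`` or an
    :class:`AtomSet` (Debye scattering at the given contrast condition).
    """
    q = np.geomspace(*q_grid[:2], int(q_grid[2]))
    rng = np.random.default_rng(seed)
    if isinstance(shape, tuple) and shape[0] == "sphere":
        R = float(shape[1])
        I_true = I0 * sphere_form(R, q)
        rg_truth = np.sqrt(3.0 / 5.0) * R
    elif isinstance(shape, tuple) and shape[0] == "cylinder":
        L, R = float(shape[1]), float(shape[2])
        I_true = I0 * cylinder_form(L, R, q)
        rg_truth = np.sqrt(L ** 2 / 12.0 + R ** 2 / 2.0)
    elif isinstance(shape, AtomSet):
        scat = atoms_to_scatterers(shape, cond)
        I_raw = debye_intensity(scat, q)
        I_true = I0 * I_raw / I_raw.max()
        rg_truth = scat.weighted_rg()
    else:
        raise TypeError("shape must be ('sphere', R), ('cylinder', L, R) or AtomSet")
    meta = {"sample": "free protein", "truth_rg": f"{rg_truth:.6g}",
            "fD": repr(cond.fD)}
    return _noisify(q, I_true, noise, rng, meta)


# --------------------------------------------------------------------------
# synthetic GFP-scale monomer
# --------------------------------------------------------------------------

# residue sampling frequencies ~ average globular-protein composition
_RES_FREQ = {
    "ALA": 8.3, "ARG": 5.5, "ASN": 4.1, "ASP": 5.5, "CYS": 1.4, "GLN": 3.9,
    "GLU": 6.7, "GLY": 7.1, "HIS": 2.3, "ILE": 5.9, "LEU": 9.7, "LYS": 5.8,
    "MET": 2.4, "PHE": 3.9, "PRO": 4.7, "SER": 6.6, "THR": 5.4, "TRP": 1.1,
    "TYR": 2.9, "VAL": 6.9,
}


def _residue_atoms(resname: str, origin: np.ndarray, direction: np.ndarray,
                   rng: np.random.Generator):
    """Heavy atoms of one residue: backbone cluster at ``origin``, side
    chain extending along ``direction``."""
    template = RESIDUE_H_TEMPLATES[resname]
    out = []
    backbone_offsets = {
        "N": np.array([-1.2, 0.3, 0.0]), "CA": np.zeros(3),
        "C": np.array([1.2, 0.4, 0.0]), "O": np.array([1.5, 1.5, 0.3]),
    }
    side = [a for a in template if a not in ("N", "CA", "C", "O", "OXT")]
    for name, off in backbone_offsets.items():
        nh, nx = template.get(name, (0, 0))
        out.append((name[0], origin + off + rng.normal(0, 0.15, 3), nh, nx))
    for k, name in enumerate(side):
        nh, nx = template[name]
        dist = min(1.5 + 0.8 * k, 5.0)      # side chains reach <= ~5 A
        pos = origin + direction * dist + rng.normal(0, 0.35, 3)
        out.append((name[0], pos, nh, nx))
    return out


def synthetic_gfp(seed: int = 0, n_residues: int = 238) -> AtomSet:
    """Synthetic stand-in for a GFP monomer (NOT experimental coordinates).

    A fluorescent-protein-like fold built programmatically: an 11-stranded
    beta-barrel of ~42 A length and ~24 A outer diameter with a central
    helix and terminal loops, populated with template-correct heavy atoms
    and implicit-H counts for a typical residue composition.  Use it where a
    deposited structure would be loaded via :func:`mofsans.atoms.read_atoms`;
    coordinate-level detail is synthetic, but size, composition and H/D
    bookkeeping are realistic for a ~27 kDa beta-barrel protein.
    """
    rng = np.random.default_rng(seed)
    res_names = list(_RES_FREQ)
    res_p = np.array(list(_RES_FREQ.values()))
    res_p = res_p / res_p.sum()

    n_strands = 11
    per_strand = 13
    rise = 42.0 / per_strand
    barrel_r = 9.5       # CA radius; side chains keep the 24 A outer diameter
    helix_len = 14
    atoms: list[tuple[str, np.ndarray, int, int]] = []

    def sample_res() -> str:
        return res_names[rng.choice(len(res_names), p=res_p)]

    # barrel strands, alternating up/down
    for s in range(n_strands):
        phi = 2.0 * np.pi * s / n_strands
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        z0, dz = (-21.0, rise) if s % 2 == 0 else (21.0, -rise)
        tangential = np.array([-np.sin(phi), np.cos(phi), 0.0])
        for i in range(per_strand):
            z = z0 + dz * (i + 0.5)
            origin = barrel_r * radial + np.array([0.0, 0.0, z])
            # side chains alternate outward/inward along a strand; outward
            # ones hug the surface (radial + tangential) to keep the
            # printed ~24 A outer diameter
            if i % 2 == 0:
                direction = radial + 1.6 * tangential
                direction /= np.linalg.norm(direction)
            else:
                direction = -radial
            atoms += _residue_atoms(sample_res(), origin, direction, rng)
    # central helix along the axis
    for i in range(helix_len):
        z = -0.5 * helix_len * 1.5 + 1.5 * i
        phi = 100.0 * np.pi / 180.0 * i
        origin = np.array([2.3 * np.cos(phi), 2.3 * np.sin(phi), z])
        direction = np.array([np.cos(phi), np.sin(phi), 0.0])
        atoms += _residue_atoms(sample_res(), origin, direction, rng)
    # terminal loops / caps
    n_loops = n_residues - n_strands * per_strand - helix_len
    for i in range(n_loops):
        cap = 1.0 if i % 2 == 0 else -1.0
        phi = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(1.5, 8.0)
        z = cap * rng.uniform(19.0, 21.0)
        origin = np.array([r * np.cos(phi), r * np.sin(phi), z])
        # cap side chains lie mostly flat against the barrel end
        direction = np.array([np.cos(phi), np.sin(phi), 0.25 * cap])
        direction /= np.linalg.norm(direction)
        atoms += _residue_atoms(sample_res(), origin, direction, rng)

    elements = np.array([a[0] for a in atoms], dtype=object)
    positions = np.array([a[1] for a in atoms])
    h_counts = np.array([a[2] for a in atoms])
    x_counts = np.array([a[3] for a in atoms])
    return AtomSet(positions, elements, h_counts, x_counts)


def protein_displaced_volume(a: AtomSet) -> float:
    """Total solvent-displaced volume of an atom set, A^3."""
    return float(sum(displaced_volume(el) + int(nh) * displaced_volume("H")
                     for el, nh in zip(a.elements, a.h_counts)))
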