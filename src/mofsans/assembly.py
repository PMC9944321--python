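"""Protein multimers constrained by a mesocage lattice.

A hierarchical porous framework of the MTN-topology type offers micro- and
mesocages joined by apertures; proteins loaded into it can only sit one per
cage, so candidate "multimers" are monomer templates duplicated into
adjacent cages.  This module builds such cage lattices, places assemblies,
predicts their size and scattering, and classifies experimental curves
against a candidate library.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import minimize_scalar

from .atoms import AtomSet
from .curves import Curve1D
from .models import ScattererSet, debye_intensity

__all__ = [
    "CageLattice", "AssemblyModel", "build_lattice", "place_assembly",
    "assembly_rg", "classify_assembly", "ClassificationResult",
    "ConfinementError",
    "MICROCAGE_RADIUS", "SMALL_MESOCAGE_RADIUS", "LARGE_MESOCAGE_RADIUS",
    "PENTAGONAL_APERTURE_RADIUS", "HEXAGONAL_APERTURE_RADIUS",
    "DEFAULT_CAGE_SPACING",
]

# cage dimensions of the MTN-type framework studied here (radii, A):
# microcage 1.8 nm diameter, mesocages 4.9 and 6.0 nm, joined through
# 2.0 nm pentagonal and 2.4 nm hexagonal apertures
MICROCAGE_RADIUS = 9.0
SMALL_MESOCAGE_RADIUS = 24.5
LARGE_MESOCAGE_RADIUS = 30.0
PENTAGONAL_APERTURE_RADIUS = 10.0
HEXAGONAL_APERTURE_RADIUS = 12.0
#: default center-to-center distance of adjacent mesocages, A (configurable;
#: consistent with the cage diameters and the confined-dimer length scale)
DEFAULT_CAGE_SPACING = 51.5


class ConfinementError(ValueError):
    """A template does not fit inside its cage."""


@dataclasses.dataclass
class CageLattice:
    """Cage centers/radii plus the aperture adjacency graph."""

    cage_centers: np.ndarray
    cage_radii: np.ndarray
    adjacency: list[tuple[int, int]]
    aperture_radii: np.ndarray

    def __post_init__(self) -> None:
        self.cage_centers = np.asarray(self.cage_centers, dtype=float).reshape(-1, 3)
        self.cage_radii = np.asarray(self.cage_radii, dtype=float)
        self.aperture_radii = np.asarray(self.aperture_radii, dtype=float)
        if len(self.cage_radii) != len(self.cage_centers):
            raise ValueError("cage_radii length mismatch")
        if np.any(self.cage_radii <= 0):
            raise ValueError("cage radii must be positive")
        if len(self.aperture_radii) != len(self.adjacency):
            raise ValueError("one aperture radius per adjacency required")
        self.adjacency = [tuple(sorted(p)) for p in self.adjacency]
        if len(set(self.adjacency)) != len(self.adjacency):
            raise ValueError("duplicate adjacency entries")
        for (i, j), ap in zip(self.adjacency, self.aperture_radii):
            if ap >= self.cage_radii[i] or ap >= self.cage_radii[j]:
                raise ValueError(f"aperture radius {ap} not smaller than cages {i},{j}")

    def __len__(self) -> int:
        return len(self.cage_centers)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.adjacency:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


def build_lattice(topology_spec: dict) -> CageLattice:
    """Build a cage lattice from an explicit or shorthand topology spec.

    Explicit form::

        {"centers": [[x, y, z], ...], "radii": [...],
         "aperture_radius": 12.0}          # scalar or per-pair list

    Adjacent-chain shorthand::

        {"chain": 3, "radius": 30.0, "spacing": 51.5, "aperture_radius": 12.0}

    Adjacency is inferred for every pair with center distance smaller than
    the sum of the two radii; a pair whose centers are closer than the
    larger single radius (one center inside the other cage) is rejected as
    overlapping beyond aperture tolerance.
    """
    ap_r = topology_spec.get("aperture_radius", HEXAGONAL_APERTURE_RADIUS)
    if "chain" in topology_spec:
        n = int(topology_spec["chain"])
        r = float(topology_spec.get("radius", LARGE_MESOCAGE_RADIUS))
        d = float(topology_spec.get("spacing", DEFAULT_CAGE_SPACING))
        centers = np.column_stack([np.arange(n) * d, np.zeros(n), np.zeros(n)])
        radii = np.full(n, r)
    else:
        centers = np.asarray(topology_spec["centers"], dtype=float)
        radii = np.asarray(topology_spec["radii"], dtype=float)
    adjacency: list[tuple[int, int]] = []
    apertures: list[float] = []
    ap_list = np.atleast_1d(np.asarray(ap_r, dtype=float))
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dist = float(np.linalg.norm(centers[i] - centers[j]))
            if dist < max(radii[i], radii[j]):
                raise ValueError(
                    f"cages {i} and {j} overlap beyond aperture tolerance "
                    f"(distance {dist:.1f} A)"
                )
            if dist < radii[i] + radii[j]:
                adjacency.append((i, j))
                apertures.append(float(ap_list[len(apertures) % len(ap_list)]))
    return CageLattice(centers, radii, adjacency, np.array(apertures))


@dataclasses.dataclass
class AssemblyModel:
    """A multimer candidate: one monomer per occupied cage.

    ``placements`` records (cage index, 3x3 rotation applied to the
    recentered template); ``scatterers`` is the realized point set used for
    forward scattering.
    """

    label: str
    placements: list[tuple[int, np.ndarray]]
    scatterers: ScattererSet
    lattice: CageLattice | None = None
    monomer_rg: float | None = None

    @property
    def centers(self) -> np.ndarray:
        if self.lattice is None:
            raise ValueError("assembly has no lattice")
        return self.lattice.cage_centers[[i for i, _ in self.placements]]

    def intensity(self, q: np.ndarray, **kwargs) -> np.ndarray:
        return debye_intensity(self.scatterers, q, **kwargs)


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _align_long_axis(positions: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Rotation taking the principal (long) axis of a point cloud onto
    ``direction``."""
    centered = positions - positions.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    long_axis = vt[0]
    direction = direction / np.linalg.norm(direction)
    v = np.cross(long_axis, direction)
    c = float(np.dot(long_axis, direction))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else _rotation([1.0, 0.0, 0.0], np.pi)
    return _rotation(v / np.linalg.norm(v), np.arccos(np.clip(c, -1, 1)))


def _connected_path(lat: CageLattice, n: int, prefer_large: bool = False) -> list[int]:
    """Greedy depth-first path of n mutually connected cages."""
    order = np.argsort(-lat.cage_radii) if prefer_large else np.arange(len(lat))

    def dfs(path: list[int]) -> list[int] | None:
        if len(path) == n:
            return path
        for nb in lat.neighbors(path[-1]):
            if nb not in path:
                found = dfs(path + [nb])
                if found:
                    return found
        return None

    for start in order:
        found = dfs([int(start)])
        if found:
            return found
    raise ValueError(f"no connected path of {n} cages in the lattice")


def place_assembly(lat: CageLattice, template: AtomSet | ScattererSet | float,
                   n: int, mode: str = "custom",
                   prefer_large: bool = False) -> AssemblyModel:
    """Place ``n`` copies of a monomer template into connected cages.

    ``template`` may be an :class:`AtomSet` whose scattering lengths were not
    yet assigned (unit weights are used), a :class:`ScattererSet`, or a float
    monomer Rg (sphere proxy of radius sqrt(5/3) Rg, one bead per cage).

    Orientation modes: ``side_by_side`` aligns every copy's long axis with
    the cage-to-cage direction (parallel axes); ``perpendicular`` rotates
    every second copy by 90 degrees; anything else keeps the template
    orientation.  The monomer bounding sphere must fit inside its cage.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    path = _connected_path(lat, n, prefer_large=prefer_large)
    centers = lat.cage_centers[path]
    axis = (centers[1] - centers[0]) if n > 1 else np.array([1.0, 0.0, 0.0])

    if isinstance(template, float) or isinstance(template, int):
        monomer_rg = float(template)
        bead_R = np.sqrt(5.0 / 3.0) * monomer_rg
        for idx in path:
            if bead_R > lat.cage_radii[idx]:
                raise ConfinementError(
                    f"sphere proxy radius {bead_R:.1f} A exceeds cage radius "
                    f"{lat.cage_radii[idx]:.1f} A"
                )
        scat = ScattererSet(centers, np.ones(n), radius=bead_R)
        placements = [(idx, np.eye(3)) for idx in path]
        return AssemblyModel(mode, placements, scat, lat, monomer_rg)

    if isinstance(template, AtomSet):
        positions = template.positions - template.centroid
        weights = np.ones(len(template))
        monomer_rg = template.rg()
    else:
        # geometry (centering, extent) uses |b| so a near-matched template
        # with vanishing net contrast still places sensibly
        w_geo = np.abs(template.b_eff)
        com = (w_geo[:, None] * template.centers).sum(axis=0) / w_geo.sum()
        positions = template.centers - com
        weights = template.b_eff
        d2 = ((template.centers - com) ** 2).sum(axis=1)
        monomer_rg = float(np.sqrt((w_geo * d2).sum() / w_geo.sum()))

    bounding = float(np.sqrt((positions ** 2).sum(axis=1).max()))
    base_rot = _align_long_axis(positions, axis)
    all_pos, all_b, placements = [], [], []
    for k, idx in enumerate(path):
        if bounding > lat.cage_radii[idx]:
            raise ConfinementError(
                f"template bounding radius {bounding:.1f} A exceeds cage "
                f"radius {lat.cage_radii[idx]:.1f} A (cage {idx})"
            )
        rot = base_rot
        if mode in ("dimer_perp", "perpendicular") and k % 2 == 1:
            perp = np.cross(axis, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(axis, [0.0, 1.0, 0.0])
            rot = _rotation(perp, np.pi / 2) @ base_rot
        placed = positions @ rot.T + lat.cage_centers[idx]
        all_pos.append(placed)
        all_b.append(weights)
        placements.append((idx, rot))
    scat = ScattererSet(np.vstack(all_pos), np.concatenate(all_b))
    return AssemblyModel(mode, placements, scat, lat, monomer_rg)


def assembly_rg(monomer_rg: float, centers: np.ndarray) -> float:
    """Rg of identical monomers at the given centers (parallel-axis theorem).

    Rg^2 = Rg_monomer^2 + <|c_i - c_mean|^2>, assuming every copy carries the
    same total scattering weight.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    if len(centers) < 1:
        raise ValueError("need at least one center")
    d2 = ((centers - centers.mean(axis=0)) ** 2).sum(axis=1)
    return float(np.sqrt(monomer_rg ** 2 + d2.mean()))


@dataclasses.dataclass
class ClassificationResult:
    """Ranked candidate labels with goodness-of-fit scores."""

    ranking: list[tuple[str, float, float]]  # (label, score, scale)
    metric: str                              # "chi2_reduced" or "pr_l2"
    mixture: tuple[str, str, float, float] | None  # (label1, label2, w1, score)
    no_adequate_candidate: bool

    @property
    def best_label(self) -> str:
        return self.ranking[0][0]

    def summary(self) -> str:
        lines = [f"Assembly classification ({self.metric}):"]
        for label, score, scale in self.ranking:
            lines.append(f"  {label:<14s} score = {score:10.4g}  scale = {scale:.4g}")
        if self.mixture is not None:
            l1, l2, w, score = self.mixture
            lines.append(f"  mixture {w:.2f} x {l1} + {1 - w:.2f} x {l2}: "
                         f"score = {score:.4g}")
        if self.no_adequate_candidate:
            lines.append("  WARNING: no adequate candidate (all scores poor)")
        return "\n".join(lines)


def _chi2_with_scale(I_cand: np.ndarray, I: np.ndarray, w: np.ndarray,
                     fit_background: bool = True) -> tuple[float, float]:
    """Best intensity scale (and optional flat background) and reduced chi2.

    A matrix-subtracted curve retains an unknown flat incoherent offset, so
    by default the candidate is fitted as s * I_cand + b by weighted linear
    least squares; the background is not part of the score's dof.
    """
    if fit_background:
        X = np.column_stack([I_cand, np.ones_like(I_cand)])
        Xw = X * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(Xw, I * np.sqrt(w), rcond=None)
        s, b = float(coef[0]), float(coef[1])
        chi2 = float(np.sum(w * (s * I_cand + b - I) ** 2)) / max(1, len(I) - 2)
        return s, chi2
    denom = float(np.sum(w * I_cand ** 2))
    s = float(np.sum(w * I_cand * I)) / denom if denom > 0 else 0.0
    chi2 = float(np.sum(w * (s * I_cand - I) ** 2)) / max(1, len(I) - 1)
    return s, chi2


def classify_assembly(exp, library: list[AssemblyModel],
                      chi2_threshold: float = 2.0,
                      fit_background: bool = True) -> ClassificationResult:
    """Rank candidate assemblies against data.

    ``exp`` may be a :class:`Curve1D` (ranking by reduced chi2 after a free
    intensity scale, plus a flat background unless ``fit_background`` is
    False) or a :class:`~mofsans.inference.PofR` (ranking by L2 distance of
    area-normalized P(r)).  The two best candidates are also combined in a
    single-weight mixture fit.
    """
    if not library:
        raise ValueError("empty candidate library")

    if isinstance(exp, Curve1D):
        w = 1.0 / np.maximum(exp.sigma, 1e-30) ** 2
        cand_curves = {}
        scored = []
        for model in library:
            I_c = model.intensity(exp.q)
            cand_curves[model.label] = I_c
            s, chi2 = _chi2_with_scale(I_c, exp.I, w, fit_background)
            scored.append((model.label, chi2, s))
        scored.sort(key=lambda t: t[1])
        mixture = None
        if len(scored) >= 2:
            l1, l2 = scored[0][0], scored[1][0]
            c1 = cand_curves[l1] / cand_curves[l1][0]
            c2 = cand_curves[l2] / cand_curves[l2][0]

            def neg_quality(wmix: float) -> float:
                _, chi2 = _chi2_with_scale(wmix * c1 + (1 - wmix) * c2, exp.I, w,
                                           fit_background)
                return chi2

            opt = minimize_scalar(neg_quality, bounds=(0.0, 1.0), method="bounded")
            mixture = (l1, l2, float(opt.x), float(opt.fun))
        flag = scored[0][1] > chi2_threshold and (
            mixture is None or mixture[3] > chi2_threshold)
        return ClassificationResult(scored, "chi2_reduced", mixture, flag)

    # P(r) route: L2 distance between area-normalized distributions
    from .inference import PofR  # local import to avoid a cycle

    if not isinstance(exp, PofR):
        raise TypeError("exp must be a Curve1D or PofR")
    r_grid = exp.r
    p_exp = exp.pr / np.trapezoid(exp.pr, r_grid)
    scored = []
    for model in library:
        q = np.linspace(2e-3, 0.35, 180)
        I_c = model.intensity(q)
        sigma = np.maximum(0.01 * I_c, 1e-12)
        from .inference import ift_pr
        res = ift_pr(Curve1D(q, I_c, sigma), Dmax=max(r_grid), alpha=None)
        pr_c = np.interp(r_grid, res.r, res.pr)
        p_c = pr_c / max(np.trapezoid(pr_c, r_grid), 1e-30)
        dist = float(np.sqrt(np.trapezoid((p_c - p_exp) ** 2, r_grid)))
        scored.append((model.label, dist, 1.0))
    scored.sort(key=lambda t: t[1])
    return ClassificationResult(scored, "pr_l2", None, False)
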