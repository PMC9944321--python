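import numpy as np
import pytest

import mofsans as m
from mofsans.assembly import (
    DEFAULT_CAGE_SPACING,
    ConfinementError,
    build_lattice,
    classify_assembly,
    place_assembly,
)
from mofsans.models import ScattererSet, debye_intensity


class TestLattice:
    def test_two_adjacent_mesocages(self):
        lat = build_lattice({"centers": [[0, 0, 0], [55, 0, 0]],
                             "radii": [30.0, 30.0]})
        assert lat.adjacency == [(0, 1)]

    def test_single_cage_no_adjacency(self):
        lat = build_lattice({"centers": [[0, 0, 0]], "radii": [30.0]})
        assert lat.adjacency == []

    def test_chain_shorthand(self):
        lat = build_lattice({"chain": 4})
        assert len(lat) == 4
        assert lat.adjacency == [(0, 1), (1, 2), (2, 3)]
        d = np.linalg.norm(lat.cage_centers[1] - lat.cage_centers[0])
        assert d == pytest.approx(DEFAULT_CAGE_SPACING)

    def test_tetrahedral_connectivity(self):
        a = 52.0 / np.sqrt(2.0)
        centers = np.array([[a, a, a], [a, -a, -a], [-a, a, -a], [-a, -a, a]]) / 2
        lat = build_lattice({"centers": centers, "radii": [30.0] * 4})
        assert len(lat.adjacency) == 6        # fully connected tetrahedron

    def test_overlapping_cages_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            build_lattice({"centers": [[0, 0, 0], [20, 0, 0]],
                           "radii": [30.0, 30.0]})

    def test_aperture_must_be_smaller_than_cages(self):
        with pytest.raises(ValueError, match="aperture"):
            build_lattice({"centers": [[0, 0, 0], [15, 0, 0]],
                           "radii": [9.0, 9.0], "aperture_radius": 10.0})


class TestPlacement:
    def test_single_copy_recentered(self, mesocage_chain, gfp_scatterers):
        asm = place_assembly(mesocage_chain, gfp_scatterers, 1, "monomer")
        assert len(asm.scatterers) == len(gfp_scatterers)
        w = np.abs(asm.scatterers.b_eff)
        com = (w[:, None] * asm.scatterers.centers).sum(0) / w.sum()
        assert np.allclose(com, mesocage_chain.cage_centers[0], atol=1e-8)
        assert asm.scatterers.weighted_rg() == pytest.approx(
            gfp_scatterers.weighted_rg(), rel=1e-9)

    def test_dimer_parallel_axis_rg(self, mesocage_chain, gfp_scatterers):
        rg_m = gfp_scatterers.weighted_rg()
        asm = place_assembly(mesocage_chain, gfp_scatterers, 2, "dimer_side")
        expected = np.sqrt(rg_m ** 2 + (51.5 / 2.0) ** 2)
        assert asm.scatterers.weighted_rg() == pytest.approx(expected, rel=0.005)

    def test_template_too_big_for_microcage(self, gfp_scatterers):
        lat = build_lattice({"chain": 2, "radius": 9.0, "spacing": 16.0,
                             "aperture_radius": 8.0})
        with pytest.raises(ConfinementError, match="exceeds cage radius"):
            place_assembly(lat, gfp_scatterers, 1, "monomer")

    def test_confinement_invariant_all_atoms_inside(self, mesocage_chain,
                                                    gfp_scatterers):
        asm = place_assembly(mesocage_chain, gfp_scatterers, 3, "trimer")
        per = len(gfp_scatterers)
        for k, (idx, _) in enumerate(asm.placements):
            block = asm.scatterers.centers[k * per:(k + 1) * per]
            d = np.linalg.norm(block - mesocage_chain.cage_centers[idx], axis=1)
            assert d.max() <= mesocage_chain.cage_radii[idx] + 1e-9

    def test_more_copies_than_connected_cages(self, gfp_scatterers):
        lat = build_lattice({"chain": 2})
        with pytest.raises(ValueError, match="connected"):
            place_assembly(lat, gfp_scatterers, 3, "trimer")

    def test_perpendicular_mode_differs_from_parallel(self, mesocage_chain,
                                                      gfp_scatterers):
        side = place_assembly(mesocage_chain, gfp_scatterers, 2, "dimer_side")
        perp = place_assembly(mesocage_chain, gfp_scatterers, 2, "dimer_perp")
        q = np.geomspace(0.01, 0.3, 40)
        assert not np.allclose(side.intensity(q), perp.intensity(q), rtol=1e-3)


class TestAssemblyRg:
    def test_single_center_returns_monomer_rg(self):
        assert m.assembly_rg(16.82, [[0, 0, 0]]) == 16.82

    def test_two_centers_parallel_axis(self):
        d = 51.5
        got = m.assembly_rg(16.82, [[0, 0, 0], [d, 0, 0]])
        assert got == pytest.approx(np.sqrt(16.82 ** 2 + (d / 2) ** 2), rel=1e-12)
        assert got == pytest.approx(30.7, abs=0.1)

    def test_equilateral_trimer_against_duplicated_cloud(self):
        """Brute-force oracle: duplicate a point cloud onto the three
        vertices and compare coordinate Rg."""
        d = 60.0
        centers = np.array([[0, 0, 0], [d, 0, 0], [d / 2, d * np.sqrt(3) / 2, 0]])
        rng = np.random.default_rng(0)
        cloud = rng.normal(0, 1, (500, 3))
        cloud *= 16.82 / np.sqrt((cloud ** 2).sum(1).mean())
        cloud -= cloud.mean(0)
        dup = np.vstack([cloud + c for c in centers])
        rg_brute = np.sqrt(((dup - dup.mean(0)) ** 2).sum(1).mean())
        rg_m = np.sqrt((cloud ** 2).sum(1).mean())
        got = m.assembly_rg(rg_m, centers)
        assert got == pytest.approx(rg_brute, rel=1e-12)
        assert got == pytest.approx(np.sqrt(16.82 ** 2 + d ** 2 / 3), rel=1e-3)

    def test_exact_identity_for_point_template(self):
        """assembly_rg equals duplicated-coordinate Rg exactly for point
        scatterers at arbitrary centers."""
        rng = np.random.default_rng(3)
        centers = rng.normal(0, 30, (5, 3))
        dup = centers.copy()                  # point template: Rg_m = 0
        rg_brute = np.sqrt(((dup - dup.mean(0)) ** 2).sum(1).mean())
        assert m.assembly_rg(0.0, centers) == pytest.approx(rg_brute, rel=1e-12)


@pytest.fixture(scope="module")
def library(mesocage_chain, gfp_scatterers):
    lib = []
    for n, lbl in [(1, "monomer"), (2, "dimer_side"), (3, "trimer"),
                   (4, "tetramer")]:
        mod = place_assembly(mesocage_chain, gfp_scatterers, n, lbl)
        mod.label = lbl
        lib.append(mod)
    return lib


class TestClassification:
    def _noisy_curve(self, I, rel=0.01, seed=0):
        rng = np.random.default_rng(seed)
        q = np.geomspace(0.004, 0.3, 150)
        sigma = rel * np.abs(I)
        return m.Curve1D(q, I + rng.normal(0, 1, len(q)) * sigma, sigma)

    def test_self_identification(self, library):
        q = np.geomspace(0.004, 0.3, 150)
        I = library[1].intensity(q) * 3.7e-9
        exp = self._noisy_curve(I)
        res = classify_assembly(exp, library)
        assert res.best_label == "dimer_side"
        assert res.ranking[0][1] < 2.0
        assert not res.no_adequate_candidate

    def test_intensity_scale_invariance(self, library):
        q = np.geomspace(0.004, 0.3, 150)
        exp = self._noisy_curve(library[2].intensity(q))
        r1 = classify_assembly(exp, library)
        exp2 = m.Curve1D(exp.q, 1e-7 * exp.I, 1e-7 * exp.sigma)
        r2 = classify_assembly(exp2, library)
        assert [t[0] for t in r1.ranking] == [t[0] for t in r2.ranking]
        assert r1.ranking[0][1] == pytest.approx(r2.ranking[0][1], rel=1e-6)

    def test_fifty_fifty_mixture_weight_recovered(self, library):
        q = np.geomspace(0.004, 0.3, 150)
        c_dim = library[1].intensity(q)
        c_tri = library[2].intensity(q)
        I = 0.5 * c_dim / c_dim[0] + 0.5 * c_tri / c_tri[0]
        exp = self._noisy_curve(I, rel=0.005, seed=2)
        res = classify_assembly(exp, library)
        top2 = {res.mixture[0], res.mixture[1]}
        assert top2 == {"dimer_side", "trimer"}
        w = res.mixture[2] if res.mixture[0] == "dimer_side" else 1 - res.mixture[2]
        assert w == pytest.approx(0.5, abs=0.1)

    def test_monomer_against_multimer_only_library_flagged(self, mesocage_chain,
                                                           gfp_scatterers,
                                                           library):
        q = np.geomspace(0.004, 0.3, 150)
        mono = library[0]
        I = mono.intensity(q)
        exp = self._noisy_curve(I, rel=0.005, seed=4)
        res = classify_assembly(exp, library[2:], fit_background=False)
        assert res.ranking[0][1] > 2.0
        assert res.no_adequate_candidate

    def test_pr_route_ranks_generator_first(self, library):
        import warnings
        q = np.geomspace(0.004, 0.3, 160)
        I = library[2].intensity(q)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pr = m.ift_pr(m.Curve1D(q, I / I[0], 0.01 * I / I[0]), Dmax=160.0)
            res = classify_assembly(pr, library)
        assert res.metric == "pr_l2"
        assert res.best_label == "trimer"


def test_sphere_proxy_template(mesocage_chain):
    asm = place_assembly(mesocage_chain, 16.82, 2, "dimer_side")
    assert len(asm.scatterers) == 2
    q = np.geomspace(0.001, 0.3, 80)
    I = debye_intensity(asm.scatterers, q)
    assert I[0] == pytest.approx(4.0, rel=1e-3)   # (sum b)^2 with unit beads
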