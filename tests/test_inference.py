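import warnings

import numpy as np
import pytest

import mofsans as m
from mofsans.inference import (
    GuinierModel,
    HierarchicalModel,
    IndirectFourierTransform,
)
from mofsans.models import HierarchicalParams, eval_hierarchical, sphere_form
from mofsans.simulate import GeneratorSpec, default_dry_params, gen_dry_mof


# ---------------------------------------------------------------- fitting

class TestHierarchicalFit:
    def test_noiseless_recovery_of_correlation_length_and_exponent(self):
        """A noiseless synthetic dry-framework curve refits to the truth:
        xi = 265 A within 1%, n = 3.4 within 2%."""
        spec = GeneratorSpec(noise_level=0.0, q_grid=(0.003, 0.25, 250))
        curve = gen_dry_mof(spec)
        res = m.fit_hierarchical(curve, default_dry_params(), seed=0)
        assert res.params.xi == pytest.approx(265.0, rel=0.01)
        assert res.params.n == pytest.approx(3.4, rel=0.02)

    def test_all_fixed_echoes_init_and_direct_chi2(self):
        spec = GeneratorSpec(noise_level=0.002, seed=1)
        curve = gen_dry_mof(spec)
        init = default_dry_params()
        names = HierarchicalModel(curve, init).param_names
        res = m.fit_hierarchical(curve, init, fixed=set(names))
        assert res.params.to_dict() == init.to_dict()
        direct = float(np.sum(((eval_hierarchical(init, curve.q) - curve.I)
                               / curve.sigma) ** 2))
        assert res.chi2 == pytest.approx(direct, rel=1e-12)
        assert res.bse == {}

    def test_too_few_points_rejected(self):
        q = np.geomspace(0.01, 0.1, 12)
        c = m.Curve1D(q, np.ones(12), 0.1 * np.ones(12))
        with pytest.raises(ValueError, match="at least"):
            HierarchicalModel(c, default_dry_params())

    def test_summary_lists_all_parameters(self):
        spec = GeneratorSpec(noise_level=0.0, q_grid=(0.003, 0.25, 250))
        res = m.fit_hierarchical(gen_dry_mof(spec), default_dry_params(), seed=0)
        text = res.summary()
        for name in ("xi", "I_bgd", "q01", "D3"):
            assert name in text

    def test_noisy_parameter_recovery_within_3_sigma(self):
        """With 1% relative noise, xi and n stay within 3 sigma of truth for
        every seed and >= 95% of all free-parameter draws do."""
        truth = default_dry_params()
        td = truth.to_dict()
        q = np.geomspace(0.0015, 0.5, 250)
        I_true = eval_hierarchical(truth, q)
        total = ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            I = I_true * (1.0 + 0.01 * rng.normal(size=len(q)))
            c = m.Curve1D(q, I, 0.01 * I_true)
            res = m.fit_hierarchical(c, truth, n_starts=3, seed=seed)
            fit = res.params.to_dict()
            for k, err in res.bse.items():
                if not err:
                    continue
                total += 1
                within = abs(fit[k] - td[k]) <= 3.0 * err
                ok += within
                if k in ("xi", "n"):
                    assert within, f"{k} off by >3 sigma at seed {seed}"
        assert ok / total >= 0.95

    def test_qgrid_density_independence(self):
        """Recovered parameters shift < 1% when the grid is refined beyond
        the default 250 points."""
        out = {}
        for n_pts in (250, 400):
            spec = GeneratorSpec(noise_level=0.0, q_grid=(0.0015, 0.5, n_pts))
            res = m.fit_hierarchical(gen_dry_mof(spec), default_dry_params(),
                                     seed=0)
            out[n_pts] = res.params
        assert out[400].xi == pytest.approx(out[250].xi, rel=0.01)
        assert out[400].n == pytest.approx(out[250].n, rel=0.01)


# ---------------------------------------------------------------- subtraction

class TestSubtraction:
    def _curve(self, I, q=None, sigma=0.05):
        q = np.geomspace(0.003, 0.4, 120) if q is None else q
        I_arr = np.broadcast_to(I, q.shape).astype(float) if np.ndim(I) == 0 else I
        return m.Curve1D(q, I_arr, sigma * np.ones_like(q))

    def test_identity_subtraction_gives_zero_and_sqrt2_sigma(self):
        c = self._curve(2.0)
        out = m.subtract_matched(c, c, scale=1.0)
        assert np.allclose(out.I, 0.0, atol=1e-12)
        assert np.allclose(out.sigma, np.sqrt(2) * 0.05)
        assert "nonpositive_indices" in out.meta

    def test_zero_scale_returns_composite(self):
        q = np.geomspace(0.003, 0.4, 120)
        comp = self._curve(1.0 / q, q)
        matrix = self._curve(5.0, q)
        out = m.subtract_matched(comp, matrix, scale=0.0)
        assert np.allclose(out.I, comp.I)
        assert np.allclose(out.sigma, comp.sigma)

    def test_interpolated_grids(self):
        qc = np.geomspace(0.004, 0.3, 100)
        qm = np.geomspace(0.003, 0.4, 83)
        comp = m.Curve1D(qc, 3.0 / qc ** 2, 0.01 * 3.0 / qc ** 2)
        matrix = m.Curve1D(qm, 1.0 / qm ** 2, 0.01 / qm ** 2)
        out = m.subtract_matched(comp, matrix)
        assert np.allclose(out.I, 2.0 / out.q ** 2, rtol=1e-6)

    def test_no_overlap_errors(self):
        a = self._curve(1.0, np.geomspace(0.001, 0.002, 20))
        b = self._curve(1.0, np.geomspace(0.01, 0.02, 20))
        with pytest.raises(ValueError, match="overlap"):
            m.subtract_matched(a, b)


# ---------------------------------------------------------------- Guinier

class TestGuinier:
    def test_exact_guinier_curve(self):
        q = np.geomspace(0.003, 0.3, 200)
        I = 100.0 * np.exp(-q ** 2 * 20.0 ** 2 / 3.0)
        g = m.guinier_fit(m.Curve1D(q, I, 0.01 * I))
        assert g.Rg == pytest.approx(20.0, rel=1e-6)
        assert g.I0 == pytest.approx(100.0, rel=1e-6)
        assert g.qmaxRg <= 1.3 + 1e-9

    def test_sphere_rg(self, sphere_curve):
        g = m.guinier_fit(sphere_curve)
        assert g.Rg == pytest.approx(np.sqrt(3.0 / 5.0) * 30.0, rel=0.01)

    def test_gfp_like_cylinder_rg(self):
        q = np.geomspace(0.003, 0.3, 220)
        I = m.cylinder_form(42.0, 12.0, q)
        g = m.guinier_fit(m.Curve1D(q, I, 0.01 * I))
        assert g.Rg == pytest.approx(np.sqrt(42.0 ** 2 / 12 + 12.0 ** 2 / 2),
                                     rel=0.02)

    def test_too_few_positive_points_errors(self):
        q = np.geomspace(0.01, 0.1, 30)
        I = np.full(30, -1.0)
        I[:3] = 1.0
        with pytest.raises(ValueError, match="positive"):
            GuinierModel(m.Curve1D(q, I, np.ones(30))).fit()

    def test_rising_curve_errors(self):
        q = np.geomspace(0.01, 0.1, 50)
        I = q ** 2
        with pytest.raises(ValueError, match="slope"):
            GuinierModel(m.Curve1D(q, I, 0.01 * I)).fit()


# ---------------------------------------------------------------- P(r) / IFT

class TestIFT:
    def test_sphere_pr_peak_and_moments(self, sphere_curve):
        res = m.ift_pr(sphere_curve, Dmax=60.0)
        step = res.r[1] - res.r[0]
        assert res.r[np.argmax(res.pr)] == pytest.approx(1.05 * 30.0, abs=step)
        assert res.pr[0] == 0.0 and res.pr[-1] == 0.0
        g = m.guinier_fit(sphere_curve)
        assert res.Rg_pr == pytest.approx(g.Rg, rel=0.02)
        assert res.I0_pr == pytest.approx(g.I0, rel=0.02)

    def test_forward_transform_reproduces_noisy_curve(self):
        rng = np.random.default_rng(7)
        q = np.geomspace(0.005, 0.5, 260)
        I_true = sphere_form(30.0, q)
        sigma = 0.01 * np.sqrt(I_true * 1.0)
        I = I_true + rng.normal(0, 1, len(q)) * sigma
        res = m.ift_pr(m.Curve1D(q, I, sigma), Dmax=60.0)
        chi2 = np.mean(((res.forward(q) - I) / sigma) ** 2)
        assert 0.5 < chi2 < 2.0

    def test_two_sphere_assembly_shows_cross_mode(self):
        """Dummy dimer: two R = 15 spheres 50 A apart produce P(r) mass
        beyond the monomer diameter, out to ~ 50 + 2R."""
        rng = np.random.default_rng(0)
        n = 400
        beads = []
        for cx in (0.0, 50.0):
            pts = rng.normal(0, 1, (n, 3))
            pts = pts / np.linalg.norm(pts, axis=1)[:, None]
            pts = pts * rng.uniform(0, 15, n)[:, None] ** (1 / 1.0)
            beads.append(pts + [cx, 0, 0])
        from mofsans.models import ScattererSet, debye_intensity
        s = ScattererSet(np.vstack(beads), np.ones(2 * n))
        q = np.geomspace(0.004, 0.4, 200)
        I = debye_intensity(s, q)
        res = m.ift_pr(m.Curve1D(q, I / I[0], 0.01 * I / I[0]), Dmax=85.0)
        # brute-force pair-distance histogram of the bead model as oracle
        from scipy.spatial.distance import pdist
        d = pdist(np.vstack(beads))
        assert d.max() > 70.0
        frac_beyond = res.pr[res.r > 35].sum() / res.pr.sum()
        oracle_frac = (d > 35).mean()
        assert frac_beyond == pytest.approx(oracle_frac, abs=0.15)
        assert len(res.peaks()) >= 2

    def test_ill_conditioned_alpha_zero_errors(self, sphere_curve):
        with pytest.raises(ValueError, match="alpha"):
            m.ift_pr(sphere_curve, Dmax=60.0, alpha=0.0, nonneg=False)

    def test_low_qmin_warning(self):
        q = np.geomspace(0.05, 0.5, 100)
        I = sphere_form(30.0, q)
        with pytest.warns(UserWarning, match="extrapolations"):
            IndirectFourierTransform(m.Curve1D(q, I, 0.01 * I), Dmax=80.0)


class TestDmaxScan:
    def test_sphere_diameter_recovered(self, sphere_curve):
        scan = m.scan_dmax(sphere_curve, (40.0, 90.0))
        assert scan.converged
        assert scan.Dmax == pytest.approx(60.0, abs=5.0)

    def test_guinier_only_data_unconstrained(self):
        q = np.geomspace(0.002, 0.02, 60)          # no high-q content
        I = np.exp(-q ** 2 * 30 ** 2 / 3)
        with pytest.warns(UserWarning, match="plateau"):
            scan = m.scan_dmax(m.Curve1D(q, I, 0.01 * I), (40.0, 90.0),
                               n_grid=7)
        assert not scan.converged
        assert scan.Dmax == 90.0


# ---------------------------------------------------------------- Porod

class TestPorod:
    def test_sphere_volume(self, sphere_curve):
        v = m.porod_volume(sphere_curve)
        assert v == pytest.approx(4.0 / 3.0 * np.pi * 30.0 ** 3, rel=0.03)

    def test_scale_invariance(self, sphere_curve):
        v1 = m.porod_volume(sphere_curve)
        scaled = m.Curve1D(sphere_curve.q, 4.0 * sphere_curve.I,
                           4.0 * sphere_curve.sigma)
        assert m.porod_volume(scaled) == pytest.approx(v1, rel=1e-6)

    def test_grid_refinement_invariance(self):
        vols = []
        for n in (260, 520):
            q = np.geomspace(0.005, 0.5, n)
            I = sphere_form(30.0, q)
            vols.append(m.porod_volume(m.Curve1D(q, I, 0.01 * I)))
        assert vols[1] == pytest.approx(vols[0], rel=0.01)

    def test_cylinder_volume(self):
        q = np.geomspace(0.004, 0.8, 400)
        I = m.cylinder_form(42.0, 12.0, q)
        v = m.porod_volume(m.Curve1D(q, I, 0.01 * I))
        assert v == pytest.approx(np.pi * 12.0 ** 2 * 42.0, rel=0.05)


# ---------------------------------------------------------------- Kratky

class TestKratky:
    def test_transform_is_pointwise_q2I(self, sphere_curve):
        res = m.kratky(sphere_curve)
        assert np.allclose(res.q2I, sphere_curve.q ** 2 * sphere_curve.I)

    def test_globular_vs_chain_classification(self, sphere_curve):
        assert m.kratky(sphere_curve).classification == "folded"
        q = sphere_curve.q
        chain = m.Curve1D(q, q ** -2.0, 0.01 * q ** -2.0)
        assert m.kratky(chain).classification == "not-globular"
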