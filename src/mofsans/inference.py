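"""Parameter estimation from 1D scattering curves.

The module follows a Model/Results layout: a model object is constructed
from a :class:`~mofsans.curves.Curve1D` (plus settings), its ``fit()``
returns a results object carrying estimates, uncertainties, goodness of fit
and a ``summary()`` table.  Thin functional wrappers (``fit_hierarchical``,
``guinier_fit``, ``ift_pr`` ...) are provided for script use.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar, nnls
from scipy.signal import find_peaks

from .curves import Curve1D
from .models import HierarchicalParams, eval_hierarchical

__all__ = [
    "HierarchicalModel", "HierarchicalResults", "fit_hierarchical", "FitError",
    "subtract_matched",
    "GuinierModel", "GuinierResult", "guinier_fit",
    "IndirectFourierTransform", "PofR", "ift_pr",
    "scan_dmax", "DmaxScan",
    "porod_volume", "kratky", "KratkyResult",
]


def _fit_sigma(curve: Curve1D) -> np.ndarray:
    """Usable fit weights: experimental sigma, else sqrt(I) floored at 1% I."""
    sigma = np.array(curve.sigma, dtype=float)
    bad = ~(sigma > 0)
    if np.all(bad):
        raise ValueError("all sigma values are non-positive; cannot weight fit")
    if np.any(bad):
        surrogate = np.sqrt(np.abs(curve.I[bad]))
        sigma[bad] = np.maximum(surrogate, 0.01 * np.abs(curve.I[bad]))
    return sigma


# --------------------------------------------------------------------------
# hierarchical model fitting
# --------------------------------------------------------------------------

class FitError(RuntimeError):
    """Fit failure; carries the best result found so far, if any."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


_PARAM_NAMES = ("A", "n", "B", "xi", "m", "I_bgd")


class _FixedEval:
    """Stand-in minimizer result for an all-parameters-fixed evaluation."""

    def __init__(self, params, chisqr):
        self.params = params
        self.chisqr = chisqr


class HierarchicalModel:
    """Weighted least-squares fit of the hierarchical porous-framework model.

    Parameters
    ----------
    curve : Curve1D
        Data; ``sigma`` is used as the weight (surrogate sqrt(I) with a 1%
        floor where missing).
    init : HierarchicalParams
        Initial values; the number of Gaussian peaks is fixed by ``init``.
    fixed : iterable of str, optional
        Parameter names to hold at their initial value ("A", "n", "B",
        "xi", "m", "I_bgd", "C1", "q01", "D1", ...).
    """

    def __init__(self, curve: Curve1D, init: HierarchicalParams,
                 fixed: set[str] | None = None):
        self.curve = curve
        self.init = init
        self.fixed = set(fixed or ())
        names = list(_PARAM_NAMES)
        for i in range(1, len(init.peaks) + 1):
            names += [f"C{i}", f"q0{i}", f"D{i}"]
        unknown = self.fixed - set(names)
        if unknown:
            raise ValueError(f"unknown fixed parameter names: {sorted(unknown)}")
        self.param_names = names
        n_free = len(names) - len(self.fixed)
        if n_free > 0 and len(curve) < 3 * n_free:
            raise ValueError(
                f"need at least {3 * n_free} points for {n_free} free parameters"
            )
        self._sigma = _fit_sigma(curve)

    # bounds keep every parameter inside the model's validity domain while
    # staying wide enough not to clip a +-50% multi-start perturbation
    def _make_params(self, values: dict[str, float]) -> lmfit.Parameters:
        p = lmfit.Parameters()
        init = self.init.to_dict()
        bounds = {
            "A": (0.0, np.inf), "n": (0.1, 8.0), "B": (0.0, np.inf),
            "xi": (1.0, 1e5), "m": (0.3, 8.0), "I_bgd": (0.0, np.inf),
        }
        qlo, qhi = self.curve.q[0], self.curve.q[-1]
        for name in self.param_names:
            if name.startswith("C"):
                lo, hi = 0.0, np.inf
            elif name.startswith("q0"):
                lo = max(qlo, 0.3 * init[name])
                hi = min(qhi, 3.0 * init[name])
            elif name.startswith("D"):
                lo, hi = 1e-5, 0.3
            else:
                lo, hi = bounds[name]
            val = float(np.clip(values[name], lo if np.isfinite(lo) else None,
                                hi if np.isfinite(hi) else None))
            p.add(name, value=val, min=lo, max=hi, vary=name not in self.fixed)
        return p

    def _residual(self, params: lmfit.Parameters) -> np.ndarray:
        hp = HierarchicalParams.from_dict({k: params[k].value for k in self.param_names})
        return (eval_hierarchical(hp, self.curve.q) - self.curve.I) / self._sigma

    def fit(self, n_starts: int = 5, perturb: float = 0.5, seed: int = 0
            ) -> "HierarchicalResults":
        """Multi-start bounded least squares.

        The first start is ``init`` itself; the remaining ``n_starts - 1``
        perturb every free parameter by a uniform factor in
        [1 - perturb, 1 + perturb], deterministically from ``seed``.
        """
        rng = np.random.default_rng(seed)
        init = self.init.to_dict()
        best = None
        failures: list[str] = []
        for start in range(n_starts):
            values = dict(init)
            if start > 0:
                for name in self.param_names:
                    if name not in self.fixed:
                        values[name] = init[name] * rng.uniform(1 - perturb, 1 + perturb)
            params = self._make_params(values)
            if all(not par.vary for par in params.values()):
                # nothing to optimize: evaluate the residual at init
                resid = self._residual(params)
                result = _FixedEval(params, float(np.sum(resid ** 2)))
            else:
                try:
                    with warnings.catch_warnings():
                        # noiseless data make the covariance scale-free and
                        # lmfit's stderr extraction noisy about it
                        warnings.simplefilter("ignore", RuntimeWarning)
                        result = lmfit.minimize(self._residual, params,
                                                method="least_squares")
                except Exception as err:  # singular Jacobian etc.
                    failures.append(str(err))
                    continue
            if best is None or result.chisqr < best.chisqr:
                best = result
        if best is None:
            raise FitError("all fit starts failed: " + "; ".join(failures))
        return HierarchicalResults(self, best)

    def eval(self, params: HierarchicalParams | None = None) -> np.ndarray:
        return eval_hierarchical(params or self.init, self.curve.q)


class HierarchicalResults:
    """Results of :meth:`HierarchicalModel.fit`.

    Attributes
    ----------
    params : HierarchicalParams
        Best-fit parameters.
    bse : dict
        1-sigma uncertainties for the free parameters only.
    chi2_reduced : float
    fixed_mask : dict of str -> bool
    """

    def __init__(self, model: HierarchicalModel, minimizer_result):
        self.model = model
        self._res = minimizer_result
        values = {k: minimizer_result.params[k].value for k in model.param_names}
        bse = {
            k: minimizer_result.params[k].stderr
            for k in model.param_names
            if k not in model.fixed and minimizer_result.params[k].stderr is not None
        }
        params = HierarchicalParams.from_dict(values)
        # canonical peak order (ascending center); a multi-start fit may
        # converge with the Gaussians permuted
        if len(params.peaks) > 1 and not any(
                name in model.fixed for name in values if name[0] in "CqD"
                and name not in _PARAM_NAMES):
            order = np.argsort([pk[1] for pk in params.peaks])
            if not np.array_equal(order, np.arange(len(params.peaks))):
                params.peaks = [params.peaks[i] for i in order]
                newbse = dict(bse)
                for new_i, old_i in enumerate(order, start=1):
                    for stem in ("C", "q0", "D"):
                        key_old = f"{stem}{old_i + 1}"
                        if key_old in bse:
                            newbse[f"{stem}{new_i}"] = bse[key_old]
                bse = newbse
        self.params = params
        self.bse = bse
        dof = max(1, len(model.curve) - (len(model.param_names) - len(model.fixed)))
        self.chi2 = float(minimizer_result.chisqr)
        self.chi2_reduced = self.chi2 / dof
        self.fixed_mask = {k: (k in model.fixed) for k in model.param_names}

    @property
    def fittedvalues(self) -> np.ndarray:
        return eval_hierarchical(self.params, self.model.curve.q)

    def summary(self) -> str:
        rows = []
        d = self.params.to_dict()
        for name in self.model.param_names:
            rows.append({
                "parameter": name,
                "value": d[name],
                "stderr": self.bse.get(name, np.nan),
                "fixed": self.fixed_mask[name],
            })
        table = pd.DataFrame(rows).to_string(index=False, float_format="{:.6g}".format)
        head = (f"Hierarchical model fit | n_points={len(self.model.curve)} "
                f"n_peaks={len(self.params.peaks)} chi2_red={self.chi2_reduced:.4g}")
        return head + "\n" + table

    def to_config(self) -> str:
        """Results block in the ``name: value +- sigma`` config format."""
        lines = [f"chi2_reduced: {self.chi2_reduced:.6g}"]
        d = self.params.to_dict()
        for name in self.model.param_names:
            err = self.bse.get(name)
            tail = f" +- {err:.4g}" if err is not None else " (fixed)" \
                if self.fixed_mask[name] else ""
            lines.append(f"{name}: {d[name]:.8g}{tail}")
        return "\n".join(lines) + "\n"


def fit_hierarchical(curve: Curve1D, init: HierarchicalParams,
                     fixed: set[str] | None = None, n_starts: int = 5,
                     perturb: float = 0.5, seed: int = 0) -> HierarchicalResults:
    """Functional wrapper around :class:`HierarchicalModel`."""
    return HierarchicalModel(curve, init, fixed).fit(n_starts=n_starts,
                                                     perturb=perturb, seed=seed)


# --------------------------------------------------------------------------
# matched-background subtraction
# --------------------------------------------------------------------------

def _loglog_interp(qt: np.ndarray, q: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Interpolate y(q) onto qt, linear in (log q, log y); falls back to
    linear-in-log-q where y <= 0."""
    lqt, lq = np.log(qt), np.log(q)
    if np.all(y > 0):
        return np.exp(np.interp(lqt, lq, np.log(y)))
    return np.interp(lqt, lq, y)


def subtract_matched(composite: Curve1D, matrix: Curve1D,
                     scale: float = 1.0) -> Curve1D:
    """Subtract the (scaled) residual matrix curve from a composite curve.

    The matrix is interpolated onto the composite grid (log-log linear);
    uncertainties add in quadrature; extrapolation outside the matrix
    q-range is refused, so the output lives on the overlapping range.
    Points with non-positive result are flagged in
    ``meta["nonpositive_indices"]``, not dropped.
    """
    qlo = max(composite.q[0], matrix.q[0])
    qhi = min(composite.q[-1], matrix.q[-1])
    if qlo >= qhi:
        raise ValueError("no overlapping q range between composite and matrix")
    sub = composite.trimmed(qlo, qhi)
    i_m = _loglog_interp(sub.q, matrix.q, matrix.I)
    s_m = _loglog_interp(sub.q, matrix.q, matrix.sigma)
    I_out = sub.I - scale * i_m
    s_out = np.sqrt(sub.sigma ** 2 + scale ** 2 * s_m ** 2)
    meta = dict(sub.meta)
    meta["subtraction_scale"] = repr(scale)
    flagged = np.flatnonzero(I_out <= 0)
    if len(flagged):
        meta["nonpositive_indices"] = ",".join(map(str, flagged.tolist()))
    return Curve1D(sub.q, I_out, s_out, sub.dq, meta)


# --------------------------------------------------------------------------
# Guinier analysis
# --------------------------------------------------------------------------

@dataclasses.dataclass
class GuinierResult:
    """Result of a Guinier fit: ln I = ln I0 - q^2 Rg^2 / 3 at low q."""

    Rg: float
    I0: float
    q_window: tuple[float, float]
    qmaxRg: float
    r2: float
    n_points: int

    def summary(self) -> str:
        return (f"Guinier fit: Rg = {self.Rg:.2f} A, I0 = {self.I0:.4g}, "
                f"window q = [{self.q_window[0]:.4g}, {self.q_window[1]:.4g}] "
                f"({self.n_points} pts), qmax*Rg = {self.qmaxRg:.2f}, "
                f"r^2 = {self.r2:.4f}")


class GuinierModel:
    """Iterative low-q Guinier window selection and weighted fit.

    ln I is regressed on q^2 over the largest window with qmax*Rg below the
    validity limit.  A quadratic correction term in q^2 (i.e. a q^4 term) is
    included when the window holds enough points and is statistically
    significant; it absorbs the leading departure from the pure Guinier law
    (noticeable for compact shapes already at qRg ~ 1.3) so the reported Rg,
    taken from the q^2 coefficient, is unbiased by the window choice.
    """

    def __init__(self, curve: Curve1D, qmaxRg_limit: float = 1.3,
                 min_points: int = 5):
        self.curve = curve
        self.limit = qmaxRg_limit
        self.min_points = min_points

    def _linfit(self, k: int) -> tuple[float, float, float]:
        """Weighted (optionally quadratic-corrected) fit of ln I on q^2 over
        the first k usable points; returns (slope at q^2 -> 0, intercept, r2)."""
        c = self.curve
        q2 = c.q[:k] ** 2
        y = np.log(c.I[:k])
        sigma = _fit_sigma(c)[:k]
        w = (c.I[:k] / sigma) ** 2          # var(ln I) = (sigma/I)^2
        sw = np.sqrt(w)

        def wpolyfit(deg: int):
            X = np.vander(q2, deg + 1, increasing=True)
            coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
            resid = y - X @ coef
            ss_res = float(np.sum(w * resid ** 2))
            return coef, ss_res

        coef1, ss1 = wpolyfit(1)
        slope, intercept = coef1[1], coef1[0]
        use_quad = k >= 2 * self.min_points
        if use_quad:
            coef2, ss2 = wpolyfit(2)
            # keep the correction only if it significantly improves the fit
            # (F-like criterion) and does not flip the leading slope sign
            improved = ss2 < ss1 * (1.0 - 2.0 / max(k - 3, 1))
            if improved and coef2[1] < 0:
                slope, intercept = coef2[1], coef2[0]
                ss1 = ss2
        ym = np.sum(w * y) / np.sum(w)
        ss_tot = float(np.sum(w * (y - ym) ** 2))
        r2 = 1.0 - ss1 / ss_tot if ss_tot > 0 else 1.0
        return float(slope), float(intercept), r2

    def fit(self, max_iter: int = 50) -> GuinierResult:
        c = self.curve
        n_pos = int(np.argmax(c.I <= 0)) if np.any(c.I <= 0) else len(c)
        if n_pos < self.min_points:
            raise ValueError("fewer than 5 positive low-q intensities")
        k = n_pos
        seen: set[int] = set()
        for _ in range(max_iter):
            seen.add(k)
            slope, intercept, r2 = self._linfit(k)
            if slope >= 0:
                # no decay visible: shrink window and retry
                if k <= self.min_points:
                    raise ValueError("no negative Guinier slope found at low q")
                k = max(self.min_points, k // 2)
                continue
            rg = float(np.sqrt(-3.0 * slope))
            k_new = int(np.searchsorted(c.q[:n_pos], self.limit / rg, side="right"))
            k_new = max(self.min_points, min(k_new, n_pos))
            if k_new in seen and k_new != k:
                # cycling between adjacent windows: accept the smaller one
                k_new = min(k, k_new)
            if k_new == k:
                return GuinierResult(
                    Rg=rg, I0=float(np.exp(intercept)),
                    q_window=(float(c.q[0]), float(c.q[k - 1])),
                    qmaxRg=float(c.q[k - 1] * rg), r2=float(r2), n_points=k,
                )
            k = k_new
        raise ValueError("Guinier window selection did not converge")


def guinier_fit(curve: Curve1D, qmaxRg_limit: float = 1.3) -> GuinierResult:
    """Functional wrapper around :class:`GuinierModel`."""
    return GuinierModel(curve, qmaxRg_limit=qmaxRg_limit).fit()


# --------------------------------------------------------------------------
# indirect Fourier transform P(r)
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PofR:
    """Pair-distance distribution on [0, Dmax] with derived quantities.

    P(0) = P(Dmax) = 0 are imposed; Rg and I(0) come from the moments
    Rg^2 = int r^2 P dr / (2 int P dr) and I0 = 4 pi int P dr.
    """

    r: np.ndarray
    pr: np.ndarray
    Dmax: float
    Rg_pr: float
    I0_pr: float
    alpha: float
    chi2_reduced: float
    V_porod: float | None = None
    misfit_warning: bool = False

    def peaks(self, prominence_frac: float = 0.05) -> np.ndarray:
        """r positions of P(r) local maxima above a prominence threshold."""
        idx, _ = find_peaks(self.pr, prominence=prominence_frac * self.pr.max())
        return self.r[idx]

    def forward(self, q: np.ndarray) -> np.ndarray:
        """I(q) = 4 pi int P(r) sinc(qr) dr for this P(r)."""
        K = _ift_kernel(np.asarray(q, dtype=float), self.r)
        return K @ self.pr

    def summary(self) -> str:
        pk = ", ".join(f"{p:.1f}" for p in self.peaks())
        vp = f"{self.V_porod:.4g}" if self.V_porod is not None else "n/a"
        return (f"P(r): Dmax = {self.Dmax:.1f} A, Rg = {self.Rg_pr:.2f} A, "
                f"I0 = {self.I0_pr:.4g}, alpha = {self.alpha:.3g}, "
                f"chi2_red = {self.chi2_reduced:.3g}, V_porod = {vp} A^3, "
                f"peaks at r = [{pk}] A")


def _ift_kernel(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Trapezoid-weighted kernel K[i,j] = 4 pi w_j sinc(q_i r_j)."""
    w = np.gradient(r)
    w[0] *= 0.5
    w[-1] *= 0.5
    return 4.0 * np.pi * np.sinc(np.outer(q, r) / np.pi) * w


class IndirectFourierTransform:
    """Regularized indirect Fourier transform of a 1D scattering curve.

    Expands P(r) on ``n_r`` grid points over [0, Dmax] with P(0) = P(Dmax)
    = 0 and solves the sigma-weighted linear inverse problem

        I(q) = 4 pi int_0^Dmax P(r) sin(qr)/(qr) dr

    with second-difference (curvature) smoothness regularization of weight
    ``alpha`` and optional nonnegativity (default on).  When ``alpha`` is
    not supplied it is chosen automatically (see :meth:`_auto_alpha`).
    """

    def __init__(self, curve: Curve1D, Dmax: float, alpha: float | None = None,
                 n_r: int = 101, nonneg: bool = True):
        if Dmax <= 0:
            raise ValueError("Dmax must be positive")
        if curve.q[0] * Dmax > np.pi:
            warnings.warn("lowest q resolves only r > pi/q_min; "
                          "I(0) and Rg will be extrapolations", stacklevel=2)
        self.curve = curve
        self.Dmax = float(Dmax)
        self.alpha = alpha
        self.n_r = n_r
        self.nonneg = nonneg
        self.r = np.linspace(0.0, Dmax, n_r)
        sigma = _fit_sigma(curve)
        K = _ift_kernel(curve.q, self.r)
        # endpoint values are fixed to zero: solve for interior nodes only
        self._A = (K / sigma[:, None])[:, 1:-1]
        self._y = curve.I / sigma
        # second-difference operator acting on the full vector (with the
        # zero endpoints included, so curvature at the ends is penalized too)
        n_in = n_r - 2
        L = np.zeros((n_r - 2, n_in))
        for j in range(n_r - 2):
            for k, c in ((j - 1, 1.0), (j, -2.0), (j + 1, 1.0)):
                if 0 <= k < n_in:
                    L[j, k] = c
        self._L = L

    def _solve(self, alpha: float) -> tuple[np.ndarray, float, float]:
        A, y, L = self._A, self._y, self._L
        if alpha == 0:
            cond = np.linalg.cond(A)
            if cond > 1e10:
                raise ValueError(
                    f"system is ill-conditioned (cond ~ {cond:.2g}) at alpha = 0; "
                    "supply a positive regularization weight alpha"
                )
        stacked = np.vstack([A, alpha * L])
        rhs = np.concatenate([y, np.zeros(L.shape[0])])
        if self.nonneg:
            try:
                p, _ = nnls(stacked, rhs, maxiter=50 * stacked.shape[1])
            except RuntimeError:
                # active-set stall on ill-conditioned trials: fall back to a
                # bounded least-squares solve
                from scipy.optimize import lsq_linear
                p = lsq_linear(stacked, rhs, bounds=(0.0, np.inf),
                               method="bvls", max_iter=200).x
        else:
            p, *_ = np.linalg.lstsq(stacked, rhs, rcond=None)
        resid = float(np.sum((A @ p - y) ** 2))
        seminorm = float(np.sum((L @ p) ** 2))
        return p, resid, seminorm

    def _auto_alpha(self) -> float:
        """Discrepancy-style choice: the largest trial alpha whose reduced
        chi2 stays within max(1.0, 1.2 * chi2_min).

        With the nonnegativity constraint active the classical L-curve is
        degenerate (the solution seminorm barely responds to alpha), so the
        selection maximizes smoothing subject to not degrading the fit
        beyond the noise level.
        """
        a0 = np.linalg.norm(self._A) / max(np.linalg.norm(self._L), 1e-12)
        alphas = a0 * np.logspace(-6, 2, 17)
        dof = max(1, len(self.curve) - self._A.shape[1])
        chi2 = np.empty(len(alphas))
        for i, al in enumerate(alphas):
            _, resid, _ = self._solve(al)
            chi2[i] = resid / dof
        threshold = max(1.0, 1.2 * float(chi2.min()))
        ok = np.flatnonzero(chi2 <= threshold)
        return float(alphas[ok.max()]) if len(ok) else float(alphas[0])

    def fit(self) -> PofR:
        alpha = self.alpha if self.alpha is not None else self._auto_alpha()
        p_in, resid, _ = self._solve(alpha)
        pr = np.concatenate([[0.0], p_in, [0.0]])
        dof = max(1, len(self.curve) - len(p_in))
        chi2_red = resid / dof
        w = np.gradient(self.r)
        total = float(np.sum(pr * w))
        if total <= 0:
            raise ValueError("P(r) integrates to <= 0; check Dmax and data")
        rg2 = float(np.sum(self.r ** 2 * pr * w)) / (2.0 * total)
        i0 = 4.0 * np.pi * total
        misfit = chi2_red > 5.0
        if misfit:
            warnings.warn(f"systematic misfit (chi2_red = {chi2_red:.3g}); "
                          "Dmax may be too small", stacklevel=2)
        return PofR(r=self.r, pr=pr, Dmax=self.Dmax, Rg_pr=float(np.sqrt(rg2)),
                    I0_pr=i0, alpha=alpha, chi2_reduced=chi2_red,
                    misfit_warning=misfit)


def ift_pr(curve: Curve1D, Dmax: float, alpha: float | None = None,
           n_r: int = 101, nonneg: bool = True) -> PofR:
    """Functional wrapper around :class:`IndirectFourierTransform`."""
    return IndirectFourierTransform(curve, Dmax, alpha=alpha, n_r=n_r,
                                    nonneg=nonneg).fit()


# --------------------------------------------------------------------------
# Dmax scan
# --------------------------------------------------------------------------

@dataclasses.dataclass
class DmaxScan:
    Dmax: float
    grid: np.ndarray
    chi2: np.ndarray
    converged: bool

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame({"Dmax": self.grid, "chi2_reduced": self.chi2})


def scan_dmax(curve: Curve1D, dmax_range: tuple[float, float],
              alpha: float | None = None, n_grid: int = 13,
              rel_tol: float = 0.02) -> DmaxScan:
    """Estimate Dmax as the smallest value where the IFT fit quality plateaus.

    Runs the IFT over a Dmax grid; returns the smallest Dmax whose reduced
    chi2 is within ``rel_tol`` (relative) of the next grid value's and whose
    P(r) carries negligible weight at the endpoint.  Without a plateau the
    upper bound is returned with ``converged=False`` and a warning.
    """
    lo, hi = dmax_range
    if not 0 < lo < hi:
        raise ValueError("invalid Dmax range")
    grid = np.linspace(lo, hi, n_grid)
    if alpha is None:
        # one shared weight so chi2 is comparable across the grid
        alpha = IndirectFourierTransform(curve, hi)._auto_alpha()
    chi2 = np.empty(n_grid)
    end_ok = np.empty(n_grid, dtype=bool)
    for i, dm in enumerate(grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ift_pr(curve, dm, alpha=alpha)
        chi2[i] = res.chi2_reduced
        # mass near the endpoint signals truncation; the 10% threshold
        # allows for regularization smearing on noisy data
        tail = res.pr[-6:-1]
        end_ok[i] = tail.max() <= 0.10 * res.pr.max()
    chi2_min = float(chi2.min())
    for i in range(n_grid - 1):
        # denominator floored at 1: changes far below the chi2 ~ 1 noise
        # floor do not signal structure
        rel = abs(chi2[i] - chi2[i + 1]) / max(chi2[i], 1.0)
        at_floor = chi2[i] <= chi2_min * (1.0 + 2.0 * rel_tol) + 1e-12
        if (rel < rel_tol or at_floor) and end_ok[i]:
            return DmaxScan(float(grid[i]), grid, chi2, True)
    warnings.warn("no chi2 plateau in the scanned Dmax range; "
                  "returning the upper bound", stacklevel=2)
    return DmaxScan(float(hi), grid, chi2, False)


# --------------------------------------------------------------------------
# Porod invariant / volume and Kratky transform
# --------------------------------------------------------------------------

def porod_volume(curve: Curve1D, I0: float | None = None,
                 Rg: float | None = None, background: float = 0.0,
                 n_tail: int | None = None) -> float:
    """Porod (excluded) volume V_p = 2 pi^2 I(0) / Q, in A^3.

    The invariant Q = int q^2 I dq is computed by trapezoidal integration
    over the data (after subtracting ``background``), extended to q = 0 with
    the Guinier form I0 exp(-q^2 Rg^2/3) and to q -> infinity with a Porod
    q^-4 tail whose level averages q^4 I over the last ``n_tail`` points
    (the default, a quarter of the curve, spans several form-factor
    oscillations).  I0 and Rg come from a Guinier fit when not supplied.
    """
    if I0 is None or Rg is None:
        g = guinier_fit(curve)
        I0 = I0 if I0 is not None else g.I0
        Rg = Rg if Rg is not None else g.Rg
    I_net = curve.I - background
    Q_data = float(np.trapezoid(curve.q ** 2 * I_net, curve.q))
    # low-q Guinier extension on a fine grid
    q_lo = np.linspace(0.0, curve.q[0], 200)
    Q_lo = float(np.trapezoid(q_lo ** 2 * I0 * np.exp(-q_lo ** 2 * Rg ** 2 / 3.0), q_lo))
    # high-q Porod tail: I ~ Ap / q^4  ->  int_qmax^inf q^2 I dq = Ap / qmax
    if n_tail is None:
        n_tail = max(10, len(curve) // 4)
    tail = slice(-n_tail, None)
    Ap = float(np.mean(curve.q[tail] ** 4 * I_net[tail]))
    Q_hi = max(Ap, 0.0) / curve.q[-1]
    Q = Q_data + Q_lo + Q_hi
    if Q <= 0:
        raise ValueError("non-positive Porod invariant")
    return 2.0 * np.pi ** 2 * I0 / Q


@dataclasses.dataclass
class KratkyResult:
    q: np.ndarray
    q2I: np.ndarray
    classification: str  # "folded" or "not-globular"

    def summary(self) -> str:
        return f"Kratky: classified {self.classification}"


def kratky(curve: Curve1D) -> KratkyResult:
    """Kratky transform q^2 I(q) with a folded/unfolded heuristic.

    A compact folded particle shows a bell-shaped maximum followed by decay;
    a chain-like or unfolded one rises monotonically to a plateau.  The
    heuristic: the global maximum of (lightly smoothed) q^2 I must sit in
    the first 70% of the q range and the final 20% must fall below 60% of
    the maximum.
    """
    y = curve.q ** 2 * curve.I
    n = len(y)
    k = max(1, n // 25)
    ys = np.convolve(y, np.ones(2 * k + 1) / (2 * k + 1), mode="same")
    imax = int(np.argmax(ys))
    tail = ys[int(0.8 * n):]
    folded = (imax < 0.7 * n) and (tail.mean() < 0.6 * ys[imax])
    return KratkyResult(curve.q.copy(), y,
                        "folded" if folded else "not-globular")
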