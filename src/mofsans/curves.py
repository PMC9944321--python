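"""Reduced 1D small-angle scattering curves and their ASCII on-disk format.

The canonical reduced-SAS dialect is whitespace-delimited columns
``q  I  sigma  [dq]`` with ``# key: value`` header lines.  ``q`` is the
momentum transfer in 1/Angstrom, ``I`` the azimuthally averaged intensity in
1/cm (absolute scale unless the metadata says otherwise), ``sigma`` the
one-sigma counting uncertainty of ``I`` and ``dq`` an optional Gaussian
resolution width.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = ["Curve1D", "read_curve", "write_curve", "CurveParseError"]


class CurveParseError(ValueError):
    """Raised when an ASCII curve file cannot be parsed."""


@dataclasses.dataclass
class Curve1D:
    """A reduced 1D scattering profile.

    Parameters
    ----------
    q : ndarray
        Momentum transfer, 1/Angstrom, strictly increasing and positive.
    I : ndarray
        Intensity, 1/cm on absolute scale (or arbitrary units if
        ``meta["absolute_scale"] == "false"``).
    sigma : ndarray
        One-sigma uncertainty of ``I``, same units.
    dq : ndarray, optional
        Resolution width, 1/Angstrom.
    meta : dict of str -> str
        Free-form metadata (sample label, D2O fraction, dry/wet state ...).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    dq: np.ndarray | None = None
    meta: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise ValueError("q, I and sigma must have equal length")
        if self.dq is not None and len(self.dq) != len(self.q):
            raise ValueError("dq must match q in length")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) == 0):
            raise ValueError("duplicate q values")
        if np.any(np.diff(self.q) < 0):
            raise ValueError("q must be strictly increasing (use read_curve to sort)")

    def __len__(self) -> int:
        return len(self.q)

    def trimmed(self, qmin: float = -np.inf, qmax: float = np.inf) -> "Curve1D":
        """Return the sub-curve with qmin <= q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        return Curve1D(
            self.q[m], self.I[m], self.sigma[m],
            None if self.dq is None else self.dq[m], dict(self.meta),
        )

    def plot(self, ax=None, **kwargs):
        """Log-log errorbar plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.q, self.I, yerr=self.sigma, fmt=".", **kwargs)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(r"q ($\mathrm{\AA}^{-1}$)")
        ax.set_ylabel(r"I(q) (cm$^{-1}$)")
        return ax


def read_curve(path: str | Path, dialect: str = "auto") -> Curve1D:
    """Read an ASCII scattering curve.

    ``# key: value`` lines become metadata; numeric rows must have three
    (``q I sigma``) or four (``q I sigma dq``) columns.  If rows arrive in
    descending or shuffled q order they are sorted and ``meta["sorted"]`` is
    set to ``"true"``.

    Parameters
    ----------
    path : path
    dialect : {"auto", "three_col", "four_col"}
        Expected column count; "auto" infers it from the first numeric row.
    """
    if dialect not in ("auto", "three_col", "four_col"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    ncol = {"three_col": 3, "four_col": 4}.get(dialect)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise CurveParseError(
                    f"{path}: non-numeric payload on line {lineno}: {line!r}"
                ) from None
            if len(vals) not in (3, 4):
                raise CurveParseError(
                    f"{path}: expected 3 or 4 columns on line {lineno}, got {len(vals)}"
                )
            if ncol is None:
                ncol = len(vals)
            elif len(vals) != ncol:
                raise CurveParseError(
                    f"{path}: inconsistent column count on line {lineno}"
                )
            rows.append(vals)
    if not rows:
        raise CurveParseError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    q = arr[:, 0]
    if len(np.unique(q)) != len(q):
        raise CurveParseError(f"{path}: duplicate q values")
    order = np.argsort(q)
    if not np.array_equal(order, np.arange(len(q))):
        arr = arr[order]
        meta["sorted"] = "true"
    dq = arr[:, 3] if arr.shape[1] == 4 else None
    return Curve1D(arr[:, 0], arr[:, 1], arr[:, 2], dq, meta)


def write_curve(curve: Curve1D, path: str | Path) -> None:
    """Write a curve in the ASCII dialect read by :func:`read_curve`.

    Values are printed with 10 significant digits so a read/write round trip
    is the identity to full printed precision.
    """
    path = Path(path)
    with path.open("w") as fh:
        for key, val in curve.meta.items():
            fh.write(f"# {key}: {val}\n")
        cols = [curve.q, curve.I, curve.sigma]
        if curve.dq is not None:
            cols.append(curve.dq)
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
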