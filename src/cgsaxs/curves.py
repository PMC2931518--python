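"""Scattering-curve container and ASCII I/O.

Curves are stored as plain arrays of q (1/Angstrom), intensity (arbitrary
units) and optional per-point standard deviations.  On disk they use the
3-column whitespace ``q I sigma`` dialect with ``#`` comment headers;
2-column files (no sigma) and 5-column CRYSOL ``.int`` files are read too.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


class CurveError(ValueError):
    """Raised for invalid curve content or unreadable curve files."""


@dataclass
class ScatteringCurve:
    """A 1-D SAXS intensity profile I(q)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise CurveError("q and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.q) <= 0):
            raise CurveError("q values must be strictly increasing")
        i0 = abs(self.intensity[0]) if self.intensity.size else 0.0
        if np.any(self.intensity < -1e-9 * max(i0, 1.0)):
            raise CurveError("intensities are significantly negative")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise CurveError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise CurveError("sigma values must be positive")

    def __len__(self) -> int:
        return self.q.size

    def same_grid(self, other: "ScatteringCurve", tol: float = 1e-9) -> bool:
        return (len(self) == len(other)
                and bool(np.allclose(self.q, other.q, atol=tol, rtol=0)))


def write_dat(curve: ScatteringCurve, path, header: str = "cgsaxs curve") -> None:
    """Write a curve as 3-column (or 2-column, if no sigma) ASCII."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {header}\n")
        for i in range(len(curve)):
            if curve.sigma is not None:
                fh.write(f"{curve.q[i]:.6e} {curve.intensity[i]:.8e} "
                         f"{curve.sigma[i]:.8e}\n")
            else:
                fh.write(f"{curve.q[i]:.6e} {curve.intensity[i]:.8e}\n")


def _read_numeric_rows(path) -> np.ndarray:
    rows = []
    ncols = None
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith(("#", ";")):
                continue
            parts = s.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                continue          # header line (e.g. CRYSOL title)
            if ncols is None:
                ncols = len(vals)
            if len(vals) == ncols:
                rows.append(vals)
    if not rows:
        raise CurveError(f"no numeric data rows in {path}")
    return np.asarray(rows, dtype=float)


def read_dat(path) -> ScatteringCurve:
    """Read a 2- or 3-column ASCII curve (``q I [sigma]``)."""
    data = _read_numeric_rows(path)
    if data.shape[1] < 2:
        raise CurveError(f"{path}: expected at least 2 columns")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return ScatteringCurve(data[:, 0], data[:, 1], sigma)


def read_int(path) -> ScatteringCurve:
    """Read a CRYSOL ``.int`` file (column 1 = q, column 2 = total intensity)."""
    data = _read_numeric_rows(path)
    if data.shape[1] < 2:
        raise CurveError(f"{path}: expected at least 2 columns")
    return ScatteringCurve(data[:, 0], data[:, 1], None)
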