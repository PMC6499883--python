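"""Statistical Total Correlation Spectroscopy (STOCSY).

Pearson correlation of spectral intensities across samples.  Points of one
molecule are collinear (they all scale with that molecule's concentration),
so intramolecular correlations approach 1; pathway-linked metabolites
correlate more weakly, and anti-correlations (e.g. hydrolysis substrate vs
products) appear with negative r.  The full points × points matrix is the
2D representation; the row at a chosen driver resonance is the 1D trace,
conventionally colour-coded on the mean spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import SpectralMatrix


@dataclass
class Stocsy2D:
    """Full correlation matrix with a thresholded display view."""

    r: np.ndarray
    ppm: np.ndarray
    threshold_r2: float
    zero_variance_columns: list[int] = field(default_factory=list)

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    @property
    def masked(self) -> np.ndarray:
        """Display view: entries with r² below threshold set to NaN."""
        out = self.r.copy()
        out[self.r2 < self.threshold_r2] = np.nan
        return out

    def to_triplets(self) -> pd.DataFrame:
        """Sparse upper-triangle (ppm_i, ppm_j, r) rows above threshold."""
        iu, ju = np.triu_indices_from(self.r, k=1)
        keep = self.r2[iu, ju] >= self.threshold_r2
        return pd.DataFrame({
            "ppm_i": self.ppm[iu[keep]],
            "ppm_j": self.ppm[ju[keep]],
            "r": self.r[iu[keep], ju[keep]],
        })


@dataclass
class Stocsy1D:
    """Driver-peak correlation trace over the retained axis."""

    driver_ppm: float          # requested driver position
    driver_column_ppm: float   # retained column actually used
    ppm: np.ndarray
    projection: np.ndarray     # mean of all spectra
    r: np.ndarray

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ppm": self.ppm, "projection": self.projection,
            "r": self.r, "r2": self.r2,
        })


def _column_correlations(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each column of X against y; zero-variance columns -> 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    zero = sx <= 0
    Z = Xc / np.where(zero, 1.0, sx)
    z = yc / sy if sy > 0 else yc
    r = Z.T @ z
    r[zero] = 0.0
    if sy <= 0:
        r[:] = 0.0
    return np.clip(r, -1.0, 1.0), zero


def stocsy_2d(m: SpectralMatrix, threshold_r2: float = 0.85,
              decimate: int = 1) -> Stocsy2D:
    """Full correlation matrix between retained spectral points.

    ``decimate`` keeps every k-th column — a plotting-memory control only
    (the matrix is quadratic in points); statistics are unchanged on the
    kept columns.  Zero-variance columns get r = 0 everywhere off their
    diagonal and are reported in ``zero_variance_columns``.
    """
    if m.n_samples < 3:
        raise ValueError("STOCSY needs at least 3 samples")
    if not (0 <= threshold_r2 < 1):
        raise ValueError("threshold_r2 must be in [0, 1)")
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    X = m.X[:, ::decimate]
    ppm = m.ppm[::decimate]
    Xc = X - X.mean(axis=0)
    s = np.sqrt((Xc**2).sum(axis=0))
    zero = np.where(s <= 0)[0]
    safe = np.where(s <= 0, 1.0, s)
    Z = Xc / safe
    r = np.clip(Z.T @ Z, -1.0, 1.0)
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.fill_diagonal(r, 1.0)
    return Stocsy2D(r, ppm.copy(), threshold_r2, list(zero))


def stocsy_1d(m: SpectralMatrix, driver_ppm: float) -> Stocsy1D:
    """Correlation vector of the driver column against every retained point.

    The driver maps to the nearest retained column; if the requested
    position falls in an excluded gap (further than 1.5 axis steps from any
    retained point) the error names the nearest retained ppm.
    """
    if m.n_samples < 3:
        raise ValueError("STOCSY needs at least 3 samples")
    idx = m.nearest_index(driver_ppm)
    step = np.median(np.abs(np.diff(m.ppm)))
    dist = abs(m.ppm[idx] - driver_ppm)
    if dist > 1.5 * step:
        raise ValueError(
            f"driver {driver_ppm} ppm lies in an excluded region; "
            f"nearest retained point is {m.ppm[idx]:.4f} ppm"
        )
    r, _ = _column_correlations(m.X, m.X[:, idx])
    r[idx] = 1.0
    return Stocsy1D(driver_ppm, float(m.ppm[idx]), m.ppm.copy(),
                    m.X.mean(axis=0), r)
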