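"""Spectral-matrix construction: alignment, region exclusion, normalization.

The matrix is samples × points on one shared descending ppm axis.  Alignment
is segment-wise integer-point correlation shifting against the mean spectrum
(interval-correlation-shifting practice); exclusion removes the residual
water / reference-standard windows; each retained row is then normalized to
unit total intensity.  Order is fixed: exclude, then normalize.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reconstruction import Spectrum

#: Residual-water window (ppm) excluded before any statistics.
WATER_REGION = (4.66, 5.18)
#: Default exclusions: water plus the TSP / upfield reference-standard edge
#: and the downfield empty region (standard windows are configurable; the
#: study's exact ones are not published).
DEFAULT_EXCLUSIONS = (WATER_REGION, (-0.5, 0.5), (9.0, 10.0))


@dataclass
class SpectralMatrix:
    """Samples × points intensity matrix with group labels."""

    X: np.ndarray
    ppm: np.ndarray
    sample_ids: list[str]
    group_labels: list[str]
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.X.ndim != 2 or self.X.shape != (len(self.sample_ids), self.ppm.size):
            raise ValueError(
                f"matrix shape {self.X.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {self.ppm.size} points"
            )
        if len(self.group_labels) != len(self.sample_ids):
            raise ValueError("group labels and sample ids differ in length")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_points(self) -> int:
        return self.X.shape[1]

    def nearest_index(self, ppm: float) -> int:
        return int(np.argmin(np.abs(self.ppm - ppm)))

    def copy(self) -> "SpectralMatrix":
        return SpectralMatrix(self.X.copy(), self.ppm.copy(), list(self.sample_ids),
                              list(self.group_labels), list(self.excluded_regions),
                              self.normalized)


def matrix_from_spectra(spectra: dict[str, Spectrum] | list[Spectrum],
                        groups: dict[str, str]) -> SpectralMatrix:
    """Stack spectra (which must share their axis) into a matrix."""
    items = list(spectra.values()) if isinstance(spectra, dict) else list(spectra)
    if not items:
        raise ValueError("no spectra given")
    ppm = items[0].ppm
    for sp in items[1:]:
        if sp.ppm.shape != ppm.shape or not np.array_equal(sp.ppm, ppm):
            raise ValueError(f"sample {sp.sample_id!r} is not on the shared ppm axis")
    ids = [sp.sample_id for sp in items]
    return SpectralMatrix(
        np.vstack([sp.intensity for sp in items]), ppm.copy(), ids,
        [groups[sid] for sid in ids],
    )


def _shift_segment(seg: np.ndarray, s: int) -> np.ndarray:
    """Shift right by s points (left for negative), edge-value fill."""
    if s == 0:
        return seg
    out = np.empty_like(seg)
    if s > 0:
        out[s:] = seg[:-s]
        out[:s] = seg[0]
    else:
        out[:s] = seg[-s:]
        out[s:] = seg[-1]
    return out


def align(m: SpectralMatrix, n_segments: int = 1, max_shift: int = 20) -> SpectralMatrix:
    """Segment-wise integer alignment against the mean spectrum.

    Each row is split into ``n_segments`` near-equal segments; each segment
    is shifted by the integer offset (|offset| ≤ max_shift) maximizing its
    cross-correlation with the corresponding mean-spectrum segment, scored
    on the unshifted overlap only (edge-filled points would otherwise bias
    the score).  Vacated points take the segment edge value; ties break
    toward zero shift.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    bounds = np.linspace(0, m.n_points, n_segments + 1).astype(int)
    seg_lengths = np.diff(bounds)
    if max_shift >= seg_lengths.min() and max_shift > 0:
        raise ValueError(
            f"max_shift {max_shift} >= shortest segment length {seg_lengths.min()}"
        )
    reference = m.X.mean(axis=0)
    out = m.X.copy()
    # candidate shifts ordered by |s| then positive first => first strict
    # maximum wins, i.e. ties resolve toward zero
    shifts = sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s < 0))
    for r in range(m.n_samples):
        for a, b in zip(bounds[:-1], bounds[1:]):
            ref_seg = reference[a:b]
            seg = m.X[r, a:b]
            best_s, best_c = 0, -np.inf
            for s in shifts:
                if s > 0:
                    c = float(seg[:-s] @ ref_seg[s:])
                elif s < 0:
                    c = float(seg[-s:] @ ref_seg[:s])
                else:
                    c = float(seg @ ref_seg)
                if c > best_c:
                    best_s, best_c = s, c
            out[r, a:b] = _shift_segment(seg, best_s)
    return SpectralMatrix(out, m.ppm.copy(), list(m.sample_ids), list(m.group_labels),
                          list(m.excluded_regions), m.normalized)


def exclude_and_normalize(m: SpectralMatrix,
                          regions=DEFAULT_EXCLUSIONS) -> SpectralMatrix:
    """Drop columns inside the closed ppm intervals, then row-normalize.

    Every retained row is divided by its summed retained intensity (total
    intensity normalization).  A row whose retained sum is ≤ 0 aborts with
    the offending sample named.
    """
    keep = np.ones(m.n_points, dtype=bool)
    for lo, hi in regions:
        lo, hi = min(lo, hi), max(lo, hi)
        keep &= ~((m.ppm >= lo) & (m.ppm <= hi))
    if not keep.any():
        raise ValueError("exclusion regions remove every spectral point")
    X = m.X[:, keep]
    sums = X.sum(axis=1)
    bad = np.where(sums <= 0)[0]
    if bad.size:
        raise ValueError(
            f"sample {m.sample_ids[bad[0]]!r} has non-positive total intensity "
            "after exclusion; cannot normalize"
        )
    X = X / sums[:, None]
    merged = list(m.excluded_regions) + [tuple(sorted(r)) for r in regions]
    return SpectralMatrix(X, m.ppm[keep].copy(), list(m.sample_ids),
                          list(m.group_labels), merged, normalized=True)
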