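"""Multivariate analysis: Pareto scaling, PCA, NIPALS PLS-DA, Q², ellipses.

PLS-DA regresses a one-hot class membership matrix Y on the spectral matrix
X with the NIPALS algorithm (deflation of both blocks).  Reporting is
per-component, non-cumulative: R²X_a = ‖t_a p_aᵀ‖²_F / ‖X₀‖²_F and R²Y
analogously on Y₀.  The cross-validated Q² follows the convention
Q²_a = 1 − PRESS_a / RSS_{a−1}, where PRESS_a sums squared held-out
prediction errors of a-component models over stratified folds and
RSS_{a−1} is the residual sum of squares of the full-data (a−1)-component
model (RSS₀ = total centred Y sum of squares).  The cumulative-Q²
convention of other packages differs; this one is fixed and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stocsy import Stocsy1D

NIPALS_TOL = 1e-10
# linear convergence can be slow when the two leading covariance eigenvalues
# are close; the cap guards against genuine stagnation only
NIPALS_MAX_ITER = 10_000


@dataclass
class ScalingRecord:
    mean: np.ndarray
    scale: np.ndarray
    zero_variance_columns: list[int] = field(default_factory=list)


def pareto_scale(X: np.ndarray) -> tuple[np.ndarray, ScalingRecord]:
    """Column-centre and divide by the square root of the standard deviation.

    Pareto scaling shrinks the dominance of intense resonances while, unlike
    unit-variance scaling, not blowing up baseline noise.  Zero-variance
    columns are passed through centred (flagged in the record).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to scale")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.where(sd <= 0)[0]
    scale = np.sqrt(np.where(sd <= 0, 1.0, sd))
    return (X - mean) / scale, ScalingRecord(mean, scale, list(zero))


def pca(X: np.ndarray, n_components: int | None = None):
    """SVD principal components of a centred matrix.

    Returns (scores, loadings, explained_variance_fraction).
    """
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but rank is {rank}")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    ev = s**2 / (s**2).sum()
    return scores, loadings, ev[:n_components]


def one_hot(groups) -> tuple[np.ndarray, list[str]]:
    """Class membership matrix with columns in sorted class order."""
    labels = sorted(set(groups))
    y = np.zeros((len(groups), len(labels)))
    for i, g in enumerate(groups):
        y[i, labels.index(g)] = 1.0
    return y, labels


@dataclass
class PlsModel:
    """NIPALS PLS(-DA) decomposition with per-component variance bookkeeping."""

    T: np.ndarray  # X scores (n, A)
    P: np.ndarray  # X loadings (p, A)
    W: np.ndarray  # X weights (p, A), unit norm
    C: np.ndarray  # Y loadings (g, A)
    r2x: np.ndarray  # per-component R²X
    r2y: np.ndarray  # per-component R²Y
    x_mean: np.ndarray
    y_mean: np.ndarray
    classes: list[str]
    ppm: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.T.shape[1]

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression coefficient matrix B (p × classes) of the truncated model."""
        a = self.n_components if n_components is None else n_components
        w, p, c = self.W[:, :a], self.P[:, :a], self.C[:, :a]
        return w @ np.linalg.solve(p.T @ w, c.T)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        return (np.asarray(X) - self.x_mean) @ self.coefficients(n_components) + self.y_mean

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.T, columns=[f"t{a + 1}" for a in range(self.n_components)])


def _nipals_component(E: np.ndarray, F: np.ndarray):
    """One NIPALS latent variable from the deflated blocks E, F."""
    u = F[:, int(np.argmax(F.var(axis=0)))].copy()
    w = np.zeros(E.shape[1])
    for _ in range(NIPALS_MAX_ITER):
        w_new = E.T @ u / (u @ u)
        nrm = np.linalg.norm(w_new)
        if nrm == 0:
            raise np.linalg.LinAlgError("NIPALS weight vector collapsed to zero")
        w_new /= nrm
        t = E @ w_new
        c = F.T @ t / (t @ t)
        u = F @ c / (c @ c)
        if np.linalg.norm(w_new - w) < NIPALS_TOL:
            w = w_new
            break
        w = w_new
    else:
        raise RuntimeError(f"NIPALS did not converge within {NIPALS_MAX_ITER} iterations")
    t = E @ w
    p = E.T @ t / (t @ t)
    c = F.T @ t / (t @ t)
    return t, p, w, c


def pls_da(X: np.ndarray, groups, n_components: int = 3,
           ppm: np.ndarray | None = None) -> PlsModel:
    """NIPALS PLS-DA of (already scaled) X against one-hot group membership.

    X and Y are centred internally; deterministic (the Y-score starts from
    the Y column of largest variance).  Each group needs ≥ 2 samples.
    """
    X = np.asarray(X, dtype=float)
    groups = list(groups)
    counts = pd.Series(groups).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    if len(counts) < 2:
        raise ValueError("PLS-DA needs at least 2 groups")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but X rank is {rank}")

    Y, classes = one_hot(groups)
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    E, F = X - x_mean, Y - y_mean
    ssx, ssy = (E**2).sum(), (F**2).sum()

    T, P, W, C, r2x, r2y = [], [], [], [], [], []
    for _ in range(n_components):
        t, p, w, c = _nipals_component(E, F)
        E = E - np.outer(t, p)
        F = F - np.outer(t, c)
        T.append(t); P.append(p); W.append(w); C.append(c)
        r2x.append((t @ t) * (p @ p) / ssx)
        r2y.append((t @ t) * (c @ c) / ssy)
    return PlsModel(np.column_stack(T), np.column_stack(P), np.column_stack(W),
                    np.column_stack(C), np.array(r2x), np.array(r2y),
                    x_mean, y_mean, classes, ppm)


@dataclass
class CvResult:
    q2: np.ndarray  # per-component Q²
    press: np.ndarray
    rss: np.ndarray  # RSS_0 .. RSS_{A-1}
    folds: np.ndarray  # fold index per sample
    seed: int


def stratified_folds(groups, k: int, seed: int) -> np.ndarray:
    """Seeded group-stratified fold assignment covering each sample once."""
    groups = list(groups)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(groups), dtype=int)
    start = 0
    for g in sorted(set(groups)):
        idx = np.array([i for i, x in enumerate(groups) if x == g])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[i] = (start + j) % k
        start += len(idx)  # rotate so small groups spread over folds
    return folds


def crossval_q2(X: np.ndarray, groups, n_components: int = 3, k: int = 5,
                seed: int = 0) -> CvResult:
    """Per-component cross-validated Q² of a PLS-DA model.

    Q²_a = 1 − PRESS_a / RSS_{a−1}; PRESS from a-component models trained on
    k−1 folds and evaluated on the held-out fold, RSS from full-data models.
    """
    X = np.asarray(X, dtype=float)
    groups = list(groups)
    n = len(groups)
    if k > n:
        raise ValueError(f"k = {k} exceeds n = {n}")
    Y, _ = one_hot(groups)
    folds = stratified_folds(groups, k, seed)

    full = pls_da(X, groups, n_components)
    rss = np.empty(n_components + 1)
    Yc = Y - Y.mean(axis=0)
    rss[0] = (Yc**2).sum()
    for a in range(1, n_components + 1):
        rss[a] = ((Y - full.predict(X, a)) ** 2).sum()

    press = np.zeros(n_components)
    for f in range(k):
        test = folds == f
        train = ~test
        train_groups = [g for g, t in zip(groups, train) if t]
        if len(set(train_groups)) < 2:
            warnings.warn(f"fold {f}: training split has a single class; fold skipped")
            continue
        sub = pls_da(X[train], train_groups, n_components)
        # align class columns of the fold model with the global one-hot order
        col = [sub.classes.index(c) if c in sub.classes else -1
               for c in sorted(set(groups))]
        for a in range(1, n_components + 1):
            pred = np.zeros((test.sum(), Y.shape[1]))
            sub_pred = sub.predict(X[test], a)
            for j, cj in enumerate(col):
                if cj >= 0:
                    pred[:, j] = sub_pred[:, cj]
            press[a - 1] += ((Y[test] - pred) ** 2).sum()
    q2 = 1.0 - press / rss[:-1]
    return CvResult(q2, press, rss, folds, seed)


@dataclass
class EllipseSpec:
    center: np.ndarray
    semi_axes: np.ndarray  # (2,)
    orientation_rad: float
    level: float

    def contains(self, scores: np.ndarray) -> np.ndarray:
        d = np.asarray(scores) - self.center
        c, s = np.cos(self.orientation_rad), np.sin(self.orientation_rad)
        rot = d @ np.array([[c, -s], [s, c]])
        return (rot[:, 0] / self.semi_axes[0]) ** 2 + (rot[:, 1] / self.semi_axes[1]) ** 2 <= 1.0

    def outline(self, n: int = 200) -> np.ndarray:
        th = np.linspace(0, 2 * np.pi, n)
        xy = np.column_stack([self.semi_axes[0] * np.cos(th), self.semi_axes[1] * np.sin(th)])
        c, s = np.cos(self.orientation_rad), np.sin(self.orientation_rad)
        return xy @ np.array([[c, s], [-s, c]]) + self.center


def hotelling_ellipse(scores: np.ndarray, level: float = 0.95) -> EllipseSpec:
    """Hotelling T² confidence ellipse for two score columns.

    T²_crit = 2(n²−1)/(n(n−2)) · F(level; 2, n−2); the semi-axes are
    sqrt(T²_crit · variance) along the principal directions of the score
    covariance.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be an n x 2 array")
    n = scores.shape[0]
    if n <= 3:
        raise ValueError("Hotelling ellipse needs n >= 4")
    t2crit = 2.0 * (n**2 - 1) / (n * (n - 2)) * stats.f.ppf(level, 2, n - 2)
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    semi = np.sqrt(t2crit * w)
    angle = float(np.arctan2(v[1, 0], v[0, 0]))
    return EllipseSpec(center, semi, angle, level)


def coefficient_stocsy_overlay(model: PlsModel, s: Stocsy1D,
                               component: int = 1) -> pd.DataFrame:
    """Per-point table pairing a PLS component's loading with STOCSY r².

    The plotted "coefficient of the first PLS component" is the component's
    X-loading vector (a single value per spectral point even for a
    multi-class Y); the r² colour channel is the 1D-STOCSY correlation
    against the chosen driver.  Model and STOCSY must share the retained
    axis.
    """
    if not (1 <= component <= model.n_components):
        raise ValueError(f"component {component} outside 1..{model.n_components}")
    if model.ppm is None or model.ppm.shape != s.ppm.shape or not np.allclose(model.ppm, s.ppm):
        raise ValueError("PLS model and STOCSY result are not on the same retained axis")
    return pd.DataFrame({
        "ppm": s.ppm,
        "coefficient": model.P[:, component - 1],
        "r2": s.r2,
    })
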