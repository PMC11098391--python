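"""Functional PCA of OGTT curves with penalized cubic B-splines.

Each 7-point curve is smoothed into a function on [0, 2] h by penalized
least squares in a 6-function cubic B-spline basis, with a roughness
penalty lambda on the integrated squared second derivative; lambda is
chosen by generalized cross-validation (GCV) unless pinned.  The smoothed
cohort is then decomposed into a mean curve, orthonormal eigenfunctions
(the dominant modes of variation about the mean under the L2 inner
product), per-component variance proportions, and per-participant scores
(L2 projections of the mean-centered curve onto each eigenfunction).

The eigenproblem is solved in the basis-coefficient domain: with Gram
matrix G (inner products of basis functions) and centered coefficient
matrix D, the eigenvectors of G^{1/2} (D'D/n) G^{1/2} map back to
eigenfunction coefficients through G^{-1/2}.  All L2 integrals use
Simpson's rule on a uniform 401-point grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline

from .curves import OGTTCurve, TIME_GRID_HOURS

__all__ = [
    "BasisSpec",
    "SmoothedCurve",
    "FPCAModel",
    "FPCScores",
    "smooth_curve",
    "select_lambda_gcv",
    "mean_curve",
    "compute_fpca",
    "fpc_scores",
    "reconstruct",
]

QUADRATURE_POINTS = 401


def _simpson_weights(n: int, h: float) -> np.ndarray:
    if n % 2 == 0:
        raise ValueError("Simpson's rule needs an odd number of points")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0


@dataclass(frozen=True)
class BasisSpec:
    """Cubic B-spline basis on [0, 2] h.

    n_basis = order + number of interior knots; the default 6 cubic
    functions force 2 interior knots, placed at 2/3 and 4/3 h.
    """

    n_basis: int = 6
    order: int = 4  # cubic
    domain: tuple[float, float] = (0.0, 2.0)
    interior_knots: tuple[float, ...] = (2.0 / 3.0, 4.0 / 3.0)

    def __post_init__(self):
        if self.n_basis != self.order + len(self.interior_knots):
            raise ValueError("n_basis must equal order + number of interior knots")
        a, b = self.domain
        if not all(a < k < b for k in self.interior_knots):
            raise ValueError("interior knots must lie strictly inside the domain")

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def knots(self) -> np.ndarray:
        a, b = self.domain
        return np.concatenate(
            [np.full(self.order, a), np.asarray(self.interior_knots), np.full(self.order, b)]
        )

    def design_matrix(self, t) -> np.ndarray:
        """Basis evaluations, shape (len(t), n_basis)."""
        t = np.asarray(t, dtype=float)
        return BSpline.design_matrix(t, self.knots, self.degree).toarray()

    def second_derivative_matrix(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.empty((t.size, self.n_basis))
        for j in range(self.n_basis):
            coef = np.zeros(self.n_basis)
            coef[j] = 1.0
            out[:, j] = BSpline(self.knots, coef, self.degree).derivative(2)(t)
        return out


@lru_cache(maxsize=8)
def _basis_matrices(basis: BasisSpec):
    """(grid, weights, B, Gram, penalty).

    The Gram matrix uses Simpson's rule on the uniform 401-point grid like
    every other L2 integral.  The curvature penalty integrand is piecewise
    quadratic between knots, so it is integrated exactly with per-interval
    Gauss-Legendre; an exact penalty keeps the straight line precisely in
    its null space, which matters in the heavy-smoothing limit.
    """
    a, b = basis.domain
    grid = np.linspace(a, b, QUADRATURE_POINTS)
    w = _simpson_weights(QUADRATURE_POINTS, grid[1] - grid[0])
    B = basis.design_matrix(grid)
    gram = B.T @ (w[:, None] * B)

    breaks = np.concatenate([[a], np.asarray(basis.interior_knots), [b]])
    gl_nodes, gl_weights = np.polynomial.legendre.leggauss(5)
    penalty = np.zeros((basis.n_basis, basis.n_basis))
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        nodes = mid + half * gl_nodes
        B2 = basis.second_derivative_matrix(nodes)
        penalty += half * (B2.T @ (gl_weights[:, None] * B2))
    return grid, w, B, gram, penalty


@lru_cache(maxsize=8)
def _penalty_root(basis: BasisSpec) -> np.ndarray:
    """Symmetric PSD square root of the roughness-penalty matrix."""
    _, _, _, _, penalty = _basis_matrices(basis)
    vals, vecs = np.linalg.eigh(penalty)
    return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None))) @ vecs.T


@dataclass(frozen=True)
class SmoothedCurve:
    participant_id: str
    coefficients: np.ndarray  # mg/mL, length n_basis
    lambda_used: float
    basis: BasisSpec = field(default_factory=BasisSpec)

    def __call__(self, t):
        return self.basis.design_matrix(np.atleast_1d(t)) @ self.coefficients


@dataclass(frozen=True)
class FPCAModel:
    """Mean curve, eigenfunctions and variance shares in basis coordinates.

    ``eigen_coefficients`` has one column per eigenfunction (all n_basis of
    them); ``variance_proportions`` are eigenvalue shares of the total
    variance, non-increasing.  Scores and reconstructions use the first
    ``n_retained`` components.
    """

    basis: BasisSpec
    mean_coefficients: np.ndarray
    eigen_coefficients: np.ndarray  # (n_basis, n_basis)
    eigenvalues: np.ndarray
    variance_proportions: np.ndarray
    n_retained: int = 3

    def mean_function(self, t):
        return self.basis.design_matrix(np.atleast_1d(t)) @ self.mean_coefficients

    def eigenfunction(self, j: int):
        coef = self.eigen_coefficients[:, j]
        basis = self.basis
        return lambda t: basis.design_matrix(np.atleast_1d(t)) @ coef


@dataclass(frozen=True)
class FPCScores:
    participant_id: str
    scores: np.ndarray  # length n_retained, mg/mL*h scale


def smooth_curve(
    curve: OGTTCurve, basis: BasisSpec | None = None, lam: float = 733.0
) -> SmoothedCurve:
    """Penalized least-squares smooth of one curve.

    Minimizes sum of squared residuals at the 7 sample times plus
    lam * integral of the squared second derivative over the domain.
    """
    if lam < 0:
        raise ValueError("penalty lambda must be non-negative")
    basis = basis or BasisSpec()
    phi = basis.design_matrix(curve.times)
    # Augmented least squares [phi; sqrt(lam) R^{1/2}] keeps the solve well
    # conditioned even for penalty weights many orders beyond the GCV range.
    root = _penalty_root(basis)
    aug = np.vstack([phi, np.sqrt(lam) * root])
    rhs = np.concatenate([curve.glucose, np.zeros(basis.n_basis)])
    coef, *_ = np.linalg.lstsq(aug, rhs, rcond=None)
    return SmoothedCurve(curve.participant_id, coef, lam, basis)


def select_lambda_gcv(
    curves: list[OGTTCurve], basis: BasisSpec | None = None, grid=None
) -> float:
    """Pick the penalty minimizing mean GCV across curves.

    GCV(lambda) = n * SSE / (n - df)^2 per curve, with df the trace of the
    smoothing hat matrix; ties break toward the smaller lambda.  The
    default grid is 50 log-spaced points between 1e-2 and 1e5.
    """
    if grid is None:
        grid = np.logspace(-2, 5, 50)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty candidate grid")
    if np.any(grid <= 0):
        raise ValueError("candidate penalties must be positive")
    basis = basis or BasisSpec()
    _, _, _, _, penalty = _basis_matrices(basis)
    phi = basis.design_matrix(TIME_GRID_HOURS)
    y = np.stack([c.glucose for c in curves])  # (n_curves, 7)
    n = phi.shape[0]

    best_lam, best_gcv = None, np.inf
    for lam in np.sort(grid):
        m = np.linalg.solve(phi.T @ phi + lam * penalty, phi.T)
        hat = phi @ m
        df = float(np.trace(hat))
        resid = y - y @ hat.T
        sse = np.sum(resid**2, axis=1)
        gcv = float(np.mean(n * sse / (n - df) ** 2))
        if gcv < best_gcv - 1e-15:
            best_lam, best_gcv = float(lam), gcv
    return best_lam


def mean_curve(smoothed: list[SmoothedCurve]) -> np.ndarray:
    """Pointwise mean curve = elementwise mean of basis coefficients."""
    if not smoothed:
        raise ValueError("need at least one smoothed curve")
    return np.mean([s.coefficients for s in smoothed], axis=0)


def _sqrt_and_inv_sqrt(gram: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(gram)
    vals = np.clip(vals, 1e-14, None)
    half = vecs @ np.diag(np.sqrt(vals)) @ vecs.T
    inv_half = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
    return half, inv_half


def compute_fpca(
    smoothed: list[SmoothedCurve],
    mean_coefficients: np.ndarray | None = None,
    n_retained: int = 3,
) -> FPCAModel:
    """Eigen-decompose the cohort's covariance operator.

    Sign convention: each eigenfunction is flipped if needed so its integral
    over the domain is positive (midpoint value decides if the integral is
    numerically zero), making score signs reproducible.
    """
    if len(smoothed) < n_retained + 1:
        raise ValueError("need at least n_retained + 1 curves")
    basis = smoothed[0].basis
    if mean_coefficients is None:
        mean_coefficients = mean_curve(smoothed)
    grid, w, B, gram, _ = _basis_matrices(basis)
    C = np.stack([s.coefficients for s in smoothed])
    D = C - mean_coefficients
    half, inv_half = _sqrt_and_inv_sqrt(gram)
    W = half @ (D.T @ D / len(smoothed)) @ half
    vals, vecs = np.linalg.eigh(W)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    coefs = inv_half @ vecs[:, order]  # eigenfunction coefficients, columns

    # Reproducible signs: integral of each eigenfunction positive.
    basis_integrals = w @ B  # integral of each basis function
    mid = basis.design_matrix([(basis.domain[0] + basis.domain[1]) / 2.0])[0]
    for j in range(coefs.shape[1]):
        integral = basis_integrals @ coefs[:, j]
        decider = integral if abs(integral) >= 1e-10 else mid @ coefs[:, j]
        if decider < 0:
            coefs[:, j] = -coefs[:, j]

    total = float(np.sum(vals))
    proportions = vals / total if total > 0 else np.zeros_like(vals)
    return FPCAModel(
        basis=basis,
        mean_coefficients=np.asarray(mean_coefficients, dtype=float),
        eigen_coefficients=coefs,
        eigenvalues=vals,
        variance_proportions=proportions,
        n_retained=n_retained,
    )


def fpc_scores(smoothed_curve: SmoothedCurve, model: FPCAModel) -> FPCScores:
    """L2 projections of the mean-centered curve on the retained eigenfunctions."""
    if smoothed_curve.basis != model.basis:
        raise ValueError("smoothed curve and model use different bases")
    _, _, _, gram, _ = _basis_matrices(model.basis)
    centered = smoothed_curve.coefficients - model.mean_coefficients
    scores = model.eigen_coefficients[:, : model.n_retained].T @ (gram @ centered)
    return FPCScores(smoothed_curve.participant_id, scores)


def reconstruct(scores: FPCScores, model: FPCAModel, n_components: int | None = None):
    """Curve rebuilt from the mean plus the first n_components score terms.

    Returns a callable on the domain.
    """
    if n_components is None:
        n_components = model.n_retained
    if n_components > model.n_retained:
        raise ValueError("n_components exceeds the number of retained components")
    coef = model.mean_coefficients + (
        model.eigen_coefficients[:, :n_components] @ scores.scores[:n_components]
    )
    basis = model.basis
    return lambda t: basis.design_matrix(np.atleast_1d(t)) @ coef
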