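"""Scattered-data radial basis function interpolation.

An RBF interpolant of data ``(X_i, f_i)`` in R^d has the form

    s(X) = p_m(X) + Σ_i λ_i φ(‖X − X_i‖₂)

where φ is a fixed radial kernel and p_m an optional low-degree polynomial
tail. The weights λ and tail coefficients solve the symmetric saddle-point
system

    [[A, P], [Pᵀ, 0]] · [λ; c] = [f; 0],   A_ij = φ(‖X_i − X_j‖₂),

whose lower block imposes the side conditions Σ_i λ_i q(X_i) = 0 for every
polynomial q of degree ≤ m. The tail makes conditionally positive definite
kernels (linear, thin-plate spline) uniquely solvable provided the nodes are
unisolvent — for degree 1, not all on one hyperplane.

Kernels
-------
linear              φ(r) = r                      degree-1 tail required
thin_plate_spline   φ(r) = r² log r, φ(0) = 0     degree-1 tail required (d = 2)
gaussian            φ(r) = exp(−(r/ρ)²)           no tail
multiquadric        φ(r) = √(r² + ρ²)             no tail

ρ is the shape parameter; ``shape_param="auto"`` uses the mean nearest-
neighbour distance among the centers, which makes fits resolution-independent
when coordinates are physical (mm).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lstsq
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import ConditioningError, RankDeficiencyError, UnisolvencyError

KERNELS = ("linear", "thin_plate_spline", "gaussian", "multiquadric")

#: polynomial tail degree each kernel needs for a well-posed interpolant
#: (None: positive definite kernel, no tail needed)
KERNEL_TAIL_DEGREE = {
    "linear": 1,
    "thin_plate_spline": 1,
    "gaussian": None,
    "multiquadric": None,
}

_ALIASES = {"tps": "thin_plate_spline", "mq": "multiquadric", "multiquadratic": "multiquadric"}

#: condition-number threshold above which a fit is flagged as ill-conditioned
COND_WARN = 1e12


def canonical_kernel(name: str) -> str:
    name = _ALIASES.get(name, name)
    if name not in KERNELS:
        raise ValueError(f"unknown kernel {name!r}; valid kernels: {', '.join(KERNELS)}")
    return name


def kernel_matrix(kernel: str, r: np.ndarray, shape_param: float | None) -> np.ndarray:
    """Apply the radial kernel φ elementwise to a distance array."""
    kernel = canonical_kernel(kernel)
    r = np.asarray(r, dtype=float)
    if kernel == "linear":
        return r
    if kernel == "thin_plate_spline":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r * r * np.log(np.where(r > 0, r, 1.0)), 0.0)
        return out
    if shape_param is None or shape_param <= 0:
        raise ValueError(f"kernel {kernel!r} needs a positive shape parameter")
    if kernel == "gaussian":
        return np.exp(-((r / shape_param) ** 2))
    return np.sqrt(r * r + shape_param * shape_param)  # multiquadric


def monomial_exponents(dim: int, degree: int) -> list[tuple[int, ...]]:
    """Exponent multi-indices of the monomial basis of π_degree^dim.

    Deterministic order: by total degree, then leading coordinates first —
    in 2D: 1, x, y, x², xy, y².
    """
    exps = [
        e
        for e in itertools.product(range(degree + 1), repeat=dim)
        if sum(e) <= degree
    ]
    return sorted(exps, key=lambda e: (sum(e), [-v for v in e]))


def monomial_matrix(points: np.ndarray, degree: int) -> np.ndarray:
    """Evaluate the monomial basis of degree ≤ ``degree`` at each point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    exps = monomial_exponents(points.shape[1], degree)
    cols = [np.prod(points ** np.asarray(e), axis=1) for e in exps]
    return np.column_stack(cols)


def check_unisolvency(nodes: np.ndarray, degree: int) -> bool:
    """True iff no nonzero polynomial of the given degree vanishes at all nodes.

    Decided by the numerical rank of the monomial-basis matrix: the node set
    is unisolvent for π_degree^d exactly when that matrix has full column
    rank. For degree 1 this is the classical "not collinear / not coplanar"
    condition.
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    if nodes.size == 0:
        raise ValueError("empty node set")
    V = monomial_matrix(nodes, degree)
    return int(np.linalg.matrix_rank(V)) == V.shape[1]


@dataclass
class RBFModel:
    """A fitted radial basis interpolant (kernel, centers, weights, tail)."""

    kernel: str
    centers: np.ndarray
    weights: np.ndarray
    poly_degree: int | None = None
    poly_coeffs: np.ndarray | None = None
    shape_param: float | None = None
    condition_number: float | None = None

    @property
    def dim(self) -> int:
        return self.centers.shape[1]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return evaluate_rbf(self, points)

    def to_json(self) -> str:
        doc = {
            "kernel": self.kernel,
            "centers": self.centers.tolist(),
            "weights": self.weights.tolist(),
            "poly_degree": self.poly_degree,
            "poly_coeffs": None if self.poly_coeffs is None else self.poly_coeffs.tolist(),
            "shape_param": self.shape_param,
            "condition_number": self.condition_number,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RBFModel":
        doc = json.loads(text)
        return cls(
            kernel=doc["kernel"],
            centers=np.asarray(doc["centers"], dtype=float),
            weights=np.asarray(doc["weights"], dtype=float),
            poly_degree=doc["poly_degree"],
            poly_coeffs=None
            if doc["poly_coeffs"] is None
            else np.asarray(doc["poly_coeffs"], dtype=float),
            shape_param=doc["shape_param"],
            condition_number=doc["condition_number"],
        )


def _auto_shape(centers: np.ndarray) -> float:
    if len(centers) < 2:
        return 1.0
    tree = cKDTree(centers)
    dists, _ = tree.query(centers, k=2)
    return float(dists[:, 1].mean())


def fit_rbf(
    nodes: np.ndarray,
    values: np.ndarray,
    kernel: str = "linear",
    shape_param="auto",
    max_nodes: int = 500,
    seed: int = 0,
    include_tail: bool | None = None,
    residual_rtol: float = 1e-6,
) -> RBFModel:
    """Fit an RBF interpolant through ``(nodes, values)``.

    When the node count exceeds ``max_nodes``, a seeded uniform subsample of
    the nodes is retained as centers (identical seed → bit-identical model);
    the interpolation conditions then hold at the retained centers. The
    saddle-point system is solved with a pivoted least-squares factorisation;
    fits whose estimated condition number exceeds 1e12 raise a warning, and
    systems whose node residuals exceed ``residual_rtol`` × data range raise
    :class:`ConditioningError`.

    ``include_tail`` overrides the kernel's default tail: True forces a
    degree-1 tail (useful when a positive definite kernel must extrapolate a
    polynomial trend), False drops it (only legal for gaussian/multiquadric).
    """
    kernel = canonical_kernel(kernel)
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if len(nodes) != len(values):
        raise ValueError(f"{len(nodes)} nodes but {len(values)} values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")

    if len(nodes) > max_nodes:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(nodes), size=max_nodes, replace=False))
        nodes, values = nodes[keep], values[keep]

    if len(np.unique(nodes, axis=0)) != len(nodes):
        raise ValueError("interpolation nodes must be pairwise distinct")

    if include_tail is None:
        degree = KERNEL_TAIL_DEGREE[kernel]
    elif include_tail:
        degree = 1
    else:
        if KERNEL_TAIL_DEGREE[kernel] is not None:
            raise ValueError(f"kernel {kernel!r} requires its degree-1 tail")
        degree = None

    if degree is not None and not check_unisolvency(nodes, degree):
        raise UnisolvencyError(
            f"nodes are not unisolvent for a degree-{degree} tail "
            "(all on one hyperplane?)"
        )

    shape = None
    if kernel in ("gaussian", "multiquadric"):
        shape = _auto_shape(nodes) if shape_param == "auto" else float(shape_param)

    n = len(nodes)
    A = kernel_matrix(kernel, cdist(nodes, nodes), shape)
    if degree is not None:
        P = monomial_matrix(nodes, degree)
        q = P.shape[1]
        M = np.block([[A, P], [P.T, np.zeros((q, q))]])
        rhs = np.concatenate([values, np.zeros(q)])
    else:
        q = 0
        M, rhs = A, values

    sol, _, _, _ = lstsq(M, rhs, lapack_driver="gelsy")
    cond = float(np.linalg.cond(M)) if M.shape[0] <= 2000 else None
    lam = sol[:n]
    coeffs = sol[n:] if q else None

    fitted = A @ lam + (P @ coeffs if q else 0.0)
    data_range = float(np.ptp(values)) or 1.0
    max_resid = float(np.max(np.abs(fitted - values)))
    if max_resid > residual_rtol * data_range:
        raise ConditioningError(cond if cond is not None else np.inf)
    if cond is not None and cond > COND_WARN:
        warnings.warn(
            f"ill-conditioned RBF system (condition number {cond:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )

    return RBFModel(
        kernel=kernel,
        centers=nodes.copy(),
        weights=lam,
        poly_degree=degree,
        poly_coeffs=coeffs,
        shape_param=shape,
        condition_number=cond,
    )


def evaluate_rbf(model: RBFModel, points: np.ndarray) -> np.ndarray:
    """Evaluate s(X) = Σ λ_i φ(‖X − X_i‖) + p_m(X) at the given points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != model.dim:
        raise ValueError(f"points have dimension {points.shape[1]}, model expects {model.dim}")
    B = kernel_matrix(model.kernel, cdist(points, model.centers), model.shape_param)
    out = B @ model.weights
    if model.poly_degree is not None:
        out = out + monomial_matrix(points, model.poly_degree) @ model.poly_coeffs
    return out


@dataclass
class PolyModel:
    """A multivariate polynomial fitted by (weighted) least squares."""

    dim: int
    degree: int
    coeffs: np.ndarray
    fit_weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        expected = len(monomial_exponents(self.dim, self.degree))
        if len(self.coeffs) != expected:
            raise ValueError(
                f"degree-{self.degree} polynomial in {self.dim}D needs {expected} "
                f"coefficients, got {len(self.coeffs)}"
            )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[1] != self.dim:
            raise ValueError(f"points have dimension {points.shape[1]}, model expects {self.dim}")
        return monomial_matrix(points, self.degree) @ self.coeffs


def fit_polynomial_wls(
    nodes: np.ndarray,
    values: np.ndarray,
    weights: np.ndarray | None = None,
    degree: int = 1,
) -> PolyModel:
    """Weighted least-squares polynomial fit minimising Σ w_j (p(X_j) − f_j)².

    Unit weights by default. Nodes with zero weight do not influence the fit.

    Raises
    ------
    RankDeficiencyError
        If the (weighted) monomial design matrix does not have full column
        rank — too few nodes or degenerate node geometry.
    """
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if weights is None:
        weights = np.ones(len(nodes))
    weights = np.asarray(weights, dtype=float).ravel()
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if not weights.any():
        raise ValueError("weights must not all be zero")
    if not (len(nodes) == len(values) == len(weights)):
        raise ValueError("nodes, values and weights must have equal lengths")

    V = monomial_matrix(nodes, degree)
    sw = np.sqrt(weights)
    Vw = V * sw[:, None]
    if int(np.linalg.matrix_rank(Vw)) < V.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank-deficient: {len(nodes)} effective nodes cannot "
            f"determine the {V.shape[1]} coefficients of a degree-{degree} "
            f"polynomial in {nodes.shape[1]}D"
        )
    coeffs, _, _, _ = lstsq(Vw, values * sw, lapack_driver="gelsy")
    return PolyModel(dim=nodes.shape[1], degree=degree, coeffs=coeffs, fit_weights=weights)
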