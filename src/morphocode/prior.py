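"""Empirical Gaussian shape priors from populations of initial momenta.

Tangent-space PCA of vertex-indexed momentum fields under the kernel (dual
space) inner product

    <p, q>_K = sum_ab p_a^T K(x_a - x_b) q_b,

the reproducing-kernel bilinear form induced by the Gaussian kernel on the
template vertices.  The fitted prior consists of the population mean b0, a
kernel-orthonormal basis {b_i} and a descending variance spectrum {sigma_i^2};
a momentum is approximated as p0 = b0 + sum_i beta_i b_i with independent
coefficients beta_i ~ N(0, sigma_i^2).

Metric PCA is computed by Cholesky whitening: with G = L L^T the vertex Gram
matrix, the map p -> L^T p is an isometry from the kernel metric to the
Euclidean one, so ordinary PCA of the whitened, centered momenta yields the
spectrum, and back-substitution through L^T returns a basis orthonormal in
the kernel metric by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .shooting import KernelSpec, gram_matrix
from .surface_io import (
    MomentumField,
    TriSurface,
    read_momenta,
    read_surface,
    write_momenta,
    write_surface,
)

logger = logging.getLogger(__name__)

DEFAULT_TRACE_FRACTION = 0.95
_ORTHO_TOL = 1e-8
_RANK_TOL = 1e-12  # eigenvalues below this fraction of the lead are noise


@dataclass(frozen=True)
class ShapePrior:
    """Template, mean momentum, kernel-orthonormal basis and variances."""

    template: TriSurface
    kernel: KernelSpec
    b0: MomentumField
    basis: np.ndarray  # (B, n, 3), rows orthonormal under <.,.>_K
    variances: np.ndarray  # (B,), strictly positive, non-increasing
    trace_fraction: float = DEFAULT_TRACE_FRACTION

    def __post_init__(self) -> None:
        basis = np.asarray(self.basis, float)
        var = np.asarray(self.variances, float)
        if basis.ndim != 3 or basis.shape[0] != var.shape[0] or basis.shape[0] < 1:
            raise ValueError(
                f"basis {basis.shape} inconsistent with variances {var.shape}"
            )
        if np.any(var <= 0) or np.any(np.diff(var) > 0):
            raise ValueError("variances must be strictly positive and non-increasing")
        gram = gram_matrix(self.template.vertices, self.kernel)
        inner = np.einsum("iak,ab,jbk->ij", basis, gram, basis)
        err = np.abs(inner - np.eye(basis.shape[0])).max()
        if err > 100 * _ORTHO_TOL:
            raise ValueError(f"basis not kernel-orthonormal (max deviation {err:.2e})")
        object.__setattr__(self, "basis", basis)
        object.__setattr__(self, "variances", var)

    @property
    def n_modes(self) -> int:
        return self.variances.shape[0]

    @property
    def total_variance(self) -> float:
        return float(self.variances.sum())


@dataclass(frozen=True)
class CoefficientVector:
    """Coefficients beta of a momentum in a prior's basis."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, float).ravel()
        if not np.all(np.isfinite(b)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "beta", b)


def kernel_inner(
    p: MomentumField | np.ndarray,
    q: MomentumField | np.ndarray,
    points: np.ndarray,
    spec: KernelSpec = KernelSpec(),
) -> float:
    """Kernel inner product sum_ab p_a . q_b K(x_a - x_b) of two momenta."""
    pv = p.values if isinstance(p, MomentumField) else np.asarray(p, float)
    qv = q.values if isinstance(q, MomentumField) else np.asarray(q, float)
    points = np.asarray(points, float)
    if pv.shape != qv.shape or pv.shape[0] != points.shape[0]:
        raise ValueError(
            f"shape mismatch: p {pv.shape}, q {qv.shape}, points {points.shape}"
        )
    gram = gram_matrix(points, spec)
    return float(np.sum(pv * (gram @ qv)))


def _cholesky_with_jitter(gram: np.ndarray) -> np.ndarray:
    try:
        return scipy.linalg.cholesky(gram, lower=True)
    except scipy.linalg.LinAlgError:
        logger.warning("Gram matrix numerically singular; adding 1e-10 jitter")
        return scipy.linalg.cholesky(
            gram + 1e-10 * np.eye(gram.shape[0]), lower=True
        )


def fit_prior(
    momenta: Sequence[MomentumField],
    template: TriSurface,
    spec: KernelSpec = KernelSpec(),
    trace_fraction: float = DEFAULT_TRACE_FRACTION,
) -> ShapePrior:
    """Fit the empirical prior to a population of M >= 2 momentum fields.

    The mean b0 is the sample mean; the basis and variances are the
    kernel-metric PCA of the centered momenta (covariance divisor M - 1).
    The number of retained modes B is the smallest count whose cumulative
    variance reaches ``trace_fraction`` of the total covariance trace.
    """
    if len(momenta) < 2:
        raise ValueError("need at least 2 momentum fields")
    n = template.n_vertices
    for i, m in enumerate(momenta):
        if m.vertex_count != n:
            raise ValueError(
                f"momentum {i} has {m.vertex_count} vectors, template has {n}"
            )
    if not 0 < trace_fraction <= 1:
        raise ValueError("trace_fraction must be in (0, 1]")

    stack = np.stack([m.values for m in momenta])  # (M, n, 3)
    mean = stack.mean(axis=0)
    centered = stack - mean

    gram = gram_matrix(template.vertices, spec)
    chol = _cholesky_with_jitter(gram)
    # isometry p -> L^T p, applied per 3-vector component
    whitened = np.einsum("an,mnk->mak", chol.T, centered).reshape(len(momenta), -1)

    _, svals, vt = np.linalg.svd(whitened, full_matrices=False)
    eigvals = svals**2 / (len(momenta) - 1)
    total = float(eigvals.sum())
    if total <= 0:
        raise ValueError("zero total variance: all momenta are identical")

    keep = eigvals > _RANK_TOL * eigvals[0]
    eigvals, vt = eigvals[keep], vt[keep]
    cum = np.cumsum(eigvals)
    target = trace_fraction * total * (1.0 - 1e-12)  # guard float ties
    n_modes = int(np.searchsorted(cum, target) + 1)
    n_modes = min(n_modes, eigvals.shape[0])

    # back-substitute L^T b = u to return to momentum coordinates
    u = vt[:n_modes].reshape(n_modes, n, 3)
    basis = np.stack(
        [scipy.linalg.solve_triangular(chol.T, uk, lower=False) for uk in u]
    )
    return ShapePrior(
        template=template,
        kernel=spec,
        b0=MomentumField(mean),
        basis=basis,
        variances=eigvals[:n_modes],
        trace_fraction=trace_fraction,
    )


def project(p: MomentumField, prior: ShapePrior) -> CoefficientVector:
    """Coefficients beta_i = <p - b0, b_i>_K of a momentum in the prior basis."""
    if p.vertex_count != prior.template.n_vertices:
        raise ValueError("momentum does not match the prior's template")
    gram = gram_matrix(prior.template.vertices, prior.kernel)
    centered = p.values - prior.b0.values
    beta = np.einsum("iak,ak->i", prior.basis, gram @ centered)
    return CoefficientVector(beta)


def reconstruct(beta: CoefficientVector | np.ndarray, prior: ShapePrior) -> MomentumField:
    """Momentum b0 + sum_i beta_i b_i from basis coefficients."""
    b = beta.beta if isinstance(beta, CoefficientVector) else np.asarray(beta, float)
    if b.shape[0] != prior.n_modes:
        raise ValueError(f"expected {prior.n_modes} coefficients, got {b.shape[0]}")
    return MomentumField(prior.b0.values + np.einsum("i,iak->ak", b, prior.basis))


def sample_prior(
    prior: ShapePrior, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw n i.i.d. coefficient vectors beta_i ~ N(0, sigma_i^2), shape (n, B)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, prior.n_modes)) * np.sqrt(prior.variances)


def save_prior(prior: ShapePrior, directory: str | Path) -> None:
    """Serialize a prior as a directory: template.ply, momenta binaries, JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_surface(prior.template, directory / "template.ply")
    write_momenta(prior.b0, directory / "b0.bin")
    for i in range(prior.n_modes):
        write_momenta(MomentumField(prior.basis[i]), directory / f"basis_{i:04d}.bin")
    meta = {
        "sigma": prior.kernel.sigma,
        "variances": prior.variances.tolist(),
        "trace_fraction": prior.trace_fraction,
        "n_modes": prior.n_modes,
    }
    (directory / "prior.json").write_text(json.dumps(meta, indent=2))


def load_prior(directory: str | Path) -> ShapePrior:
    directory = Path(directory)
    meta = json.loads((directory / "prior.json").read_text())
    template = read_surface(directory / "template.ply")
    b0 = read_momenta(directory / "b0.bin")
    basis = np.stack(
        [
            read_momenta(directory / f"basis_{i:04d}.bin").values
            for i in range(meta["n_modes"])
        ]
    )
    return ShapePrior(
        template=template,
        kernel=KernelSpec(meta["sigma"]),
        b0=b0,
        basis=basis,
        variances=np.asarray(meta["variances"]),
        trace_fraction=meta["trace_fraction"],
    )
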