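"""Gaussian rate-distortion: reverse water-filling and random codebooks.

For B independent Gaussian coefficients with variances sigma_i^2 and squared
error distortion, the optimal trade-off between code rate R (bits, codebook
size 2^R) and expected distortion D is

    R(D) = sum_i 1/2 log2(sigma_i^2 / D_i),
    D_i  = min(lambda, sigma_i^2),   lambda s.t. sum_i D_i = D,

the reverse water-filling allocation: dimensions with variance below the
water level lambda are not coded at all.  The curve is achievable
asymptotically by random codebooks whose i-th component is drawn
N(0, sigma_i^2 - lambda) when sigma_i^2 >= lambda and is exactly zero
otherwise, coding blocks of N independent shape instances jointly with
2^(N R) codewords.

This module builds those codebooks from a fitted shape prior, performs
nearest-codeword encoding/decoding, and measures empirical distortion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .prior import ShapePrior

logger = logging.getLogger(__name__)

DEFAULT_SIZE_CAP = 2**20  # codewords; override for rates beyond 20 bits
_BISECT_REL_TOL = 1e-12
_RATE_TOL_BITS = 1e-9


@dataclass(frozen=True)
class WaterfillSolution:
    """Water level and per-dimension distortion allocation."""

    lam: float
    per_dim_distortion: np.ndarray
    rate_bits: float
    total_distortion: float


@dataclass(frozen=True)
class Codebook:
    """A random Gaussian codebook for block coding of N shape instances.

    ``codewords`` has shape (2^(N R), N B): each row concatenates N
    coefficient vectors.  Components whose prior variance lies below the
    water level are exactly zero in every codeword.
    """

    rate_bits: int
    block_size: int
    lam: float
    codewords: np.ndarray
    seed: int
    variances: np.ndarray
    prior_id: str = ""

    @property
    def size(self) -> int:
        return self.codewords.shape[0]

    @property
    def n_dims(self) -> int:
        """Coefficient dimension per structure (B)."""
        return self.codewords.shape[1] // self.block_size


def rd_rate_single(distortion: float, sigma2: float) -> float:
    """Rate 1/2 log2(sigma^2 / D) of a single Gaussian, 0 beyond the variance."""
    if distortion <= 0:
        raise ValueError(f"distortion must be positive, got {distortion}")
    if sigma2 < 0:
        raise ValueError(f"variance must be non-negative, got {sigma2}")
    if distortion >= sigma2:
        return 0.0
    return 0.5 * np.log2(sigma2 / distortion)


def _allocation(variances: np.ndarray, lam: float) -> np.ndarray:
    return np.minimum(lam, variances)


def _rate_at_level(variances: np.ndarray, lam: float) -> float:
    coded = variances > lam
    if not np.any(coded):
        return 0.0
    return float(0.5 * np.sum(np.log2(variances[coded] / lam)))


def reverse_waterfill(variances, distortion: float) -> WaterfillSolution:
    """Find the water level lambda with sum_i min(lambda, sigma_i^2) = D.

    The allocation is monotone in lambda, so bisection on
    [0, max sigma_i^2] converges unconditionally.  A requested distortion
    above the total variance is clamped to the R = 0 solution.
    """
    variances = np.asarray(variances, float)
    if distortion <= 0:
        raise ValueError(f"distortion must be positive, got {distortion}")
    if np.any(variances < 0):
        raise ValueError("variances must be non-negative")
    total = float(variances.sum())
    hi = float(variances.max())
    if distortion >= total:
        if distortion > total:
            logger.warning(
                "requested distortion %.4g exceeds total variance %.4g; "
                "clamping to the zero-rate solution",
                distortion,
                total,
            )
        return WaterfillSolution(hi, variances.copy(), 0.0, total)

    lo, up = 0.0, hi
    for _ in range(200):
        mid = 0.5 * (lo + up)
        if _allocation(variances, mid).sum() < distortion:
            lo = mid
        else:
            up = mid
        if up - lo <= _BISECT_REL_TOL * hi:
            break
    lam = 0.5 * (lo + up)
    per_dim = _allocation(variances, lam)
    # rescale the waterline so the allocation sums exactly to D
    scale = distortion / per_dim.sum()
    lam *= scale
    per_dim = _allocation(variances, lam)
    return WaterfillSolution(
        lam=lam,
        per_dim_distortion=per_dim,
        rate_bits=_rate_at_level(variances, lam),
        total_distortion=float(per_dim.sum()),
    )


def rate_of_distortion(variances, distortion: float) -> float:
    """R(D) in bits via reverse water-filling."""
    return reverse_waterfill(variances, distortion).rate_bits


def lambda_for_rate(variances, rate_bits: float) -> WaterfillSolution:
    """Invert the rate-distortion curve: water level achieving a target rate.

    Every rate R >= 0 is achievable; R = 0 returns the full-variance
    allocation (a single codeword at the mean).
    """
    variances = np.asarray(variances, float)
    if rate_bits < 0:
        raise ValueError(f"rate must be non-negative, got {rate_bits}")
    hi = float(variances.max())
    if rate_bits == 0:
        return WaterfillSolution(hi, variances.copy(), 0.0, float(variances.sum()))
    # rate is decreasing in lambda; lam = hi * 4^-R guarantees rate >= R
    lo = hi * 4.0 ** (-rate_bits)
    up = hi
    for _ in range(200):
        mid = 0.5 * (lo + up)
        if _rate_at_level(variances, mid) > rate_bits:
            lo = mid
        else:
            up = mid
        if abs(_rate_at_level(variances, mid) - rate_bits) <= _RATE_TOL_BITS:
            break
    lam = 0.5 * (lo + up)
    per_dim = _allocation(variances, lam)
    return WaterfillSolution(
        lam=lam,
        per_dim_distortion=per_dim,
        rate_bits=_rate_at_level(variances, lam),
        total_distortion=float(per_dim.sum()),
    )


def codebook_size(rate_bits: int, block_size: int = 1) -> int:
    """Number of codewords 2^(N R) for rate R bits over blocks of N."""
    if rate_bits < 0 or block_size < 1:
        raise ValueError("rate_bits must be >= 0 and block_size >= 1")
    return 2 ** (block_size * rate_bits)


def make_codebook(
    prior: ShapePrior,
    rate_bits: int,
    block_size: int = 1,
    seed: int = 0,
    size_cap: int = DEFAULT_SIZE_CAP,
) -> Codebook:
    """Draw a random Gaussian codebook at rate R bits per structure.

    Blocks of N structures are coded jointly: the variance spectrum is tiled
    N times and the water level solves the tiled problem at N R total bits
    (by symmetry this equals the single-structure level at R bits).  Each
    codeword component i is N(0, sigma_i^2 - lambda) above the water level
    and exactly zero below it; the draw is reproducible from the seed.
    """
    size = codebook_size(rate_bits, block_size)
    if size > size_cap:
        raise ValueError(
            f"codebook of 2^{block_size * rate_bits} codewords exceeds the size "
            f"cap {size_cap}; lower the rate or raise size_cap"
        )
    tiled = np.tile(prior.variances, block_size)
    sol = lambda_for_rate(tiled, float(block_size * rate_bits))
    coded_var = np.clip(tiled - sol.lam, 0.0, None)
    coded_var[tiled < sol.lam] = 0.0
    rng = np.random.default_rng(seed)
    codewords = rng.standard_normal((size, tiled.shape[0])) * np.sqrt(coded_var)
    if rate_bits == 0:
        codewords = np.zeros_like(codewords)
    return Codebook(
        rate_bits=rate_bits,
        block_size=block_size,
        lam=sol.lam,
        codewords=codewords,
        seed=seed,
        variances=prior.variances.copy(),
    )


_ENCODE_CHUNK = 1 << 14


def encode(beta: np.ndarray, codebook: Codebook) -> int:
    """Index of the nearest codeword in squared Euclidean distance.

    ``beta`` concatenates the coefficient vectors of the N structures in the
    block.  Ties break toward the lowest index.
    """
    beta = np.asarray(beta, float).ravel()
    if beta.shape[0] != codebook.codewords.shape[1]:
        raise ValueError(
            f"expected {codebook.codewords.shape[1]} coefficients "
            f"(N={codebook.block_size} blocks), got {beta.shape[0]}"
        )
    best_idx, best_d2 = 0, np.inf
    for start in range(0, codebook.size, _ENCODE_CHUNK):
        chunk = codebook.codewords[start : start + _ENCODE_CHUNK]
        d2 = np.sum((chunk - beta) ** 2, axis=1)
        i = int(np.argmin(d2))
        if d2[i] < best_d2:
            best_idx, best_d2 = start + i, float(d2[i])
    return best_idx


def decode(index: int, codebook: Codebook) -> np.ndarray:
    """The codeword stored at an index (concatenated block coefficients)."""
    if not 0 <= index < codebook.size:
        raise IndexError(f"codeword index {index} out of range [0, {codebook.size})")
    return codebook.codewords[index].copy()


def encode_decode_batch(samples: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Vectorized nearest-codeword quantization of many blocks at once."""
    samples = np.atleast_2d(np.asarray(samples, float))
    if samples.shape[1] != codebook.codewords.shape[1]:
        raise ValueError(
            f"samples have {samples.shape[1]} coefficients, codebook expects "
            f"{codebook.codewords.shape[1]}"
        )
    cw = codebook.codewords
    cw_sq = np.sum(cw**2, axis=1)
    best_idx = np.zeros(samples.shape[0], dtype=np.int64)
    best_d2 = np.full(samples.shape[0], np.inf)
    for start in range(0, codebook.size, _ENCODE_CHUNK):
        chunk, chunk_sq = cw[start : start + _ENCODE_CHUNK], cw_sq[start : start + _ENCODE_CHUNK]
        # |s - c|^2 = |s|^2 - 2 s.c + |c|^2; |s|^2 constant per sample
        d2 = chunk_sq[None, :] - 2.0 * samples @ chunk.T
        i = np.argmin(d2, axis=1)
        d2min = d2[np.arange(samples.shape[0]), i]
        better = d2min < best_d2  # strict: ties keep the lower index
        best_idx[better] = start + i[better]
        best_d2[better] = d2min[better]
    return cw[best_idx]


def empirical_distortion(samples: np.ndarray, codebook: Codebook) -> float:
    """Mean squared quantization error per structure over sample blocks."""
    samples = np.atleast_2d(np.asarray(samples, float))
    if samples.shape[0] < 1:
        raise ValueError("need at least one sample")
    decoded = encode_decode_batch(samples, codebook)
    sq = np.sum((samples - decoded) ** 2, axis=1)
    return float(sq.mean() / codebook.block_size)


def save_codebook(codebook: Codebook, path: str | Path) -> None:
    """Flat float64 binary + JSON metadata sidecar."""
    path = Path(path)
    codebook.codewords.astype("<f8").tofile(path)
    meta = {
        "rate_bits": codebook.rate_bits,
        "block_size": codebook.block_size,
        "lambda": codebook.lam,
        "seed": codebook.seed,
        "prior_id": codebook.prior_id,
        "variances": codebook.variances.tolist(),
        "shape": list(codebook.codewords.shape),
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_codebook(path: str | Path) -> Codebook:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    shape = tuple(meta["shape"])
    codewords = np.fromfile(path, dtype="<f8").reshape(shape)
    return Codebook(
        rate_bits=meta["rate_bits"],
        block_size=meta["block_size"],
        lam=meta["lambda"],
        codewords=codewords,
        seed=meta["seed"],
        variances=np.asarray(meta["variances"]),
        prior_id=meta.get("prior_id", ""),
    )
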