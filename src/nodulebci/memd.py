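"""Multivariate empirical mode decomposition (MEMD).

MEMD extends envelope-mean sifting to multichannel signals: the signal is
projected along a set of direction vectors on the unit hypersphere, the
extrema of each projection anchor a multivariate envelope (a cubic spline
through the multichannel signal values at those time points), and the mean
of those envelopes is subtracted iteratively until an intrinsic mode
function (IMF) emerges.  Because all channels are sifted jointly, every
channel receives the same number of IMFs with matched frequency content —
the property that makes cross-channel phase/frequency comparisons between
mode indices meaningful.

The decomposition telescopes, so the sum of the IMFs plus the residual
reconstructs the input exactly up to floating point.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg.lapack import dgtsv as _dgtsv
from scipy.signal import find_peaks
from scipy.special import ndtri

from .errors import DataError, ValidationError

__all__ = ["DirectionSet", "IMFSet", "generate_directions", "envelope_mean", "memd"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DirectionSet:
    """K unit vectors in R^dim, approximately uniform on the hypersphere."""

    vectors: np.ndarray  # (K, dim)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2:
            raise ValidationError("vectors must be 2-D (K, dim)")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValidationError("direction vectors must have unit norm")
        object.__setattr__(self, "vectors", v)

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class IMFSet:
    """Count-aligned IMFs: imfs has shape (n_imfs, n_channels, n_samples)."""

    imfs: np.ndarray
    residual: np.ndarray

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        if self.n_imfs == 0:
            return self.residual.copy()
        return self.imfs.sum(axis=0) + self.residual


def _radical_inverse(base: int, idx: np.ndarray) -> np.ndarray:
    i = idx.astype(np.int64).copy()
    r = np.zeros(len(i))
    f = 1.0 / base
    while np.any(i > 0):
        r += f * (i % base)
        i //= base
        f /= base
    return r


_PRIMES = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59, 61]


def generate_directions(K: int, dim: int, seed: int = 0) -> DirectionSet:
    """Low-discrepancy direction set on the (dim-1)-sphere.

    A Hammersley point set in the unit cube is given a seeded
    Cranley-Patterson rotation, pushed through the inverse normal CDF
    (making the point cloud rotation-invariant in law), and normalised to
    unit length.  The set is antithetic — each direction is paired with its
    negation — so every projection sees both its maxima and (via the paired
    direction) its minima, and the envelope mean of a symmetric oscillation
    cancels as in classic bivariate sifting.  Deterministic for a given
    seed.
    """
    if dim < 2:
        raise ValidationError("dim must be >= 2 (univariate input needs plain EMD)")
    if K < dim:
        raise ValidationError("need at least as many directions as channels")
    if dim - 1 > len(_PRIMES):
        raise ValidationError(f"dim={dim} exceeds supported direction dimension")
    half = (K + 1) // 2
    idx = np.arange(half)
    pts = np.empty((half, dim))
    pts[:, 0] = (idx + 0.5) / half
    for d in range(1, dim):
        pts[:, d] = _radical_inverse(_PRIMES[d - 1], idx)
    shift = np.random.default_rng(seed).random(dim)
    pts = (pts + shift) % 1.0
    z = ndtri(np.clip(pts, 1e-12, 1 - 1e-12))
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    v = z / norms
    return DirectionSet(vectors=np.concatenate([v, -v], axis=0)[:K])


def _mirror_anchors(
    maxima: np.ndarray, signal: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor points plus extrema mirrored about both signal edges.

    Mirroring suppresses spline end-swings; the signal values at the
    reflected time points are the values at the original extrema.
    """
    n = signal.shape[1]
    vals = signal[:, maxima]
    k = min(2, len(maxima))
    left_t = -maxima[:k][::-1]
    left_v = vals[:, :k][:, ::-1]
    right_t = 2 * (n - 1) - maxima[-k:][::-1]
    right_v = vals[:, -k:][:, ::-1]
    # find_peaks never returns edge samples, so the mirrored anchor times
    # are strictly increasing without deduplication
    t = np.concatenate([left_t, maxima, right_t])
    v = np.concatenate([left_v, vals, right_v], axis=1)
    return t, v


def _natural_spline_eval(
    t_anchor: np.ndarray, v_anchor: np.ndarray, n_samples: int
) -> np.ndarray:
    """Natural cubic spline through (t_anchor, v_anchor) sampled at 0..n-1.

    v_anchor is (n_channels, n_anchors); all channels share the knots, so
    one banded solve interpolates the whole multivariate envelope.  Falls
    back to linear interpolation with fewer than three anchors.
    """
    t = np.arange(n_samples)
    m = len(t_anchor)
    if m < 3:
        return np.vstack([
            np.interp(t, t_anchor, v_anchor[ch]) for ch in range(len(v_anchor))
        ])
    h = np.diff(t_anchor).astype(float)          # (m-1,)
    slopes = np.diff(v_anchor, axis=1) / h       # (ch, m-1)
    # second derivatives M, natural boundary: M[0] = M[-1] = 0
    M = np.zeros_like(v_anchor)
    rhs = 6.0 * np.diff(slopes, axis=1).T        # (m-2, ch)
    _, _, _, x, info = _dgtsv(
        h[1:-1], 2.0 * (h[:-1] + h[1:]), h[1:-1], rhs
    )
    if info != 0:  # pragma: no cover - anchors are strictly increasing
        raise DataError("spline system is singular")
    M[:, 1:-1] = x.T
    idx = np.clip(np.searchsorted(t_anchor, t, side="right") - 1, 0, m - 2)
    hi = h[idx]
    dl = (t - t_anchor[idx]) / hi                # in [0, 1]
    dr = 1.0 - dl
    h2 = (hi * hi) / 6.0
    z0 = M[:, idx] * h2
    z1 = M[:, idx + 1] * h2
    return (
        dr * (v_anchor[:, idx] - z0 + z0 * dr * dr)
        + dl * (v_anchor[:, idx + 1] - z1 + z1 * dl * dl)
    )


def envelope_mean(
    signal: np.ndarray, directions: DirectionSet
) -> tuple[np.ndarray | None, int]:
    """Mean m(t) of the multivariate envelopes over all usable directions.

    For each direction the signal is projected, the projection's local maxima
    anchor a per-channel cubic-spline envelope, and the envelopes are
    averaged over directions.  A direction whose projection has fewer than
    two maxima is skipped; if every direction is degenerate the signal is a
    residual and (None, 0) is returned.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[1]
    env_sum = np.zeros_like(signal)
    used = 0
    for x in directions.vectors:
        p = x @ signal
        maxima, _ = find_peaks(p)
        if len(maxima) < 2:
            continue
        t_anchor, v_anchor = _mirror_anchors(maxima, signal)
        env_sum += _natural_spline_eval(t_anchor, v_anchor, n)
        used += 1
    if used == 0:
        return None, 0
    return env_sum / used, used


def _n_projection_extrema(signal: np.ndarray, directions: DirectionSet) -> int:
    """Maximum extrema count (maxima + minima) over all projections."""
    most = 0
    for x in directions.vectors:
        p = x @ signal
        most = max(most, len(find_peaks(p)[0]) + len(find_peaks(-p)[0]))
    return most


def memd(
    signal: np.ndarray,
    K: int = 64,
    max_imfs: int = 8,
    sift_rtol: float = 0.05,
    sift_quantile: float = 0.95,
    max_sift_iters: int = 15,
    seed: int = 0,
) -> IMFSet:
    """Decompose a (n_channels, n_samples) signal into count-aligned IMFs.

    Sifting stops when the multivariate envelope mean is small relative to
    the current proto-IMF (``||m(t)|| / ||d(t)|| < sift_rtol`` across
    channels at a ``sift_quantile`` fraction of samples) or after
    ``max_sift_iters`` iterations, whichever comes first; failure to
    converge accepts the current proto-IMF and logs.  The decomposition
    stops at ``max_imfs`` or when the residual is monotone (fewer than
    three extrema) along every test projection.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValidationError("signal must be 2-D (n_channels, n_samples)")
    if signal.shape[0] < 2:
        raise ValidationError("memd needs >= 2 channels")
    if not np.all(np.isfinite(signal)):
        raise DataError("signal contains non-finite samples")

    directions = generate_directions(K, signal.shape[0], seed=seed)
    residual = signal.copy()
    imfs: list[np.ndarray] = []

    while len(imfs) < max_imfs:
        if _n_projection_extrema(residual, directions) < 3:
            break
        d = residual.copy()
        converged = False
        for _ in range(max_sift_iters):
            m, used = envelope_mean(d, directions)
            if m is None:
                converged = True
                break
            norm_m = np.linalg.norm(m, axis=0)
            norm_d = np.linalg.norm(d, axis=0)
            # a zero proto-IMF sample with zero envelope mean counts as small
            small = np.mean(norm_m < sift_rtol * norm_d + 1e-300)
            d = d - m
            if small >= sift_quantile:
                converged = True
                break
        if not converged:
            logger.info("sifting hit max_sift_iters; accepting current proto-IMF")
        if not np.any(d):
            break
        imfs.append(d)
        residual = residual - d

    imf_arr = (
        np.stack(imfs) if imfs
        else np.empty((0,) + signal.shape)
    )
    return IMFSet(imfs=imf_arr, residual=residual)
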