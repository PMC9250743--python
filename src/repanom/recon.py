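"""Period standardization, PCA reconstruction, and scaled reconstruction error.

Each segmented repetition is warped onto a standard length of ``n`` slots
using the CDTW matching (samples sharing a slot are averaged; empty slots are
filled by linear interpolation over the circular slot axis).  Per feature
channel the warped period is flattened to an N_c-vector (N_c = 2n for AZEQ
sphere channels, n for scalars), standardized to zero mean / unit variance
per dimension, and passed through the PCA dimensionality bottleneck

    c_hat = U_r^T U_r c

with U_r the smallest set of leading principal components explaining at
least 95% of the training variance.  The reconstruction is inverted through
the whole chain — unstandardize, un-warp to the original segment length,
AZEQ-unproject — and compared to the original samples: angle between unit
vectors for sphere channels, absolute difference for scalars.  Errors are
finally divided by the root mean square of the training error at the same
discrete phase, putting all channels and phases on a common scale so one
global threshold applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .features import Channel, SphereProjection, azeq_unproject

__all__ = [
    "ChannelModel",
    "StandardPeriod",
    "warp_to_standard",
    "fit_channel_model",
    "select_n_components",
    "reconstruct",
    "invert_chain",
    "reconstruction_error",
    "scale_errors",
    "fit_error_scale",
]

_SD_FLOOR = 1e-8
_SCALE_FLOOR = 1e-12


@dataclass
class StandardPeriod:
    """One repetition warped to ``n`` slots, per channel.

    ``slots``: channel name -> (n, flat_dim) array (2 cols for spheres, 1 for
    scalars).  ``bins``: per original sample, the slot index it maps back to
    (the middle matched template row).  ``start``/``end`` are the source
    segment bounds; ``partial`` marks first/last segments.
    """

    slots: dict[str, np.ndarray]
    bins: np.ndarray
    start: int
    end: int
    partial: bool
    n: int

    def flat(self, name: str) -> np.ndarray:
        """Channel slots flattened slot-major to an N_c vector."""
        return self.slots[name].reshape(-1)


def _fill_empty_circular(values: np.ndarray, filled: np.ndarray) -> np.ndarray:
    """Linear interpolation of empty slots over the circular slot axis."""
    n = values.shape[0]
    if filled.all():
        return values
    if not filled.any():
        raise ValueError("no slot received any sample")
    idx_f = np.nonzero(filled)[0]
    for i in np.nonzero(~filled)[0]:
        prev_pos = idx_f[np.searchsorted(idx_f, i) - 1] if np.any(idx_f < i) else idx_f[-1]
        nxt_candidates = idx_f[idx_f > i]
        nxt_pos = nxt_candidates[0] if nxt_candidates.size else idx_f[0]
        d_prev = (i - prev_pos) % n
        d_next = (nxt_pos - i) % n
        w = d_prev / (d_prev + d_next)
        values[i] = (1 - w) * values[prev_pos] + w * values[nxt_pos]
    return values


def warp_to_standard(
    flat_segment: np.ndarray,
    run_lo: np.ndarray,
    run_hi: np.ndarray,
    i_mid: np.ndarray,
    round_index: int,
    n: int,
    flat_slices: dict[str, slice],
    start: int = 0,
    partial: bool = False,
) -> StandardPeriod:
    """Warp one segmented period onto ``n`` standard slots.

    ``flat_segment`` is the (L, D) AZEQ-flattened feature slice of the
    segment; ``run_lo``/``run_hi``/``i_mid`` are the unwrapped matched-row
    runs of its columns from the CDTW path.  Slot i collects (and averages)
    every sample whose run covers unwrapped row round_index*n + i; sphere
    channels are averaged in the AZEQ plane.
    """
    L, D = flat_segment.shape
    if L < 2:
        raise ValueError("segment must contain at least 2 samples")
    base = round_index * n
    acc = np.zeros((n, D))
    cnt = np.zeros(n, dtype=int)
    for j in range(L):
        lo = max(run_lo[j] - base, 0)
        hi = min(run_hi[j] - base, n - 1)
        for i in range(lo, hi + 1):
            acc[i] += flat_segment[j]
            cnt[i] += 1
    filled = cnt > 0
    acc[filled] /= cnt[filled, None]
    acc = _fill_empty_circular(acc, filled)
    bins = np.clip(i_mid - base, 0, n - 1).astype(int)
    slots = {name: acc[:, sl] for name, sl in flat_slices.items()}
    return StandardPeriod(slots, bins, start, start + L, partial, n)


@dataclass
class ChannelModel:
    """Learned per-channel statistics: standardization, PCA bottleneck, and
    per-phase-bin error scaling."""

    channel: Channel
    mean: np.ndarray  # (N_c,)
    sd: np.ndarray  # (N_c,) strictly positive (floored)
    U_r: np.ndarray  # (N_d, N_c) orthonormal rows
    explained_ratio: np.ndarray  # full explained-variance-ratio curve
    n: int
    var_threshold: float = 0.95
    error_scale: np.ndarray | None = None  # (n,) per-bin mean square error

    @property
    def n_components(self) -> int:
        return self.U_r.shape[0]

    def standardize(self, c: np.ndarray) -> np.ndarray:
        return (c - self.mean) / self.sd

    def unstandardize(self, z: np.ndarray) -> np.ndarray:
        return z * self.sd + self.mean


def select_n_components(explained_ratio: np.ndarray, threshold: float) -> int:
    """Smallest component count whose cumulative explained variance reaches
    the threshold (monotone in the threshold)."""
    cum = np.cumsum(explained_ratio)
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def fit_channel_model(
    training_vectors: np.ndarray,
    channel: Channel,
    n: int,
    var_threshold: float = 0.95,
) -> ChannelModel:
    """Standardization + PCA bottleneck from (P, N_c) training period vectors."""
    X = np.asarray(training_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training periods")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < _SD_FLOOR, _SD_FLOOR, sd)
    Z = (X - mean) / sd
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    ratio = pca.explained_variance_ratio_
    nd = select_n_components(ratio, var_threshold)
    U_r = pca.components_[:nd].copy()
    return ChannelModel(channel, mean, sd, U_r, ratio, n, var_threshold)


def reconstruct(c: np.ndarray, U_r: np.ndarray) -> np.ndarray:
    """PCA bottleneck reconstruction c_hat = U_r^T (U_r c); an idempotent
    orthogonal projection.  Accepts a vector or a (P, N_c) stack."""
    c = np.asarray(c, dtype=float)
    if c.shape[-1] != U_r.shape[1]:
        raise ValueError("vector length does not match the model dimensions")
    return (c @ U_r.T) @ U_r


def invert_chain(
    standard_recon_flat: np.ndarray,
    model: ChannelModel,
    bins: np.ndarray,
    projection: SphereProjection | None = None,
) -> np.ndarray:
    """Invert standardization, warping and (for spheres) AZEQ.

    ``standard_recon_flat`` is the reconstructed standardized N_c-vector;
    each original sample receives the value of its slot (piecewise-constant
    inverse of the warp), and sphere channels are unprojected back to 3D unit
    vectors.
    """
    n = model.n
    vec = model.unstandardize(np.asarray(standard_recon_flat, dtype=float))
    dim = model.channel.flat_dim
    slots = vec.reshape(n, dim)
    per_sample = slots[np.asarray(bins, dtype=int)]
    if model.channel.kind == "sphere3":
        if projection is None:
            raise ValueError("sphere channel inversion needs its projection")
        return azeq_unproject(per_sample, projection)
    return per_sample[:, 0]


def reconstruction_error(original: np.ndarray, reconstructed: np.ndarray, kind: str) -> np.ndarray:
    """Per-sample error: angle between unit vectors (sphere3), |difference|
    (scalar)."""
    original = np.asarray(original, dtype=float)
    reconstructed = np.asarray(reconstructed, dtype=float)
    if original.shape != reconstructed.shape:
        raise ValueError("length mismatch between original and reconstruction")
    if kind == "sphere3":
        dots = np.einsum("ij,ij->i", original, reconstructed)
        dots /= np.linalg.norm(original, axis=1) * np.linalg.norm(reconstructed, axis=1)
        return np.arccos(np.clip(dots, -1.0, 1.0))
    return np.abs(original - reconstructed)


def fit_error_scale(
    errors: np.ndarray, bins: np.ndarray, n: int, min_count: int = 3
) -> np.ndarray:
    """Per-phase-bin mean square of training reconstruction errors.

    Bins with fewer than ``min_count`` training samples borrow the channel's
    global mean square; everything is floored away from zero.
    """
    errors = np.asarray(errors, dtype=float)
    bins = np.asarray(bins, dtype=int)
    sq = errors**2
    global_ms = max(float(sq.mean()), _SCALE_FLOOR)
    scale = np.full(n, global_ms)
    counts = np.bincount(bins, minlength=n)
    sums = np.bincount(bins, weights=sq, minlength=n)
    ok = counts >= min_count
    scale[ok] = np.maximum(sums[ok] / counts[ok], _SCALE_FLOOR)
    return scale


def scale_errors(errors: np.ndarray, bins: np.ndarray, error_scale: np.ndarray) -> np.ndarray:
    """Divide errors by the training RMS at the same phase bin, so scaled
    training errors have mean square ~= 1 per bin."""
    return np.asarray(errors, dtype=float) / np.sqrt(error_scale[np.asarray(bins, dtype=int)])
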