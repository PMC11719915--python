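"""Frame-theoretic pooling/unpooling operators for encoder-decoders.

Three non-local bases are provided, all stride-2 and dimension-generic
(the networks use them in 3D):

* **Orthonormal average pooling** ``Φ⊤`` — block mean scaled by
  ``2^(ndim/2)`` so that its rows are orthonormal and the unpooling
  ``Φ`` is the exact adjoint with ``Φ⊤Φ = I``.  The *extended* pair
  ``[I; Φ⊤]`` used by a standard U-Net skip connection does **not**
  satisfy the frame condition: naive synthesis ``x + ΦΦ⊤x`` duplicates
  the low-frequency (block-constant) component.
* **Dual-frame decomposition** — the canonical left inverse of the
  extended pooling, ``x ↦ (I − ΦΦ⊤/2)·bypass + Φ·coarse/2``.  The frame
  condition holds exactly, at the price of noise amplification governed
  by ``cond(I + ΦΦ⊤) = 2`` (``ΦΦ⊤`` is an orthogonal projection, so the
  spectrum of ``I + ΦΦ⊤`` is {1, 2}).
* **3D Haar tight filter bank** — separable tensor products of the 1D
  pair ``(1,1)/√2``, ``(1,−1)/√2``, giving ``2^ndim`` (= 8 in 3D)
  stride-2 subbands with Parseval energy preservation and exact
  reconstruction: a tight frame, hence no noise amplification.

A plain (unnormalized) averaging convention is available behind the
``orthonormal`` flag for literal comparison with block-mean notation;
all frame identities hold under either convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "avg_pool",
    "avg_unpool",
    "condition_number_extended",
    "dual_frame_decompose",
    "dual_frame_reconstruct",
    "haar_analysis",
    "haar_synthesis",
    "weighted_sum",
    "reflect_pad_to_even",
    "HAAR_SUBBAND_LABELS",
]


def _check_even(x: np.ndarray) -> None:
    if any(s % 2 for s in x.shape):
        raise ValueError(
            f"spatial sizes must be even, got {x.shape}; "
            "use reflect_pad_to_even() first"
        )


def avg_pool(x: np.ndarray, orthonormal: bool = True) -> np.ndarray:
    """Stride-2 average pooling ``Φ⊤`` over 2^ndim blocks.

    With ``orthonormal=True`` the block mean is scaled by ``2^(ndim/2)``
    so the analysis rows are orthonormal (``Φ⊤Φ = I``); otherwise the
    plain block mean is returned.
    """
    x = np.asarray(x, float)
    _check_even(x)
    for ax in range(x.ndim):
        n = x.shape[ax]
        x = x.reshape(x.shape[:ax] + (n // 2, 2) + x.shape[ax + 1 :]).mean(
            axis=ax + 1
        )
    if orthonormal:
        x = x * (2.0 ** (x.ndim / 2.0))
    return x


def avg_unpool(y: np.ndarray, orthonormal: bool = True) -> np.ndarray:
    """Unpooling ``Φ``: the adjoint of orthonormal pooling, or plain
    nearest-neighbour replication in the unnormalized convention."""
    y = np.asarray(y, float)
    out = y
    for ax in range(y.ndim):
        out = np.repeat(out, 2, axis=ax)
    if orthonormal:
        out = out * (2.0 ** (-y.ndim / 2.0))
    return out


def condition_number_extended(signal_shape) -> float:
    """Condition number of ``I + ΦΦ⊤`` assembled densely.

    ``signal_shape`` may be an int (1D) or a tuple of even sizes.  The
    operator is applied to every basis vector, symmetrized against
    round-off, and the ratio of extreme eigenvalues returned.  Because
    ``ΦΦ⊤`` is an orthogonal projection this equals 2 on every shape.
    """
    if np.isscalar(signal_shape):
        signal_shape = (int(signal_shape),)
    shape = tuple(int(s) for s in signal_shape)
    n = int(np.prod(shape))
    if n > 4096:
        raise ValueError("dense assembly is intended for small shapes")
    M = np.empty((n, n))
    basis = np.zeros(n)
    for j in range(n):
        basis[:] = 0.0
        basis[j] = 1.0
        e = basis.reshape(shape)
        M[:, j] = (e + avg_unpool(avg_pool(e))).ravel()
    eig = np.linalg.eigvalsh((M + M.T) / 2.0)
    return float(eig[-1] / eig[0])


def dual_frame_decompose(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extended analysis: the bypass branch and the pooled branch."""
    x = np.asarray(x, float)
    _check_even(x)
    return x.copy(), avg_pool(x)


def dual_frame_reconstruct(bypass: np.ndarray, coarse: np.ndarray) -> np.ndarray:
    """Canonical dual-frame synthesis ``(I − ΦΦ⊤/2)·bypass + Φ·coarse/2``.

    Satisfies ``reconstruct(decompose(x)) == x`` exactly.
    """
    bypass = np.asarray(bypass, float)
    coarse = np.asarray(coarse, float)
    if tuple(2 * s for s in coarse.shape) != bypass.shape:
        raise ValueError(
            f"coarse shape {coarse.shape} incompatible with bypass {bypass.shape}"
        )
    return (
        bypass
        - avg_unpool(avg_pool(bypass)) / 2.0
        + avg_unpool(coarse) / 2.0
    )


#: Subband labels in analysis output order; character i is the filter
#: applied along axis i ('l' low-pass, 'h' high-pass).
HAAR_SUBBAND_LABELS = tuple(
    "".join("lh"[(k >> (2 - i)) & 1] for i in range(3)) for k in range(8)
)


def _haar_axis_analysis(x: np.ndarray, ax: int) -> tuple[np.ndarray, np.ndarray]:
    even = x.take(np.arange(0, x.shape[ax], 2), axis=ax)
    odd = x.take(np.arange(1, x.shape[ax], 2), axis=ax)
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    return (even + odd) * inv_sqrt2, (even - odd) * inv_sqrt2


def _haar_axis_synthesis(lo: np.ndarray, hi: np.ndarray, ax: int) -> np.ndarray:
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    even = (lo + hi) * inv_sqrt2
    odd = (lo - hi) * inv_sqrt2
    shape = list(lo.shape)
    shape[ax] *= 2
    out = np.empty(shape)
    sl_even = [slice(None)] * lo.ndim
    sl_even[ax] = slice(0, None, 2)
    sl_odd = [slice(None)] * lo.ndim
    sl_odd[ax] = slice(1, None, 2)
    out[tuple(sl_even)] = even
    out[tuple(sl_odd)] = odd
    return out


def haar_analysis(x: np.ndarray) -> list[np.ndarray]:
    """Orthonormal separable Haar analysis into ``2^ndim`` subbands.

    Subband ``k`` applies low/high-pass along axis ``i`` according to
    bit ``i`` of ``k`` (see :data:`HAAR_SUBBAND_LABELS` for 3D).  Each
    subband has half the size along every axis; the transform is
    orthonormal, so energies add up to the input energy (Parseval).
    """
    x = np.asarray(x, float)
    _check_even(x)
    bands = [x]
    for ax in range(x.ndim):
        nxt: list[np.ndarray] = []
        for b in bands:
            lo, hi = _haar_axis_analysis(b, ax)
            nxt.extend([lo, hi])
        bands = nxt
    return bands


def haar_synthesis(subbands: list[np.ndarray]) -> np.ndarray:
    """Exact inverse of :func:`haar_analysis`."""
    n = len(subbands)
    ndim = int(np.log2(n))
    if 2**ndim != n:
        raise ValueError("subband count must be a power of two")
    bands = [np.asarray(b, float) for b in subbands]
    if any(b.shape != bands[0].shape for b in bands):
        raise ValueError("all subbands must share one shape")
    for ax in reversed(range(ndim)):
        nxt = []
        for i in range(0, len(bands), 2):
            nxt.append(_haar_axis_synthesis(bands[i], bands[i + 1], ax))
        bands = nxt
    return bands[0]


def weighted_sum(tensors, weights) -> np.ndarray:
    """``Σ_i w_i · t_i`` over same-shaped tensors.

    This is the lightweight merge used by the tight-frame network in
    place of channel concatenation + convolution: one scalar per merged
    tensor (9 per merge point: 8 subband branches plus the bypass).
    """
    tensors = [np.asarray(t, float) for t in tensors]
    weights = np.asarray(weights, float).ravel()
    if len(tensors) != weights.size:
        raise ValueError("one weight per tensor required")
    shape = tensors[0].shape
    if any(t.shape != shape for t in tensors):
        raise ValueError("all tensors must share one shape")
    out = np.zeros(shape)
    for w, t in zip(weights, tensors):
        out += w * t
    return out


def reflect_pad_to_even(x: np.ndarray) -> np.ndarray:
    """Reflect-pad each odd-sized axis by one sample at the far end."""
    x = np.asarray(x)
    pad = [(0, s % 2) for s in x.shape]
    if not any(p[1] for p in pad):
        return x
    return np.pad(x, pad, mode="reflect")
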