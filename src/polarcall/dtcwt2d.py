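"""2-D dual-tree complex wavelet transform (DTCWT).

The dual tree runs four real separable DWTs (one per row-tree/column-tree
combination) whose filters are offset by approximately a quarter sample
between trees.  Combining the four real subbands pairwise yields six
complex, directionally selective subbands per level whose magnitudes are
nearly shift invariant — the property that makes coefficient-magnitude
selection a good focus measure for all-in-focus fusion.

Filter choices:

* level 1: CDF 9/7 biorthogonal filters; the second tree filters the
  signal advanced by one sample, which realises the required half-sample
  offset at the first scale,
* levels >= 2: Kingsbury's 14-tap Q-shift scaling filter (its group delay
  is ~1/4 sample; the second tree uses the time-reversed filter, delay
  ~3/4 sample).  The printed coefficients are re-orthogonalised
  numerically at import time so each tree is an exactly orthonormal
  filter bank and the whole transform is perfect-reconstruction to
  machine precision.

All filtering is done by PyWavelets with periodic ("periodization")
signal extension, so input sides must be divisible by 2**nlevels; callers
pad and crop (see :mod:`polarcall.fusion`).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.optimize import least_squares

__all__ = ["dtcwt2d_forward", "dtcwt2d_inverse", "Pyramid"]

# Kingsbury's 14-tap Q-shift scaling filter (standard published values).
_QSHIFT_14 = np.array(
    [
        0.00325314,
        -0.00388321,
        0.03466035,
        -0.03887280,
        -0.11720389,
        0.27529538,
        0.75614564,
        0.56881042,
        0.01186609,
        -0.10671180,
        0.02382538,
        0.01702522,
        -0.00543948,
        -0.00455690,
    ]
)


def _orthonormalize_scaling_filter(h: np.ndarray) -> np.ndarray:
    """Project a near-orthonormal scaling filter onto the orthonormality
    constraints sum(h)=sqrt(2) and sum_n h[n] h[n+2k] = delta_k.

    The printed coefficients are rounded to 8 decimals; solving the
    constraint system from that starting point restores perfect
    reconstruction (residual ~1e-15) without moving any tap by more than
    ~1e-7.
    """
    n = h.size

    def residual(x):
        out = [x.sum() - np.sqrt(2.0), np.dot(x, x) - 1.0]
        for k in range(1, n // 2):
            out.append(np.dot(x[: n - 2 * k], x[2 * k :]))
        # weak pull toward the published taps fixes the underdetermined
        # directions without perturbing the hard constraints
        return np.concatenate([np.asarray(out, float), 1e-8 * (x - h)])

    sol = least_squares(residual, h, xtol=1e-15, ftol=1e-15, gtol=1e-15).x
    worst = max(
        abs(np.dot(sol[: n - 2 * k], sol[2 * k :])) for k in range(1, n // 2)
    )
    worst = max(worst, abs(np.dot(sol, sol) - 1.0), abs(sol.sum() - np.sqrt(2.0)))
    if worst > 1e-12:
        raise RuntimeError("Q-shift filter orthonormalization failed")
    return sol


def _build_wavelets():
    h0a = _orthonormalize_scaling_filter(_QSHIFT_14)
    h0b = h0a[::-1].copy()
    wav_a = pywt.Wavelet("qshift14a", filter_bank=pywt.orthogonal_filter_bank(h0a))
    wav_b = pywt.Wavelet("qshift14b", filter_bank=pywt.orthogonal_filter_bank(h0b))
    wav_l1 = pywt.Wavelet("bior4.4")
    return wav_l1, (wav_a, wav_b)


_WAV_L1, _WAV_Q = _build_wavelets()


class Pyramid:
    """DTCWT coefficient pyramid.

    Attributes
    ----------
    lowpass : ndarray, shape (2, 2, h, w)
        Residual lowpass image of each (row-tree, col-tree) combination.
    highpasses : list of ndarray
        One complex array per level, shape (6, h_l, w_l); axis 0 indexes
        the six orientations (±15°, ±45°, ±75°).
    shape : tuple
        Shape of the analysed image.
    """

    def __init__(self, lowpass, highpasses, shape):
        self.lowpass = lowpass
        self.highpasses = highpasses
        self.shape = shape


def _q2c(aa, ab, ba, bb):
    """Four real subbands (row-tree x col-tree) -> two complex orientations."""
    z1 = (aa - bb) + 1j * (ab + ba)
    z2 = (aa + bb) + 1j * (ab - ba)
    return z1 / 2.0, z2 / 2.0


def _c2q(z1, z2):
    z1 = z1 * 2.0
    z2 = z2 * 2.0
    aa = (z1.real + z2.real) / 2.0
    bb = (z2.real - z1.real) / 2.0
    ab = (z1.imag + z2.imag) / 2.0
    ba = (z1.imag - z2.imag) / 2.0
    return aa, ab, ba, bb


def dtcwt2d_forward(image: np.ndarray, nlevels: int) -> Pyramid:
    """Forward 2-D DTCWT.

    Parameters
    ----------
    image : 2-D float array; both sides must be divisible by 2**nlevels.
    nlevels : number of decomposition levels (>= 1).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("dtcwt2d_forward expects a 2-D image")
    if nlevels < 1:
        raise ValueError("nlevels must be >= 1")
    h, w = image.shape
    if h % (1 << nlevels) or w % (1 << nlevels):
        raise ValueError(
            f"image sides {image.shape} must be divisible by 2**{nlevels}"
        )

    # level 1: same biorthogonal filters, tree b takes the odd sampling
    # phase (input advanced by one sample along the tree's axis)
    low = {}
    bands1 = {}
    for rt in (0, 1):
        for ct in (0, 1):
            x = image
            if rt:
                x = np.roll(x, -1, axis=0)
            if ct:
                x = np.roll(x, -1, axis=1)
            cA, (cH, cV, cD) = pywt.dwt2(x, _WAV_L1, mode="periodization")
            low[rt, ct] = cA
            bands1[rt, ct] = (cH, cV, cD)
    highpasses = [_combine(bands1)]

    # deeper levels: tree-specific Q-shift filters per axis
    for _ in range(1, nlevels):
        bands = {}
        for rt in (0, 1):
            for ct in (0, 1):
                wav = (_WAV_Q[rt], _WAV_Q[ct])
                cA, (cH, cV, cD) = pywt.dwt2(
                    low[rt, ct], wav, mode="periodization"
                )
                low[rt, ct] = cA
                bands[rt, ct] = (cH, cV, cD)
        highpasses.append(_combine(bands))

    lowpass = np.stack(
        [np.stack([low[0, 0], low[0, 1]]), np.stack([low[1, 0], low[1, 1]])]
    )
    return Pyramid(lowpass, highpasses, image.shape)


def _combine(bands):
    """Stack the 6 oriented complex subbands from the 4 trees' (H,V,D)."""
    out = []
    for k in range(3):  # H (LH), V (HL), D (HH)
        aa = bands[0, 0][k]
        ab = bands[0, 1][k]
        ba = bands[1, 0][k]
        bb = bands[1, 1][k]
        z1, z2 = _q2c(aa, ab, ba, bb)
        out.extend([z1, z2])
    return np.stack(out)


def _split(highpass):
    """Inverse of :func:`_combine`."""
    bands = {}
    for k in range(3):
        z1 = highpass[2 * k]
        z2 = highpass[2 * k + 1]
        aa, ab, ba, bb = _c2q(z1, z2)
        for (rt, ct), v in (((0, 0), aa), ((0, 1), ab), ((1, 0), ba), ((1, 1), bb)):
            bands.setdefault((rt, ct), [None, None, None])[k] = v
    return bands


def dtcwt2d_inverse(pyr: Pyramid) -> np.ndarray:
    """Inverse 2-D DTCWT: reconstruct each of the four trees and average."""
    nlevels = len(pyr.highpasses)
    low = {
        (rt, ct): pyr.lowpass[rt, ct].copy() for rt in (0, 1) for ct in (0, 1)
    }
    for lev in range(nlevels - 1, 0, -1):
        bands = _split(pyr.highpasses[lev])
        for rt in (0, 1):
            for ct in (0, 1):
                wav = (_WAV_Q[rt], _WAV_Q[ct])
                cH, cV, cD = bands[rt, ct]
                low[rt, ct] = pywt.idwt2(
                    (low[rt, ct], (cH, cV, cD)), wav, mode="periodization"
                )

    bands = _split(pyr.highpasses[0])
    recons = []
    for rt in (0, 1):
        for ct in (0, 1):
            cH, cV, cD = bands[rt, ct]
            x = pywt.idwt2(
                (low[rt, ct], (cH, cV, cD)), _WAV_L1, mode="periodization"
            )
            if rt:
                x = np.roll(x, 1, axis=0)
            if ct:
                x = np.roll(x, 1, axis=1)
            recons.append(x)
    return np.mean(recons, axis=0)
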