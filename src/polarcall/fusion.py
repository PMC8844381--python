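"""Z-stack compression: all-in-focus fusion (DIC) and maximum projection.

A DIC z-stack images each blastomere sharply only near its own focal
plane.  The all-in-focus (AIF) fusion decomposes every slice with the
dual-tree complex wavelet transform, keeps — per subband coefficient —
the coefficient from the slice where its complex magnitude is largest
(magnitude is a local, orientation-selective sharpness measure), fuses
the residual lowpass by averaging (or local-energy maximum), and inverts
the transform.  The fluorescence channel carries a sparse bright signal
(the apical cap), for which a plain maximum-intensity projection along z
is appropriate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .dtcwt2d import dtcwt2d_forward, dtcwt2d_inverse
from .io_5d import Recording5D

__all__ = [
    "FocusStack",
    "FusionConfig",
    "FusedSequence",
    "fuse_aif_dtcwt",
    "max_intensity_projection",
    "fuse_recording",
]


@dataclass
class FocusStack:
    """An ordered z-stack of equally shaped 2-D frames."""

    slices: np.ndarray  # (z, y, x)
    z_step_um: float = 1.0

    def __post_init__(self):
        arr = np.asarray(self.slices, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError("FocusStack needs a nonempty (z, y, x) array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("FocusStack slices must be finite")
        self.slices = arr


@dataclass
class FusionConfig:
    """Parameters of the AIF fusion.

    n_levels is clamped to log2 of the smaller image side; lowpass_rule
    'average' takes the mean lowpass across slices, 'max_local_energy'
    picks per pixel the slice whose lowpass has the largest local (3x3)
    energy.  Coefficient-magnitude ties go to the lowest z index.
    """

    n_levels: int = 4
    lowpass_rule: str = "average"

    def __post_init__(self):
        if self.n_levels < 1:
            raise ValueError("n_levels must be a positive integer")
        if self.lowpass_rule not in ("average", "max_local_energy"):
            raise ValueError(f"unknown lowpass_rule {self.lowpass_rule!r}")


@dataclass
class FusedSequence:
    """Per-time 2-D frames after z compression of both channels."""

    recording_id: str
    dic: np.ndarray  # (t, y, x) all-in-focus DIC
    fluorescence: np.ndarray  # (t, y, x) maximum projection
    frame_interval_s: float

    def __len__(self):
        return self.dic.shape[0]


def _effective_levels(shape, n_levels):
    return int(min(n_levels, np.floor(np.log2(min(shape)))))


def _pad_to_multiple(img, m):
    h, w = img.shape
    ph, pw = (-h) % m, (-w) % m
    if ph == 0 and pw == 0:
        return img, (0, 0)
    return np.pad(img, ((0, ph), (0, pw)), mode="symmetric"), (ph, pw)


def fuse_aif_dtcwt(stack: FocusStack, cfg: FusionConfig | None = None) -> np.ndarray:
    """Fuse a z-stack into one all-in-focus frame via DTCWT coefficient
    magnitude selection."""
    cfg = cfg or FusionConfig()
    slices = stack.slices
    nz, h, w = slices.shape
    nlev = _effective_levels((h, w), cfg.n_levels)
    if nlev < 1:
        raise ValueError(f"image {h}x{w} too small for any DTCWT level")

    padded = []
    for z in range(nz):
        p, crop = _pad_to_multiple(slices[z], 1 << nlev)
        padded.append(p)
    pyrs = [dtcwt2d_forward(p, nlev) for p in padded]

    fused = pyrs[0]
    if nz > 1:
        for lev in range(nlev):
            mags = np.stack([np.abs(p.highpasses[lev]) for p in pyrs])  # (z,6,h,w)
            pick = np.argmax(mags, axis=0)  # first max -> lowest z on ties
            coeffs = np.stack([p.highpasses[lev] for p in pyrs])
            fused.highpasses[lev][...] = np.take_along_axis(
                coeffs, pick[None], axis=0
            )[0]
        lows = np.stack([p.lowpass for p in pyrs])  # (z,2,2,h,w)
        if cfg.lowpass_rule == "average":
            fused.lowpass = lows.mean(axis=0)
        else:
            energy = np.stack(
                [
                    uniform_filter(slices_low**2, size=3, axes=(-2, -1))
                    for slices_low in lows
                ]
            )
            pick = np.argmax(energy, axis=0)
            fused.lowpass = np.take_along_axis(lows, pick[None], axis=0)[0]

    out = dtcwt2d_inverse(fused)[:h, :w]
    # keep the fused frame inside the stack's intensity range (wavelet
    # selection can overshoot near strong edges)
    return np.clip(out, slices.min(), slices.max())


def max_intensity_projection(stack: FocusStack) -> np.ndarray:
    """Element-wise maximum over z."""
    return stack.slices.max(axis=0)


def fuse_recording(rec: Recording5D, cfg: FusionConfig | None = None) -> FusedSequence:
    """Compress a 5-D recording to 2-D frame sequences: AIF for the DIC
    channel, maximum projection for the fluorescence channel."""
    cfg = cfg or FusionConfig()
    c_dic = rec.channel_index("dic")
    c_fluo = rec.channel_index("fluorescence")
    dic_frames = []
    fluo_frames = []
    for t in range(rec.n_frames):
        dic_stack = FocusStack(rec.tensor[t, :, c_dic], rec.z_step_um)
        fluo_stack = FocusStack(rec.tensor[t, :, c_fluo], rec.z_step_um)
        dic_frames.append(fuse_aif_dtcwt(dic_stack, cfg))
        fluo_frames.append(max_intensity_projection(fluo_stack))
    return FusedSequence(
        recording_id=rec.id,
        dic=np.stack(dic_frames),
        fluorescence=np.stack(fluo_frames),
        frame_interval_s=rec.frame_interval_s,
    )
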