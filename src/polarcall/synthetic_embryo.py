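"""Synthetic 8-cell-stage embryo time-lapse generator.

Generates 5-D recordings (t, z, c, y, x) with exactly known compaction
and polarization ground truth so the whole pipeline — fusion,
annotation, classification, onset calling, evaluation — can be
exercised without microscope data.

The embryo is modelled as a ring of spherical blastomeres whose 2-D
projections are circles of equal radius.  Compaction is realized
geometrically: the smallest inter-blastomere angle follows a
nondecreasing trajectory that crosses 120° exactly at the configured
compaction frame, and blastomere centre distances are set from that
angle via circle-overlap geometry (the same geometry the annotation
module measures).  Polarization is realized in the fluorescence
channel as an apical cap: a bright arc on the first polarized
blastomere's contact-free surface whose closed-surface fraction grows
linearly and reaches 1/3 exactly at the configured onset frame.  From
the onset frame the DIC channel additionally carries a high-frequency
membrane ripple of amplitude ``dic_cue_strength`` — the stand-in for
whatever label-free optical signature polarization produces.  Each z
slice is blurred by a defocus kernel growing linearly with the distance
to each blastomere's focal plane, and Gaussian noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotate import label_frames
from .io_5d import LabelTable, Recording5D
import pandas as pd

__all__ = ["SynthConfig", "GroundTruth", "generate_recording", "generate_cohort", "cohort_label_table"]

ANGLE_THRESHOLD = 120.0
CAP_THRESHOLD = 1.0 / 3.0


@dataclass
class SynthConfig:
    """Generation parameters for one synthetic recording.

    Defaults describe the study conditions: 8 blastomeres, 64x64 frames,
    7 optical sections 4 um apart, 24 frames with an interval sampled
    uniformly from 1200-2400 s, compaction at frame 7 and polarization
    onset at frame 11 (compaction precedes polarization).
    """

    n_blastomeres: int = 8
    size: int = 64
    n_z: int = 7
    n_frames: int = 24
    blastomere_radius: float = 10.0
    packing_jitter: float = 0.15  # radians of angular jitter on the ring
    angle_start_deg: float = 95.0
    angle_end_deg: float = 165.0
    compaction_frame: int = 7
    polarization_frame: int = 11
    cap_growth_per_frame: float = 0.12
    dic_cue_strength: float = 0.35
    defocus_sigma_per_um: float = 0.30  # px of blur per um of defocus
    z_step_um: float = 4.0
    noise_sd: float = 0.03
    frame_interval_s: float | None = None  # None -> sampled U[1200, 2400]
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.compaction_frame <= self.polarization_frame < self.n_frames:
            raise ValueError(
                "need 0 <= compaction_frame <= polarization_frame < n_frames"
            )
        if not 0 < self.cap_growth_per_frame <= 1:
            raise ValueError("cap_growth_per_frame must be in (0, 1]")
        for name in ("blastomere_radius", "defocus_sigma_per_um", "z_step_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.dic_cue_strength < 0:
            raise ValueError("noise_sd and dic_cue_strength must be nonnegative")
        if not self.angle_start_deg < ANGLE_THRESHOLD < self.angle_end_deg:
            raise ValueError(
                "angle trajectory must straddle the 120 deg compaction threshold"
            )
        if self.n_blastomeres < 2:
            raise ValueError("need at least 2 blastomeres")
        if self.frame_interval_s is not None and not (
            1200 <= self.frame_interval_s <= 2400
        ):
            raise ValueError("frame_interval_s must lie in [1200, 2400] s")


@dataclass
class GroundTruth:
    """Exact per-recording truth the generator built the images from."""

    recording_id: str
    polarization_onset_idx: int
    compaction_idx: int
    angle_series_deg: np.ndarray
    cap_fraction_series: np.ndarray
    labels: np.ndarray
    frame_interval_s: float
    # contact geometry (ring neighbours): per-frame centre distances of
    # adjacent blastomere pairs, and the common projected radius
    blastomere_radius: float = np.nan
    adjacent_distances: np.ndarray | None = None


def _angle_trajectory(cfg: SynthConfig) -> np.ndarray:
    """Nondecreasing smallest-angle series crossing 120° between frames
    compaction_frame-1 and compaction_frame (threshold is strict >)."""
    t = np.arange(cfg.n_frames, dtype=float)
    if cfg.compaction_frame == 0:
        knots_x = [-0.5, cfg.n_frames - 1.0]
        knots_y = [ANGLE_THRESHOLD, cfg.angle_end_deg]
    else:
        knots_x = [0.0, cfg.compaction_frame - 0.5, cfg.n_frames - 1.0]
        knots_y = [cfg.angle_start_deg, ANGLE_THRESHOLD, cfg.angle_end_deg]
    return np.interp(t, knots_x, knots_y)


def _cap_trajectory(cfg: SynthConfig) -> np.ndarray:
    """Nondecreasing closed-cap fraction series reaching 1/3 exactly at
    the polarization onset frame."""
    t = np.arange(cfg.n_frames, dtype=float)
    f = CAP_THRESHOLD + (t - cfg.polarization_frame) * cfg.cap_growth_per_frame
    return np.clip(f, 0.0, 1.0)


def _pair_distance(radius: float, angle_deg: float) -> float:
    """Centre distance of two equal circles whose exterior tangent angle
    is ``angle_deg`` (inverse of annotate.measure_interblastomere_angle)."""
    phi = np.radians(180.0 - angle_deg) / 2.0
    return 2.0 * radius * np.sin(phi)


def generate_recording(cfg: SynthConfig, recording_id: str = "synthetic_embryo"):
    """Render one recording; deterministic given cfg (including seed).

    Returns (Recording5D, GroundTruth).
    """
    rng = np.random.default_rng(cfg.seed)
    n, size, nz, nb = cfg.n_frames, cfg.size, cfg.n_z, cfg.n_blastomeres
    r = cfg.blastomere_radius

    angles = _angle_trajectory(cfg)
    caps = _cap_trajectory(cfg)
    labels = label_frames(cfg.polarization_frame, n)

    interval = (
        float(cfg.frame_interval_s)
        if cfg.frame_interval_s is not None
        else float(rng.uniform(1200.0, 2400.0))
    )

    # fixed per-embryo geometry randomness
    ring_phase = rng.uniform(0, 2 * np.pi)
    dphi = rng.uniform(-cfg.packing_jitter, cfg.packing_jitter, nb)
    phis = ring_phase + 2 * np.pi * np.arange(nb) / nb + dphi
    gaps = np.diff(np.concatenate([phis, [phis[0] + 2 * np.pi]]))
    max_gap = gaps.max()
    focal = rng.integers(0, nz, nb)  # focal z-slice per blastomere
    first_polarized = int(rng.integers(0, nb))
    texture = gaussian_filter(rng.normal(0, 1, (size, size)), 1.2)
    texture /= max(np.abs(texture).max(), 1e-9)
    cue_phase = rng.uniform(0, 2 * np.pi)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0

    tensor = np.zeros((n, nz, 2, size, size))
    adjacent = np.zeros((n, nb))
    for t in range(n):
        # ring radius such that the WIDEST adjacent gap realizes the
        # smallest (ground-truth) inter-blastomere angle
        d = _pair_distance(r, angles[t])
        ring_r = d / (2 * np.sin(max_gap / 2))
        centers = np.stack([cy + ring_r * np.sin(phis), cx + ring_r * np.cos(phis)], 1)
        adjacent[t] = 2 * ring_r * np.sin(gaps / 2)

        dic_parts = [[] for _ in range(nz)]  # per focal-distance groups
        fluo_parts = [[] for _ in range(nz)]
        dic_sharp = np.zeros((nb, size, size))
        fluo_sharp = np.zeros((nb, size, size))
        for k in range(nb):
            rho = np.hypot(yy - centers[k, 0], xx - centers[k, 1])
            membrane = np.exp(-((rho - r) ** 2) / (2 * 1.2**2))
            interior = 1.0 / (1.0 + np.exp((rho - r) / 1.0))
            img = 0.55 * membrane + 0.20 * interior + 0.12 * texture * interior
            if labels[t] and cfg.dic_cue_strength > 0:
                ripple = np.sin(2 * np.pi * rho / 2.5 + cue_phase)
                img = img + cfg.dic_cue_strength * membrane * ripple
            dic_sharp[k] = img
            fimg = 0.06 * membrane
            if k == first_polarized and caps[t] > 0:
                out_dir = np.arctan2(
                    centers[k, 0] - cy, centers[k, 1] - cx
                )
                pix_dir = np.arctan2(yy - centers[k, 0], xx - centers[k, 1])
                ddir = np.angle(np.exp(1j * (pix_dir - out_dir)))
                cap_mask = np.abs(ddir) <= np.pi * caps[t]
                fimg = fimg + 0.9 * membrane * cap_mask
            fluo_sharp[k] = fimg

        for j in range(nz):
            # group blastomeres by focal distance to share blur kernels
            dists = np.abs(j - focal)
            dic_slice = np.zeros((size, size))
            fluo_slice = np.zeros((size, size))
            for dist in np.unique(dists):
                sel = dists == dist
                sigma = cfg.defocus_sigma_per_um * cfg.z_step_um * float(dist)
                dsum = dic_sharp[sel].sum(axis=0)
                fsum = fluo_sharp[sel].sum(axis=0)
                if sigma > 0:
                    dsum = gaussian_filter(dsum, sigma)
                    fsum = gaussian_filter(fsum, sigma)
                dic_slice += dsum
                fluo_slice += fsum
            tensor[t, j, 0] = dic_slice
            tensor[t, j, 1] = fluo_slice

    tensor += rng.normal(0, cfg.noise_sd, tensor.shape)
    tensor = np.clip(tensor, 0.0, None)

    rec = Recording5D(
        id=recording_id,
        tensor=tensor,
        channel_roles={0: "dic", 1: "fluorescence"},
        frame_interval_s=interval,
        z_step_um=cfg.z_step_um,
    )
    truth = GroundTruth(
        recording_id=recording_id,
        polarization_onset_idx=cfg.polarization_frame,
        compaction_idx=cfg.compaction_frame,
        angle_series_deg=angles,
        cap_fraction_series=caps,
        labels=labels,
        frame_interval_s=interval,
        blastomere_radius=r,
        adjacent_distances=adjacent,
    )
    return rec, truth


def generate_cohort(
    n_embryos: int,
    template: SynthConfig | None = None,
    seed: int = 0,
    compaction_range: tuple = (4, 9),
    lag_range: tuple = (2, 5),
):
    """Generate a cohort of recordings with per-embryo jittered onset
    frames, geometry and frame intervals; seeds derive deterministically
    from the master seed.

    compaction_range and lag_range are inclusive frame-index ranges for
    the compaction frame and the compaction-to-polarization lag.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    template = template or SynthConfig()
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_embryos):
        emb_seed = int(rng.integers(0, 1 << 31))
        cf = int(rng.integers(compaction_range[0], compaction_range[1] + 1))
        lag = int(rng.integers(lag_range[0], lag_range[1] + 1))
        cf = min(cf, template.n_frames - 2)  # clamp into short recordings
        pf = min(cf + lag, template.n_frames - 1)
        radius = template.blastomere_radius * float(rng.uniform(0.9, 1.1))
        cfg = replace(
            template,
            seed=emb_seed,
            compaction_frame=cf,
            polarization_frame=pf,
            blastomere_radius=radius,
        )
        out.append(generate_recording(cfg, recording_id=f"embryo_{k:03d}"))
    return out


def cohort_label_table(cohort) -> LabelTable:
    """Frame labels of a generated cohort as a LabelTable."""
    rows = []
    for _, truth in cohort:
        for i, lab in enumerate(truth.labels):
            rows.append(
                {
                    "recording_id": truth.recording_id,
                    "frame_index": i,
                    "label": "after" if lab else "before",
                }
            )
    return LabelTable(pd.DataFrame(rows, columns=["recording_id", "frame_index", "label"]))
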