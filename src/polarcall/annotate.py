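"""Ground-truth-style annotation of polarization and compaction.

Polarization onset is the first frame whose largest closed apical-cap
fraction reaches 1/3 of the blastomere surface; every frame at or after
onset is labelled after-onset.  Compaction is the first frame whose
smallest inter-blastomere angle exceeds 120° (strictly).  The angle
between two contacting blastomeres is defined on circle-overlap
geometry: the exterior angle between the two membrane tangents at a
contact point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AnnotationConfig",
    "annotate_polarization_onset",
    "label_frames",
    "measure_interblastomere_angle",
    "estimate_angle_from_masks",
    "annotate_compaction",
]


@dataclass
class AnnotationConfig:
    cap_fraction_threshold: float = 1.0 / 3.0  # inclusive (>=)
    angle_threshold_deg: float = 120.0  # strict (>)

    def __post_init__(self):
        if not 0 < self.cap_fraction_threshold <= 1:
            raise ValueError("cap_fraction_threshold must be in (0, 1]")
        if not 0 < self.angle_threshold_deg < 180:
            raise ValueError("angle_threshold_deg must be in (0, 180)")


def annotate_polarization_onset(cap_fraction_series, cfg: AnnotationConfig | None = None):
    """First frame index whose cap fraction >= threshold, or None."""
    cfg = cfg or AnnotationConfig()
    s = np.asarray(cap_fraction_series, dtype=float)
    if s.size == 0:
        raise ValueError("cap fraction series is empty")
    if s.min() < 0 or s.max() > 1:
        raise ValueError("cap fractions must lie in [0, 1]")
    hits = np.flatnonzero(s >= cfg.cap_fraction_threshold)
    return int(hits[0]) if hits.size else None


def label_frames(onset_idx, n_frames: int) -> np.ndarray:
    """0 before onset, 1 at and after; all 0 when onset is None."""
    if n_frames < 0:
        raise ValueError("n_frames must be nonnegative")
    labels = np.zeros(n_frames, dtype=int)
    if onset_idx is None:
        return labels
    if not 0 <= onset_idx <= n_frames:
        raise ValueError(f"onset index {onset_idx} outside [0, {n_frames}]")
    labels[onset_idx:] = 1
    return labels


def measure_interblastomere_angle(r1: float, r2: float, d: float) -> float:
    """Exterior angle (degrees) between two circles' tangents at their
    intersection point.

    For circles of radii r1, r2 with centre distance d, the tangent of
    each membrane at the contact point makes an angle with the contact
    axis; the reported inter-blastomere angle is 180° minus the two
    tangent-to-axis deviations.  Approaches 0° at point contact
    (d -> r1+r2) and 180° for fully merged equal circles (d -> 0).
    """
    if not (abs(r1 - r2) < d < r1 + r2):
        raise ValueError(
            f"circles (r1={r1}, r2={r2}, d={d}) do not intersect transversally"
        )
    # intersection point: distance a from centre 1 along the axis, height h
    a = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h = np.sqrt(r1 * r1 - a * a)
    # angle of each radius vector to the centre axis; tangents are normal
    # to the radii, so the exterior angle between tangents is:
    alpha1 = np.arctan2(h, a)
    alpha2 = np.arctan2(h, d - a)
    return float(np.degrees(alpha1 + alpha2))


def annotate_compaction(angle_series, cfg: AnnotationConfig | None = None):
    """First frame index whose smallest inter-blastomere angle is
    strictly above the compaction threshold, or None."""
    cfg = cfg or AnnotationConfig()
    s = np.asarray(angle_series, dtype=float)
    if s.size == 0:
        raise ValueError("angle series is empty")
    if s.min() <= 0 or s.max() >= 180:
        raise ValueError("angles must lie in (0, 180)")
    hits = np.flatnonzero(s > cfg.angle_threshold_deg)
    return int(hits[0]) if hits.size else None


def estimate_angle_from_masks(mask1: np.ndarray, mask2: np.ndarray, arc_px: int = 5) -> float:
    """Contour-based inter-blastomere angle estimate (±3° on rendered
    circle pairs).

    Finds the two contact endpoints (extremes of the overlap region
    perpendicular to the centre axis), fits a tangent line over a short
    arc of each cell's outer contour near each endpoint, and returns the
    mean exterior angle over the two endpoints.
    """
    from scipy.spatial import cKDTree

    m1 = np.asarray(mask1, bool)
    m2 = np.asarray(mask2, bool)
    if not (m1 & m2).any():
        raise ValueError("masks do not overlap; no contact to measure")
    c1 = _largest_contour(m1)
    c2 = _largest_contour(m2)
    # contact endpoints = the two places the contours intersect: contour-1
    # points within a pixel of contour 2, extremal perpendicular to the
    # centre axis
    tree2 = cKDTree(c2)
    near_d, near_j = tree2.query(c1)
    candidates = np.flatnonzero(near_d < 1.0)
    if candidates.size < 2:
        raise ValueError("contours do not cross; cannot locate contact points")
    axis = _principal_axis(np.argwhere(m2).mean(0) - np.argwhere(m1).mean(0))
    perp = np.array([-axis[1], axis[0]])
    proj = c1[candidates] @ perp
    angles = []
    for i in (candidates[np.argmax(proj)], candidates[np.argmin(proj)]):
        t1 = _tangent_at(c1, i, arc_px)
        t2 = _tangent_at(c2, int(near_j[i]), arc_px)
        cosang = abs(np.dot(t1, t2))
        angles.append(180.0 - np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    return float(np.mean(angles))


def _largest_contour(mask):
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    return max(contours, key=len)


def _principal_axis(v):
    n = np.linalg.norm(v)
    return v / n if n else np.array([1.0, 0.0])


def _tangent_at(contour, index, arc_px):
    """Direction of the best-fit line through a contour arc centred at
    ``index`` (closed-contour wraparound)."""
    n = len(contour)
    idx = (np.arange(index - arc_px, index + arc_px + 1)) % n
    arc = contour[idx] - contour[idx].mean(axis=0)
    _, _, vt = np.linalg.svd(arc, full_matrices=False)
    return vt[0] / np.linalg.norm(vt[0])
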