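"""Ensemble CNN classification of fused DIC frames.

The classifier decides, per frame, whether the embryo is before or
after polarization onset.  K independently initialized members (first
half trained with SGD, second half with Adam, all for the same number
of epochs) are combined either by element-wise probability averaging
(default: the class with the larger mean probability wins) or by
majority vote over member labels.  Splitting into training and testing
cohorts is done at the embryo level so no recording contributes frames
to both sides.  Class order is [before, after] everywhere and the
positive class is after-onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .nn import Adam, SGD, SmallConvNet, standardize, train_network

__all__ = [
    "EnsembleConfig",
    "split_cohort",
    "train_member",
    "train_ensemble",
    "ensemble_predict",
    "predict_proba_series",
    "compute_cam",
    "save_models",
    "load_models",
]

CLASS_ORDER = ("before", "after")


@dataclass
class EnsembleConfig:
    """Training and ensembling hyperparameters.

    The first ``ceil(n_members/2)`` members use SGD, the rest Adam.
    ``backbone`` selects the conv channel stack; augmentation applies
    random flips and 90° rotations.
    """

    n_members: int = 6
    epochs: int = 40
    threshold: float = 0.5
    ensemble_mode: str = "probability_average"
    input_size: int = 64
    backbone: tuple = (8, 16, 32)
    sgd_lr: float = 0.05
    adam_lr: float = 1e-3
    batch_size: int = 32
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.ensemble_mode not in ("probability_average", "label_majority"):
            raise ValueError(f"unknown ensemble_mode {self.ensemble_mode!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def member_seed(self, member_index: int) -> int:
        return (self.seed * 1000003 + member_index) % (1 << 31)

    def optimizer_for(self, member_index: int):
        n_sgd = (self.n_members + 1) // 2
        if member_index < n_sgd:
            return SGD(lr=self.sgd_lr)
        return Adam(lr=self.adam_lr)


def split_cohort(recording_ids, test_fraction=None, counts=None, seed: int = 0):
    """Embryo-level train/test split: disjoint id sets, deterministic
    given the seed.  Give either ``test_fraction`` or explicit
    ``counts=(n_train, n_test)``."""
    ids = [str(r) for r in recording_ids]
    if len(ids) != len(set(ids)):
        raise ValueError("recording ids must be unique")
    if len(ids) < 2:
        raise ValueError("need at least 2 recordings to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    if counts is not None:
        n_train, n_test = counts
        if n_train + n_test != len(ids):
            raise ValueError(
                f"counts {counts} do not sum to the number of recordings {len(ids)}"
            )
    else:
        if test_fraction is None:
            test_fraction = 0.2
        n_test = int(round(len(ids) * test_fraction))
        n_train = len(ids) - n_test
    if n_train < 1 or n_test < 1:
        raise ValueError("split leaves an empty cohort")
    test_ids = [ids[i] for i in order[:n_test]]
    train_ids = [ids[i] for i in order[n_test:]]
    return sorted(train_ids), sorted(test_ids)


def train_member(images, labels, member_index: int, cfg: EnsembleConfig) -> SmallConvNet:
    """Train one ensemble member; deterministic given the member seed.

    Raises on a single-class training set or a diverging (NaN) loss.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    seed = cfg.member_seed(member_index)
    net = SmallConvNet(cfg.input_size, cfg.backbone, seed=seed)
    train_network(
        net,
        images,
        labels,
        cfg.optimizer_for(member_index),
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        augment=cfg.augment,
        seed=seed + 1,
    )
    preds = net.predict_proba(images).argmax(axis=1)
    net.train_accuracy = float(np.mean(preds == labels))
    return net


def train_ensemble(images, labels, cfg: EnsembleConfig) -> list:
    return [train_member(images, labels, k, cfg) for k in range(cfg.n_members)]


def ensemble_predict(models, frames, cfg: EnsembleConfig | None = None):
    """Combine member predictions on one or more frames.

    probability_average: element-wise mean of member probability
    vectors; label = after iff mean p_after > threshold (ties are
    called before-onset).  label_majority: majority of member labels,
    ties before.  Returns (mean probabilities, labels); scalar frame in
    -> 1-row outputs.
    """
    cfg = cfg or EnsembleConfig()
    if not models:
        raise ValueError("empty model list")
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    member_probs = np.stack([m.predict_proba(frames) for m in models])  # (K,N,2)
    mean_probs = member_probs.mean(axis=0)
    if cfg.ensemble_mode == "probability_average":
        labels = (mean_probs[:, 1] > cfg.threshold).astype(int)
    else:
        member_labels = (member_probs[:, :, 1] > cfg.threshold).astype(int)
        votes = member_labels.sum(axis=0)
        labels = (2 * votes > len(models)).astype(int)  # ties -> before
    return mean_probs, labels


def predict_proba_series(models, frames, cfg: EnsembleConfig | None = None):
    """Member and ensemble probabilities for an ordered frame sequence:
    returns (member probs (K,N,2), mean probs (N,2), labels (N,))."""
    cfg = cfg or EnsembleConfig()
    frames = np.asarray(frames, dtype=np.float64)
    member_probs = np.stack([m.predict_proba(frames) for m in models])
    mean_probs, labels = ensemble_predict(models, frames, cfg)
    return member_probs, mean_probs, labels


def compute_cam(model: SmallConvNet, frame: np.ndarray, class_index: int, upsample: bool = True):
    """Class activation map: dense-head-weighted sum of the pre-GAP
    feature maps.

    The spatial mean of the raw map equals the class logit minus the
    class bias (GAP and the weighted sum commute).  With
    ``upsample=True`` the map is bilinearly rescaled to the input frame
    size for overlay.
    """
    if class_index not in (0, 1):
        raise ValueError("class_index must be 0 (before) or 1 (after)")
    frame = np.asarray(frame, dtype=np.float64)
    x = standardize(frame[None])
    model.forward(x, keep_features=True)
    feats = model.features[0]  # (F, h, w)
    raw = np.tensordot(model.w[class_index], feats, axes=(0, 0))
    if not upsample:
        return raw
    zy = frame.shape[0] / raw.shape[0]
    zx = frame.shape[1] / raw.shape[1]
    return ndimage.zoom(raw, (zy, zx), order=1, grid_mode=True, mode="nearest")


def save_cam_overlay(frame, cam, path, alpha: float = 0.45):
    """Write a PNG of the frame with the CAM as a diverging overlay
    (red = evidence for the class, blue = against)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(frame, cmap="gray")
    vmax = max(np.abs(cam).max(), 1e-12)
    ax.imshow(cam, cmap="bwr", alpha=alpha, vmin=-vmax, vmax=vmax)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)


def save_models(models, directory):
    """Serialize ensemble members as one .npz checkpoint per member."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, net in enumerate(models):
        np.savez(directory / f"member_{k:02d}.npz", **net.state_dict())


def load_models(directory):
    directory = Path(directory)
    paths = sorted(directory.glob("member_*.npz"))
    if not paths:
        raise FileNotFoundError(f"no member_*.npz checkpoints in {directory}")
    models = []
    for p in paths:
        with np.load(p) as state:
            models.append(SmallConvNet.from_state(dict(state)))
    return models
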