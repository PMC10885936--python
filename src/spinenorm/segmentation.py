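"""Training and inference for the spinal-canal U-Net.

Training follows a fixed recipe: Adam at an initial learning rate of 1e-3,
batches of 8 slices, and a plateau schedule that halves the learning rate
whenever the monitored loss fails to improve (by more than 1e-4 absolute)
for 10 consecutive epochs, flooring at 1e-5.

Inference maps every acquired slice through the network, assembles the
per-slice probabilities on the composed whole-body grid (most superior to
most inferior), linearly interpolates probabilities at grid positions with
no acquired slice (station gaps), and thresholds at 0.5 for the binary mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dwi_model import fit_study, scale_network_input, study_log_s0_max, _resample_slice
from .losses import LossConfig, loss_grad, loss_value
from .nn import Adam
from .types import CanalSegmentation, DWIStudy
from .unet import UNet

__all__ = ["TrainConfig", "PlateauScheduler", "train", "predict_canal",
           "interpolate_probability"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    initial_lr: float = 1e-3
    min_lr: float = 1e-5
    lr_halving_patience: int = 10
    improvement_threshold: float = 1e-4
    epochs: int = 150
    batch_size: int = 8
    seed: int = 0


class PlateauScheduler:
    """Halve the learning rate after ``patience`` epochs without improvement.

    An epoch improves when the monitored loss drops below the best seen by
    more than ``threshold`` (absolute).  The rate floors at ``min_lr``; the
    resulting trace is non-increasing.
    """

    def __init__(self, initial_lr: float, min_lr: float, patience: int,
                 threshold: float) -> None:
        self.lr = initial_lr
        self.min_lr = min_lr
        self.patience = patience
        self.threshold = threshold
        self.best = np.inf
        self.stagnant = 0

    def update(self, monitored: float) -> float:
        if monitored < self.best - self.threshold:
            self.best = monitored
            self.stagnant = 0
        else:
            self.stagnant += 1
            if self.stagnant >= self.patience and self.lr > self.min_lr:
                self.lr = max(self.lr / 2.0, self.min_lr)
                self.stagnant = 0
        return self.lr


def _epoch_loss(model: UNet, x: np.ndarray, y: np.ndarray,
                loss_cfg: LossConfig, batch: int) -> float:
    losses = []
    for i in range(0, len(x), batch):
        p = model.forward(x[i:i + batch], train=False)
        losses.append(loss_value(y[i:i + batch], p, loss_cfg))
    return float(np.mean(losses))


def train(model: UNet, inputs: np.ndarray, masks: np.ndarray,
          cfg: TrainConfig | None = None, loss_cfg: LossConfig | None = None,
          val_inputs: np.ndarray | None = None,
          val_masks: np.ndarray | None = None) -> dict[str, list[float]]:
    """Train ``model`` in place; returns per-epoch history.

    ``inputs`` is ``(N, 2, H, W)`` (scaled ADC and S0 channels), ``masks`` is
    ``(N, 1, H, W)`` binary.  The plateau schedule monitors the validation
    loss when a validation set is supplied, else the training loss.
    """
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    if len(inputs) == 0:
        raise ValueError("empty training set")
    if masks.shape[0] != inputs.shape[0]:
        raise ValueError("inputs and masks must align")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam([*model.enc, *model.pools, *model.drop_enc, model.bottleneck,
                *model.up, *model.drop_dec, *model.dec, model.out_conv],
               lr=cfg.initial_lr)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "lr": []}
    sched = PlateauScheduler(cfg.initial_lr, cfg.min_lr, cfg.lr_halving_patience,
                             cfg.improvement_threshold)

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(inputs))
        batch_losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = inputs[idx], masks[idx]
            p = model.forward(xb, train=True)
            lv = loss_value(yb, p, loss_cfg)
            if not np.isfinite(lv):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {lv}")
            batch_losses.append(lv)
            model.backward(loss_grad(yb, p, loss_cfg).astype(p.dtype))
            opt.step()
        train_loss = float(np.mean(batch_losses))
        if val_inputs is not None and len(val_inputs):
            monitored = _epoch_loss(model, val_inputs, val_masks, loss_cfg, cfg.batch_size)
        else:
            monitored = train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(monitored)
        history["lr"].append(opt.lr)

        new_lr = sched.update(monitored)
        if new_lr != opt.lr:
            log.info("epoch %d: plateau, lr -> %.2e", epoch, new_lr)
            opt.lr = new_lr
    model.trained = True
    return history


def interpolate_probability(positions: np.ndarray, prob_slices: np.ndarray,
                            target_positions: np.ndarray) -> np.ndarray:
    """Linearly interpolate per-slice probability maps along the patient axis.

    ``positions`` (n,) are the acquired slice locations, ``prob_slices``
    ``(n, H, W)`` the network outputs; returns ``(m, H, W)`` at
    ``target_positions``.  Targets beyond the acquired range clamp to the
    nearest slice.
    """
    order = np.argsort(positions)
    pos = positions[order]
    probs = prob_slices[order]
    out = np.empty((len(target_positions),) + probs.shape[1:], dtype=probs.dtype)
    for i, t in enumerate(target_positions):
        j = np.searchsorted(pos, t)
        if j == 0:
            out[i] = probs[0]
        elif j == len(pos):
            out[i] = probs[-1]
        elif pos[j] == t:
            out[i] = probs[j]
        else:
            w = (t - pos[j - 1]) / (pos[j] - pos[j - 1])
            out[i] = (1 - w) * probs[j - 1] + w * probs[j]
    return out


def predict_canal(model: UNet, study: DWIStudy, *, threshold: float = 0.5,
                  net_matrix: int = 256, net_mm: float = 1.6,
                  target_positions: np.ndarray | None = None,
                  batch_size: int = 8) -> CanalSegmentation:
    """Segment the spinal canal of a whole study.

    Each station is fitted, scaled to the two-channel network input (with the
    S0 log-max pooled over the study), and pushed through the network slice
    by slice.  Probabilities are mapped back to the native in-plane grid and
    assembled superior -> inferior; where ``target_positions`` requests grid
    slices that were never acquired, probabilities are linearly interpolated
    between the nearest predicted slices before thresholding.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained")
    maps = fit_study(study)
    mx = study_log_s0_max(maps)
    native = study.stations[0].matrix
    in_plane = study.stations[0].spacing[1:]

    all_pos: list[float] = []
    all_prob: list[np.ndarray] = []
    seen: set[float] = set()
    for st_maps in maps:   # stations ordered superior -> inferior
        ni = scale_network_input(st_maps, out_matrix=net_matrix, out_mm=net_mm,
                                 log_s0_max=mx)
        x = np.stack([ni.scaled_adc, ni.scaled_s0], axis=1).astype(np.float32)
        probs = np.concatenate([model.forward(x[i:i + batch_size], train=False)
                                for i in range(0, len(x), batch_size)])[:, 0]
        native_grid = (net_matrix, net_matrix) == native and (net_mm, net_mm) == in_plane
        for k, pos in enumerate(st_maps.slice_positions):
            if pos in seen:       # overlap: the more superior station wins
                continue
            seen.add(float(pos))
            if native_grid:
                p_native = probs[k]
            else:  # map the probability back onto the native in-plane grid
                p_native = _resample_slice(probs[k], (net_mm, net_mm), native, in_plane)
            all_pos.append(float(pos))
            all_prob.append(p_native)

    pos_arr = np.asarray(all_pos)
    prob_arr = np.asarray(all_prob)
    order = np.argsort(pos_arr)
    pos_arr, prob_arr = pos_arr[order], prob_arr[order]
    if target_positions is not None:
        prob_arr = interpolate_probability(pos_arr, prob_arr,
                                           np.asarray(target_positions, dtype=float))
        pos_arr = np.asarray(target_positions, dtype=float)
    mask = prob_arr >= threshold
    return CanalSegmentation(probability=prob_arr, mask=mask,
                             threshold=threshold, slice_positions=pos_arr)
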