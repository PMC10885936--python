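"""Scaled-down phantom segmentation benchmark.

Patient data cannot ship with the package, so segmentation quality is
measured on a reproducible synthetic benchmark: 15 seeded phantoms (two
stations of 12 slices, 64 x 64 at 1.6 mm, mild random station gains, Rician
noise), split by phantom 70/15/15 into train/validation/test, a reduced
U-Net (filters 8/16/32/64, bottleneck 128) trained for up to 30 epochs with
the default Focal Tversky loss, and patient-wise Dice / precision / recall
of the predicted canal masks against ground truth.  The split is by phantom,
never by slice, so no phantom leaks between sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .characterisation import overlap_metrics
from .dwi_model import fit_study, scale_network_input, study_log_s0_max
from .losses import LossConfig
from .phantom import PhantomSpec, generate_phantom
from .segmentation import TrainConfig, predict_canal, train
from .types import DWIStudy
from .unet import UNet, UNetConfig, build_unet

__all__ = ["BenchmarkResult", "benchmark_spec", "make_slice_dataset",
           "run_segmentation_benchmark"]

log = logging.getLogger(__name__)

REDUCED_UNET = UNetConfig(encoder_filters=(8, 16, 32, 64), bottleneck_filters=128)
N_PHANTOMS = 15
N_TRAIN, N_VAL, N_TEST = 10, 2, 3    # 70/15/15 by phantom
BENCH_EPOCHS = 30


@dataclass
class BenchmarkResult:
    model: UNet
    history: dict
    val_dice: float
    test_dice: float
    test_precision: float
    test_recall: float

    @property
    def test_min_metric(self) -> float:
        return min(self.test_dice, self.test_precision, self.test_recall)


def benchmark_spec(seed: int, gain_rng: np.random.Generator) -> PhantomSpec:
    """Study conditions of one benchmark phantom."""
    gains = tuple(gain_rng.uniform(0.8, 1.2, 2))
    return PhantomSpec(n_stations=2, slices_per_station=12, matrix=64,
                       station_gains=gains, noise_sigma=10.0, seed=seed)


def make_slice_dataset(phantoms: list[tuple[DWIStudy, np.ndarray]]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Stack two-channel network inputs and canal masks for all slices of the
    given (study, canal truth) pairs."""
    xs, ys = [], []
    for study, canal in phantoms:
        maps = fit_study(study)
        mx = study_log_s0_max(maps)
        m = study.stations[0].matrix[0]
        offset = 0
        for st_maps in maps:
            ni = scale_network_input(st_maps, out_matrix=m,
                                     out_mm=study.stations[0].spacing[1],
                                     log_s0_max=mx)
            xs.append(np.stack([ni.scaled_adc, ni.scaled_s0], axis=1).astype(np.float32))
            n = len(st_maps.slice_positions)
            ys.append(canal[offset:offset + n, None].astype(np.float32))
            offset += n
    return np.concatenate(xs), np.concatenate(ys)


def run_segmentation_benchmark(seed: int = 0, epochs: int = BENCH_EPOCHS,
                               n_phantoms: int = N_PHANTOMS) -> BenchmarkResult:
    """Train the reduced U-Net on the phantom benchmark and evaluate it.

    Deterministic for a fixed ``seed``; returns patient-wise mean metrics on
    the validation and held-out test phantoms.
    """
    rng = np.random.default_rng(seed)
    phantoms = [generate_phantom(benchmark_spec(int(rng.integers(2 ** 31)), rng))
                for _ in range(n_phantoms)]
    pairs = [(study, truth.canal_mask) for study, truth in phantoms]
    n_train = round(n_phantoms * 0.7)
    n_val = max(1, round(n_phantoms * 0.15))
    train_p = pairs[:n_train]
    val_p = pairs[n_train:n_train + n_val]
    test_p = pairs[n_train + n_val:]
    log.info("benchmark split: %d train / %d val / %d test phantoms",
             len(train_p), len(val_p), len(test_p))

    x_tr, y_tr = make_slice_dataset(train_p)
    x_va, y_va = make_slice_dataset(val_p)

    model = build_unet(REDUCED_UNET, seed=seed)
    history = train(model, x_tr, y_tr,
                    cfg=TrainConfig(epochs=epochs, seed=seed),
                    loss_cfg=LossConfig(),
                    val_inputs=x_va, val_masks=y_va)

    def patientwise(pair_list):
        scores = []
        for study, canal in pair_list:
            m = study.stations[0].matrix[0]
            seg = predict_canal(model, study, net_matrix=m,
                                net_mm=study.stations[0].spacing[1])
            scores.append(overlap_metrics(seg.mask, canal))
        return np.asarray(scores).mean(axis=0)

    val_dice = float(patientwise(val_p)[0])
    test_dice, test_prec, test_rec = (float(v) for v in patientwise(test_p))
    log.info("benchmark val Dice %.3f | test Dice %.3f prec %.3f rec %.3f",
             val_dice, test_dice, test_prec, test_rec)
    return BenchmarkResult(model=model, history=history, val_dice=val_dice,
                           test_dice=test_dice, test_precision=test_prec,
                           test_recall=test_rec)
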