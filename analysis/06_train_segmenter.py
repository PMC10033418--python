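#!/usr/bin/env python
"""Desk-scale training run of the trinary segmentation network.

Trains the narrow desk-scale variant of the encoder-decoder on four
synthetic 128x128 slices (pure memorization check: augmentation off,
lr 1e-3, 60 epochs) and reports per-slice DICE / IoU / precision / recall.
The full-width configuration and the published-style schedule (1e-4 dropped
to 1e-5 after epoch 150, 200 epochs, batch 8) remain the library defaults.
"""

import time
from pathlib import Path

import numpy as np
import pandas as pd

from mitomap.nn import NetConfig, TrainConfig, build_model, predict_mask, train_model
from mitomap.segmentation import evaluate_segmentation
from mitomap.synthetic import (MitoShapeParams, NucleusSpec, SceneSpec,
                               generate_cell_volume)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    spec = SceneSpec(
        grid_shape=(10, 128, 128), voxel_size=(50, 10, 10),
        nucleus=NucleusSpec(semi_axes=(220, 300, 300), center=(250, 400, 400)),
        n_mitochondria=12,
        mito_shape=MitoShapeParams(radius_nm=60, length_mean_um=0.25, length_sd_um=0.05),
        n_lipid_droplets=0, seed=5)
    gray, truth = generate_cell_volume(spec)
    data = [(np.asarray(gray.data[k], dtype=np.float32),
             np.asarray(truth.class_volume.data[k], dtype=np.int64))
            for k in (3, 4, 5, 6)]

    model = build_model(NetConfig(encoder_filters=(16, 32, 64, 64, 64),
                                  input_size=128, seed=0))
    t0 = time.time()
    model, history = train_model(
        model, data,
        TrainConfig(epochs=60, batch_size=4, lr_initial=1e-3, lr_late=1e-3,
                    lr_switch_epoch=60, augment=False, seed=0))
    print(f"trained 60 epochs in {time.time() - t0:.0f} s; "
          f"loss {history[0]:.3f} -> {history[-1]:.4f}")

    rows = []
    for k, (img, lab) in zip((3, 4, 5, 6), data):
        m = evaluate_segmentation(predict_mask(model, img), lab)
        rows.append(dict(slice=k, dice=m.dice, iou=m.iou,
                         precision=m.precision, recall=m.recall))
        print(f"slice {k}: DICE {m.dice:.3f}  IoU {m.iou:.3f}  "
              f"precision {m.precision:.3f}  recall {m.recall:.3f}")
    df = pd.DataFrame(rows)
    print(f"macro DICE over 4 slices: {df.dice.mean():.3f}")
    ROOT.mkdir(parents=True, exist_ok=True)
    df.to_csv(ROOT / "segmenter_training_metrics.csv", index=False)


if __name__ == "__main__":
    main()
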