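"""Train the full two-stage pipeline at desk scale and evaluate it.

Generates a 6-patient cohort at 64x64, trains the mask auto-encoder (the
shape prior), then the aligned segmentation network for a short budget, and
prints the held-out metric table.  With the short schedule used here the
numbers are modest; the acceptance script runs the longer (300-step)
version of the same chain.
"""

import tempfile
from pathlib import Path

import numpy as np

from laaseg import generate_dataset, split_by_patient
from laaseg.config import NetworkConfig, TrainConfig
from laaseg.training import (evaluate_split, train_reconstruction,
                             train_segmentation)

with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_dataset(n_patients=6, images_per_patient=10,
                                thrombus_fraction=0.5, size=(64, 64),
                                seed=7, out_dir=Path(tmp) / "data")
    manifest = split_by_patient(manifest, rng=np.random.default_rng(7))

    net_cfg = NetworkConfig(depths=(1, 1, 2, 1), dims=(16, 32, 64, 128),
                            input_size=(64, 64))
    train_cfg = TrainConfig(input_size=(64, 64), steps=60, recon_steps=60,
                            batch_size=8, seed=7, eval_interval=20)

    print("stage 1: mask auto-encoder (shape prior) ...")
    recon, recon_hist = train_reconstruction(manifest, net_cfg, train_cfg)
    print(f"  reconstruction L1: {recon_hist['l1'][0]:.3f} -> {recon_hist['l1'][-1]:.3f}")

    print("stage 2: segmentation with latent alignment ...")
    seg, disc, hist = train_segmentation(manifest, recon, net_cfg, train_cfg)
    c0, c1 = hist["val_cosine"][0][1], hist["val_cosine"][-1][1]
    print(f"  val latent cosine(q, k+): {c0:.3f} -> {c1:.3f} "
          "(image latents moving toward their mask latents)")

    report = evaluate_split(seg, manifest, "test")
    row = report.summary.iloc[0]
    print(f"\ntest split (n={int(row['n'])} frames, unseen patient):")
    for m in ("dice", "iou", "acc", "gmean", "kappa", "auc"):
        print(f"  {m:5s} = {row[f'{m}_mean']:.3f} +/- {row[f'{m}_std']:.3f}")
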