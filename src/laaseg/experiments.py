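"""Desk-scale benchmark experiments used by the acceptance checks.

Both experiments run the full package machinery on generated data at a
64x64 scale chosen so the whole suite trains on one CPU in minutes: the
scaled architecture keeps the (stem /4, three /2) stride layout with widths
(16, 32, 64, 128) and block depths (1, 1, 2, 1).
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np

from .config import NetworkConfig, TrainConfig
from .data import DatasetManifest
from .synthetic import generate_dataset
from .training import (evaluate_split, load_split_arrays,
                       reconstruction_heldout_metrics, split_by_patient,
                       train_reconstruction, train_segmentation)

SCALED_NET = dict(depths=(1, 1, 2, 1), dims=(16, 32, 64, 128), input_size=(64, 64))

# thrombus prevalence of the emulated cohort (23 of 41 patients)
THROMBUS_FRACTION = 23 / 41


def scaled_network_config() -> NetworkConfig:
    return NetworkConfig(**SCALED_NET)


def mask_reconstruction_experiment(seed: int, workdir: str | Path,
                                   n_patients: int = 10,
                                   images_per_patient: int = 20,
                                   size: tuple[int, int] = (64, 64),
                                   steps: int = 300,
                                   holdout: int = 40) -> dict:
    """Shape-prior recovery: train the mask auto-encoder on a pool of
    synthetic masks and score held-out reconstructions.

    A pool of ``n_patients * images_per_patient`` masks is generated, split
    at random (not by patient) into training and ``holdout`` held-out masks,
    the auto-encoder is trained for ``steps`` batches, and held-out mean
    per-pixel L1 and mean Dice of the 0.5-thresholded reconstruction are
    returned.
    """
    workdir = Path(workdir)
    man = generate_dataset(n_patients, images_per_patient, THROMBUS_FRACTION,
                           size, seed, workdir / "recon_pool")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(man))
    held = set(perm[:holdout].tolist())
    recs = [replace(r, split=("test" if i in held else "train"))
            for i, r in enumerate(man.records)]
    man = DatasetManifest(recs, man.image_size, man.seed, man.root)

    net_cfg = scaled_network_config()
    train_cfg = TrainConfig(input_size=size, recon_steps=steps, batch_size=8,
                            seed=seed)
    net, history = train_reconstruction(man, net_cfg, train_cfg)
    l1, dice = reconstruction_heldout_metrics(net, man, "test", size)
    return {"heldout_l1": l1, "heldout_dice": dice,
            "final_train_l1": history["l1"][-1], "n_train": len(man) - holdout,
            "n_heldout": holdout, "net": net, "manifest": man}


def scaled_pipeline_experiment(seed: int, workdir: str | Path,
                               n_patients: int = 10,
                               images_per_patient: int = 20,
                               size: tuple[int, int] = (64, 64),
                               steps: int = 300,
                               recon_steps: int = 300) -> dict:
    """End-to-end scaled run: generate a cohort, split patient-level 4:1:1,
    train the mask auto-encoder, train the aligned segmentation network,
    and evaluate the test split.

    Returns the metric report plus the validation cosine-alignment history
    (median cos(q, k+) at step 0 and during training).
    """
    workdir = Path(workdir)
    man = generate_dataset(n_patients, images_per_patient, THROMBUS_FRACTION,
                           size, seed, workdir / "pipeline_data")
    man = split_by_patient(man, rng=np.random.default_rng(seed))
    net_cfg = scaled_network_config()
    train_cfg = TrainConfig(input_size=size, steps=steps, recon_steps=recon_steps,
                            batch_size=8, seed=seed)
    recon, recon_hist = train_reconstruction(man, net_cfg, train_cfg)
    seg, disc, seg_hist = train_segmentation(man, recon, net_cfg, train_cfg)
    report = evaluate_split(seg, man, "test")
    return {"report": report, "seg_history": seg_hist, "recon_history": recon_hist,
            "manifest": man, "seg": seg, "recon": recon, "disc": disc}
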