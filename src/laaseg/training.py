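"""Two-stage training: (1) mask auto-encoder, (2) segmentation network with
adversarial + contrastive latent-space alignment against the frozen mask
encoder; plus the patient-level split, rotation augmentation, prediction and
checkpointing.

Stage 2, per batch: one discriminator update (real = frozen mask-encoder
latents of the ground-truth masks, fake = image-encoder latents) followed by
one generator update minimizing ``L_seg + lambda_gan * L_GAN(G) +
lambda_cl * L_CL``.  Gradients never flow into the reconstruction network.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import losses as L
from . import metrics as M
from .config import LossWeights, NetworkConfig, SplitSpec, TrainConfig
from .data import DatasetManifest, SampleRecord, read_image_png, read_mask_png
from .networks import (Discriminator, ReconNetwork, SegNetwork,
                       pool_latent, pool_latent_with_grad)
from .nn import Adam, poly_decay

logger = logging.getLogger(__name__)

_SPLIT_NAMES = ("train", "val", "test")


# ---------------------------------------------------------------------------
# patient-level split


def _deviation(counts: np.ndarray, targets: np.ndarray) -> float:
    return float(np.abs(counts - targets).sum())


def split_by_patient(manifest: DatasetManifest, spec: SplitSpec | None = None,
                     rng: np.random.Generator | None = None) -> DatasetManifest:
    """Assign whole patients to train/val/test approximating the image-count
    ratio; no patient ever spans two splits.

    For up to 9 patients the assignment minimizing the absolute deviation
    from the target image counts is found exhaustively (ties broken by the
    rng); for more patients a greedy largest-first placement is used.
    """
    spec = spec if spec is not None else SplitSpec()
    rng = rng if rng is not None else np.random.default_rng(0)
    patients = manifest.patients()
    if len(patients) < 3:
        raise ValueError("patient-level split needs at least 3 patients")
    counts = {p: 0 for p in patients}
    for r in manifest.records:
        counts[r.patient_id] += 1
    total = sum(counts.values())
    fracs = np.asarray(spec.ratio, dtype=float)
    fracs /= fracs.sum()
    targets = fracs * total

    if len(patients) <= 9:
        assignment = _split_exhaustive(patients, counts, targets, rng)
    else:
        assignment = _split_greedy(patients, counts, targets, rng)
    return manifest.with_splits(assignment)


def _split_exhaustive(patients, counts, targets, rng):
    best_dev = np.inf
    best: list[tuple[int, ...]] = []
    cvec = np.array([counts[p] for p in patients], dtype=float)
    for combo in itertools.product(range(3), repeat=len(patients)):
        lab = np.asarray(combo)
        if len(set(combo)) < 3:      # every split must receive >= 1 patient
            continue
        c = np.array([cvec[lab == s].sum() for s in range(3)])
        dev = _deviation(c, targets)
        if dev < best_dev - 1e-12:
            best_dev, best = dev, [combo]
        elif dev <= best_dev + 1e-12:
            best.append(combo)
    chosen = best[rng.integers(len(best))]
    return {p: _SPLIT_NAMES[s] for p, s in zip(patients, chosen)}


def _split_greedy(patients, counts, targets, rng):
    order = list(patients)
    rng.shuffle(order)
    order.sort(key=lambda p: -counts[p])         # stable: rng breaks ties
    filled = np.zeros(3)
    assignment: dict[str, str] = {}
    for p in order:
        deficits = targets - filled
        s = int(np.argmax(deficits))
        assignment[p] = _SPLIT_NAMES[s]
        filled[s] += counts[p]
    return assignment


# ---------------------------------------------------------------------------
# augmentation and array loading


def rotate_pair(image: np.ndarray, mask: np.ndarray, angle_deg: float):
    """Rotate both by the same angle: image bilinearly, mask nearest-neighbor
    (stays binary); pixels rotated in from outside the frame are 0."""
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    if angle_deg == 0.0:
        return image.copy(), mask.copy()
    img = ndimage.rotate(image, angle_deg, reshape=False, order=1,
                         mode="constant", cval=0.0)
    msk = ndimage.rotate(mask.astype(np.uint8), angle_deg, reshape=False, order=0,
                         mode="constant", cval=0)
    return np.clip(img, 0.0, 1.0), msk


def augment_pair(image: np.ndarray, mask: np.ndarray, cfg: TrainConfig,
                 rng: np.random.Generator):
    """Online augmentation: one random rotation in ``cfg.rot_range_deg``."""
    angle = float(rng.uniform(*cfg.rot_range_deg))
    return rotate_pair(image, mask, angle)


def _resize(arr: np.ndarray, size: tuple[int, int], order: int) -> np.ndarray:
    if arr.shape == tuple(size):
        return arr
    zoom = (size[0] / arr.shape[0], size[1] / arr.shape[1])
    out = ndimage.zoom(arr, zoom, order=order, mode="nearest", grid_mode=True)
    return out[:size[0], :size[1]]


def load_split_arrays(manifest: DatasetManifest, split: str,
                      size: tuple[int, int]):
    """Images (N,1,h,w) in [0,1] and masks (N,h,w) in {0,1} for one split."""
    recs = manifest.subset(split)
    imgs, msks = [], []
    for r in recs:
        img = read_image_png(manifest.resolve(r.image_path))
        msk = read_mask_png(manifest.resolve(r.mask_path))
        imgs.append(_resize(img, size, order=1))
        msks.append(_resize(msk, size, order=0))
    if not recs:
        return np.zeros((0, 1, *size)), np.zeros((0, *size), dtype=np.uint8), recs
    return (np.stack(imgs)[:, None].astype(np.float32),
            np.stack(msks).astype(np.uint8), recs)


def _batches(n: int, batch_size: int, steps: int, rng: np.random.Generator):
    """Yield ``steps`` index batches, reshuffling each epoch."""
    produced = 0
    while produced < steps:
        order = rng.permutation(n)
        for start in range(0, n - batch_size + 1, batch_size):
            if produced >= steps:
                return
            yield order[start:start + batch_size]
            produced += 1
        if n < batch_size:   # tiny dataset: sample with replacement
            yield rng.integers(0, n, size=batch_size)
            produced += 1


def _check_finite(value: float, step: int, what: str) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"{what} diverged (non-finite loss) at step {step}")


# ---------------------------------------------------------------------------
# stage 1: mask auto-encoder


def train_reconstruction(manifest: DatasetManifest, net_cfg: NetworkConfig,
                         train_cfg: TrainConfig):
    """Train the mask auto-encoder with mean-L1 reconstruction loss.

    Returns ``(recon_net, history)``; ``history['l1']`` holds the per-step
    training loss.  With ``recon_steps == 0`` the freshly initialized
    network is returned untouched.
    """
    ss = np.random.SeedSequence(train_cfg.seed)
    init_rng, data_rng, aug_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    net = ReconNetwork(net_cfg, init_rng)
    _, masks, _ = load_split_arrays(manifest, "train", train_cfg.input_size)
    if masks.shape[0] == 0:
        raise ValueError("train split is empty")
    history: dict[str, list] = {"step": [], "l1": [], "lr": []}
    steps = train_cfg.recon_steps
    if steps == 0:
        return net, history
    opt = Adam(net.trainable_parameters(), lr=train_cfg.lr_init, beta1=train_cfg.beta1)
    net.train()
    for step, idx in enumerate(_batches(len(masks), train_cfg.batch_size, steps, data_rng)):
        mb = np.stack([
            augment_pair(masks[i].astype(np.float64), masks[i], train_cfg, aug_rng)[1]
            for i in idx
        ])[:, None]
        net.zero_grad()
        recon, _ = net.forward(mb, validate=False)
        loss, grad = L.l1_reconstruction_loss(recon, mb.astype(recon.dtype), return_grad=True)
        _check_finite(loss, step, "reconstruction training")
        net.backward(grad.astype(recon.dtype))
        lr = poly_decay(train_cfg.lr_init, step, steps, train_cfg.lr_power)
        opt.step(lr)
        history["step"].append(step)
        history["l1"].append(loss)
        history["lr"].append(lr)
        if step % 50 == 0:
            logger.info("recon step=%d l1=%.4f lr=%.2e", step, loss, lr)
    return net, history


def reconstruction_heldout_metrics(net: ReconNetwork, manifest: DatasetManifest,
                                   split: str, size: tuple[int, int],
                                   threshold: float = 0.5):
    """Held-out per-pixel L1 and Dice of the thresholded reconstruction."""
    _, masks, _ = load_split_arrays(manifest, split, size)
    net.eval()
    l1s, dices = [], []
    for i in range(0, len(masks), 8):
        mb = masks[i:i + 8][:, None].astype(np.float32)
        recon, _ = net.forward(mb, validate=False)
        for j in range(mb.shape[0]):
            gt = masks[i + j]
            l1s.append(L.l1_reconstruction_loss(recon[j, 0], gt.astype(recon.dtype)))
            pred = (recon[j, 0] > threshold).astype(np.uint8)
            dices.append(M.dice(M.confusion_counts(pred, gt)))
    net.train()
    return float(np.mean(l1s)), float(np.mean(dices))


# ---------------------------------------------------------------------------
# stage 2: segmentation with latent alignment


def _val_cosine_median(seg: SegNetwork, recon: ReconNetwork,
                       val_imgs: np.ndarray, val_msks: np.ndarray) -> float:
    """Median over validation images of cos(q, k+): pooled image latent vs
    pooled frozen mask latent."""
    seg.eval()
    cosines = []
    for i in range(0, len(val_imgs), 8):
        xb = val_imgs[i:i + 8]
        mb = val_msks[i:i + 8][:, None].astype(np.float32)
        _, latent = seg(xb)
        q = pool_latent(latent)
        k = pool_latent(recon.encode(mb))
        cosines.extend((q * k).sum(axis=1).tolist())
    seg.train()
    return float(np.median(cosines))


def _val_dice(seg: SegNetwork, imgs: np.ndarray, msks: np.ndarray) -> float:
    seg.eval()
    dices = []
    for i in range(0, len(imgs), 8):
        logits, _ = seg(imgs[i:i + 8])
        prob = L.softmax(logits, axis=1)[:, 1]
        for j in range(prob.shape[0]):
            pred = (prob[j] > 0.5).astype(np.uint8)
            dices.append(M.dice(M.confusion_counts(pred, msks[i + j])))
    seg.train()
    return float(np.mean(dices))


def _apply_prior_bias(seg: SegNetwork, masks: np.ndarray) -> None:
    """Class-prior initialization of the segmentation head: start the
    foreground/background logit gap at the empirical foreground log-odds of
    the training masks, so early optimization is spent on shape rather than
    on finding the base rate."""
    rate = float(np.clip(masks.mean(), 1e-4, 1.0 - 1e-4))
    b = np.log(rate / (1.0 - rate))
    seg.decoder.head.bias.data[0] = -0.5 * b
    seg.decoder.head.bias.data[1] = +0.5 * b


def _prepare_stage2(manifest, train_cfg):
    imgs, msks, _ = load_split_arrays(manifest, "train", train_cfg.input_size)
    if imgs.shape[0] == 0:
        raise ValueError("train split is empty")
    val_imgs, val_msks, _ = load_split_arrays(manifest, "val", train_cfg.input_size)
    return imgs, msks, val_imgs, val_msks


def train_segmentation(manifest: DatasetManifest, recon_net: ReconNetwork,
                       net_cfg: NetworkConfig, train_cfg: TrainConfig,
                       weights: LossWeights | None = None):
    """Stage 2: alternate one discriminator and one generator update per
    batch.  ``recon_net`` is frozen (bit-identical before and after).

    Returns ``(seg_net, discriminator, history)``.  With
    ``lambda_gan == lambda_cl == 0`` the alignment paths are skipped and the
    procedure reduces to plain CE+Dice training (the discriminator is still
    created, untouched).  The returned network carries the
    best-validation-Dice parameters when a validation split exists.
    """
    weights = weights if weights is not None else LossWeights()
    if train_cfg.batch_size < 2:
        raise ValueError("batch_size must be >= 2 (contrastive loss needs negatives)")
    ss = np.random.SeedSequence(train_cfg.seed)
    seg_rng, disc_rng, data_rng, aug_rng = (np.random.default_rng(c) for c in ss.spawn(4))

    imgs, msks, val_imgs, val_msks = _prepare_stage2(manifest, train_cfg)
    seg = SegNetwork(net_cfg, seg_rng)
    _apply_prior_bias(seg, msks)
    latent_sp = net_cfg.latent_spatial(train_cfg.input_size)
    disc = Discriminator(net_cfg, disc_rng, latent_spatial=latent_sp)
    align = weights.lambda_gan > 0 or weights.lambda_cl > 0

    recon_net.eval()
    opt_g = Adam(seg.trainable_parameters(), lr=train_cfg.lr_init, beta1=train_cfg.beta1)
    opt_d = Adam(disc.trainable_parameters(), lr=train_cfg.lr_init, beta1=train_cfg.beta1)

    history: dict[str, list] = {k: [] for k in
                                ("step", "l_seg", "l_ce", "l_dice", "l_gan_g",
                                 "l_cl", "l_la", "l_disc", "lr")}
    history["val_dice"] = []
    history["val_cosine"] = []
    if align and len(val_imgs):
        history["val_cosine"].append((0, _val_cosine_median(seg, recon_net, val_imgs, val_msks)))

    best = {"dice": -1.0, "state": None}
    seg.train()
    steps = train_cfg.steps
    b = train_cfg.batch_size
    for step, idx in enumerate(_batches(len(imgs), b, steps, data_rng)):
        pairs = [augment_pair(imgs[i, 0].astype(np.float64), msks[i], train_cfg, aug_rng)
                 for i in idx]
        xb = np.stack([p[0] for p in pairs])[:, None].astype(np.float32)
        gtb = np.stack([p[1] for p in pairs]).astype(np.int64)
        mb = gtb[:, None].astype(np.float32)
        lr = poly_decay(train_cfg.lr_init, step, steps, train_cfg.lr_power)

        l_disc = float("nan")
        if align:
            k_latent = recon_net.encode(mb)          # frozen shape prior
            _, f_latent = seg.encoder(xb)            # detached fake latents
            disc.zero_grad()
            scores = disc(np.concatenate([k_latent, f_latent]))
            l_disc, g_real, g_fake = L.lsgan_discriminator_loss(
                scores[:b], scores[b:], return_grad=True)
            _check_finite(l_disc, step, "discriminator")
            disc.backward(np.concatenate([g_real, g_fake]).astype(np.float32))
            opt_d.step(lr)

        seg.zero_grad()
        logits, latent = seg(xb)
        l_seg, dlogits, parts = L.segmentation_loss(logits, gtb, weights, return_grad=True)
        _check_finite(l_seg, step, "segmentation")
        l_gan_g = l_cl = l_la = float("nan")
        dlatent = None
        if align:
            scores_f = disc(latent)
            l_gan_g, dscore = L.lsgan_generator_loss(scores_f, return_grad=True)
            dlatent = weights.lambda_gan * disc.backward(dscore.astype(np.float32))
            q, pool_back = pool_latent_with_grad(latent)
            k = pool_latent(k_latent)
            l_cl, dq, _ = L.contrastive_loss(q, k, weights.tau, return_grad=True)
            dlatent = dlatent + weights.lambda_cl * pool_back(dq.astype(np.float32))
            l_la = L.latent_alignment_loss(l_gan_g, l_cl, weights)
            _check_finite(l_la, step, "latent alignment")
        seg.backward(dlogits.astype(np.float32), dlatent)
        opt_g.step(lr)

        history["step"].append(step)
        history["l_seg"].append(l_seg)
        history["l_ce"].append(parts["ce"])
        history["l_dice"].append(parts["dice"])
        history["l_gan_g"].append(l_gan_g)
        history["l_cl"].append(l_cl)
        history["l_la"].append(l_la)
        history["l_disc"].append(l_disc)
        history["lr"].append(lr)

        last = step == steps - 1
        if len(val_imgs) and (last or (step + 1) % train_cfg.eval_interval == 0):
            vd = _val_dice(seg, val_imgs, val_msks)
            history["val_dice"].append((step + 1, vd))
            if align:
                history["val_cosine"].append(
                    (step + 1, _val_cosine_median(seg, recon_net, val_imgs, val_msks)))
            if vd > best["dice"]:
                best = {"dice": vd, "state": seg.state_dict()}
            logger.info("seg step=%d l_seg=%.4f l_la=%s val_dice=%.4f lr=%.2e",
                        step, l_seg, f"{l_la:.4f}" if align else "off", vd, lr)
    if best["state"] is not None:
        seg.load_state_dict(best["state"])
    seg.eval()
    return seg, disc, history


def train_segmentation_baseline(manifest: DatasetManifest, net_cfg: NetworkConfig,
                                train_cfg: TrainConfig,
                                weights: LossWeights | None = None):
    """Plain CE+Dice trainer with no alignment machinery at all — the
    ablation configuration with the adversarial and contrastive paths
    removed.  Seeded identically to :func:`train_segmentation`, so with
    ``lambda_gan = lambda_cl = 0`` the two produce bit-identical updates."""
    weights = weights if weights is not None else LossWeights(lambda_gan=0.0, lambda_cl=0.0)
    ss = np.random.SeedSequence(train_cfg.seed)
    seg_rng, _disc_rng, data_rng, aug_rng = (np.random.default_rng(c) for c in ss.spawn(4))
    imgs, msks, val_imgs, val_msks = _prepare_stage2(manifest, train_cfg)
    seg = SegNetwork(net_cfg, seg_rng)
    _apply_prior_bias(seg, msks)
    opt_g = Adam(seg.trainable_parameters(), lr=train_cfg.lr_init, beta1=train_cfg.beta1)
    history: dict[str, list] = {"step": [], "l_seg": [], "l_ce": [], "l_dice": [],
                                "lr": [], "val_dice": []}
    best = {"dice": -1.0, "state": None}
    seg.train()
    steps = train_cfg.steps
    for step, idx in enumerate(_batches(len(imgs), train_cfg.batch_size, steps, data_rng)):
        pairs = [augment_pair(imgs[i, 0].astype(np.float64), msks[i], train_cfg, aug_rng)
                 for i in idx]
        xb = np.stack([p[0] for p in pairs])[:, None].astype(np.float32)
        gtb = np.stack([p[1] for p in pairs]).astype(np.int64)
        lr = poly_decay(train_cfg.lr_init, step, steps, train_cfg.lr_power)
        seg.zero_grad()
        logits, _ = seg(xb)
        l_seg, dlogits, parts = L.segmentation_loss(logits, gtb, weights, return_grad=True)
        _check_finite(l_seg, step, "segmentation")
        seg.backward(dlogits.astype(np.float32), None)
        opt_g.step(lr)
        history["step"].append(step)
        history["l_seg"].append(l_seg)
        history["l_ce"].append(parts["ce"])
        history["l_dice"].append(parts["dice"])
        history["lr"].append(lr)
        last = step == steps - 1
        if len(val_imgs) and (last or (step + 1) % train_cfg.eval_interval == 0):
            vd = _val_dice(seg, val_imgs, val_msks)
            history["val_dice"].append((step + 1, vd))
            if vd > best["dice"]:
                best = {"dice": vd, "state": seg.state_dict()}
    if best["state"] is not None:
        seg.load_state_dict(best["state"])
    seg.eval()
    return seg, history


# ---------------------------------------------------------------------------
# inference and evaluation


def predict(net: SegNetwork, image: np.ndarray, threshold: float = 0.5):
    """Segment one grayscale image.

    The image is resized to the network input size (bilinear), passed
    through the network, and the foreground softmax probability is resized
    back to the original resolution by nearest neighbor and thresholded.
    """
    h0, w0 = image.shape
    hin, win = net.cfg.input_size
    net.eval()
    x = _resize(np.asarray(image, dtype=np.float64), (hin, win), order=1)
    logits, _ = net(x[None, None].astype(np.float32))
    prob = L.softmax(logits, axis=1)[0, 1]
    prob = _resize(prob.astype(np.float64), (h0, w0), order=0)
    return prob, (prob > threshold).astype(np.uint8)


def evaluate_split(net: SegNetwork, manifest: DatasetManifest, split: str = "test",
                   out_csv: str | Path | None = None) -> M.MetricReport:
    """Predict every image of a split and score it at native resolution."""
    recs = manifest.subset(split)
    if not recs:
        raise ValueError(f"split {split!r} is empty")
    preds, rows = [], []
    for r in recs:
        img = read_image_png(manifest.resolve(r.image_path))
        gt = read_mask_png(manifest.resolve(r.mask_path))
        preds.append(predict(net, img))
        rows.append((r.image_path, r.thrombus, gt))
    return M.evaluate(preds, rows, out_csv=out_csv)


# ---------------------------------------------------------------------------
# checkpoints


_NET_KINDS = {"seg": SegNetwork, "recon": ReconNetwork, "disc": Discriminator}


def save_checkpoint(net, cfg: NetworkConfig, path: str | Path, kind: str) -> None:
    if kind not in _NET_KINDS:
        raise ValueError(f"kind must be one of {sorted(_NET_KINDS)}")
    meta = {"kind": kind, "depths": list(cfg.depths), "dims": list(cfg.dims),
            "num_classes": cfg.num_classes, "input_size": list(cfg.input_size),
            "in_channels": cfg.in_channels}
    state = net.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path):
    """Returns ``(net, cfg)`` rebuilt from a checkpoint file."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = NetworkConfig(depths=tuple(meta["depths"]), dims=tuple(meta["dims"]),
                        num_classes=meta["num_classes"],
                        input_size=tuple(meta["input_size"]),
                        in_channels=meta["in_channels"])
    kind = meta["kind"]
    if kind == "disc":
        net = Discriminator(cfg, np.random.default_rng(0))
    else:
        net = _NET_KINDS[kind](cfg, np.random.default_rng(0))
    net.load_state_dict(state)
    net.eval()
    return net, cfg
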