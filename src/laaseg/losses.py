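"""Objective functions: segmentation (CE + soft Dice), mask-reconstruction L1,
least-squares adversarial alignment, and the InfoNCE contrastive term.

Conventions
-----------
* ``logits`` are per-pixel class scores ``(C, H, W)`` or batched
  ``(N, C, H, W)``; the softmax is taken over the class axis internally.
* Cross-entropy and L1 are *averaged* over pixels so that loss magnitudes
  are resolution-independent; the soft-Dice ratio is scale-free by
  construction and its sums are left unnormalized.
* Each function optionally returns the analytic gradient with respect to
  its first argument (``return_grad=True``); the gradients are what the
  training loop feeds back through the networks.
"""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _batched(logits: np.ndarray) -> np.ndarray:
    if logits.ndim == 3:
        return logits[None]
    if logits.ndim == 4:
        return logits
    raise ValueError(f"logits must be (C,H,W) or (N,C,H,W), got {logits.shape}")


def _batched_mask(gt: np.ndarray, n: int) -> np.ndarray:
    if gt.ndim == 2:
        gt = gt[None]
    if gt.ndim != 3 or gt.shape[0] != n:
        raise ValueError(f"mask batch shape {gt.shape} does not match logits batch {n}")
    return gt


def cross_entropy_loss(logits: np.ndarray, gt: np.ndarray, num_classes: int = 2,
                       return_grad: bool = False):
    """Per-pixel multi-class cross-entropy, averaged over all pixels.

    ``gt`` holds integer class labels; a label outside ``{0..C-1}`` is a
    validation error.
    """
    lg = _batched(logits)
    n, c, h, w = lg.shape
    if c != num_classes:
        raise ValueError(f"logits have {c} classes, expected {num_classes}")
    gtb = _batched_mask(gt, n)
    labels = gtb.astype(np.int64)
    if labels.min() < 0 or labels.max() >= num_classes:
        raise ValueError("ground-truth labels outside {0..C-1}")
    # stable log-softmax
    z = lg - lg.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    ni, hi, wi = np.ogrid[:n, :h, :w]
    picked = logp[ni, labels, hi, wi]
    npix = n * h * w
    loss = float(-picked.sum() / npix)
    if not return_grad:
        return loss
    p = np.exp(logp)
    grad = p.copy()
    grad[ni, labels, hi, wi] -= 1.0
    grad /= npix
    if logits.ndim == 3:
        grad = grad[0]
    return loss, grad


def dice_loss(probs: np.ndarray, gt: np.ndarray, epsilon: float = 1e-6,
              return_grad: bool = False):
    """Soft Dice loss ``1 - (2*sum(p*g)+eps) / (sum(p^2)+sum(g^2)+eps)``.

    ``probs`` is the foreground-probability map (same shape as ``gt``); for
    batches the loss is the mean of per-sample Dice losses.
    """
    p = np.asarray(probs, dtype=np.result_type(probs, np.float32))
    g = np.asarray(gt, dtype=p.dtype)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs gt {g.shape}")
    if p.ndim == 2:
        p, g, squeeze = p[None], g[None], True
    else:
        squeeze = False
    axes = tuple(range(1, p.ndim))
    inter = (p * g).sum(axis=axes)
    denom = (p * p).sum(axis=axes) + (g * g).sum(axis=axes) + epsilon
    ratio = (2.0 * inter + epsilon) / denom
    losses = 1.0 - ratio
    loss = float(losses.mean())
    if not return_grad:
        return loss
    nb = p.shape[0]
    shp = (nb,) + (1,) * (p.ndim - 1)
    grad = -(2.0 * g * denom.reshape(shp) - (2.0 * inter + epsilon).reshape(shp) * 2.0 * p) \
        / (denom.reshape(shp) ** 2) / nb
    if squeeze:
        grad = grad[0]
    return loss, grad


def segmentation_loss(logits: np.ndarray, gt: np.ndarray, weights,
                      return_grad: bool = False):
    """Weighted CE + soft-Dice; the Dice term acts on the softmax foreground
    channel so the whole objective is differentiable in the logits.

    Returns ``loss`` or ``(loss, dlogits, parts)`` where ``parts`` is a dict
    with the unweighted CE and Dice values.
    """
    lg = _batched(logits)
    gtb = _batched_mask(np.asarray(gt), lg.shape[0])
    ce_out = cross_entropy_loss(lg, gtb, weights.num_classes, return_grad=return_grad)
    p = softmax(lg, axis=1)
    pfg = p[:, 1]
    dice_out = dice_loss(pfg, gtb.astype(pfg.dtype), weights.epsilon, return_grad=return_grad)
    if not return_grad:
        loss = weights.lambda_ce * ce_out + weights.lambda_dice * dice_out
        return float(loss)
    ce_val, dce = ce_out
    dice_val, dpfg = dice_out
    # route dDice/dp_fg through the softmax: dz_c = p_fg*(delta_{c,1}-p_c)*dpfg
    dz_dice = -pfg[:, None] * p * dpfg[:, None]
    dz_dice[:, 1] += pfg * dpfg
    dlogits = weights.lambda_ce * dce + weights.lambda_dice * dz_dice
    if logits.ndim == 3:
        dlogits = dlogits[0]
    loss = float(weights.lambda_ce * ce_val + weights.lambda_dice * dice_val)
    return loss, dlogits, {"ce": ce_val, "dice": dice_val}


def l1_reconstruction_loss(recon: np.ndarray, gt_mask: np.ndarray,
                           return_grad: bool = False):
    """Mean absolute difference between reconstruction and mask."""
    r = np.asarray(recon)
    g = np.asarray(gt_mask, dtype=r.dtype)
    if r.shape != g.shape:
        raise ValueError(f"shape mismatch: recon {r.shape} vs mask {g.shape}")
    diff = r - g
    loss = float(np.abs(diff).mean())
    if not return_grad:
        return loss
    grad = np.sign(diff) / diff.size
    return loss, grad


def lsgan_discriminator_loss(d_real: np.ndarray, d_fake: np.ndarray,
                             return_grad: bool = False):
    """Least-squares discriminator objective:
    ``0.5*mean((D(k)-1)^2) + 0.5*mean(D(G(x))^2)``."""
    dr = np.asarray(d_real, dtype=float).ravel()
    df = np.asarray(d_fake, dtype=float).ravel()
    if dr.size == 0 or df.size == 0:
        raise ValueError("empty score batch")
    loss = float(0.5 * np.mean((dr - 1.0) ** 2) + 0.5 * np.mean(df ** 2))
    if not return_grad:
        return loss
    g_real = (dr - 1.0) / dr.size
    g_fake = df / df.size
    return loss, g_real, g_fake


def lsgan_generator_loss(d_fake: np.ndarray, return_grad: bool = False):
    """Least-squares generator objective: ``0.5*mean((D(G(x))-1)^2)``."""
    df = np.asarray(d_fake, dtype=float).ravel()
    if df.size == 0:
        raise ValueError("empty score batch")
    loss = float(0.5 * np.mean((df - 1.0) ** 2))
    if not return_grad:
        return loss
    return loss, (df - 1.0) / df.size


def contrastive_loss(q_batch: np.ndarray, k_batch: np.ndarray, tau: float = 0.1,
                     return_grad: bool = False):
    """InfoNCE over pooled latent vectors.

    ``q_batch[i]`` (image latent) is pulled toward ``k_batch[i]`` (its mask
    latent) and pushed from the other B-1 mask latents; the denominator sums
    over all B in-batch keys.  Computed with a max-shifted log-sum-exp; the
    batch mean is returned.
    """
    q = np.asarray(q_batch, dtype=float)
    k = np.asarray(k_batch, dtype=float)
    if q.ndim != 2 or k.shape != q.shape:
        raise ValueError(f"q and k must be (B, d) with equal shapes, got {q.shape} / {k.shape}")
    b = q.shape[0]
    if b < 2:
        raise ValueError("contrastive loss needs batch size >= 2 (no negatives otherwise)")
    sims = q @ k.T / tau                                # (B, B); row i: q_i vs all k_j
    shift = sims.max(axis=1, keepdims=True)
    z = sims - shift
    lse = np.log(np.exp(z).sum(axis=1))                 # log-sum-exp per row
    pos = np.diag(z)
    losses = lse - pos
    loss = float(losses.mean())
    if not return_grad:
        return loss
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)  # row-softmax
    coeff = p - np.eye(b)
    dq = coeff @ k / tau / b
    dk = coeff.T @ q / tau / b                          # exact, though keys are frozen in training
    return loss, dq, dk


def latent_alignment_loss(gan_term: float, cl_term: float, weights) -> float:
    """Joint latent-space alignment objective:
    ``lambda_gan * L_GAN + lambda_cl * L_CL`` (generator-side GAN term)."""
    return float(weights.lambda_gan * gan_term + weights.lambda_cl * cl_term)
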