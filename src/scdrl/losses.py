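"""The four training objectives and their weighted sum.

All terms are *means* over the relevant units — labeled (cell, factor) pairs
for classification, unlabeled pairs for the entropy regularizer, cells for
the residual penalty, and cells (x genes for counts) for reconstruction — so
the weight defaults are independent of dataset size. This is a positive
rescaling of the corresponding per-cell sums and has the same minimizers for
a fixed label mask. Entropies and cross-entropies are in nats.

Each function accepts either plain numpy arrays (returning a float) or
autodiff :class:`~scdrl.autodiff.Tensor` inputs (returning a scalar tensor
through which gradients flow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .autodiff import Tensor, as_tensor
from .data import LabelTable

__all__ = [
    "LossBreakdown",
    "classification_loss",
    "entropy_loss",
    "residual_loss",
    "reconstruction_loss",
    "total_loss",
]


@dataclass(frozen=True)
class LossBreakdown:
    """Per-term values on the mean scale plus their weighted total."""

    cls: float
    ent: float
    res: float
    rec: float
    total: float


def _finish(value, had_tensor: bool):
    return value if had_tensor else float(value.data)


def _labels_and_mask(labels) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(labels, LabelTable):
        return labels.labels, labels.mask
    raise TypeError("labels must be a LabelTable")


def classification_loss(logits: list, labels: LabelTable):
    """Mean cross-entropy over labeled (cell, factor) pairs; 0 when unlabeled.

    ``logits[j]`` is the (n, K_j) logit matrix of factor ``j``'s encoder.
    """
    lab, mask = _labels_and_mask(labels)
    had_tensor = any(isinstance(l, Tensor) for l in logits)
    total = Tensor(0.0)
    n_pairs = 0
    for j, lj in enumerate(logits):
        lj = as_tensor(lj)
        K = lj.shape[1]
        col = lab[:, j]
        mj = mask[:, j].astype(np.float64)
        if np.any(col >= K):
            raise ValueError(f"label index >= K for factor {j}")
        if not mj.any():
            continue
        onehot = np.zeros((lab.shape[0], K))
        onehot[np.arange(lab.shape[0]), np.clip(col, 0, K - 1)] = 1.0
        onehot *= mj[:, None]  # zero rows for unlabeled cells
        ls = lj.log_softmax(axis=1)
        total = total + -(ls * onehot).sum()
        n_pairs += int(mj.sum())
    if n_pairs == 0:
        return _finish(Tensor(0.0), had_tensor)
    return _finish(total * (1.0 / n_pairs), had_tensor)


def entropy_loss(logits: list, mask: np.ndarray):
    """Mean Shannon entropy (nats) of predictions over unlabeled pairs."""
    mask = np.asarray(mask)
    had_tensor = any(isinstance(l, Tensor) for l in logits)
    total = Tensor(0.0)
    n_pairs = 0
    for j, lj in enumerate(logits):
        lj = as_tensor(lj)
        w = (1.0 - mask[:, j]).astype(np.float64)
        if not w.any():
            continue
        ls = lj.log_softmax(axis=1)
        p = ls.exp()
        ent = -(p * ls).sum(axis=1)  # p -> 0 limit handled: p*log p -> 0 smoothly
        total = total + (ent * w).sum()
        n_pairs += int(w.sum())
    if n_pairs == 0:
        return _finish(Tensor(0.0), had_tensor)
    return _finish(total * (1.0 / n_pairs), had_tensor)


def residual_loss(residuals):
    """Mean over cells of the squared l2 norm of the residual vector."""
    had_tensor = isinstance(residuals, Tensor)
    r = as_tensor(residuals)
    n = r.shape[0] if r.ndim == 2 else 1
    return _finish((r * r).sum() * (1.0 / n), had_tensor)


def reconstruction_loss(x, xhat, mode: str = "mse", theta=None):
    """Reconstruction error: MSE for normalized data, NB NLL for counts.

    mse
        Mean over cells of the mean-over-genes squared error.
    nb
        Mean over cells and genes of the negative-binomial negative
        log-likelihood with mean ``xhat`` and dispersion ``theta``
        (var = mu + mu^2/theta); ``x`` must be integral counts.
    """
    had_tensor = any(isinstance(v, Tensor) for v in (x, xhat, theta) if v is not None)
    x_arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
    xhat = as_tensor(xhat)
    if mode == "mse":
        diff = xhat - Tensor(x_arr)
        return _finish((diff * diff).mean() if diff.ndim == 1
                       else (diff * diff).sum() * (1.0 / diff.data.size), had_tensor)
    if mode == "nb":
        if not np.allclose(x_arr, np.round(x_arr)):
            raise ValueError("nb reconstruction requires integer counts")
        if theta is None:
            raise ValueError("nb reconstruction requires a dispersion theta")
        theta = as_tensor(theta)
        xt = Tensor(x_arr)
        # -log NB(x | mu, theta) with constants in x kept for an honest NLL
        log_t_mu = (theta + xhat).log()
        nll = (
            theta.lgamma()
            + Tensor(gammaln(x_arr + 1.0))
            - (theta + xt).lgamma()
            - theta * theta.log()
            + (theta + xt) * log_t_mu
            - xt * xhat.log()
        )
        return _finish(nll.sum() * (1.0 / nll.data.size), had_tensor)
    raise ValueError(f"unknown reconstruction mode {mode!r}")


def total_loss(cls, ent, res, rec, lambda1: float, lambda2: float,
               lambda3: float) -> LossBreakdown:
    """Weighted sum: total = cls + lambda1*ent + lambda2*res + lambda3*rec."""
    if min(lambda1, lambda2, lambda3) < 0:
        raise ValueError("loss weights must be non-negative")
    vals = [float(v) for v in (cls, ent, res, rec)]
    total = vals[0] + lambda1 * vals[1] + lambda2 * vals[2] + lambda3 * vals[3]
    return LossBreakdown(cls=vals[0], ent=vals[1], res=vals[2], rec=vals[3],
                         total=total)
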