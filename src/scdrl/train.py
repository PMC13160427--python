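"""Semi-supervised optimization loop, prediction and latent extraction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .data import ExpressionDataset, FactorSpec, LabelTable
from .losses import (LossBreakdown, classification_loss, entropy_loss,
                     reconstruction_loss, residual_loss, total_loss)
from .model import ModelConfig, SCDRLModel

__all__ = ["TrainConfig", "FitResult", "fit", "predict_factors", "extract_latent"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; lambdas weight entropy/residual/reconstruction."""

    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    lambda1: float = 0.5
    lambda2: float = 0.01
    lambda3: float = 1.0
    seed: int = 0
    early_stop_patience: int = 0  # 0 disables early stopping

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid optimization settings")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("lambdas must be non-negative")


@dataclass
class FitResult:
    model: SCDRLModel
    history: list[LossBreakdown] = field(default_factory=list)
    label_mask_seed: int = 0


def _check_compat(ds: ExpressionDataset, mcfg: ModelConfig) -> None:
    if mcfg.reconstruction == "mse" and ds.layer != "lognorm":
        raise ValueError("mse reconstruction requires a lognorm dataset")
    if mcfg.reconstruction == "nb" and ds.layer != "raw_counts":
        raise ValueError("nb reconstruction requires a raw_counts dataset")


def fit(ds: ExpressionDataset, labels: LabelTable, spec: FactorSpec,
        mcfg: ModelConfig, tcfg: TrainConfig) -> FitResult:
    """Train by mini-batch Adam on the weighted semi-supervised objective.

    Labeled and unlabeled cells are mixed in every batch; residual noise
    injection is active. Fully reproducible given the model and training
    seeds. The per-epoch history records all four terms even when their
    weight is zero (zero-weight terms do not enter the total).
    """
    _check_compat(ds, mcfg)
    if labels.n_cells != ds.n_cells or labels.k != spec.k:
        raise ValueError("label table shape does not match dataset / spec")
    for j, f in enumerate(spec.factors):
        seen = set(labels.labels[labels.mask[:, j] == 1, j].tolist())
        missing = set(range(f.n_categories)) - seen
        if missing:
            warnings.warn(
                f"factor {f.name!r}: categories {sorted(missing)} have no labeled "
                "cells and receive no supervised signal", stacklevel=2)

    model = SCDRLModel(ds.n_genes, mcfg)
    if labels.mask.sum() == 0 and tcfg.lambda3 == 0:
        warnings.warn("no labels and lambda3=0: objective has no data signal",
                      stacklevel=2)
    opt = Adam(model.parameters(), lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed)
    X = ds.matrix
    n = ds.n_cells
    bs = min(tcfg.batch_size, n)
    history: list[LossBreakdown] = []
    best = np.inf
    stale = 0
    for _epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        sums = np.zeros(4)
        weights = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            out = model.forward(X[idx], labels=labels.labels[idx],
                                mask=labels.mask[idx], training=True, rng=rng)
            batch_labels = LabelTable(labels.labels[idx], labels.mask[idx])
            cls = classification_loss(out["logits"], batch_labels)
            ent = entropy_loss(out["logits"], labels.mask[idx])
            res = residual_loss(out["residual"])
            if mcfg.reconstruction == "mse":
                rec = reconstruction_loss(X[idx], out["recon"]["xhat"], mode="mse")
            else:
                rec = reconstruction_loss(X[idx], out["recon"]["mu"], mode="nb",
                                          theta=out["recon"]["theta"])
            parts = [cls, ent, res, rec]
            lams = [1.0, tcfg.lambda1, tcfg.lambda2, tcfg.lambda3]
            graph_total = Tensor(0.0)
            for lam, part in zip(lams, parts):
                if lam > 0 and isinstance(part, Tensor):
                    graph_total = graph_total + part * lam
            opt.zero_grad()
            graph_total.backward()
            opt.step()
            sums += len(idx) * np.array([float(p) for p in parts])
            weights += len(idx)
        means = sums / weights
        history.append(total_loss(*means, tcfg.lambda1, tcfg.lambda2, tcfg.lambda3))
        if tcfg.early_stop_patience > 0:
            if history[-1].total < best - 1e-9:
                best = history[-1].total
                stale = 0
            else:
                stale += 1
                if stale >= tcfg.early_stop_patience:
                    break
    return FitResult(model=model, history=history, label_mask_seed=tcfg.seed)


def _batched_forward(model: SCDRLModel, ds: ExpressionDataset,
                     labels: LabelTable | None = None, batch: int = 2048):
    if ds.n_genes != model.n_genes:
        raise ValueError("gene space of dataset does not match the trained model")
    outs = []
    for start in range(0, ds.n_cells, batch):
        sl = slice(start, start + batch)
        lab = labels.labels[sl] if labels is not None else None
        msk = labels.mask[sl] if labels is not None else None
        outs.append(model.forward(ds.matrix[sl], labels=lab, mask=msk,
                                  training=False))
    return outs


def predict_factors(model: SCDRLModel, ds: ExpressionDataset) -> LabelTable:
    """Argmax category per cell per factor (ties break to the lowest index)."""
    outs = _batched_forward(model, ds)
    preds = []
    for j in range(model.spec.k):
        lj = np.vstack([o["logits"][j].data for o in outs])
        preds.append(np.argmax(lj, axis=1))
    labels = np.stack(preds, axis=1)
    return LabelTable.full(labels, model.spec.n_categories)


def extract_latent(model: SCDRLModel, ds: ExpressionDataset,
                   use_labels: LabelTable | None = None
                   ) -> tuple[np.ndarray, dict[str, tuple[int, int]]]:
    """Concatenated factor codes + residual, noise off.

    When ``use_labels`` is given, cells with a known label for a factor use
    the hard one-hot composition for that factor's code. Returns the
    (n, sum(code_dims) + residual_dim) matrix and a map
    ``factor name -> (start, stop)`` column range (plus ``"residual"``).
    """
    outs = _batched_forward(model, ds, labels=use_labels)
    blocks = []
    column_map: dict[str, tuple[int, int]] = {}
    start = 0
    for j, f in enumerate(model.spec.factors):
        block = np.vstack([o["codes"][j].data for o in outs])
        blocks.append(block)
        column_map[f.name] = (start, start + f.code_dim)
        start += f.code_dim
    resid = np.vstack([o["residual"].data for o in outs])
    blocks.append(resid)
    column_map["residual"] = (start, start + model.spec.residual_dim)
    return np.hstack(blocks), column_map
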